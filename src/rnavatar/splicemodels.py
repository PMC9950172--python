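"""Splice-site strength models: weight matrix, first-order Markov, score tables.

Donor (5'ss) windows are 9-mers (3 exonic + 6 intronic bases) and acceptor
(3'ss) windows are 23-mers (20 intronic + 3 exonic), the MaxEntScan
conventions. Two trainable model families are provided:

* WMM — position-independent per-position base probabilities;
* MM1 — first-order Markov chain: a marginal at position 1 and per-position
  conditionals on the previous base.

Scores are log2 odds against a background (uniform 0.25 by default), so a
model equal to its background scores every window 0, and the WMM score is
additive over positions. A pre-computed k-mer score table (``MAXENT_TABLE``)
can be loaded to stand in for a full maximum-entropy model, whose parameters
are published rather than refit here. ``delta_score`` (alt minus ref) is the
quantity of interest for variants: negative means the variant weakens the
site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_WINDOW = 9  # 3 exonic + 6 intronic
ACCEPTOR_WINDOW = 23  # 20 intronic + 3 exonic
SITE_TYPES = ("donor_5ss", "acceptor_3ss")
MODEL_KINDS = ("WMM", "MM1", "MAXENT_TABLE")


def window_length(site_type: str) -> int:
    if site_type == "donor_5ss":
        return DONOR_WINDOW
    if site_type == "acceptor_3ss":
        return ACCEPTOR_WINDOW
    raise ValueError(f"site_type must be one of {SITE_TYPES}")


def _encode(seq: str, expected_len: int) -> np.ndarray:
    if len(seq) != expected_len:
        raise ValueError(
            f"window {seq!r} has length {len(seq)}, expected {expected_len}"
        )
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()])
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r} in window {seq!r}") from None


@dataclass
class SpliceSiteModel:
    """A trained (or loaded) splice-site strength model.

    For WMM, ``matrix`` is (L, 4) positional probabilities. For MM1, ``matrix``
    holds the position-1 marginal in row 0 and ``conditionals`` is
    (L-1, 4, 4): conditionals[i, prev, b] = P(base at i+2 = b | base at i+1 = prev).
    For MAXENT_TABLE, ``table`` maps the full k-mer to its score.
    """

    site_type: str
    model_kind: str
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    matrix: np.ndarray | None = None
    conditionals: np.ndarray | None = None
    table: dict | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"site_type must be one of {SITE_TYPES}")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background probabilities must sum to 1")
        if self.matrix is not None:
            sums = self.matrix.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("positional probabilities must sum to 1 +- 1e-9")
        if self.conditionals is not None:
            if not np.allclose(self.conditionals.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError("conditional probabilities must sum to 1 +- 1e-9")

    @property
    def window(self) -> int:
        return window_length(self.site_type)


def train_model(
    seqs: list,
    site_type: str,
    model_kind: str = "WMM",
    pseudocount: float = 0.25,
    background=None,
) -> SpliceSiteModel:
    """Fit a WMM or MM1 from aligned site windows with additive pseudocounts.

    WMM positional probability = (count + pseudocount) / (n + 4 * pseudocount);
    MM1 conditionals are the analogous per-(position, previous-base) ratios.
    MAXENT_TABLE models are loaded, not trained.
    """
    if model_kind == "MAXENT_TABLE":
        raise ValueError("MAXENT_TABLE parameters are loaded, not trained")
    if model_kind not in ("WMM", "MM1"):
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    if not seqs:
        raise ValueError("training requires at least one window")
    L = window_length(site_type)
    enc = np.stack([_encode(s, L) for s in seqs])
    n = len(seqs)

    counts = np.zeros((L, 4))
    for i in range(L):
        counts[i] = np.bincount(enc[:, i], minlength=4)
    matrix = (counts + pseudocount) / (n + 4 * pseudocount)

    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if model_kind == "WMM":
        return SpliceSiteModel(site_type, "WMM", background=bg, matrix=matrix)

    cond_counts = np.zeros((L - 1, 4, 4))
    for i in range(L - 1):
        for prev, cur in zip(enc[:, i], enc[:, i + 1]):
            cond_counts[i, prev, cur] += 1
    totals = cond_counts.sum(axis=-1, keepdims=True)
    conditionals = (cond_counts + pseudocount) / (totals + 4 * pseudocount)
    return SpliceSiteModel(
        site_type, "MM1", background=bg, matrix=matrix, conditionals=conditionals
    )


def load_maxent_table(path: str, site_type: str) -> SpliceSiteModel:
    """Load an externally supplied k-mer score table (TSV: kmer<TAB>score)."""
    L = window_length(site_type)
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kmer, score = line.split("\t")
            _encode(kmer, L)
            table[kmer.upper()] = float(score)
    return SpliceSiteModel(site_type, "MAXENT_TABLE", table=table)


def score_site(model: SpliceSiteModel, seq: str) -> float:
    """Log2-odds strength score of one site window under the model."""
    seq = seq.upper()
    if model.model_kind == "MAXENT_TABLE":
        _encode(seq, model.window)
        if seq not in model.table:
            raise KeyError(f"table incomplete: no score for k-mer {seq!r}")
        return model.table[seq]
    enc = _encode(seq, model.window)
    bg = model.background
    score = np.log2(model.matrix[0, enc[0]] / bg[enc[0]])
    if model.model_kind == "WMM":
        for i in range(1, model.window):
            score += np.log2(model.matrix[i, enc[i]] / bg[enc[i]])
    else:  # MM1: conditionals for positions >= 2
        for i in range(1, model.window):
            p = model.conditionals[i - 1, enc[i - 1], enc[i]]
            score += np.log2(p / bg[enc[i]])
    return float(score)


def delta_score(model: SpliceSiteModel, ref_window: str, alt_window: str) -> float:
    """Score change (alt - ref); negative means the variant weakens the site."""
    ref_score = score_site(model, ref_window)  # validates ref before alt scored
    alt_score = score_site(model, alt_window)
    return alt_score - ref_score


def is_splice_weakening(deltas: dict) -> bool:
    """Interpretive rule: weakened under ALL available model kinds (delta < 0)."""
    if not deltas:
        return False
    return all(d < 0 for d in deltas.values())
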