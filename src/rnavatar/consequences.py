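"""Coding-consequence prediction: frameshifts, in-frame deletions, splice calls.

Frameshift consequences follow the HGVS ``fs*N`` convention: the first altered
residue (the first position where the mutant translation departs from the
reference protein) is position 1, and N is the position of the new stop codon
in that count. A deletion whose length is divisible by 3 is an in-frame
deletion, never a frameshift. Splice-site classification assigns deletions and
substitutions touching the first two intronic bases after an exon to the donor
(+1/+2) and the last two before an exon to the acceptor (-1/-2), after HGVS
3'-rule normalization — so a one-base deletion anywhere inside a homopolymer
run spanning an exon/intron boundary lands on the +1 donor position.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .transcripts import TranscriptModel, normalize_genomic_deletion, revcomp

CONSEQUENCE_KINDS = (
    "frameshift",
    "fs_no_stop",
    "inframe_deletion",
    "splice_donor_disruption",
    "splice_acceptor_region",
    "synonymous",
    "missense",
    "nonsense",
    "intronic",
    "deep_intronic",
)

SPLICE_REGION_NT = 25  # beyond this from any exon a variant is deep intronic


@dataclass(frozen=True)
class CodingConsequence:
    hgvs_c: str
    hgvs_p: str | None
    kind: str
    first_altered_residue: int | None = None
    stop_offset: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in CONSEQUENCE_KINDS:
            raise ValueError(f"unknown consequence kind {self.kind!r}")
        if self.first_altered_residue is not None and self.first_altered_residue < 1:
            raise ValueError("first_altered_residue is 1-based")


def cds_position_to_codon(n: int) -> int:
    """Codon index (1-based) containing CDS nucleotide n (1-based)."""
    if n < 1:
        raise ValueError("CDS positions are 1-based")
    return (n - 1) // 3 + 1


def _aa(code: str, style: str) -> str:
    if style == "one":
        return code
    return "Ter" if code == "*" else seq3(code)


def _translate(seq: str) -> str:
    return str(Seq(seq[: len(seq) // 3 * 3]).translate())


def predict_frameshift(
    tx: TranscriptModel, cds_del_start: int, del_len: int, aa_style: str = "one"
) -> CodingConsequence:
    """Consequence of deleting ``del_len`` nt at CDS position ``cds_del_start``.

    Translates from the first affected codon in the shifted frame until a stop
    codon; p. names use the one-letter style ("L524Tfs*3") by default, with
    ``aa_style='three'`` for the "Asp20Ilefs*51" style.
    """
    cds = tx.cds_sequence
    if cds_del_start < 1 or del_len < 1:
        raise ValueError("deletion coordinates are 1-based with positive length")
    if cds_del_start - 1 + del_len > len(cds):
        raise ValueError("deletion crosses the CDS/UTR boundary (unsupported)")
    if cds_del_start + del_len - 1 == cds_del_start:
        hgvs_c = f"c.{cds_del_start}del"
    else:
        hgvs_c = f"c.{cds_del_start}_{cds_del_start + del_len - 1}del"
    if del_len == 1:
        hgvs_c = f"c.{cds_del_start}del"

    if del_len % 3 == 0:
        return CodingConsequence(
            hgvs_c=hgvs_c,
            hgvs_p=None,
            kind="inframe_deletion",
            first_altered_residue=cds_position_to_codon(cds_del_start),
        )

    mutant = cds[: cds_del_start - 1] + cds[cds_del_start - 1 + del_len :]
    start_codon_idx = (cds_del_start - 1) // 3  # 0-based codon of first deleted base
    ref_prot = _translate(cds[start_codon_idx * 3 :])
    mut_prot = _translate(mutant[start_codon_idx * 3 :])

    # advance past any residues that happen to be conserved under the shift
    i = 0
    while i < len(mut_prot) and i < len(ref_prot) and mut_prot[i] == ref_prot[i]:
        if ref_prot[i] == "*":  # shifted translation still reaches the same stop
            break
        i += 1
    first_altered = start_codon_idx + i + 1
    ref_aa = ref_prot[i] if i < len(ref_prot) else "?"

    if i >= len(mut_prot):
        return CodingConsequence(
            hgvs_c=hgvs_c,
            hgvs_p=f"p.{_aa(ref_aa, aa_style)}{first_altered}fs*?",
            kind="fs_no_stop",
            first_altered_residue=first_altered,
        )
    mut_aa = mut_prot[i]
    if mut_aa == "*":
        return CodingConsequence(
            hgvs_c=hgvs_c,
            hgvs_p=f"p.{_aa(ref_aa, aa_style)}{first_altered}*",
            kind="nonsense",
            first_altered_residue=first_altered,
        )
    stop = mut_prot.find("*", i)
    if stop == -1:
        return CodingConsequence(
            hgvs_c=hgvs_c,
            hgvs_p=f"p.{_aa(ref_aa, aa_style)}{first_altered}{_aa(mut_aa, aa_style)}fs*?",
            kind="fs_no_stop",
            first_altered_residue=first_altered,
        )
    stop_offset = stop - i + 1  # first altered residue counts as 1
    return CodingConsequence(
        hgvs_c=hgvs_c,
        hgvs_p=(
            f"p.{_aa(ref_aa, aa_style)}{first_altered}"
            f"{_aa(mut_aa, aa_style)}fs*{stop_offset}"
        ),
        kind="frameshift",
        first_altered_residue=first_altered,
        stop_offset=stop_offset,
    )


def _exonic_snv_consequence(tx: TranscriptModel, t: int, alt_base: str) -> CodingConsequence:
    ref_base = tx.sequence[t]
    hgvs_c = f"c.{tx.c_position(t)}{ref_base}>{alt_base}"
    if not (tx.cds_start <= t < tx.cds_end):
        return CodingConsequence(hgvs_c, None, "synonymous")  # UTR: no protein change
    cds_pos = t - tx.cds_start  # 0-based
    codon_idx = cds_pos // 3
    codon = tx.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        return CodingConsequence(hgvs_c, None, "synonymous")
    offset = cds_pos % 3
    alt_codon = codon[:offset] + alt_base + codon[offset + 1 :]
    ref_aa, alt_aa = _translate(codon), _translate(alt_codon)
    if ref_aa == alt_aa:
        kind, hgvs_p = "synonymous", f"p.{ref_aa}{codon_idx + 1}="
    elif alt_aa == "*":
        kind, hgvs_p = "nonsense", f"p.{ref_aa}{codon_idx + 1}*"
    else:
        kind, hgvs_p = "missense", f"p.{ref_aa}{codon_idx + 1}{alt_aa}"
    return CodingConsequence(hgvs_p=hgvs_p, hgvs_c=hgvs_c, kind=kind,
                             first_altered_residue=codon_idx + 1)


def classify_splice_site_variant(
    tx: TranscriptModel, gstart: int, ref: str, alt: str
) -> CodingConsequence:
    """Classify a variant's relation to splice sites on a transcript.

    ``gstart`` is the 0-based genomic position of the first reference base;
    ``ref``/``alt`` describe a substitution (equal length 1) or a pure deletion
    (``alt == ''``). Deletions are 3'-normalized (HGVS rule) before
    classification so equivalent representations in a repeat run give one
    canonical call. Variants more than 25 nt from any exon are
    ``deep_intronic``; exonic substitutions fall through to coding-consequence
    calls.
    """
    is_deletion = alt == ""
    if not is_deletion and not (len(ref) == 1 and len(alt) == 1):
        raise ValueError("only substitutions and pure deletions are supported")
    if tx.genome is not None and tx.genome[gstart : gstart + len(ref)] != ref:
        raise ValueError(
            f"reference mismatch at {tx.chrom}:{gstart}: expected {ref!r}"
        )

    if is_deletion:
        gstart, length = normalize_genomic_deletion(
            tx, gstart, len(ref), mode="hgvs_right"
        )
        affected = range(gstart, gstart + length)
    else:
        length = 1
        affected = range(gstart, gstart + 1)

    located = [tx.locate_genomic(g) for g in affected]
    # donor disruption first: any affected base at intronic +1/+2
    for where, anchor, k in located:
        if where == "donor" and 1 <= k <= 2:
            c_anchor = tx.c_position(anchor)
            suffix = "del" if is_deletion else f"{ref}>{alt}"
            if is_deletion and length > 1:
                ks = [kk for w, _, kk in located if w == "donor"]
                pos = f"{c_anchor}+{min(ks)}_{c_anchor}+{max(ks)}"
            else:
                pos = f"{c_anchor}+{k}"
            return CodingConsequence(f"c.{pos}{suffix}", None, "splice_donor_disruption")
    for where, anchor, k in located:
        if where == "acceptor" and -2 <= k <= -1:
            c_anchor = tx.c_position(anchor)
            suffix = "del" if is_deletion else f"{ref}>{alt}"
            return CodingConsequence(
                f"c.{c_anchor}{k}{suffix}", None, "splice_acceptor_region"
            )

    if all(w == "exonic" for w, _, _ in located):
        if not is_deletion:
            # transcript-sense bases for '-' strand substitutions
            t = located[0][1]
            alt_t = alt if tx.strand == "+" else revcomp(alt)
            return _exonic_snv_consequence(tx, t, alt_t)
        tpos = sorted(located[_i][1] for _i in range(len(located)))
        cds_first = tpos[0] - tx.cds_start + 1
        if cds_first < 1 or tpos[-1] >= tx.cds_end:
            raise ValueError("exonic deletion crossing a CDS/UTR boundary (unsupported)")
        return predict_frameshift(tx, cds_first, length)

    distances = [abs(k) for w, _, k in located if w in ("donor", "acceptor")]
    if distances and min(distances) <= SPLICE_REGION_NT:
        return CodingConsequence("c.?", None, "intronic")
    return CodingConsequence("c.?", None, "deep_intronic")
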