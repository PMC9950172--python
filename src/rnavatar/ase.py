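"""Allele-specific expression and mosaicism statistics.

Quantifies reference/alternate read support at a variant site in DNA or RNA,
classifies zygosity (heterozygous / mosaic / homozygous) from an exact binomial
test against the germline-heterozygous expectation p = 0.5, and tests DNA-vs-RNA
allelic imbalance with a one-sided Fisher exact test. Depletion of the
alternate allele in RNA relative to DNA is the observable signature of
nonsense-mediated decay (NMD) acting on a premature-termination transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

ASSAYS = ("DNA", "RNA")

ZYGOSITY_CALLS = (
    "heterozygous",
    "mosaic",
    "homozygous_alt",
    "homozygous_ref",
    "indeterminate",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half-up (so 30.25 -> 30.3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlleleCount:
    """Reference/alternate read counts at one site, in one sample and assay."""

    sample: str
    assay: str
    site: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        for name in ("ref_count", "alt_count"):
            value = getattr(self, name)
            if value != int(value):
                raise ValueError("read counts must be integers")
            object.__setattr__(self, name, int(value))  # accept numpy integers
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


def vaf(ac: AlleleCount) -> float:
    """Variant allele fraction alt / (ref + alt).

    Raises ValueError at zero depth ("no coverage"); callers that must not
    fail use :func:`vaf_percent` with ``strict=False`` or check depth first.
    """
    if ac.depth == 0:
        raise ValueError(f"no coverage at {ac.site} ({ac.sample}/{ac.assay})")
    return ac.alt_count / ac.depth


def vaf_percent(ac: AlleleCount) -> float:
    """VAF as a percentage rounded half-up to one decimal (67 ref / 29 alt -> 30.2)."""
    return round_half_up(100.0 * vaf(ac), 1)


@dataclass(frozen=True)
class ZygosityConfig:
    """Thresholds for zygosity classification.

    min_depth: below this the call is always ``indeterminate``.
    alpha: two-sided exact-binomial significance level against p = 0.5.
    lod: limit of detection; VAF at or below it (or at/above 1 - lod) is
        called homozygous.
    mosaic_max: upper VAF bound of the mosaic band.
    """

    min_depth: int = 20
    alpha: float = 0.05
    lod: float = 0.05
    mosaic_max: float = 0.35


@dataclass(frozen=True)
class ZygosityCall:
    call: str
    vaf: float
    binomial_p: float
    depth: int


def classify_zygosity(ac: AlleleCount, config: ZygosityConfig | None = None) -> ZygosityCall:
    """Classify a DNA allele count as heterozygous, mosaic or homozygous.

    The call is a function of (VAF, exact two-sided binomial p-value vs 0.5,
    depth) only:

    * depth < min_depth            -> indeterminate (never a hard error)
    * vaf <= lod / vaf >= 1 - lod  -> homozygous_ref / homozygous_alt
    * p >= alpha                   -> heterozygous
    * p < alpha and vaf <= mosaic_max -> mosaic
    * otherwise                    -> indeterminate
    """
    cfg = config or ZygosityConfig()
    depth = ac.depth
    if depth == 0:
        return ZygosityCall("indeterminate", float("nan"), 1.0, 0)
    v = vaf(ac)
    p = stats.binomtest(ac.alt_count, depth, 0.5, alternative="two-sided").pvalue
    if depth < cfg.min_depth:
        return ZygosityCall("indeterminate", v, p, depth)
    if v <= cfg.lod:
        call = "homozygous_ref"
    elif v >= 1.0 - cfg.lod:
        call = "homozygous_alt"
    elif p >= cfg.alpha:
        call = "heterozygous"
    elif v <= cfg.mosaic_max:
        call = "mosaic"
    else:
        call = "indeterminate"
    return ZygosityCall(call, v, p, depth)


@dataclass(frozen=True)
class ImbalanceResult:
    """One-sided Fisher exact test of allelic imbalance between assays."""

    odds_ratio: float
    p_value: float
    note: str = ""
    table: tuple = field(default=())


def allelic_imbalance_test(dna: AlleleCount, rna: AlleleCount) -> ImbalanceResult:
    """Test whether the alternate allele is depleted in RNA relative to DNA.

    Fisher exact test on [[dna_ref, dna_alt], [rna_ref, rna_alt]], one-sided
    with the alternative that the RNA alt fraction is LOWER than the DNA alt
    fraction (the NMD direction). Any zero margin makes the table degenerate:
    p = 1 is returned with a note rather than an error.
    """
    if dna.depth == 0 or rna.depth == 0:
        raise ValueError("both assays must have depth > 0")
    table = [[dna.ref_count, dna.alt_count], [rna.ref_count, rna.alt_count]]
    col_ref = dna.ref_count + rna.ref_count
    col_alt = dna.alt_count + rna.alt_count
    if col_ref == 0 or col_alt == 0:
        if dna.alt_count == 0 or rna.ref_count == 0:
            odds = float("nan")
        else:
            odds = (dna.ref_count * rna.alt_count) / (dna.alt_count * rna.ref_count)
        return ImbalanceResult(odds, 1.0, "degenerate table", tuple(map(tuple, table)))
    # RNA alt depleted <=> dna_ref (cell [0,0]) small, margins fixed
    odds, p = stats.fisher_exact(table, alternative="less")
    return ImbalanceResult(float(odds), float(p), "", tuple(map(tuple, table)))
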