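"""Split-read splice-junction extraction, usage ratios, novel-junction calls.

A junction is the intron an RNA-seq read skips: every N operation in a primary
alignment's CIGAR contributes one observation of the half-open intron interval
[donor_pos, acceptor_pos) (0-based; donor_pos is the first intronic base).
Per-donor acceptor usage ratios (the numbers a sashimi plot draws) and
novel-junction detection against a reference catalog (e.g. a GTEx-like
aggregate of known junctions) are computed from the resulting count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .ase import round_half_up

logger = logging.getLogger(__name__)

MIN_INTRON = 20
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True, order=True)
class Junction:
    """Half-open intron interval; strand is annotation, not identity."""

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.donor_pos >= self.acceptor_pos:
            raise ValueError("donor_pos must be < acceptor_pos")
        if self.acceptor_pos - self.donor_pos < MIN_INTRON:
            raise ValueError(f"intron length must be >= {MIN_INTRON}")


class JunctionCountTable:
    """Split-read counts per (junction, sample)."""

    def __init__(self) -> None:
        self._counts: dict = {}
        self.skipped_records = 0

    def add(self, junction: Junction, sample: str, count: int = 1) -> None:
        if count < 0:
            raise ValueError("counts must be non-negative")
        key = (junction, sample)
        self._counts[key] = self._counts.get(key, 0) + count

    def count(self, junction: Junction, sample: str) -> int:
        return self._counts.get((junction, sample), 0)

    def items(self):
        return self._counts.items()

    @property
    def samples(self) -> set:
        return {s for (_, s) in self._counts}

    def junctions(self, sample: str | None = None) -> list:
        js = {j for (j, s) in self._counts if sample is None or s == sample}
        return sorted(js)

    def merge(self, other: "JunctionCountTable") -> "JunctionCountTable":
        out = JunctionCountTable()
        for (j, s), c in self.items():
            out.add(j, s, c)
        for (j, s), c in other.items():
            out.add(j, s, c)
        out.skipped_records = self.skipped_records + other.skipped_records
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": j.chrom,
                "donor_pos": j.donor_pos,
                "acceptor_pos": j.acceptor_pos,
                "strand": j.strand,
                "sample": s,
                "count": c,
            }
            for (j, s), c in sorted(self.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "donor_pos", "acceptor_pos", "strand", "sample", "count"],
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "JunctionCountTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for row in df.itertuples(index=False):
            table.add(
                Junction(row.chrom, int(row.donor_pos), int(row.acceptor_pos),
                         getattr(row, "strand", ".")),
                row.sample,
                int(row.count),
            )
        return table


def junctions_from_cigar(pos: int, cigartuples) -> list:
    """Intron intervals implied by a 0-based alignment start and CIGAR tuples."""
    out = []
    ref = pos
    for op, length in cigartuples:
        if op == 3:  # N
            out.append((ref, ref + length))
        if op in _REF_CONSUMING:
            ref += length
    return out


def extract_junctions(
    sam_path: str, sample: str | None = None, min_mapq: int = 0
) -> JunctionCountTable:
    """Count junction observations from spliced alignments in a SAM file.

    Only primary, mapped, non-duplicate records are counted; a read with k
    N operations contributes k observations. Records with unparsable CIGARs
    are skipped with a warning and tallied in ``table.skipped_records``.
    """
    import pysam

    table = JunctionCountTable()
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        if sample is None:
            rgs = sam.header.to_dict().get("RG", [])
            sample = rgs[0].get("SM") if rgs else "sample"
        for read in sam:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            if read.mapping_quality < min_mapq:
                continue
            cig = read.cigartuples
            if cig is None:
                table.skipped_records += 1
                logger.warning("skipping %s: missing/malformed CIGAR", read.query_name)
                continue
            for donor, acceptor in junctions_from_cigar(read.reference_start, cig):
                try:
                    table.add(Junction(read.reference_name, donor, acceptor), sample)
                except ValueError:
                    table.skipped_records += 1
                    logger.warning(
                        "skipping junction %s:%d-%d in %s",
                        read.reference_name, donor, acceptor, read.query_name,
                    )
    return table


@dataclass(frozen=True)
class UsageResult:
    """Acceptor usage at one donor in one sample; status 'no_coverage' when
    the donor has zero split reads."""

    chrom: str
    donor_pos: int
    sample: str
    status: str
    total: int
    percentages: dict  # acceptor_pos -> percent, one decimal


def donor_usage_ratios(
    table: JunctionCountTable, chrom: str, donor_pos: int, sample: str
) -> UsageResult:
    """Percent usage of each acceptor at a donor: 100 * count / total at donor.

    Percentages are reported to one decimal and allocated by largest remainder
    so they always sum to exactly 100.0 (ties broken by acceptor coordinate).
    """
    counts = {
        j.acceptor_pos: c
        for (j, s), c in table.items()
        if s == sample and j.chrom == chrom and j.donor_pos == donor_pos and c > 0
    }
    total = sum(counts.values())
    if total == 0:
        return UsageResult(chrom, donor_pos, sample, "no_coverage", 0, {})
    acceptors = sorted(counts)
    tenths = {a: 1000 * counts[a] // total for a in acceptors}
    remainders = {a: 1000 * counts[a] % total for a in acceptors}
    leftover = 1000 - sum(tenths.values())
    for a in sorted(acceptors, key=lambda a: (-remainders[a], a))[:leftover]:
        tenths[a] += 1
    pct = {a: tenths[a] / 10.0 for a in acceptors}
    return UsageResult(chrom, donor_pos, sample, "ok", total, pct)


@dataclass(frozen=True)
class NovelJunction:
    junction: Junction
    count: int
    fraction_at_donor: float  # percent, one decimal
    fraction_at_acceptor: float


def read_catalog_bed(path: str) -> set:
    """Load a reference junction catalog from BED (0-based half-open introns)."""
    catalog = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) > 5 else "."
            catalog.add(Junction(fields[0], int(fields[1]), int(fields[2]), strand))
    return catalog


def detect_novel_junctions(
    table: JunctionCountTable,
    catalog: set,
    sample: str,
    min_reads: int = 3,
    slop: int = 0,
) -> list:
    """Junctions observed at >= min_reads in a sample but absent from the catalog.

    Matching is exact by default; ``slop`` allows +-k tolerance on both ends.
    Each call reports the junction's usage fraction among junctions sharing its
    donor and among those sharing its acceptor. An empty catalog flags every
    junction and logs loudly.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not catalog:
        logger.warning(
            "empty junction catalog: EVERY junction in %s will be flagged novel", sample
        )

    def known(j: Junction) -> bool:
        if slop == 0:
            return j in catalog
        return any(
            k.chrom == j.chrom
            and abs(k.donor_pos - j.donor_pos) <= slop
            and abs(k.acceptor_pos - j.acceptor_pos) <= slop
            for k in catalog
        )

    out = []
    for j in table.junctions(sample):
        c = table.count(j, sample)
        if c < min_reads or known(j):
            continue
        donor_total = sum(
            cc
            for (jj, s), cc in table.items()
            if s == sample and jj.chrom == j.chrom and jj.donor_pos == j.donor_pos
        )
        acc_total = sum(
            cc
            for (jj, s), cc in table.items()
            if s == sample and jj.chrom == j.chrom and jj.acceptor_pos == j.acceptor_pos
        )
        out.append(
            NovelJunction(
                j,
                c,
                round_half_up(100.0 * c / donor_total, 1),
                round_half_up(100.0 * c / acc_total, 1),
            )
        )
    return out
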