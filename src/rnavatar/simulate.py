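"""Synthetic trio + RNA data generator.

Emits every input the analysis consumes — trio VCFs with planted de novo
variants, transcript models with consensus splice motifs stamped at exon
boundaries, junction reads (SAM or count tables), and DNA/RNA allele counts —
together with a truth table sufficient to score every pipeline stage.

Defaults state the observed data regimes this generator emulates: DNA depth 44
and RNA depth 138 at the variant site, a mosaic fraction of 0.30, competing
acceptor usage of (0.45, 0.55) at one donor, a proband-only aberrant junction
at 13% usage, and an NMD depletion factor of 0.5 on alternate-allele RNA
reads. Everything is driven by one seeded RNG stream; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ase import AlleleCount
from .junctions import Junction, JunctionCountTable
from .transcripts import TranscriptModel
from .variants import AnnotatedVariant

BASES = "ACGT"

# Consensus-like positional base frequencies (order ACGT) used to sample
# realistic training windows; +1/+2 GT (donor) and -2/-1 AG (acceptor) are
# invariant, as in real sites.
DONOR_FREQS = (
    (0.33, 0.37, 0.18, 0.12),
    (0.60, 0.13, 0.12, 0.15),
    (0.10, 0.03, 0.80, 0.07),
    (0.0, 0.0, 1.0, 0.0),   # +1 G
    (0.0, 0.0, 0.0, 1.0),   # +2 T
    (0.55, 0.02, 0.38, 0.05),
    (0.70, 0.08, 0.12, 0.10),
    (0.08, 0.05, 0.80, 0.07),
    (0.16, 0.15, 0.20, 0.49),
)
ACCEPTOR_FREQS = tuple(
    [(0.08, 0.40, 0.07, 0.45)] * 18  # polypyrimidine tract
    + [(1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 1.0, 0.0)]  # -2 A, -1 G
    + [(0.30, 0.25, 0.25, 0.20)] * 3  # first exonic bases
)


@dataclass(frozen=True)
class TranscriptSpec:
    """Exon/intron geometry of the synthetic transcript (plus strand)."""

    exon_lengths: tuple = (57, 120, 150)
    intron_lengths: tuple = (200, 300)
    cds_start: int = 0
    cds_len: int | None = None  # default: largest multiple of 3 that fits
    tx_offset: int = 1000  # genomic start of exon 1
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron fewer than exons")


@dataclass(frozen=True)
class JunctionSpec:
    """Junction-read regime: competing acceptors at one donor + an aberrant
    donor creating a novel junction in the proband only."""

    usage_fractions: tuple = (0.45, 0.55)  # (short-exon acceptor, long) in parents
    proband_usage_fractions: tuple = (0.38, 0.62)  # the shifted proband regime
    acceptor_shift: int = 12  # offset of the short acceptor downstream of the long
    n_reads: int = 100  # junction reads per donor per sample
    aberrant_fraction: float = 0.13  # proband-only usage at donor 1
    aberrant_donor_shift: int = -4  # aberrant donor relative to the canonical donor 1

    def __post_init__(self) -> None:
        for fracs in (self.usage_fractions, self.proband_usage_fractions):
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError("usage fractions per donor must sum to 1")
        if not 0.0 <= self.aberrant_fraction < 1.0:
            raise ValueError("aberrant fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_background_variants: int = 20
    de_novo_spec: object = "germline_het"  # "none" | "germline_het" | ("mosaic", f)
    depth_dna: int = 44
    depth_rna: int = 138
    nmd_factor: float = 0.5
    planted_cds_del: tuple = (20, 2)  # (1-based CDS start, deletion length)
    junction: JunctionSpec = field(default_factory=JunctionSpec)
    transcript: TranscriptSpec = field(default_factory=TranscriptSpec)

    def __post_init__(self) -> None:
        if not 0.0 <= self.nmd_factor <= 1.0:
            raise ValueError("nmd_factor must be in [0, 1]")
        spec = self.de_novo_spec
        if isinstance(spec, (tuple, list)):
            kind, f = spec
            if kind != "mosaic" or not 0.0 < f <= 0.5:
                raise ValueError("mosaic spec must be ('mosaic', f) with f in (0, 0.5]")
        elif spec not in ("none", "germline_het"):
            raise ValueError(f"unknown de_novo_spec {spec!r}")

    @property
    def planted_alt_fraction(self) -> float:
        if self.de_novo_spec == "germline_het":
            return 0.5
        if isinstance(self.de_novo_spec, (tuple, list)):
            return float(self.de_novo_spec[1])
        raise ValueError("no planted de novo in this configuration")


ROLES = ("proband", "mother", "father")


# ---------------------------------------------------------------------------
# transcript + genome
# ---------------------------------------------------------------------------

def _stamp(genome: list, pos: int, motif: str) -> None:
    genome[pos : pos + len(motif)] = list(motif)


def build_transcript(spec: TranscriptSpec, rng: np.random.Generator) -> TranscriptModel:
    """Random contig + transcript with consensus splice motifs at boundaries.

    Exon 1 is made to end in ...AGG with the intron opening GTAAGT, so a G run
    spans the first donor boundary (the homopolymer-deletion regime); every
    intron ends with a pyrimidine tract and CAG before the next exon.
    """
    total = spec.tx_offset + sum(spec.exon_lengths) + sum(spec.intron_lengths) + 500
    genome = list(rng.choice(list(BASES), size=total))
    exons = []
    g = spec.tx_offset
    for i, length in enumerate(spec.exon_lengths):
        exons.append((g, g + length))
        g += length
        if i < len(spec.intron_lengths):
            intron_len = spec.intron_lengths[i]
            _stamp(genome, exons[-1][1] - 3, "AGG" if i == 0 else "CAG")
            _stamp(genome, g, "GTAAGT")
            _stamp(genome, g + intron_len - 17, "TTTCTTTCTTTTCTCAG"[-17:])
            g += intron_len
    seq = "".join(genome)
    n_coding = sum(spec.exon_lengths) - spec.cds_start
    cds_len = spec.cds_len if spec.cds_len is not None else n_coding // 3 * 3
    return TranscriptModel(
        transcript_id="TX_SYN_1",
        strand="+",
        exons=tuple(exons),
        cds_start=spec.cds_start,
        cds_end=spec.cds_start + cds_len,
        chrom=spec.chrom,
        genome=seq,
    )


# ---------------------------------------------------------------------------
# trio variants
# ---------------------------------------------------------------------------

@dataclass
class TrioSimulation:
    config: SimulationConfig
    transcript: TranscriptModel
    variants: list
    truth: pd.DataFrame
    pedigree: dict

    def write_vcf(self, path: str) -> None:
        write_trio_vcf(self.variants, path, contig=self.transcript.chrom)

    def write_pedigree(self, path: str) -> None:
        rows = [
            {"sample_id": role, "role": role, "affected": "yes" if role == "proband" else "no"}
            for role in ROLES
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _genotype_counts(dosage: int, depth: int, rng: np.random.Generator):
    if dosage == 0:
        alt = 0
    elif dosage == 1:
        alt = int(rng.binomial(depth, 0.5))
    else:
        alt = depth
    return depth - alt, alt


def simulate_trio(config: SimulationConfig) -> TrioSimulation:
    """Background variants with Mendelian trio genotypes + one planted de novo.

    Background variants are common (population AF ~ U(0.05, 0.5)) so the
    frequency rule removes them all; the planted variant (absent from the
    population, parents alternate-read-free) is the intended sole survivor,
    recorded in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    tx = build_transcript(config.transcript, rng)
    variants, truth_rows = [], []

    inheritances = ("AD", "AR", "AD_AR", "unknown")
    for i in range(config.n_background_variants):
        pos = 50_000 + 137 * i
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        af = float(rng.uniform(0.05, 0.5))
        dosages = {}
        for parent in ("mother", "father"):
            dosages[parent] = int(rng.binomial(2, af))
        child = sum(
            int(rng.integers(0, 2) < dosages[parent])  # transmit 1 allele each
            if dosages[parent] == 1
            else dosages[parent] // 2
            for parent in ("mother", "father")
        )
        dosages["proband"] = child
        genotypes, counts = {}, {}
        for role in ROLES:
            d = dosages[role]
            genotypes[role] = {0: "0/0", 1: "0/1", 2: "1/1"}[d]
            rc, ac = _genotype_counts(d, config.depth_dna, rng)
            counts[role] = AlleleCount(role, "DNA", f"{tx.chrom}:{pos}", rc, ac)
        v = AnnotatedVariant(
            chrom=tx.chrom, pos=pos, ref=str(ref), alt=str(alt),
            gene=f"BG{i:03d}", gene_inheritance=inheritances[i % 4],
            population_af=af, genotypes=genotypes, allele_counts=counts,
        )
        variants.append(v)
        truth_rows.append(
            {"variant_id": v.variant_id, "gene": v.gene, "planted_de_novo": False,
             "population_af": af, "alt_fraction": None, "expected_retained": False}
        )

    if config.de_novo_spec != "none":
        p = config.planted_alt_fraction
        cds_start, del_len = config.planted_cds_del
        t = tx.cds_start + cds_start - 1
        g = tx.transcript_to_genomic(t)
        anchor = g - 1
        ref_allele = tx.genome[anchor : anchor + del_len + 1]
        alt_allele = tx.genome[anchor]
        pos = anchor + 1  # 1-based VCF
        genotypes = {"proband": "0/1", "mother": "0/0", "father": "0/0"}
        counts = {}
        alt_reads = int(rng.binomial(config.depth_dna, p))
        counts["proband"] = AlleleCount(
            "proband", "DNA", f"{tx.chrom}:{pos}", config.depth_dna - alt_reads, alt_reads
        )
        for parent in ("mother", "father"):
            counts[parent] = AlleleCount(parent, "DNA", f"{tx.chrom}:{pos}",
                                         config.depth_dna, 0)
        v = AnnotatedVariant(
            chrom=tx.chrom, pos=pos, ref=ref_allele, alt=alt_allele,
            gene="MAP4K4", gene_inheritance="unknown", population_af=None,
            genotypes=genotypes, allele_counts=counts,
        )
        variants.append(v)
        truth_rows.append(
            {"variant_id": v.variant_id, "gene": "MAP4K4", "planted_de_novo": True,
             "population_af": 0.0, "alt_fraction": p, "expected_retained": True}
        )

    truth = pd.DataFrame(truth_rows)
    pedigree = {
        role: {"sample_id": role, "affected": role == "proband"} for role in ROLES
    }
    return TrioSimulation(config, tx, variants, truth, pedigree)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length=10000000>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=AF_POP,Number=A,Type=Float,Description="Population allele frequency">
##INFO=<ID=INHERITANCE,Number=1,Type=String,Description="Gene inheritance mode">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar status">
##INFO=<ID=PENETRANCE,Number=0,Type=Flag,Description="Complete penetrance in the pediatric age">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tproband\tmother\tfather
"""


def write_trio_vcf(variants: list, path: str, contig: str = "chr1") -> None:
    lines = [VCF_HEADER.format(contig=contig)]
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
        info = [f"GENE={v.gene}", f"INHERITANCE={v.gene_inheritance}"]
        if v.population_af is not None:
            info.append(f"AF_POP={v.population_af:.6f}")
        if v.clinvar_status != "none":
            info.append(f"CLNSIG={v.clinvar_status}")
        if v.penetrance_complete_pediatric:
            info.append("PENETRANCE")
        cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                ";".join(info), "GT:AD:DP"]
        for role in ROLES:
            ac = v.allele_counts.get(role)
            if ac is None:
                cols.append(f"{v.genotypes[role]}:.:.")
            else:
                cols.append(
                    f"{v.genotypes[role]}:{ac.ref_count},{ac.alt_count}:{ac.depth}"
                )
        lines.append("\t".join(cols) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# junction reads
# ---------------------------------------------------------------------------

def junction_scene(config: SimulationConfig, tx: TranscriptModel) -> dict:
    """Coordinates of the canonical and aberrant junctions for a transcript."""
    j = config.junction
    donor1 = tx.exons[0][1]
    acceptor1 = tx.exons[1][0]
    donor2 = tx.exons[1][1]
    acceptor_long = tx.exons[2][0]
    acceptor_short = acceptor_long + j.acceptor_shift
    return {
        "exon1": Junction(tx.chrom, donor1, acceptor1),
        "aberrant": Junction(
            tx.chrom, donor1 + j.aberrant_donor_shift, acceptor1
        ),
        "short": Junction(tx.chrom, donor2, acceptor_short),
        "long": Junction(tx.chrom, donor2, acceptor_long),
    }


def simulate_junction_reads(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_reads: int | None = None,
) -> dict:
    """Multinomially sampled junction counts per trio sample.

    Every sample sees the competing short/long acceptors at donor 2 in the
    configured usage fractions; only the proband additionally emits the
    aberrant junction at donor 1 at its configured fraction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    jspec = config.junction
    n = n_reads if n_reads is not None else jspec.n_reads
    tx = build_transcript(config.transcript, np.random.default_rng(config.seed))
    scene = junction_scene(config, tx)
    tables = {}
    for role in ROLES:
        table = JunctionCountTable()
        f_short, f_long = (
            jspec.proband_usage_fractions if role == "proband" else jspec.usage_fractions
        )
        counts = rng.multinomial(n, [f_short, f_long])
        table.add(scene["short"], role, int(counts[0]))
        table.add(scene["long"], role, int(counts[1]))
        if role == "proband" and jspec.aberrant_fraction > 0:
            ab = rng.binomial(n, jspec.aberrant_fraction)
            table.add(scene["aberrant"], role, int(ab))
            table.add(scene["exon1"], role, int(n - ab))
        else:
            table.add(scene["exon1"], role, n)
        tables[role] = table
    return tables


def reference_catalog(config: SimulationConfig) -> set:
    """The GTEx-like catalog: every canonical junction, no aberrant one."""
    tx = build_transcript(config.transcript, np.random.default_rng(config.seed))
    scene = junction_scene(config, tx)
    return {scene["exon1"], scene["short"], scene["long"]}


def write_catalog_bed(catalog: set, path: str) -> None:
    with open(path, "w") as fh:
        for j in sorted(catalog):
            fh.write(f"{j.chrom}\t{j.donor_pos}\t{j.acceptor_pos}\tjxn\t0\t{j.strand}\n")


def write_junction_sam(table: JunctionCountTable, sample: str, path: str,
                       anchor: int = 25) -> None:
    """Emit one minimal SAM record per junction observation (50M-spliced reads)."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted\n",
        "@SQ\tSN:chr1\tLN:10000000\n",
        f"@RG\tID:{sample}\tSM:{sample}\n",
    ]
    i = 0
    for (j, s), c in sorted(table.items()):
        if s != sample:
            continue
        intron = j.acceptor_pos - j.donor_pos
        cigar = f"{anchor}M{intron}N{anchor}M"
        pos = j.donor_pos - anchor + 1  # SAM is 1-based
        for _ in range(c):
            lines.append(
                f"r{i:06d}\t0\t{j.chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t"
                f"{'A' * (2 * anchor)}\t*\tRG:Z:{sample}\n"
            )
            i += 1
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# allele counts (DNA/RNA)
# ---------------------------------------------------------------------------

def simulate_allele_reads(
    config: SimulationConfig,
    site: str = "planted",
    rng: np.random.Generator | None = None,
) -> tuple:
    """DNA and RNA allele counts at the planted site in the proband.

    DNA alt reads ~ Binomial(depth_dna, p) with p = 0.5 (germline het) or the
    mosaic fraction; RNA alt reads are binomially thinned by the NMD factor:
    p_rna = p * nmd / (1 - p + p * nmd).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    p = config.planted_alt_fraction
    dna_alt = int(rng.binomial(config.depth_dna, p))
    nmd = config.nmd_factor
    p_rna = p * nmd / (1.0 - p + p * nmd)
    rna_alt = int(rng.binomial(config.depth_rna, p_rna))
    dna = AlleleCount("proband", "DNA", site, config.depth_dna - dna_alt, dna_alt)
    rna = AlleleCount("proband", "RNA", site, config.depth_rna - rna_alt, rna_alt)
    return dna, rna


# ---------------------------------------------------------------------------
# splice-site training windows
# ---------------------------------------------------------------------------

def sample_site_windows(site_type: str, n: int, rng: np.random.Generator) -> list:
    """Draw realistic training windows from the consensus-like frequencies."""
    freqs = DONOR_FREQS if site_type == "donor_5ss" else ACCEPTOR_FREQS
    cols = [rng.choice(list(BASES), size=n, p=f) for f in freqs]
    return ["".join(w) for w in zip(*cols)]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
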