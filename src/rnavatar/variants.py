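"""Trio variant filtering: the five-rule removal cascade and de novo calling.

The cascade removes, in order:

i.   common variants — population AF >= 0.05 in autosomal-recessive (AR) genes,
     >= 0.01 in autosomal-dominant (AD, or AD_AR / unknown) genes;
ii.  borderline-frequency variants (AF in [0.01, 0.05]) annotated benign or
     likely benign without conflicts in ClinVar;
iii. ClinVar risk-factor / histocompatibility alleles;
iv.  proband-heterozygous variants inherited from an unaffected parent in AD
     genes with complete penetrance in the pediatric age;
v.   lone proband-heterozygous variants in AR genes without a second rare
     variant in trans.

Survivors are classified as de novo (any transmission mode), homozygous
recessive, or compound heterozygous. De novo status requires the proband to
carry the alternate allele while both parents are adequately covered
(depth >= min_depth) with at most max_parent_alt alternate reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .ase import AlleleCount

logger = logging.getLogger(__name__)

ROLES = ("proband", "mother", "father")
PARENTS = ("mother", "father")
GENE_INHERITANCE = ("AD", "AR", "AD_AR", "unknown")
CLINVAR_STATUSES = (
    "none",
    "benign",
    "likely_benign",
    "benign_conflicting",
    "risk_factor",
    "histocompatibility",
    "pathogenic",
    "likely_pathogenic",
    "VUS",
)
RULES = (
    "i_frequency",
    "ii_borderline_benign",
    "iii_clinvar_category",
    "iv_inherited_dominant",
    "v_unpaired_recessive",
    "none",
)
CANDIDATE_CLASSES = ("de_novo", "homozygous_recessive", "compound_het", "none")

AF_THRESHOLD_AR = 0.05
AF_THRESHOLD_AD = 0.01


@dataclass
class AnnotatedVariant:
    """One biallelic variant with trio genotypes, read counts and annotations.

    ``genotypes`` and ``allele_counts`` are keyed by trio role
    (proband/mother/father). ``population_af`` of None means absent from the
    population database and is treated as 0.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str
    gene_inheritance: str = "unknown"
    penetrance_complete_pediatric: bool = False
    population_af: float | None = None
    clinvar_status: str = "none"
    genotypes: dict = field(default_factory=dict)
    allele_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.gene_inheritance not in GENE_INHERITANCE:
            raise ValueError(
                f"gene_inheritance must be one of {GENE_INHERITANCE}, "
                f"got {self.gene_inheritance!r}"
            )
        if self.clinvar_status not in CLINVAR_STATUSES:
            raise ValueError(
                f"unknown ClinVar status {self.clinvar_status!r}; "
                f"valid tokens: {CLINVAR_STATUSES}"
            )
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af must be in [0, 1]")
        for role in ROLES:
            if role not in self.genotypes:
                raise ValueError(f"missing trio genotype for {role}")

    @property
    def af(self) -> float:
        return 0.0 if self.population_af is None else self.population_af

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def genotype(self, role: str) -> str:
        return self.genotypes[role]


@dataclass
class FilterDecision:
    variant_id: str
    retained: bool
    rule_fired: str = "none"
    candidate_class: str = "none"
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if (self.rule_fired == "none") != self.retained:
            raise ValueError("rule_fired must be 'none' iff retained")
        if self.candidate_class != "none" and not self.retained:
            raise ValueError("removed variants cannot carry a candidate class")


def _alleles(gt: str) -> list:
    return gt.replace("|", "/").split("/")

def has_alt(gt: str) -> bool:
    return "1" in _alleles(gt)

def is_het(gt: str) -> bool:
    a = _alleles(gt)
    return len(a) == 2 and sorted(a) == ["0", "1"]

def is_hom_alt(gt: str) -> bool:
    a = _alleles(gt)
    return len(a) == 2 and a == ["1", "1"]


def apply_frequency_filter(v: AnnotatedVariant) -> FilterDecision:
    """Rule i: remove by population allele frequency.

    AR genes use the 0.05 threshold; AD, AD_AR (the stricter annotation wins)
    and unknown-inheritance genes use 0.01. Removal is ``af >= threshold``.
    """
    threshold = AF_THRESHOLD_AR if v.gene_inheritance == "AR" else AF_THRESHOLD_AD
    if v.af >= threshold:
        return FilterDecision(v.variant_id, False, "i_frequency")
    return FilterDecision(v.variant_id, True)


def apply_clinvar_filters(v: AnnotatedVariant) -> FilterDecision:
    """Rules ii and iii: ClinVar-informed removal.

    ii removes borderline-frequency (AF in [0.01, 0.05]) benign/likely-benign
    annotations without conflicts; iii removes risk-factor and
    histocompatibility alleles at any frequency.
    """
    if AF_THRESHOLD_AD <= v.af <= AF_THRESHOLD_AR and v.clinvar_status in (
        "benign",
        "likely_benign",
    ):
        return FilterDecision(v.variant_id, False, "ii_borderline_benign")
    if v.clinvar_status in ("risk_factor", "histocompatibility"):
        return FilterDecision(v.variant_id, False, "iii_clinvar_category")
    return FilterDecision(v.variant_id, True)


def de_novo_status(
    v: AnnotatedVariant, min_depth: int = 10, max_parent_alt: int = 1
) -> str:
    """Trio de novo status: 'de_novo', 'not_de_novo' or 'unresolvable'.

    De novo requires alternate reads in the proband and, in EACH parent,
    depth >= min_depth with at most max_parent_alt alternate reads. Parents
    with missing or inadequate coverage make the call unresolvable (inheritance
    cannot be excluded), never de novo.
    """
    proband = v.allele_counts.get("proband")
    if proband is None or proband.alt_count == 0:
        return "not_de_novo"
    unresolved = False
    for parent in PARENTS:
        ac = v.allele_counts.get(parent)
        if ac is None or ac.depth < min_depth:
            unresolved = True
            continue
        if ac.alt_count > max_parent_alt:
            return "not_de_novo"
    return "unresolvable" if unresolved else "de_novo"


def detect_de_novo(
    v: AnnotatedVariant, min_depth: int = 10, max_parent_alt: int = 1
) -> bool:
    return de_novo_status(v, min_depth, max_parent_alt) == "de_novo"


def _parental_origin(v: AnnotatedVariant) -> set:
    """Parents whose genotype carries the alternate allele."""
    return {p for p in PARENTS if has_alt(v.genotype(p))}


def apply_inheritance_filters(
    variants_in_gene: list,
    pedigree_affected: dict | None = None,
    min_depth: int = 10,
    max_parent_alt: int = 1,
) -> list:
    """Rules iv and v over all variants sharing one gene, plus classification.

    Rule iv removes proband-het variants carried by an unaffected parent in AD
    genes flagged as completely penetrant in the pediatric age. Rule v removes
    a lone (non-de-novo) proband-het in an AR gene; two or more proband-hets
    with opposite parental origin survive as compound heterozygotes, and
    unresolvable phase yields retention with a ``phase_unknown`` warning rather
    than silent removal.
    """
    genes = {v.gene for v in variants_in_gene}
    if len(genes) > 1:
        raise ValueError(f"variants span multiple genes: {sorted(genes)}")
    affected = dict.fromkeys(PARENTS, False)
    if pedigree_affected:
        affected.update(pedigree_affected)

    decisions = []
    hets = [v for v in variants_in_gene if is_het(v.genotype("proband"))]
    # Trans configuration exists if two het variants have disjoint certain
    # origins; a de novo het counts as its own haplotype.
    origins = {
        v.variant_id: (_parental_origin(v) or {"de_novo"}) for v in hets
    }
    def _in_trans(a: str, b: str) -> bool:
        return bool(origins[a] - origins[b]) and bool(origins[b] - origins[a])

    for v in variants_in_gene:
        gt = v.genotype("proband")
        dn = de_novo_status(v, min_depth, max_parent_alt)
        if dn == "de_novo":
            decisions.append(
                FilterDecision(v.variant_id, True, candidate_class="de_novo")
            )
            continue
        if is_hom_alt(gt) and v.gene_inheritance in ("AR", "AD_AR"):
            decisions.append(
                FilterDecision(
                    v.variant_id, True, candidate_class="homozygous_recessive"
                )
            )
            continue
        if not is_het(gt):
            decisions.append(FilterDecision(v.variant_id, True))
            continue
        # rule iv — inherited het in a fully penetrant AD gene
        if v.gene_inheritance == "AD" and v.penetrance_complete_pediatric:
            carriers = _parental_origin(v)
            if any(not affected[p] for p in carriers):
                decisions.append(
                    FilterDecision(v.variant_id, False, "iv_inherited_dominant")
                )
                continue
        # rule v — unpaired het in an AR gene
        if v.gene_inheritance == "AR":
            partners = [o for o in hets if o.variant_id != v.variant_id]
            if not partners:
                decisions.append(
                    FilterDecision(v.variant_id, False, "v_unpaired_recessive")
                )
                continue
            if any(_in_trans(v.variant_id, o.variant_id) for o in partners):
                decisions.append(
                    FilterDecision(v.variant_id, True, candidate_class="compound_het")
                )
                continue
            ambiguous = any(
                len(origins[v.variant_id] & origins[o.variant_id]) > 0
                and (len(origins[v.variant_id]) > 1 or len(origins[o.variant_id]) > 1)
                for o in partners
            )
            if ambiguous:
                decisions.append(
                    FilterDecision(
                        v.variant_id,
                        True,
                        candidate_class="compound_het",
                        warnings=("phase_unknown",),
                    )
                )
            else:  # all hets certainly on the same parental haplotype source
                decisions.append(
                    FilterDecision(v.variant_id, False, "v_unpaired_recessive")
                )
            continue
        decisions.append(FilterDecision(v.variant_id, True))
    return decisions


def run_cascade(
    variants: list,
    pedigree_affected: dict | None = None,
    min_depth: int = 10,
    max_parent_alt: int = 1,
) -> list:
    """Apply rules i -> ii -> iii -> iv -> v in order over a variant set.

    The first rule that removes a variant is recorded; survivors are
    classified. Output is stable-sorted by (chrom, pos, ref, alt).
    """
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    decisions: dict = {}
    survivors = []
    for v in ordered:
        d = apply_frequency_filter(v)
        if d.retained:
            d = apply_clinvar_filters(v)
        if d.retained:
            survivors.append(v)
        else:
            decisions[v.variant_id] = d

    by_gene: dict = {}
    for v in survivors:
        by_gene.setdefault(v.gene, []).append(v)
    for gene_variants in by_gene.values():
        for d in apply_inheritance_filters(
            gene_variants, pedigree_affected, min_depth, max_parent_alt
        ):
            decisions[d.variant_id] = d
    return [decisions[v.variant_id] for v in ordered]


# ---------------------------------------------------------------------------
# VCF / sample-sheet I/O
# ---------------------------------------------------------------------------

DEFAULT_INFO_KEYS = {
    "gene": "GENE",
    "af": "AF_POP",
    "inheritance": "INHERITANCE",
    "clinvar": "CLNSIG",
    "penetrance": "PENETRANCE",
}


def read_pedigree(path: str) -> dict:
    """Read a 3-line sample sheet TSV (sample_id, role, affected)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role", "affected"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree must have columns {sorted(required)}")
    ped = {}
    for _, row in df.iterrows():
        role = row["role"].strip().lower()
        if role not in ROLES:
            raise ValueError(f"unknown trio role {role!r}")
        ped[role] = {
            "sample_id": row["sample_id"],
            "affected": str(row["affected"]).strip().lower() in ("1", "yes", "true"),
        }
    missing = set(ROLES) - set(ped)
    if missing:
        raise ValueError(f"pedigree missing roles: {sorted(missing)}")
    return ped


def _gt_string(gt_tuple) -> str:
    if gt_tuple is None or all(a is None for a in gt_tuple):
        return "./."
    return "/".join("." if a is None else str(min(a, 1)) for a in gt_tuple)


def read_vcf(path: str, pedigree: dict, info_keys: dict | None = None) -> list:
    """Read annotated trio variants from a VCF 4.2 file.

    Annotations come from configurable INFO keys (defaults GENE, AF_POP,
    INHERITANCE, CLNSIG plus the PENETRANCE flag); multi-allelic records are
    split into biallelic variants, with per-allele AD depths carried through.
    """
    import pysam

    keys = dict(DEFAULT_INFO_KEYS, **(info_keys or {}))
    role_by_sample = {ped["sample_id"]: role for role, ped in pedigree.items()}
    variants = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = rec.info
            gene = info.get(keys["gene"], "NA")
            af = info.get(keys["af"], None)
            inheritance = info.get(keys["inheritance"], "unknown")
            clinvar = info.get(keys["clinvar"], "none")
            penetrance = bool(info.get(keys["penetrance"], False))
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                genotypes, counts = {}, {}
                for sample_id, call in rec.samples.items():
                    role = role_by_sample.get(sample_id)
                    if role is None:
                        continue
                    gt = call.get("GT")
                    # collapse other alt alleles onto ref for the split record
                    alleles = (
                        "./."
                        if gt is None or all(a is None for a in gt)
                        else "/".join(
                            "." if a is None else ("1" if a == i + 1 else "0")
                            for a in gt
                        )
                    )
                    genotypes[role] = alleles
                    ad = call.get("AD")
                    if ad is not None and ad[0] is not None:
                        counts[role] = AlleleCount(
                            sample_id, "DNA", f"{rec.chrom}:{rec.pos}",
                            int(ad[0]), int(ad[i + 1]),
                        )
                af_i = af[i] if isinstance(af, tuple) else af
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(gene),
                        gene_inheritance=str(inheritance),
                        penetrance_complete_pediatric=penetrance,
                        population_af=None if af_i is None else float(af_i),
                        clinvar_status=str(clinvar),
                        genotypes=genotypes,
                        allele_counts=counts,
                    )
                )
    return variants


def decisions_frame(decisions: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [d.variant_id for d in decisions],
            "retained": [d.retained for d in decisions],
            "rule_fired": [d.rule_fired for d in decisions],
            "candidate_class": [d.candidate_class for d in decisions],
            "warnings": [";".join(d.warnings) for d in decisions],
        }
    )


def write_decisions(decisions: list, path: str) -> None:
    decisions_frame(decisions).to_csv(path, sep="\t", index=False)


def write_filtered_vcf(in_path: str, decisions: list, out_path: str) -> None:
    """Write the survivors of the cascade back out as a VCF."""
    import pysam

    retained_sites = set()
    for d in decisions:
        if d.retained:
            chrom, pos, _ = d.variant_id.split(":", 2)
            retained_sites.add((chrom, int(pos)))
    with pysam.VariantFile(in_path) as vcf_in:
        with pysam.VariantFile(out_path, "w", header=vcf_in.header) as vcf_out:
            for rec in vcf_in:
                if (rec.chrom, rec.pos) in retained_sites:
                    vcf_out.write(rec)
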