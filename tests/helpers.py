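"""Independent oracles and small factories shared across the test suite.

Everything here is deliberately written from first principles (hand codon
table, hypergeometric tail enumeration with exact fractions, manual CIGAR
walks) so it shares no code path with the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from rnavatar.ase import AlleleCount
from rnavatar.variants import AnnotatedVariant

# -- translation oracle -----------------------------------------------------

_B = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_B)
    for j, b in enumerate(_B)
    for k, c in enumerate(_B)
}


def translate_oracle(seq: str) -> str:
    return "".join(
        CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def frameshift_oracle(cds: str, del_start_1b: int, del_len: int):
    """Brute-force mutate-and-translate: (first_altered_residue, stop_offset).

    Translates the full mutated CDS, compares against the reference protein
    residue by residue up to and including the reference stop, and counts the
    new stop with the first altered residue as position 1. stop_offset is None
    when no stop is reached before the end of the mutated sequence.
    """
    mutated = cds[: del_start_1b - 1] + cds[del_start_1b - 1 + del_len :]
    ref_prot = translate_oracle(cds)
    mut_prot = translate_oracle(mutated)
    i = 0
    while i < min(len(ref_prot), len(mut_prot)) and ref_prot[i] == mut_prot[i]:
        if ref_prot[i] == "*":
            break
        i += 1
    first_altered = i + 1
    stop = mut_prot.find("*", i)
    if stop == -1:
        return first_altered, None, "no_stop"
    if stop == i:  # the first altered residue IS the stop: nonsense, not fs*N
        return first_altered, None, "immediate_stop"
    return first_altered, stop - i + 1, "stop"


# -- exact-test oracles -----------------------------------------------------

def fisher_less_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p = P(top-left cell <= a) by hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    k1 = a + c
    n = r1 + r2
    denom = comb(n, r1)
    lo = max(0, k1 - r2)
    total = sum(
        Fraction(comb(k1, x) * comb(n - k1, r1 - x), denom) for x in range(lo, a + 1)
    )
    return float(total)


def binom_two_sided_oracle(k: int, n: int) -> float:
    """Exact two-sided binomial p vs 0.5: sum of outcomes no more likely than k."""
    pmf = [Fraction(comb(n, i), 2**n) for i in range(n + 1)]
    pk = pmf[k]
    return float(min(Fraction(1), sum(q for q in pmf if q <= pk)))


# -- CIGAR oracle -----------------------------------------------------------

_CIGAR_REF_OPS = set("MDN=X")


def cigar_junctions_oracle(pos: int, cigar: str) -> list:
    """Manual CIGAR walk collecting (donor, acceptor) for each N op."""
    out, ref, num = [], pos, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch == "N":
            out.append((ref, ref + length))
        if ch in _CIGAR_REF_OPS:
            ref += length
    return out


# -- variant factory --------------------------------------------------------

def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="G1",
    inheritance="unknown",
    penetrance=False,
    af=None,
    clinvar="none",
    proband_gt="0/1",
    mother_gt="0/0",
    father_gt="0/0",
    proband_counts=(20, 22),
    mother_counts=(30, 0),
    father_counts=(30, 0),
) -> AnnotatedVariant:
    site = f"{chrom}:{pos}"
    counts = {}
    for role, rc in (
        ("proband", proband_counts),
        ("mother", mother_counts),
        ("father", father_counts),
    ):
        if rc is not None:
            counts[role] = AlleleCount(role, "DNA", site, rc[0], rc[1])
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        gene_inheritance=inheritance,
        penetrance_complete_pediatric=penetrance,
        population_af=af,
        clinvar_status=clinvar,
        genotypes={"proband": proband_gt, "mother": mother_gt, "father": father_gt},
        allele_counts=counts,
    )


def six_variant_toy_set() -> list:
    """One variant per removal rule i-v plus one de novo survivor."""
    return [
        make_variant(pos=100, gene="G1", inheritance="AR", af=0.06),
        make_variant(pos=200, gene="G2", inheritance="AR", af=0.03,
                     clinvar="likely_benign"),
        make_variant(pos=300, gene="G3", inheritance="AD", af=0.0,
                     clinvar="risk_factor"),
        make_variant(pos=400, gene="G4", inheritance="AD", penetrance=True,
                     af=0.0, father_gt="0/1", father_counts=(15, 16)),
        make_variant(pos=500, gene="G5", inheritance="AR", af=0.001,
                     mother_gt="0/1", mother_counts=(14, 15)),
        make_variant(pos=600, ref="CTC", alt="C", gene="MAP4K4",
                     inheritance="unknown", af=None, proband_counts=(19, 25)),
    ]
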