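"""Filter-cascade, de novo detection and inheritance-rule tests."""

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

from helpers import make_variant, six_variant_toy_set
from rnavatar.variants import (
    AnnotatedVariant,
    FilterDecision,
    apply_clinvar_filters,
    apply_frequency_filter,
    apply_inheritance_filters,
    de_novo_status,
    detect_de_novo,
    run_cascade,
)


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "inheritance,af,retained",
        [
            ("AR", 0.06, False),   # above the recessive threshold
            ("AR", 0.04, True),
            ("AD", 0.0, True),
            ("AD", 0.009999, True),
            ("AD", 0.01, False),   # removal is af >= threshold
            ("AD_AR", 0.01, False),  # the stricter AD threshold applies
            ("unknown", 0.03, False),
            ("AR", None, True),    # missing AF treated as 0
        ],
    )
    def test_thresholds(self, inheritance, af, retained):
        d = apply_frequency_filter(make_variant(inheritance=inheritance, af=af))
        assert d.retained is retained
        assert d.rule_fired == ("none" if retained else "i_frequency")

    def test_invalid_af_rejected(self):
        with pytest.raises(ValueError):
            make_variant(af=1.5)
        with pytest.raises(ValueError):
            make_variant(af=-0.1)


class TestClinvarFilters:
    @pytest.mark.parametrize(
        "af,status,rule",
        [
            (0.03, "likely_benign", "ii_borderline_benign"),
            (0.01, "benign", "ii_borderline_benign"),   # closed borderline band
            (0.05, "benign", "ii_borderline_benign"),
            (0.005, "benign", "none"),                  # below the band
            (0.03, "benign_conflicting", "none"),       # conflicts exempt
            (0.0, "risk_factor", "iii_clinvar_category"),
            (0.3, "histocompatibility", "iii_clinvar_category"),
            (0.03, "VUS", "none"),
        ],
    )
    def test_rules_ii_iii(self, af, status, rule):
        d = apply_clinvar_filters(make_variant(af=af, clinvar=status))
        assert d.rule_fired == rule

    def test_unknown_status_lists_valid_tokens(self):
        with pytest.raises(ValueError, match="benign"):
            make_variant(clinvar="bogus")


class TestDeNovo:
    def test_classic_trio_configuration(self):
        v = make_variant(proband_counts=(19, 25), mother_counts=(30, 0),
                         father_counts=(30, 0))
        assert detect_de_novo(v)

    def test_no_alt_in_proband(self):
        v = make_variant(proband_counts=(40, 0))
        assert de_novo_status(v) == "not_de_novo"

    def test_low_parent_depth_unresolvable(self):
        v = make_variant(mother_counts=(5, 0))
        assert de_novo_status(v) == "unresolvable"
        assert not detect_de_novo(v)

    def test_missing_parent_counts_unresolvable(self):
        v = make_variant(father_counts=None)
        assert de_novo_status(v) == "unresolvable"

    def test_parent_alt_reads_block_call(self):
        v = make_variant(mother_counts=(28, 2))
        assert de_novo_status(v) == "not_de_novo"
        # one stray parental alt read is tolerated by default
        v = make_variant(mother_counts=(29, 1))
        assert detect_de_novo(v)


class TestInheritanceFilters:
    def test_rule_iv_inherited_dominant(self):
        v = make_variant(gene="G", inheritance="AD", penetrance=True,
                         father_gt="0/1", father_counts=(15, 16))
        (d,) = apply_inheritance_filters([v])
        assert not d.retained and d.rule_fired == "iv_inherited_dominant"

    def test_rule_iv_needs_complete_penetrance(self):
        v = make_variant(gene="G", inheritance="AD", penetrance=False,
                         father_gt="0/1", father_counts=(15, 16))
        (d,) = apply_inheritance_filters([v])
        assert d.retained

    def test_rule_iv_spares_affected_parent(self):
        v = make_variant(gene="G", inheritance="AD", penetrance=True,
                         father_gt="0/1", father_counts=(15, 16))
        (d,) = apply_inheritance_filters([v], pedigree_affected={"father": True})
        assert d.retained

    def test_rule_v_lone_het(self):
        v = make_variant(gene="G", inheritance="AR",
                         mother_gt="0/1", mother_counts=(14, 15))
        (d,) = apply_inheritance_filters([v])
        assert not d.retained and d.rule_fired == "v_unpaired_recessive"

    def test_rule_v_spares_de_novo(self):
        v = make_variant(gene="G", inheritance="AR",
                         proband_counts=(20, 21))
        (d,) = apply_inheritance_filters([v])
        assert d.retained and d.candidate_class == "de_novo"

    def test_compound_het_in_trans(self):
        a = make_variant(pos=10, gene="G", inheritance="AR",
                         mother_gt="0/1", mother_counts=(14, 15))
        b = make_variant(pos=20, gene="G", inheritance="AR",
                         father_gt="0/1", father_counts=(14, 15))
        decisions = apply_inheritance_filters([a, b])
        assert all(d.retained for d in decisions)
        assert all(d.candidate_class == "compound_het" for d in decisions)

    def test_two_hets_in_cis_removed(self):
        a = make_variant(pos=10, gene="G", inheritance="AR",
                         mother_gt="0/1", mother_counts=(14, 15))
        b = make_variant(pos=20, gene="G", inheritance="AR",
                         mother_gt="0/1", mother_counts=(16, 17))
        decisions = apply_inheritance_filters([a, b])
        assert all(not d.retained for d in decisions)
        assert all(d.rule_fired == "v_unpaired_recessive" for d in decisions)

    def test_phase_unknown_retained_with_warning(self):
        a = make_variant(pos=10, gene="G", inheritance="AR", mother_gt="0/1",
                         father_gt="0/1", mother_counts=(14, 15),
                         father_counts=(14, 15))
        b = make_variant(pos=20, gene="G", inheritance="AR", mother_gt="0/1",
                         mother_counts=(16, 17))
        decisions = apply_inheritance_filters([a, b])
        assert all(d.retained for d in decisions)
        assert any("phase_unknown" in d.warnings for d in decisions)

    def test_homozygous_recessive(self):
        v = make_variant(gene="G", inheritance="AR", proband_gt="1/1",
                         mother_gt="0/1", father_gt="0/1",
                         proband_counts=(0, 40), mother_counts=(14, 15),
                         father_counts=(14, 15))
        (d,) = apply_inheritance_filters([v])
        assert d.retained and d.candidate_class == "homozygous_recessive"

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError):
            apply_inheritance_filters(
                [make_variant(gene="A"), make_variant(gene="B")]
            )


class TestCascade:
    def test_six_variant_toy_set(self):
        decisions = run_cascade(six_variant_toy_set())
        fired = [d.rule_fired for d in decisions]
        assert fired == [
            "i_frequency",
            "ii_borderline_benign",
            "iii_clinvar_category",
            "iv_inherited_dominant",
            "v_unpaired_recessive",
            "none",
        ]
        survivor = decisions[-1]
        assert survivor.retained and survivor.candidate_class == "de_novo"

    def test_empty_input(self):
        assert run_cascade([]) == []

    def test_absent_from_population_lof_de_novo(self):
        v = make_variant(gene="MAP4K4", ref="CTC", alt="C", af=None,
                         proband_counts=(19, 25))
        (d,) = run_cascade([v])
        assert d.retained and d.candidate_class == "de_novo"

    def test_deterministic_and_order_stable(self):
        vs = six_variant_toy_set()
        d1 = run_cascade(vs)
        d2 = run_cascade(list(reversed(vs)))
        assert d1 == d2

    def test_rule_exclusivity_invariant(self):
        for d in run_cascade(six_variant_toy_set()):
            assert (d.rule_fired == "none") == d.retained

    def test_brute_force_equivalence_random_sets(self):
        """Cascade equals independent per-rule set operations composed in order."""
        import numpy as np

        rs = np.random.default_rng(42)
        inheritances = ["AD", "AR", "AD_AR", "unknown"]
        statuses = ["none", "benign", "likely_benign", "benign_conflicting",
                    "risk_factor", "VUS"]
        for _ in range(20):
            n = int(rs.integers(1, 60))
            vs = []
            for i in range(n):
                parent_carrier = rs.random() < 0.5
                vs.append(make_variant(
                    pos=int(100 + i * 10),
                    gene=f"G{int(rs.integers(0, 6))}",
                    inheritance=inheritances[int(rs.integers(0, 4))],
                    penetrance=bool(rs.random() < 0.5),
                    af=float(rs.choice([0.0, 0.005, 0.02, 0.04, 0.2])),
                    clinvar=statuses[int(rs.integers(0, len(statuses)))],
                    mother_gt="0/1" if parent_carrier else "0/0",
                    mother_counts=(14, 15) if parent_carrier else (30, 0),
                ))
            got = run_cascade(vs)
            expected = _brute_force(vs)
            assert [(d.variant_id, d.retained, d.rule_fired) for d in got] == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        af_hi=st.floats(0.0, 1.0),
        af_lo_frac=st.floats(0.0, 1.0),
        inheritance=st.sampled_from(["AD", "AR", "AD_AR", "unknown"]),
        clinvar=st.sampled_from(["none", "benign", "benign_conflicting", "VUS"]),
    )
    def test_monotonicity_in_population_af(self, af_hi, af_lo_frac, inheritance, clinvar):
        """Lowering population AF never turns a retained variant into a removed one."""
        af_lo = af_hi * af_lo_frac
        hi = make_variant(af=af_hi, inheritance=inheritance, clinvar=clinvar)
        lo = make_variant(af=af_lo, inheritance=inheritance, clinvar=clinvar)
        (d_hi,) = run_cascade([hi])
        (d_lo,) = run_cascade([lo])
        if d_hi.retained:
            assert d_lo.retained


def _brute_force(vs):
    """Independent composition of the five rules as plain set operations."""
    from rnavatar.variants import has_alt, is_het

    removed = {}
    s = sorted(vs, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    # rule i
    stage = []
    for v in s:
        thr = 0.05 if v.gene_inheritance == "AR" else 0.01
        if v.af >= thr:
            removed[v.variant_id] = "i_frequency"
        else:
            stage.append(v)
    # rule ii
    nxt = []
    for v in stage:
        if 0.01 <= v.af <= 0.05 and v.clinvar_status in ("benign", "likely_benign"):
            removed[v.variant_id] = "ii_borderline_benign"
        else:
            nxt.append(v)
    stage = nxt
    # rule iii
    nxt = []
    for v in stage:
        if v.clinvar_status in ("risk_factor", "histocompatibility"):
            removed[v.variant_id] = "iii_clinvar_category"
        else:
            nxt.append(v)
    stage = nxt
    # rules iv/v, gene-wise
    for v in stage:
        if detect_de_novo(v):
            continue
        if (
            v.gene_inheritance == "AD"
            and v.penetrance_complete_pediatric
            and is_het(v.genotypes["proband"])
            and (has_alt(v.genotypes["mother"]) or has_alt(v.genotypes["father"]))
        ):
            removed[v.variant_id] = "iv_inherited_dominant"
            continue
        if v.gene_inheritance == "AR" and is_het(v.genotypes["proband"]):
            partners = [
                o for o in stage
                if o.gene == v.gene and o.variant_id != v.variant_id
                and is_het(o.genotypes["proband"])
            ]
            def origin(x):
                o = {p for p in ("mother", "father") if has_alt(x.genotypes[p])}
                return o or {"de_novo"}
            trans = any(
                origin(v) - origin(o) and origin(o) - origin(v) for o in partners
            )
            ambiguous = any(
                origin(v) & origin(o) and (len(origin(v)) > 1 or len(origin(o)) > 1)
                for o in partners
            )
            if not partners or (not trans and not ambiguous):
                removed[v.variant_id] = "v_unpaired_recessive"
    return [
        (v.variant_id, v.variant_id not in removed, removed.get(v.variant_id, "none"))
        for v in s
    ]


class TestDecisionInvariants:
    def test_decision_consistency_enforced(self):
        with pytest.raises(ValueError):
            FilterDecision("x", retained=True, rule_fired="i_frequency")
        with pytest.raises(ValueError):
            FilterDecision("x", retained=False, candidate_class="de_novo")

    def test_trio_completeness_enforced(self):
        with pytest.raises(ValueError, match="father"):
            AnnotatedVariant(
                chrom="chr1", pos=1, ref="A", alt="T", gene="G",
                genotypes={"proband": "0/1", "mother": "0/0"},
            )
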