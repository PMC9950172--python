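"""End-to-end orchestration: filter -> consequence -> RNA validation -> report.

Runs the filtering cascade over a trio variant set, predicts the coding/splice
consequence of each surviving candidate on the transcript model, and collects
the RNA evidence: DNA zygosity (het vs mosaic), acceptor usage ratios at the
affected donors, novel-junction flags against the reference catalog, the
DNA-vs-RNA allelic-imbalance test, and splice-site delta scores under all
trained model families. Candidates are ranked by (de novo, loss-of-function
consequence, count of supporting RNA evidence); ACMG-style tags (PVS1-like /
PS2-like / PM2-like) are informational only, never scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import ase, consequences, junctions, simulate, splicemodels, variants

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

LOF_KINDS = ("frameshift", "fs_no_stop", "nonsense", "splice_donor_disruption")

NOT_ASSESSED = "not assessed"


@dataclass
class PipelineConfig:
    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    with_rna: bool = True
    min_novel_reads: int = 3
    zygosity: ase.ZygosityConfig = field(default_factory=ase.ZygosityConfig)
    alpha_imbalance: float = 0.05
    n_training_windows: int = 200

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim_raw = raw.pop("sim", {})
        jspec = simulate.JunctionSpec(**sim_raw.pop("junction", {}))
        tspec = simulate.TranscriptSpec(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in sim_raw.pop("transcript", {}).items()}
        )
        if isinstance(sim_raw.get("de_novo_spec"), list):
            sim_raw["de_novo_spec"] = tuple(sim_raw["de_novo_spec"])
        if isinstance(sim_raw.get("planted_cds_del"), list):
            sim_raw["planted_cds_del"] = tuple(sim_raw["planted_cds_del"])
        sim = simulate.SimulationConfig(junction=jspec, transcript=tspec, **sim_raw)
        zyg = ase.ZygosityConfig(**raw.pop("zygosity", {}))
        return cls(sim=sim, zygosity=zyg, **raw)


def acmg_style_tags(evidence: dict) -> list:
    """Informational ACMG-style tags; mirrored, not scored."""
    tags = []
    if evidence.get("consequence", {}).get("kind") in LOF_KINDS:
        tags.append("PVS1-like")
    if evidence.get("filter", {}).get("candidate_class") == "de_novo":
        tags.append("PS2-like")
    if evidence.get("population_af", 1.0) == 0.0:
        tags.append("PM2-like")
    return tags


def rna_support_count(evidence: dict) -> int:
    """Number of RNA evidence sources supporting the candidate."""
    n = 0
    imb = evidence.get("allelic_imbalance")
    if isinstance(imb, dict) and imb.get("p_value", 1.0) < evidence.get(
        "alpha_imbalance", 0.05
    ):
        n += 1
    novel = evidence.get("novel_junctions")
    if isinstance(novel, list) and len(novel) > 0:
        n += 1
    usage = evidence.get("usage_shift")
    if isinstance(usage, dict) and usage.get("shifted", False):
        n += 1
    return n


def rank_candidates(candidates: list) -> list:
    """Order by (de novo, LoF consequence, RNA-support count), descending."""
    def key(ev):
        is_dn = ev.get("filter", {}).get("candidate_class") == "de_novo"
        is_lof = ev.get("consequence", {}).get("kind") in LOF_KINDS
        return (is_dn, is_lof, rna_support_count(ev))

    return sorted(candidates, key=key, reverse=True)


def run_pipeline(config: PipelineConfig | None = None, out_dir: str | None = None) -> dict:
    """Run the synthetic end-to-end analysis and assemble the evidence report."""
    cfg = config or PipelineConfig()
    sim = simulate.simulate_trio(cfg.sim)
    tx = sim.transcript
    logger.info("simulated %d variants", len(sim.variants))

    decisions = variants.run_cascade(
        sim.variants, {r: p["affected"] for r, p in sim.pedigree.items() if r != "proband"}
    )
    retained = [d for d in decisions if d.retained]
    logger.info("cascade: %d in, %d retained", len(decisions), len(retained))
    by_id = {v.variant_id: v for v in sim.variants}

    rna = None
    if cfg.with_rna:
        tables = simulate.simulate_junction_reads(cfg.sim)
        catalog = simulate.reference_catalog(cfg.sim)
        scene = simulate.junction_scene(cfg.sim, tx)
        dna_counts, rna_counts = simulate.simulate_allele_reads(cfg.sim)
        rna = {"tables": tables, "catalog": catalog, "scene": scene,
               "dna": dna_counts, "rna": rna_counts}

    candidates = []
    for d in retained:
        v = by_id[d.variant_id]
        ev: dict = {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "population_af": v.af,
            "alpha_imbalance": cfg.alpha_imbalance,
            "filter": {
                "retained": d.retained,
                "rule_fired": d.rule_fired,
                "candidate_class": d.candidate_class,
            },
        }
        # consequence on the synthetic transcript (planted variant only; the
        # background variants sit outside the transcript span)
        if v.gene == "MAP4K4" and cfg.sim.de_novo_spec != "none":
            cds_start, del_len = cfg.sim.planted_cds_del
            cons = consequences.predict_frameshift(tx, cds_start, del_len)
            ev["consequence"] = asdict(cons)
        else:
            ev["consequence"] = {"kind": "none"}
        # DNA zygosity from the proband allele counts
        ac = v.allele_counts.get("proband")
        if ac is not None and ac.depth > 0:
            call = ase.classify_zygosity(ac, cfg.zygosity)
            ev["zygosity"] = asdict(call)
        else:
            ev["zygosity"] = NOT_ASSESSED

        if rna is None:
            ev["usage_ratios"] = NOT_ASSESSED
            ev["usage_shift"] = NOT_ASSESSED
            ev["novel_junctions"] = NOT_ASSESSED
            ev["allelic_imbalance"] = NOT_ASSESSED
            ev["splice_deltas"] = NOT_ASSESSED
        elif v.gene == "MAP4K4":
            ev.update(_rna_evidence(cfg, tx, rna))
        else:
            ev["usage_ratios"] = NOT_ASSESSED
            ev["usage_shift"] = NOT_ASSESSED
            ev["novel_junctions"] = []
            ev["allelic_imbalance"] = NOT_ASSESSED
            ev["splice_deltas"] = NOT_ASSESSED
        ev["tags"] = acmg_style_tags(ev)
        ev["rna_support_count"] = rna_support_count(ev)
        candidates.append(ev)

    ranked = rank_candidates(candidates)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.sim.seed,
        "thresholds": {
            "zygosity": asdict(cfg.zygosity),
            "alpha_imbalance": cfg.alpha_imbalance,
            "min_novel_reads": cfg.min_novel_reads,
        },
        "n_variants": len(sim.variants),
        "n_retained": len(retained),
        "decisions": variants.decisions_frame(decisions).to_dict(orient="records"),
        "candidates": ranked,
        "truth": sim.truth.to_dict(orient="records"),
    }
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        variants.write_decisions(decisions, os.path.join(out_dir, "decisions.tsv"))
    return report


def _rna_evidence(config: PipelineConfig, tx, rna: dict) -> dict:
    """Junction, imbalance and splice-score evidence for the planted candidate."""
    out: dict = {}
    scene, tables = rna["scene"], rna["tables"]
    donor2 = scene["short"].donor_pos
    usage = {
        role: junctions.donor_usage_ratios(tables[role], tx.chrom, donor2, role)
        for role in simulate.ROLES
    }
    out["usage_ratios"] = {
        role: {"status": u.status, "total": u.total, "percentages": u.percentages}
        for role, u in usage.items()
    }
    # usage shift: proband's short-acceptor percentage departs from parents'
    short_acc = scene["short"].acceptor_pos
    parent_pcts = [
        usage[r].percentages.get(short_acc, 0.0)
        for r in ("mother", "father")
        if usage[r].status == "ok"
    ]
    proband_pct = (
        usage["proband"].percentages.get(short_acc, 0.0)
        if usage["proband"].status == "ok"
        else None
    )
    shifted = (
        proband_pct is not None
        and bool(parent_pcts)
        and abs(proband_pct - float(np.mean(parent_pcts))) > 5.0
    )
    out["usage_shift"] = {
        "proband_pct_short": proband_pct,
        "parents_pct_short": parent_pcts,
        "shifted": shifted,
    }
    novel = junctions.detect_novel_junctions(
        tables["proband"], rna["catalog"], "proband", config.min_novel_reads
    )
    out["novel_junctions"] = [
        {
            "chrom": n.junction.chrom,
            "donor_pos": n.junction.donor_pos,
            "acceptor_pos": n.junction.acceptor_pos,
            "count": n.count,
            "fraction_at_donor": n.fraction_at_donor,
            "fraction_at_acceptor": n.fraction_at_acceptor,
        }
        for n in novel
    ]
    imb = ase.allelic_imbalance_test(rna["dna"], rna["rna"])
    out["allelic_imbalance"] = {
        "odds_ratio": imb.odds_ratio,
        "p_value": imb.p_value,
        "note": imb.note,
        "dna": (rna["dna"].ref_count, rna["dna"].alt_count),
        "rna": (rna["rna"].ref_count, rna["rna"].alt_count),
    }
    # splice delta scores at the exon-1 donor (homopolymer-deletion regime)
    rng = np.random.default_rng(config.sim.seed + 3)
    train = simulate.sample_site_windows("donor_5ss", config.n_training_windows, rng)
    donor1 = scene["exon1"].donor_pos
    ref_window = tx.genome[donor1 - 3 : donor1 + 6]
    alt_window = tx.genome[donor1 - 3 : donor1] + tx.genome[donor1 + 1 : donor1 + 7]
    deltas = {}
    for kind in ("WMM", "MM1"):
        model = splicemodels.train_model(train, "donor_5ss", model_kind=kind)
        deltas[kind] = splicemodels.delta_score(model, ref_window, alt_window)
    out["splice_deltas"] = {
        "ref_window": ref_window,
        "alt_window": alt_window,
        "deltas": deltas,
        "splice_weakening": splicemodels.is_splice_weakening(deltas),
    }
    return out
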