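"""End-to-end pipeline: simulate -> coexpress -> prognosis -> consensus -> gsea -> stratify.

One config object drives every stage; outputs are TSVs with provenance
comment lines plus a JSON manifest, and a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coexsurv import io as cio
from coexsurv.coexpression import seed_signature
from coexsurv.consensus import annotate_direction, build_prognostic_set, intersect_signatures
from coexsurv.enrichment import preranked_gsea
from coexsurv.io import GeneSet, GeneSetCollection
from coexsurv.prognosis import cox_z_scan, flag_prognostic, prognostic_fraction, rank_signatures
from coexsurv.simulate import SimConfig, generate_cohort
from coexsurv.stratify import combine_markers, cox_hr_groups, dichotomize_expression, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "coexsurv_run"
    seed: int = 0
    cutoff: float = 0.3
    strict: bool = False
    z_threshold: float = 2.0
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    split: str = "median"
    reference_group: str = "a-low/b-high"
    expression: str | None = None   # paths; None means simulate
    survival: str | None = None
    gmt: str | None = None
    simulate: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.cutoff <= 1):
            raise ValueError(f"cutoff must lie in (0, 1], got {self.cutoff}")
        if self.z_threshold <= 0:
            raise ValueError("z threshold must be positive")
        if self.gsea_permutations < 100:
            raise ValueError("gsea_permutations must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _planted_collection(truth, rng) -> GeneSetCollection:
    """Gene sets for self-contained enrichment: the planted modules plus decoys."""
    sets = []
    for module, name in (("module_a", "PLANTED_MODULE_A"), ("module_b", "PLANTED_MODULE_B")):
        genes = truth.module_genes(module)
        if genes:
            sets.append(GeneSet(name=name, description="planted co-expression module", members=tuple(genes)))
    all_genes = truth.genes["gene"].tolist()
    for i in range(3):
        members = tuple(rng.choice(all_genes, size=min(50, len(all_genes)), replace=False))
        sets.append(GeneSet(name=f"RANDOM_SET_{i + 1}", description="random control set", members=members))
    return GeneSetCollection(sets=tuple(sets))


def run_full(config: PipelineConfig) -> dict:
    """Run every stage on one config; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "cutoff": config.cutoff, "z_threshold": config.z_threshold}
    manifest: dict = {"parameters": meta | {"split": config.split, "reference": config.reference_group},
                      "stages": {}}
    rng = np.random.default_rng(config.seed)

    # --- stage 1: cohort -------------------------------------------------
    truth = None
    if config.expression and config.survival:
        matrix = cio.read_expression(config.expression)
        surv = cio.read_survival(config.survival)
        seed_a = config.simulate.get("seed_a", "SEEDA")
        seed_b = config.simulate.get("seed_b", "SEEDB")
    else:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("rng_seed", config.seed)
        sim = SimConfig(**sim_kwargs)
        matrix, surv, truth = generate_cohort(sim)
        seed_a, seed_b = sim.seed_a, sim.seed_b
        cio.write_expression(matrix, out / "expression.tsv", meta)
        cio.write_survival(surv, out / "survival.tsv", meta)
        cio.write_table(truth.genes, out / "ground_truth_genes.tsv", meta)
    manifest["stages"]["cohort"] = {
        "outputs": ["expression.tsv", "survival.tsv"] if truth is not None else [],
        "n_genes": matrix.n_genes, "n_samples": matrix.n_samples, "n_events": surv.n_events,
    }

    # --- stage 2: co-expression signatures -------------------------------
    signatures = {}
    for seed in (seed_a, seed_b):
        sig = seed_signature(matrix, seed, cutoff=config.cutoff, strict=config.strict)
        signatures[seed] = sig
        df = pd.DataFrame(sig.members, columns=["gene", "r"])
        df["arm"] = np.where(df["r"] > 0, "positive", "negative")
        cio.write_table(df, out / f"signature_{seed}.tsv", meta | {"seed_gene": seed})
    manifest["stages"]["coexpress"] = {
        "outputs": [f"signature_{s}.tsv" for s in signatures],
        "sizes": {s: len(sig) for s, sig in signatures.items()},
    }

    # --- stage 3: per-gene survival z ------------------------------------
    stats = cox_z_scan(matrix, surv)
    flags = flag_prognostic(stats, threshold=config.z_threshold)
    prog = stats.merge(flags[["gene", "prognostic", "direction"]], on="gene")
    cio.write_table(prog, out / "prognosis.tsv", meta)
    profiles = [prognostic_fraction(signatures[s], flags) for s in signatures]
    ranked_profiles = rank_signatures(profiles)
    prof_df = pd.DataFrame([
        {"seed": p.seed_gene, "n_total": p.n_total, "n_prognostic": p.n_prognostic, "percent": p.percent}
        for p in ranked_profiles
    ])
    cio.write_table(prof_df, out / "signature_profiles.tsv", meta)
    manifest["stages"]["prognosis"] = {
        "outputs": ["prognosis.tsv", "signature_profiles.tsv"],
        "n_genes_scored": len(stats), "n_prognostic": int(flags["prognostic"].sum()),
    }

    # --- stage 4: consensus ----------------------------------------------
    set_a = build_prognostic_set(signatures[seed_a], flags)
    set_b = build_prognostic_set(signatures[seed_b], flags)
    consensus_df = pd.DataFrame(columns=["gene", "r_a", "r_b", "z", "direction", "pattern"])
    venn = {"n_a": len(set_a), "n_b": len(set_b), "n_common": 0}
    if len(set_a) and len(set_b):
        cons = intersect_signatures(set_a, set_b)
        venn = cons.provenance
        if len(cons):
            cons = annotate_direction(cons)
            consensus_df = cons.to_frame()
    cio.write_table(consensus_df, out / "consensus.tsv", meta | venn)
    manifest["stages"]["consensus"] = {"outputs": ["consensus.tsv"], "venn": venn}

    # --- stage 5: enrichment ---------------------------------------------
    if config.gmt:
        collection = cio.read_gmt(config.gmt)
    elif truth is not None:
        collection = _planted_collection(truth, rng)
    else:
        collection = GeneSetCollection()
    ranked = list(stats.sort_values(["z", "gene"], ascending=[False, True])[["gene", "z"]]
                  .itertuples(index=False, name=None))
    results = preranked_gsea(ranked, collection, weight_p=config.gsea_weight,
                             n_perm=config.gsea_permutations, rng_seed=config.seed)
    gsea_df = pd.DataFrame([
        {"set": r.set_name, "es": r.es, "nes": r.nes, "p": r.p_perm, "fdr": r.fdr, "n_hits": r.n_hits}
        for r in results
    ], columns=["set", "es", "nes", "p", "fdr", "n_hits"])
    cio.write_table(gsea_df, out / "gsea.tsv", meta | {"n_perm": config.gsea_permutations})
    manifest["stages"]["gsea"] = {"outputs": ["gsea.tsv"], "n_sets": len(gsea_df)}

    # --- stage 6: stratification -----------------------------------------
    status_a = dichotomize_expression(matrix.gene_series(seed_a), rule=config.split)
    status_b = dichotomize_expression(matrix.gene_series(seed_b), rule=config.split)
    labels = combine_markers(status_a, status_b)
    chi2, p = logrank_test(surv, labels)
    hr = cox_hr_groups(surv, labels, reference_label=config.reference_group)
    summary = hr.copy()
    summary["logrank_chi2"] = chi2
    summary["logrank_p"] = p
    cio.write_table(summary, out / "stratification.tsv", meta)
    manifest["stages"]["stratify"] = {
        "outputs": ["stratification.tsv"], "logrank_chi2": chi2, "logrank_p": p,
        "groups": {str(k): int(v) for k, v in labels.value_counts().items()},
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
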