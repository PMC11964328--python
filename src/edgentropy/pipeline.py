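"""End-to-end orchestration: simulate -> entropy -> stats -> classify ->
pls -> celltype, with a declarative config, per-stage logging, and a single
deterministic JSON run report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import group_stats as gs
from . import synthetic as syn
from . import transcriptome as tx
from .edge_network import SubnetworkMap, build_entropy_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "entropy", "stats", "classify", "pls", "celltype")
#: each stage's hard prerequisite within a single run
_REQUIRES = {"entropy": "simulate", "stats": "entropy", "classify": "entropy",
             "pls": "stats", "celltype": "pls"}
VALID_GROUPS = {"HC", "MDDNSI", "MDDSI"}


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    k: int = 10
    restarts: int = 25
    covariate_mode: str = "features"
    n_features: int = 60
    folds: int = 5
    components: int = 15
    n_perm: int = 1000
    n_boot: int = 1000
    n_perm_celltype: int = 10000
    alpha: float = 0.05
    behavior_columns: tuple[str, ...] = ("score",)
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the subject manifest CSV."""
    df = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing required column(s): "
                         f"{sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate subject id(s): {sorted(set(dup))}")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)} "
                         f"(expected {sorted(VALID_GROUPS)})")
    for opt in ("sex", "age", "education", "score"):
        if opt not in df.columns:
            logger.warning("manifest lacks optional column %r", opt)
    return df


def _celltype_sets_from_truth(
    gene_ids: list[str], signal_ids: list[str], rng: np.random.Generator
) -> tx.CellTypeSets:
    """Synthetic 7-class cell-type sets; one class is enriched for the
    planted signal genes so the overlap test has a known positive."""
    names = ("astrocytes", "endothelial", "microglia", "excitatory_neurons",
             "inhibitory_neurons", "oligodendrocytes_1", "oligodendrocytes_2")
    background = set(gene_ids)
    sets = {}
    size = max(5, len(gene_ids) // 12)
    for i, name in enumerate(names):
        draw = set(rng.choice(np.array(gene_ids), size=size, replace=False))
        if name == "excitatory_neurons":
            draw |= set(signal_ids)
        sets[name] = draw
    return tx.CellTypeSets(sets, background)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write every artifact.

    Disabled prerequisites auto-skip their dependents (with a logged
    reason).  The returned report (also written as ``report.json``) is
    deterministic for a fixed config and seed; wall-clock timings go to the
    log only.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = list(config.stages)
    for stage in STAGES:
        req = _REQUIRES.get(stage)
        if stage in enabled and req and req not in enabled:
            logger.warning("skipping stage %r: prerequisite %r disabled",
                           stage, req)
            enabled.remove(stage)

    report: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                    "stages_run": enabled, "stages": {}}
    state: dict = {}

    for stage in enabled:
        t0 = time.perf_counter()
        try:
            _run_stage(stage, config, state, report, outdir)
        except Exception:
            (outdir / "FAILED").write_text(stage)
            logger.exception("stage %r failed", stage)
            raise RuntimeError(f"pipeline stage {stage!r} failed") from None
        logger.info("stage %s finished in %.2fs", stage,
                    time.perf_counter() - t0)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    return report


def _run_stage(stage: str, config: RunConfig, state: dict, report: dict,
               outdir: Path) -> None:
    seed = config.seed
    if stage == "simulate":
        scfg = syn.SyntheticConfig(**{"seed": seed, **config.synthetic})
        subjects, manifest, truth = syn.simulate_cohort(scfg)
        subnets = syn.default_subnetwork_map(scfg.n_regions)
        # signal genes track the planted MDDSI-minus-MDDNSI entropy map,
        # which the downstream t map estimates
        grp = manifest.set_index("subject_id")["group"]
        ent = truth.per_subject_entropy
        target = (ent[grp == "MDDSI"].mean(axis=0)
                  - ent[grp == "MDDNSI"].mean(axis=0)).to_numpy()
        signal = list(range(scfg.n_signal_genes))
        expr, _, dist = syn.simulate_expression(
            scfg.n_regions, scfg.n_genes, signal, target,
            scfg.spatial_smoothness, seed=seed + 1)
        truth.signal_gene_ids = [expr.columns[j] for j in signal]
        syn.write_cohort(outdir, subjects, manifest, truth, subnets,
                         expression=expr, distance=dist)
        state.update(subjects=subjects, manifest=manifest, truth=truth,
                     subnets=subnets, expression=expr, distance=dist,
                     syn_config=scfg)
        report["stages"]["simulate"] = {
            "n_subjects": len(subjects),
            "group_sizes": list(scfg.group_sizes),
            "n_regions": scfg.n_regions, "n_time": scfg.n_time,
        }
    elif stage == "entropy":
        table = build_entropy_table(
            state["subjects"], state["manifest"], state["subnets"],
            k=config.k, n_restarts=config.restarts, seed=seed + 2,
            covariate_mode=config.covariate_mode)
        table.to_csv(outdir / "entropy_table.csv", index=False)
        state["table"] = table
        report["stages"]["entropy"] = {
            "k": config.k, "restarts": config.restarts,
            "covariate_mode": config.covariate_mode,
            "global_entropy_mean": round(float(table["global"].mean()), 6),
        }
    elif stage == "stats":
        table = state["table"]
        beh = [c for c in config.behavior_columns if c in table.columns]
        res = gs.run_group_analysis(table, beh, alpha=config.alpha)
        (outdir / "stats_report.json").write_text(
            json.dumps(gs.report_to_dict(res), indent=1, sort_keys=True))
        tmap = gs.tmap_from_table(table)
        pd.DataFrame({"region_id": tmap.region_ids, "t": tmap.values}).to_csv(
            outdir / "tmap.csv", index=False)
        state["tmap"] = tmap
        report["stages"]["stats"] = {
            "significant_measures": res["significant_measures"],
            "omnibus_p_fdr": {m: round(r.p_fdr, 6)
                              for m, r in res["omnibus"].items()},
        }
    elif stage == "classify":
        table = state["table"]
        nodal = [c for c in table.columns if c.startswith("nodal_")]
        X = table[nodal].to_numpy()
        tasks = {}
        n_feat = min(config.n_features, len(nodal))
        for task, (ga, gb) in {
            "hc_vs_mdd": ({"HC"}, {"MDDNSI", "MDDSI"}),
            "nsi_vs_si": ({"MDDNSI"}, {"MDDSI"}),
        }.items():
            y = np.where(table["group"].isin(gb), 1, 0)
            mask = table["group"].isin(ga | gb).to_numpy()
            rep = clf.train_eval_svm_cv(
                X[mask], y[mask], n_folds=config.folds,
                n_features=n_feat, seed=seed + 3)
            top, _ = clf.feature_frequency(rep, top_n=10)
            tasks[task] = {**rep.to_dict(),
                           "top_features": [nodal[i] for i in top]}
        (outdir / "classifier_report.json").write_text(
            json.dumps(tasks, indent=1, sort_keys=True))
        report["stages"]["classify"] = {
            t: {"accuracy": round(d["accuracy"], 4)} for t, d in tasks.items()}
    elif stage == "pls":
        expr, tmap = state["expression"], state["tmap"]
        res = tx.fit_pls(expr, tmap, n_components=min(
            config.components, expr.shape[0] - 2))
        p, _ = tx.permutation_test_pls(expr, tmap, n_perm=config.n_perm,
                                       distance_matrix=state.get("distance"),
                                       seed=seed + 4)
        z, _ = tx.bootstrap_gene_weights(expr, tmap, n_boot=config.n_boot,
                                         seed=seed + 5)
        pos, neg = tx.select_gene_sets(z, res.gene_ids, alpha=config.alpha)
        res.permutation_p, res.bootstrap_z = p, z
        res.pls1_pos, res.pls1_neg = pos, neg
        pd.DataFrame({"gene_id": res.gene_ids, "weight": res.weights,
                      "z": z}).sort_values("z", key=np.abs, ascending=False) \
            .to_csv(outdir / "pls_genes.csv", index=False)
        (outdir / "pls_result.json").write_text(json.dumps({
            "explained_variance": res.explained_variance.tolist(),
            "pls1_explained_variance": res.explained_variance[0],
            "permutation_p": p,
            "score_tmap_correlation": res.score_tmap_correlation,
            "pls1_pos": pos, "pls1_neg": neg,
        }, indent=1, sort_keys=True))
        state["pls"] = res
        report["stages"]["pls"] = {
            "pls1_explained_variance": round(res.explained_variance[0], 6),
            "permutation_p": p,
            "n_pls1_pos": len(pos), "n_pls1_neg": len(neg),
        }
    elif stage == "celltype":
        res = state["pls"]
        truth = state.get("truth")
        rng = np.random.default_rng(config.seed + 6)
        sets = _celltype_sets_from_truth(
            res.gene_ids, truth.signal_gene_ids if truth else [], rng)
        out = {}
        for name, gene_list in (("pls1_pos", res.pls1_pos),
                                ("pls1_neg", res.pls1_neg)):
            if not gene_list:
                logger.warning("%s empty; cell-type test skipped", name)
                out[name] = {"skipped": "empty gene list"}
                continue
            out[name] = tx.celltype_overlap_test(
                gene_list, sets, n_perm=config.n_perm_celltype,
                seed=seed + 7)
        (outdir / "celltype_report.json").write_text(
            json.dumps(out, indent=1, sort_keys=True))
        report["stages"]["celltype"] = out
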