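"""Stage orchestration: simulate -> rsa -> stats -> plsc -> report.

Each stage reads its inputs from the output directory, writes TSV/JSON
artifacts, and records seeds and file checksums in ``manifest.json``.  All
randomness flows from the master seed, split per stage with a counter-based
:class:`numpy.random.SeedSequence` scheme.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from reinstate import __version__, rsa, stats as rstats
from reinstate.config import load_config
from reinstate.plsc import (
    PLSCConfig,
    bootstrap_bsr,
    compare_brain_scores,
    perm_test,
    plsc_fit,
)
from reinstate.sim import (
    DesignParams,
    PlantedEffects,
    ROIMetricTable,
    build_catalog,
    build_design,
    read_archive,
    simulate_behavior,
    simulate_learning,
    simulate_patterns,
    write_archive,
)
from reinstate.sim.archive import config_hash

log = logging.getLogger("reinstate")

STAGES = ("simulate", "rsa", "stats", "plsc", "report")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed + stage index as spawn key."""
    idx = STAGES.index(stage)
    seq = np.random.SeedSequence(master_seed, spawn_key=(idx,))
    return int(seq.generate_state(1)[0])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, out_dir: Path):
        self.path = Path(out_dir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "package_version": __version__,
                "stages": {},
                "checksums": {},
            }

    def record(self, stage, seed, outputs, elapsed, config_digest):
        self.data["stages"][stage] = {
            "seed": seed,
            "elapsed_s": round(elapsed, 3),
            "config_hash": config_digest,
            "outputs": [str(p.name) for p in outputs],
        }
        for p in outputs:
            self.data["checksums"][str(p.name)] = _sha256(p)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))

    def verify(self, filename: str, path: Path):
        want = self.data["checksums"].get(filename)
        if want is None:
            raise FileNotFoundError(
                f"{filename} is not recorded in the manifest; run the producing "
                "stage first"
            )
        if _sha256(path) != want:
            raise RuntimeError(
                f"{filename} changed since it was produced; re-run upstream stages"
            )


def _require(out_dir: Path, name: str, manifest: Manifest) -> Path:
    path = out_dir / name
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream output {name}; run earlier stages first"
        )
    manifest.verify(name, path)
    return path


def run_simulate(cfg: dict, out_dir: Path, manifest: Manifest):
    t0 = time.time()
    seed = stage_seed(cfg["seed"], "simulate")
    sub_seeds = np.random.SeedSequence(seed).generate_state(4)
    log.info("simulate: seed=%s", seed)

    catalog = build_catalog(**cfg["catalog"])
    design = build_design(catalog, DesignParams(**cfg["design"]), seed=int(sub_seeds[0]))
    learning = simulate_learning(
        design,
        learner_accuracy=cfg["learning"]["accuracy"],
        criterion=cfg["learning"]["criterion"],
        min_cycles=cfg["learning"]["min_cycles"],
        max_cycles=cfg["learning"]["max_cycles"],
        seed=int(sub_seeds[1]),
    )
    behavior = simulate_behavior(
        design,
        learning,
        group_retention_means=cfg["behavior"]["retention_means"],
        retention_sd=cfg["behavior"]["retention_sd"],
        timeout_prob=cfg["behavior"]["timeout_prob"],
        seed=int(sub_seeds[2]),
    )
    pat_cfg = cfg["patterns"]
    planted = PlantedEffects(
        rho=pat_cfg["rho"],
        gamma=pat_cfg["gamma"],
        gamma_incorrect=pat_cfg["gamma_incorrect"],
        a=pat_cfg["a"],
        b=pat_cfg["b"],
        sigma=pat_cfg["sigma"],
        n_voxels=pat_cfg["n_voxels"],
        rois=tuple(pat_cfg["rois"]),
        control_rois=tuple(pat_cfg["control_rois"]),
    )
    patterns = simulate_patterns(design, behavior, planted, seed=int(sub_seeds[3]))

    out_dir.mkdir(parents=True, exist_ok=True)
    archive_dir = out_dir / "archive"
    write_archive(patterns, archive_dir)
    behavior_path = out_dir / "behavior.tsv"
    behavior.trials.to_csv(behavior_path, sep="\t", index=False)
    retention_path = out_dir / "retention.tsv"
    behavior.retention_rates().to_csv(retention_path, sep="\t", index=False)
    learning_path = out_dir / "learning.tsv"
    learning.table.to_csv(learning_path, sep="\t", index=False)

    manifest.record(
        "simulate",
        seed,
        [behavior_path, retention_path, learning_path, archive_dir / "meta.json"],
        time.time() - t0,
        config_hash(cfg),
    )
    return patterns


def run_rsa(cfg: dict, out_dir: Path, manifest: Manifest):
    t0 = time.time()
    seed = stage_seed(cfg["seed"], "rsa")
    _require(out_dir, "behavior.tsv", manifest)
    patterns = read_archive(out_dir / "archive")
    indices = rsa.compute_indices(patterns, alpha=cfg["stats"]["alpha"])
    path = out_dir / "indices.tsv"
    indices.to_csv(path, sep="\t", index=False)
    manifest.record("rsa", seed, [path], time.time() - t0, config_hash(cfg))
    return indices


def run_stats(cfg: dict, out_dir: Path, manifest: Manifest):
    t0 = time.time()
    seed = stage_seed(cfg["seed"], "stats")
    indices = pd.read_csv(_require(out_dir, "indices.tsv", manifest), sep="\t")
    retention = pd.read_csv(_require(out_dir, "retention.tsv", manifest), sep="\t")

    results = {"seed": seed, "df_method": "satterthwaite", "models": {}, "gist_tests": []}
    rows = []

    # retention model: delay condition x group with subject random intercept
    ret_model = rstats.fit_condition_model(
        retention, "retention", ["delay_condition", "group"]
    )
    results["models"]["retention"] = _model_json(ret_model)
    rows.extend(_model_rows("behavior", "retention", ret_model))

    # per-ROI condition models on the corrected reinstatement index
    scene = indices[indices["index_type"] == "scene_reinstatement"]
    roi_effect_p = {}
    for roi, block in scene.groupby("roi"):
        model = rstats.fit_condition_model(
            block.dropna(subset=["value"]), "value", ["condition", "group"]
        )
        results["models"][f"reinstatement:{roi}"] = _model_json(model)
        rows.extend(_model_rows(roi, "scene_reinstatement", model))
        roi_effect_p[roi] = {e.name: e.p for e in model.effects}

    # FDR across ROIs per effect name
    _fdr_across_rois(rows)

    # sign-flip permutation tests of the gist index against zero
    gist = indices[indices["index_type"] == "gist"].dropna(subset=["value"])
    gist_p = []
    for (roi, group, cond), block in gist.groupby(["roi", "group", "condition"]):
        if len(block) < 3:
            continue
        cell_key = int(
            hashlib.sha256(f"{roi}|{group}|{cond}".encode()).hexdigest()[:8], 16
        )
        res = rstats.sign_flip_perm_test(
            block["value"].to_numpy(),
            n_perm=cfg["stats"]["n_perm"],
            seed=seed + cell_key,
        )
        gist_p.append(
            {
                "roi": roi,
                "group": group,
                "condition": cond,
                "mean": float(block["value"].mean()),
                "t": res.observed,
                "p": res.p,
                "n": int(len(block)),
            }
        )
    if gist_p:
        padj = rstats.fdr_bh([g["p"] for g in gist_p])
        for g, pa in zip(gist_p, padj):
            g["p_fdr"] = float(pa)
    results["gist_tests"] = gist_p

    stats_tsv = out_dir / "stats.tsv"
    pd.DataFrame(rows).to_csv(stats_tsv, sep="\t", index=False)
    stats_json = out_dir / "stats.json"
    stats_json.write_text(json.dumps(results, indent=2, sort_keys=True, default=float))
    manifest.record(
        "stats", seed, [stats_tsv, stats_json], time.time() - t0, config_hash(cfg)
    )
    return results


def _model_json(model: rstats.StatResult) -> dict:
    return {
        "effects": [vars(e) for e in model.effects],
        "posthoc": [vars(c) for c in model.posthoc],
        "meta": model.meta,
    }


def _model_rows(scope, metric, model: rstats.StatResult):
    rows = []
    for e in model.effects:
        rows.append(
            {
                "scope": scope,
                "metric": metric,
                "kind": "effect",
                "name": e.name,
                "F": e.F,
                "df1": e.df1,
                "df2": e.df2,
                "b": np.nan,
                "t": np.nan,
                "p": e.p,
                "p_adjusted": e.p_adjusted,
                "omega2": e.omega2,
            }
        )
    for c in model.posthoc:
        rows.append(
            {
                "scope": scope,
                "metric": metric,
                "kind": "posthoc",
                "name": c.label,
                "F": np.nan,
                "df1": np.nan,
                "df2": c.df,
                "b": c.b,
                "t": c.t,
                "p": c.p,
                "p_adjusted": c.p_sidak,
                "omega2": np.nan,
            }
        )
    return rows


def _fdr_across_rois(rows):
    """FDR-adjust omnibus effect p-values across ROI models, per effect name."""
    from collections import defaultdict

    groups = defaultdict(list)
    for i, r in enumerate(rows):
        if r["kind"] == "effect" and r["metric"] == "scene_reinstatement":
            groups[r["name"]].append(i)
    for name, ixs in groups.items():
        adj = rstats.fdr_bh([rows[i]["p"] for i in ixs])
        for i, pa in zip(ixs, adj):
            rows[i]["p_adjusted"] = float(pa)


def run_plsc(cfg: dict, out_dir: Path, manifest: Manifest):
    t0 = time.time()
    seed = stage_seed(cfg["seed"], "plsc")
    indices = pd.read_csv(_require(out_dir, "indices.tsv", manifest), sep="\t")
    retention = pd.read_csv(_require(out_dir, "retention.tsv", manifest), sep="\t")

    metric = cfg["plsc"]["metric"]
    condition = cfg["plsc"]["condition"]
    block = indices[
        (indices["index_type"] == metric) & (indices["condition"] == condition)
    ]
    wide = block.pivot_table(index="subject_id", columns="roi", values="value")
    groups = block.drop_duplicates("subject_id").set_index("subject_id")["group"]
    beh = retention[retention["delay_condition"] == condition].set_index("subject_id")[
        "retention"
    ]
    common = wide.index.intersection(beh.index)
    table = ROIMetricTable(
        metrics=wide.loc[common],
        behavior=beh.loc[common],
        groups=groups.loc[common],
    )

    config = PLSCConfig(
        n_perm=cfg["plsc"]["n_perm"],
        n_boot=cfg["plsc"]["n_boot"],
        z_threshold=cfg["plsc"]["z_threshold"],
        seed=seed,
    )
    model = plsc_fit(table, config)
    perm_test(model, table, config)
    bootstrap_bsr(model, table, config)
    comparison = compare_brain_scores(model)

    payload = {
        "metric": metric,
        "condition": condition,
        "rois": model.rois,
        "R": model.R.tolist(),
        "singular_value": model.singular_value,
        "saliences": model.saliences.tolist(),
        "u": model.u,
        "latent_spearman_r": model.latent_r,
        "roi_behavior_spearman_r": model.roi_behavior_r.tolist(),
        "p_perm": model.p_perm,
        "bsr": model.bsr.tolist(),
        "robust": [bool(x) for x in model.robust],
        "n_dropped": model.n_dropped,
        "group_comparison": vars(comparison),
        "config": {
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "z_threshold": config.z_threshold,
            "seed": seed,
        },
    }
    plsc_json = out_dir / "plsc.json"
    plsc_json.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    scores = out_dir / "brain_scores.tsv"
    pd.DataFrame(
        {
            "subject_id": model.brain_scores.index,
            "group": model.groups.to_numpy(),
            "brain_score": model.brain_scores.to_numpy(),
            "behavior": model.behavior.to_numpy(),
        }
    ).to_csv(scores, sep="\t", index=False)
    manifest.record(
        "plsc", seed, [plsc_json, scores], time.time() - t0, config_hash(cfg)
    )
    return payload


def run_report(cfg: dict, out_dir: Path, manifest: Manifest):
    from reinstate.report import make_report

    t0 = time.time()
    seed = stage_seed(cfg["seed"], "report")
    outputs = make_report(out_dir)
    manifest.record("report", seed, outputs, time.time() - t0, config_hash(cfg))
    return outputs


def run_pipeline(config_path=None, stages=None, out_dir="results", overrides=None):
    cfg = load_config(config_path, overrides)
    out_dir = Path(out_dir)
    manifest = Manifest(out_dir)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    runners = {
        "simulate": run_simulate,
        "rsa": run_rsa,
        "stats": run_stats,
        "plsc": run_plsc,
        "report": run_report,
    }
    for stage in STAGES:
        if stage in stages:
            log.info("running stage %s", stage)
            runners[stage](cfg, out_dir, manifest)
    return manifest
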