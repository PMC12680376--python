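"""Plain-text + JSON summary report collating pipeline outputs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _delay_ordering(indices: pd.DataFrame) -> dict:
    """Group-mean corrected reinstatement by delay, with the recovered order."""
    scene = indices[indices["index_type"] == "scene_reinstatement"]
    out = {}
    for group, block in scene.groupby("group"):
        means = block.groupby("condition")["value"].mean()
        conds = [c for c in ("recent", "remote_short", "remote_long") if c in means]
        out[group] = {
            "means": {c: float(means[c]) for c in conds},
            "recovered_order": sorted(conds, key=lambda c: -means[c]),
        }
    return out


def make_report(out_dir) -> list:
    """Write report.txt / report.json from stats and PLSC outputs.

    Partial upstream outputs produce a partial report with warnings; a
    completely empty stats directory is an error.
    """
    out_dir = Path(out_dir)
    warnings = []
    sections = {}

    indices_path = out_dir / "indices.tsv"
    stats_path = out_dir / "stats.json"
    plsc_path = out_dir / "plsc.json"
    meta_path = out_dir / "archive" / "meta.json"

    if not stats_path.exists() and not plsc_path.exists():
        raise FileNotFoundError(
            f"no stats.json or plsc.json under {out_dir}; run upstream stages"
        )

    if indices_path.exists():
        indices = pd.read_csv(indices_path, sep="\t")
        summary = (
            indices.groupby(["roi", "group", "condition", "index_type"])["value"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        sections["index_means"] = summary.to_dict(orient="records")
        sections["delay_ordering"] = _delay_ordering(indices)
    else:
        warnings.append("indices.tsv missing; skipping index summaries")

    if stats_path.exists():
        sections["stats"] = json.loads(stats_path.read_text())
    else:
        warnings.append("stats.json missing")
    if plsc_path.exists():
        sections["plsc"] = json.loads(plsc_path.read_text())
    else:
        warnings.append("plsc.json missing")

    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        planted = meta.get("planted", {})
        sections["planted"] = planted
        if "delay_ordering" in sections and "rho" in planted:
            recovery = {}
            for group, table in planted["rho"].items():
                planted_order = sorted(table, key=lambda c: -table[c])
                got = sections["delay_ordering"].get(group, {}).get("recovered_order")
                recovery[group] = {
                    "planted_order": planted_order,
                    "recovered_order": got,
                    "match": got == planted_order,
                }
            sections["recovery_vs_planted"] = recovery

    payload = {"warnings": warnings, "sections": sections}
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))

    lines = ["# Pipeline report", ""]
    for w in warnings:
        lines.append(f"WARNING: {w}")
    if "delay_ordering" in sections:
        lines.append("## Corrected reinstatement: group means by delay")
        for group, info in sections["delay_ordering"].items():
            means = ", ".join(f"{c}={v:.4f}" for c, v in info["means"].items())
            lines.append(f"  {group}: {means}")
            lines.append(f"  {group} recovered order: {' > '.join(info['recovered_order'])}")
    if "recovery_vs_planted" in sections:
        lines.append("## Recovery vs planted")
        for group, info in sections["recovery_vs_planted"].items():
            lines.append(
                f"  {group}: planted {' > '.join(info['planted_order'])} | "
                f"recovered {' > '.join(info['recovered_order'] or [])} | "
                f"match={info['match']}"
            )
    if "plsc" in sections:
        p = sections["plsc"]
        lines.append("## PLSC")
        lines.append(
            f"  metric={p['metric']} condition={p['condition']} "
            f"S={p['singular_value']:.4f} latent Spearman r={p['latent_spearman_r']:.3f} "
            f"p_perm={p['p_perm']:.4g}"
        )
        for roi, sal, bsr, robust in zip(
            p["rois"], p["saliences"], p["bsr"], p["robust"]
        ):
            flag = "*" if robust else " "
            lines.append(f"    {roi:>8s} salience={sal:+.3f} BSR={bsr:+.2f} {flag}")
    if "stats" in sections and "gist_tests" in sections["stats"]:
        lines.append("## Gist permutation tests (FDR-adjusted)")
        for g in sections["stats"]["gist_tests"]:
            lines.append(
                f"  {g['roi']:>8s} {g['group']:>8s} {g['condition']:>12s} "
                f"mean={g['mean']:+.4f} p={g['p']:.4f} p_fdr={g.get('p_fdr', float('nan')):.4f}"
            )
    txt_path = out_dir / "report.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return [txt_path, json_path]
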