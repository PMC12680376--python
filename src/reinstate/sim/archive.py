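"""Plain-text pattern archive: one directory per subject, TSV + JSON.

Layout::

    <root>/meta.json                     seed, config hash, planted parameters
    <root>/<subject>/trials.tsv          trial metadata (0-based run/trial)
    <root>/<subject>/mean_activation.tsv per ROI x session scalar covariate
    <root>/<subject>/<roi>__<window>.tsv trial_uid, v0001..vNNNN

The same layout can hold real single-event beta estimates exported to TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from reinstate.sim.patterns import EVENT_WINDOWS, PatternSet

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "run",
    "trial",
    "item_id",
    "item_type",
    "category",
    "delay_condition",
    "learned",
    "correct",
    "timeout",
    "rt",
]


def trial_uids(trials: pd.DataFrame) -> list:
    return [
        f"{s}_r{r}_t{t}"
        for s, r, t in zip(trials["session"], trials["run"], trials["trial"])
    ]


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_archive(pattern_set: PatternSet, root) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    meta = dict(pattern_set.meta)
    meta["config_hash"] = config_hash(meta.get("planted", {}))
    (root / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    for subject_id in pattern_set.subjects:
        sdir = root / subject_id
        sdir.mkdir(exist_ok=True)
        strials = pattern_set.subject_trials(subject_id)
        cols = [c for c in TRIAL_COLUMNS if c in strials.columns]
        strials[cols].to_csv(sdir / "trials.tsv", sep="\t", index=False)
        act = pattern_set.mean_activation
        act[act["subject_id"] == subject_id].to_csv(
            sdir / "mean_activation.tsv", sep="\t", index=False
        )
        uids = trial_uids(strials)
        for roi in pattern_set.rois:
            for window in EVENT_WINDOWS:
                key = (subject_id, roi, window)
                if key not in pattern_set.patterns:
                    continue
                mat = pattern_set.patterns[key]
                df = pd.DataFrame(
                    mat,
                    columns=[f"v{j + 1:04d}" for j in range(mat.shape[1])],
                )
                df.insert(0, "trial_uid", uids)
                # %.17g guarantees bit-exact float64 round-trips
                df.to_csv(
                    sdir / f"{roi}__{window}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.17g",
                )
    return root


def read_archive(root) -> PatternSet:
    root = Path(root)
    meta = json.loads((root / "meta.json").read_text())
    subject_dirs = sorted(p for p in root.iterdir() if p.is_dir())

    patterns = {}
    trials_frames = []
    act_frames = []
    for sdir in subject_dirs:
        strials = pd.read_csv(sdir / "trials.tsv", sep="\t")
        trials_frames.append(strials)
        act_frames.append(pd.read_csv(sdir / "mean_activation.tsv", sep="\t"))
        uids = trial_uids(strials)
        for f in sorted(sdir.glob("*__*.tsv")):
            roi, window = f.stem.split("__", 1)
            df = pd.read_csv(f, sep="\t", float_precision="round_trip")
            if list(df["trial_uid"]) != uids:
                raise ValueError(f"{f}: trial_uid order does not match trials.tsv")
            patterns[(sdir.name, roi, window)] = df.drop(
                columns="trial_uid"
            ).to_numpy(dtype=np.float64)
    trials = pd.concat(trials_frames, ignore_index=True)
    if trials.isna().drop(columns=["rt"], errors="ignore").any().any():
        raise ValueError("trial metadata contains missing values")
    return PatternSet(
        patterns=patterns,
        trials=trials,
        mean_activation=pd.concat(act_frames, ignore_index=True),
        meta=meta,
    )
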