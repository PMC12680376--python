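"""Multivoxel beta-pattern generator with planted effect structure.

Each retrieval trial yields three event-window patterns over voxels:

* scene window:    ``a * u_item + b * v_category + noise``
* fixation window: ``rho * u_item + gamma * v_category + noise`` for correct
  trials; ``gamma_incorrect * v_category + noise`` (no item loading) for
  incorrect ones
* object window:   ``w_item + noise``

``u``, ``v``, ``w`` are independent voxel templates with unit per-voxel RMS
drawn once per subject x ROI and shared across that subject's sessions;
noise is iid Normal(0, sigma^2).  Control ROIs carry pure noise in every
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reinstate.errors import ConfigurationError
from reinstate.sim.behavior import BehavioralTable
from reinstate.sim.design import DELAY_CONDITIONS, ExperimentalDesign

EVENT_WINDOWS = ("object", "fixation", "scene")


def _as_loading_table(value, name: str) -> dict:
    """Normalize a loading spec (scalar | {delay: x} | {group: {delay: x}})
    to a ``{group: {delay: float}}``-style lookup callable-free dict."""
    def expand(v):
        if isinstance(v, dict):
            missing = [c for c in DELAY_CONDITIONS if c not in v]
            if missing:
                raise ConfigurationError(f"{name} missing delays {missing}")
            return {c: float(v[c]) for c in DELAY_CONDITIONS}
        return {c: float(v) for c in DELAY_CONDITIONS}

    if isinstance(value, dict) and any(isinstance(v, dict) for v in value.values()):
        return {g: expand(v) for g, v in value.items()}
    table = expand(value)
    return {"children": table, "adults": table}


@dataclass(frozen=True)
class PlantedEffects:
    """Effect-structure parameters for the pattern generator."""

    rho: object = 0.0  # fixation item loading; scalar or [group][delay]
    gamma: object = 0.0  # fixation category loading; scalar or [group][delay]
    gamma_incorrect: float = 0.0
    a: float = 1.0  # scene-window item loading
    b: float = 0.0  # scene-window category loading
    sigma: float = 1.0
    n_voxels: int = 200
    rois: tuple = ("HCa", "HCp", "PHGa", "PHGp", "mPFC")
    control_rois: tuple = ()
    mean_activation_mean: float = 0.5
    mean_activation_sd: float = 0.1

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.n_voxels < 10:
            raise ConfigurationError("n_voxels must be >= 10")
        if not self.rois and not self.control_rois:
            raise ConfigurationError("at least one ROI is required")
        self.rho_table()
        self.gamma_table()

    def rho_table(self) -> dict:
        return _as_loading_table(self.rho, "rho")

    def gamma_table(self) -> dict:
        return _as_loading_table(self.gamma, "gamma")

    @property
    def all_rois(self) -> tuple:
        return tuple(self.rois) + tuple(self.control_rois)


@dataclass
class PatternSet:
    """Trial x voxel beta patterns aligned to trial metadata.

    ``patterns[(subject_id, roi, window)]`` is an (n_trials, n_voxels) array
    row-aligned to ``subject_trials(subject_id)``.
    """

    patterns: dict
    trials: pd.DataFrame
    mean_activation: pd.DataFrame  # subject_id, roi, session, value
    meta: dict = field(default_factory=dict)
    _trial_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def rois(self) -> tuple:
        return tuple(self.meta.get("rois", ()))

    @property
    def subjects(self) -> tuple:
        return tuple(dict.fromkeys(self.trials["subject_id"]))

    def subject_trials(self, subject_id: str) -> pd.DataFrame:
        if subject_id not in self._trial_cache:
            sub = self.trials[self.trials["subject_id"] == subject_id]
            self._trial_cache[subject_id] = sub.sort_values(
                ["session", "run", "trial"]
            ).reset_index(drop=True)
        return self._trial_cache[subject_id]

    def get(self, subject_id: str, roi: str, window: str) -> np.ndarray:
        return self.patterns[(subject_id, roi, window)]


def _unit_templates(rng, n: int, n_voxels: int) -> np.ndarray:
    # rows scaled to unit per-voxel RMS (norm sqrt(n_voxels)) so a loading
    # of rho contributes rho^2 to the per-voxel pattern variance and the
    # within-trial fixation-scene correlation has the closed form
    # rho * a / sqrt((rho^2 + sigma^2) * (a^2 + sigma^2))
    t = rng.standard_normal((n, n_voxels))
    t *= np.sqrt(n_voxels) / np.linalg.norm(t, axis=1, keepdims=True)
    return t


def simulate_patterns(
    design: ExperimentalDesign,
    behavior: BehavioralTable,
    planted: PlantedEffects,
    seed: int = 0,
) -> PatternSet:
    """Generate beta patterns for every subject x ROI x event window."""
    rho = planted.rho_table()
    gamma = planted.gamma_table()
    root = np.random.SeedSequence(seed)
    subject_ids = list(design.subjects["subject_id"])
    seqs = root.spawn(len(subject_ids))
    group_of = dict(zip(design.subjects["subject_id"], design.subjects["group"]))

    patterns = {}
    act_rows = []
    for subject_id, seq in zip(subject_ids, seqs):
        rng = np.random.default_rng(seq)
        strials = behavior.trials[behavior.trials["subject_id"] == subject_id]
        strials = strials.sort_values(["session", "run", "trial"]).reset_index(drop=True)
        group = group_of[subject_id]
        n_trials = len(strials)
        items = list(dict.fromkeys(strials["item_id"]))
        cats = list(dict.fromkeys(strials["category"]))
        item_ix = strials["item_id"].map({k: i for i, k in enumerate(items)}).to_numpy()
        cat_ix = strials["category"].map({k: i for i, k in enumerate(cats)}).to_numpy()
        correct = strials["correct"].to_numpy().astype(bool)
        delay = strials["delay_condition"].to_numpy()

        rho_load = np.where(
            correct, [rho[group][d] for d in delay], 0.0
        )
        gamma_load = np.where(
            correct, [gamma[group][d] for d in delay], planted.gamma_incorrect
        )

        for roi in planted.all_rois:
            is_control = roi in planted.control_rois
            if not is_control:
                u = _unit_templates(rng, len(items), planted.n_voxels)
                v = _unit_templates(rng, len(cats), planted.n_voxels)
                w = _unit_templates(rng, len(items), planted.n_voxels)
            noise = {
                win: planted.sigma
                * rng.standard_normal((n_trials, planted.n_voxels))
                for win in EVENT_WINDOWS
            }
            if is_control:
                for win in EVENT_WINDOWS:
                    patterns[(subject_id, roi, win)] = noise[win]
            else:
                ut = u[item_ix]
                vt = v[cat_ix]
                patterns[(subject_id, roi, "scene")] = (
                    planted.a * ut + planted.b * vt + noise["scene"]
                )
                patterns[(subject_id, roi, "fixation")] = (
                    rho_load[:, None] * ut + gamma_load[:, None] * vt + noise["fixation"]
                )
                patterns[(subject_id, roi, "object")] = w[item_ix] + noise["object"]
            for session in dict.fromkeys(strials["session"]):
                act_rows.append(
                    {
                        "subject_id": subject_id,
                        "roi": roi,
                        "session": session,
                        "value": float(
                            rng.normal(
                                planted.mean_activation_mean,
                                planted.mean_activation_sd,
                            )
                        ),
                    }
                )

    meta = {
        "seed": int(seed),
        "rois": list(planted.all_rois),
        "control_rois": list(planted.control_rois),
        "n_voxels": int(planted.n_voxels),
        "planted": {
            "rho": rho,
            "gamma": gamma,
            "gamma_incorrect": planted.gamma_incorrect,
            "a": planted.a,
            "b": planted.b,
            "sigma": planted.sigma,
        },
    }
    return PatternSet(
        patterns=patterns,
        trials=behavior.trials.copy(),
        mean_activation=pd.DataFrame(act_rows),
        meta=meta,
    )
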