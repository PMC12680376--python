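"""Retrieval behavior simulation: correctness, reaction times, retention."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from reinstate.errors import ConfigurationError
from reinstate.sim.design import DELAY_CONDITIONS, ExperimentalDesign
from reinstate.sim.learning import LearningResult

CHANCE_LEVEL = 1.0 / 3.0  # 3AFC guessing rate for items not initially learned


@dataclass(frozen=True)
class BehavioralTable:
    """Trial-level outcomes plus per-subject retention-rate targets."""

    trials: pd.DataFrame  # design trial columns + learned, correct, timeout, rt
    retention_targets: pd.DataFrame  # subject_id, group, delay_condition, rate

    def retention_rates(self) -> pd.DataFrame:
        """Observed retention: % correct among initially learned, non-timeout
        trials, per subject x delay condition."""
        t = self.trials
        ok = t[t["learned"] & ~t["timeout"]]
        out = (
            ok.groupby(["subject_id", "group", "delay_condition"], observed=True)["correct"]
            .mean()
            .mul(100.0)
            .rename("retention")
            .reset_index()
        )
        return out


def simulate_behavior(
    design: ExperimentalDesign,
    learning: LearningResult,
    group_retention_means: dict,
    retention_sd: float = 8.0,
    seed: int = 0,
    timeout_prob=0.0,
    rt_shift: float = 0.8,
    rt_mu: float = -0.3,
    rt_sigma: float = 0.4,
) -> BehavioralTable:
    """Draw per-subject retention rates and trial-level outcomes.

    ``group_retention_means[group][delay_condition]`` are percentages;
    each subject's condition rate is drawn Normal(mean, retention_sd) and
    clipped to [0, 100].  Correctness for initially learned items is
    Bernoulli at that rate; unlearned items fall back to 3AFC chance.
    Reaction times are a shifted lognormal (plumbing only).  ``timeout_prob``
    (scalar or per-group dict) marks trials as timed out; these are scored
    incorrect and excluded from retention.
    """
    for group, means in group_retention_means.items():
        for cond in DELAY_CONDITIONS:
            if cond not in means:
                raise ConfigurationError(
                    f"group_retention_means[{group!r}] missing {cond!r}"
                )
            if not 0.0 <= float(means[cond]) <= 100.0:
                raise ConfigurationError("retention means must be in [0, 100]")
    if retention_sd < 0:
        raise ConfigurationError("retention_sd must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subjects = design.subjects

    target_rows = []
    rates = {}
    for _, subj in subjects.iterrows():
        means = group_retention_means[subj.group]
        for cond in DELAY_CONDITIONS:
            rate = float(
                np.clip(rng.normal(float(means[cond]), retention_sd), 0.0, 100.0)
            )
            rates[(subj.subject_id, cond)] = rate
            target_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "delay_condition": cond,
                    "rate": rate,
                }
            )

    trials = design.trials.copy()
    enc_session = np.where(trials["item_type"] == "remote", "day0", trials["session"])
    learned = np.array(
        [
            item in learning.learned_items[(sid, ses)]
            for sid, ses, item in zip(
                trials["subject_id"], enc_session, trials["item_id"]
            )
        ]
    )
    p_correct = np.array(
        [
            rates[(sid, cond)] / 100.0 if ok else CHANCE_LEVEL
            for sid, cond, ok in zip(
                trials["subject_id"], trials["delay_condition"], learned
            )
        ]
    )
    correct = (rng.random(len(trials)) < p_correct).astype(int)

    if isinstance(timeout_prob, dict):
        p_to = trials["group"].map(timeout_prob).astype(float).to_numpy()
    else:
        p_to = np.full(len(trials), float(timeout_prob))
    timeout = rng.random(len(trials)) < p_to
    correct[timeout] = 0

    rt = rt_shift + rng.lognormal(rt_mu, rt_sigma, size=len(trials))
    rt[timeout] = np.nan

    trials["learned"] = learned
    trials["correct"] = correct
    trials["timeout"] = timeout
    trials["rt"] = rt
    return BehavioralTable(
        trials=trials, retention_targets=pd.DataFrame(target_rows)
    )
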