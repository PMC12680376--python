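"""Adaptive learning-to-criterion simulation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from reinstate.errors import ConfigurationError
from reinstate.sim.design import ExperimentalDesign


@dataclass(frozen=True)
class LearningResult:
    """Per subject x encoding session: cycles run, per-cycle accuracy, and
    the set of items answered correctly on the final cycle."""

    table: pd.DataFrame  # subject_id, session, cycles_executed, final_accuracy
    cycle_accuracy: dict  # (subject_id, session) -> tuple of proportions
    learned_items: dict  # (subject_id, session) -> frozenset of item_ids

    def learned(self, subject_id: str, session: str) -> frozenset:
        return self.learned_items[(subject_id, session)]


def _resolve_accuracy(learner_accuracy, group: str) -> float:
    p = learner_accuracy[group] if isinstance(learner_accuracy, dict) else learner_accuracy
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError("learner_accuracy must be in [0, 1]")
    return p


def simulate_learning(
    design: ExperimentalDesign,
    learner_accuracy=0.85,
    criterion: float = 0.83,
    min_cycles: int = 2,
    max_cycles: int = 4,
    seed: int = 0,
    sampler: str = "bernoulli",
) -> LearningResult:
    """Run adaptive retrieval-encoding cycles until criterion.

    Cycling halts at the first cycle whose accuracy is >= ``criterion``
    (inclusive) once ``min_cycles`` have run, else at ``max_cycles``.
    ``learner_accuracy`` is the per-item per-cycle success probability,
    either a scalar or a mapping by group.  ``sampler="exact"`` makes the
    number of correct items deterministic (round(p * n), first items
    correct) for boundary testing.

    ``learned_items`` holds the items answered correctly on the final
    cycle; downstream retention is computed only over these.
    """
    if not 0.0 < criterion <= 1.0:
        raise ConfigurationError("criterion must be in (0, 1]")
    if min_cycles > max_cycles:
        raise ConfigurationError("min_cycles must be <= max_cycles")
    if min_cycles < 1:
        raise ConfigurationError("min_cycles must be >= 1")
    if sampler not in ("bernoulli", "exact"):
        raise ConfigurationError("sampler must be 'bernoulli' or 'exact'")

    group_of = dict(zip(design.subjects["subject_id"], design.subjects["group"]))
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    cycle_accuracy = {}
    learned_items = {}
    enc = design.encoding
    for (subject_id, session), block in enc.groupby(["subject_id", "session"], sort=True):
        items = list(block["item_id"])
        p = _resolve_accuracy(learner_accuracy, group_of[subject_id])
        accs = []
        correct_mask = np.zeros(len(items), dtype=bool)
        for cycle in range(1, max_cycles + 1):
            if sampler == "bernoulli":
                correct_mask = rng.random(len(items)) < p
            else:
                k = int(round(p * len(items)))
                correct_mask = np.arange(len(items)) < k
            acc = float(correct_mask.mean())
            accs.append(acc)
            if cycle >= min_cycles and acc >= criterion:
                break
        key = (subject_id, session)
        cycle_accuracy[key] = tuple(accs)
        learned_items[key] = frozenset(
            item for item, ok in zip(items, correct_mask) if ok
        )
        rows.append(
            {
                "subject_id": subject_id,
                "session": session,
                "cycles_executed": len(accs),
                "final_accuracy": accs[-1],
            }
        )
    return LearningResult(
        table=pd.DataFrame(rows),
        cycle_accuracy=cycle_accuracy,
        learned_items=learned_items,
    )
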