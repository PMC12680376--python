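"""Experimental design generator: subjects, item sets, and retrieval trials.

The emulated design has three testing days.  On day 0 subjects learn a large
item set that is later split into two remote sets; on day 1 and day 14 they
learn a fresh recent set and then retrieve, in the scanner, a mix of that
day's recent items and remote items from day 0.  Retrieval trials are
organized into runs holding a fixed number of recent and remote items each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reinstate.errors import ConfigurationError
from reinstate.sim.catalog import StimulusCatalog

GROUPS = ("children", "adults")
RETRIEVAL_SESSIONS = ("day1", "day14")
DELAY_CONDITIONS = ("recent", "remote_short", "remote_long")

#: Maximum reshuffles before the same-category run-order constraint is relaxed.
_MAX_SHUFFLES = 2000


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the emulated three-day design."""

    n_children: int = 20
    n_adults: int = 20
    runs_per_session: int = 3
    recent_per_run: int = 10
    remote_per_run: int = 10
    max_consecutive_same_category: int = 2

    def __post_init__(self):
        if self.runs_per_session < 1:
            raise ConfigurationError("runs_per_session must be >= 1")
        if self.recent_per_run < 1 or self.remote_per_run < 1:
            raise ConfigurationError("recent/remote items per run must be >= 1")
        if self.n_children < 0 or self.n_adults < 0:
            raise ConfigurationError("group sizes must be >= 0")
        if self.n_children + self.n_adults == 0:
            raise ConfigurationError("at least one subject is required")

    @property
    def recent_per_session(self) -> int:
        return self.runs_per_session * self.recent_per_run

    @property
    def remote_per_session(self) -> int:
        return self.runs_per_session * self.remote_per_run

    @property
    def trials_per_session(self) -> int:
        return self.recent_per_session + self.remote_per_session

    @property
    def items_per_subject(self) -> int:
        # day0 pool (both remote sets) + one recent set per retrieval session
        return self.remote_per_session * 2 + self.recent_per_session * 2


@dataclass(frozen=True)
class ExperimentalDesign:
    """Subjects, per-session encoding sets, and retrieval trial lists."""

    subjects: pd.DataFrame  # subject_id, group
    encoding: pd.DataFrame  # subject_id, session, item_id, category
    trials: pd.DataFrame  # subject_id, group, session, run, trial, item_id, ...
    params: DesignParams = field(default_factory=DesignParams)

    def subject_trials(self, subject_id: str) -> pd.DataFrame:
        sub = self.trials[self.trials["subject_id"] == subject_id]
        return sub.sort_values(["session", "run", "trial"]).reset_index(drop=True)


def _balanced_draw(rng, by_category: dict, n: int) -> list:
    """Draw ``n`` items cycling over categories (category-balanced up to
    divisibility); ``by_category`` lists are consumed in place."""
    cats = [c for c in by_category if by_category[c]]
    order = list(cats)
    rng.shuffle(order)
    out = []
    while len(out) < n:
        progressed = False
        for cat in order:
            if len(out) >= n:
                break
            if by_category[cat]:
                out.append(by_category[cat].pop())
                progressed = True
        if not progressed:
            raise ConfigurationError("catalog too small for requested design")
    return out


def _order_run(rng, items: list, categories: dict, max_same: int) -> list:
    """Shuffle a run's trial order rejecting >max_same consecutive
    same-category trials; falls back to the best sequence found."""
    best = None
    best_viol = None
    items = list(items)
    for _ in range(_MAX_SHUFFLES):
        rng.shuffle(items)
        viol = 0
        streak = 1
        for a, b in zip(items, items[1:]):
            if categories[a] == categories[b]:
                streak += 1
                if streak > max_same:
                    viol += 1
            else:
                streak = 1
        if viol == 0:
            return list(items)
        if best_viol is None or viol < best_viol:
            best, best_viol = list(items), viol
    return best  # pragma: no cover - pathological category mixes only


def build_design(
    catalog: StimulusCatalog,
    params: DesignParams | None = None,
    seed: int = 0,
) -> ExperimentalDesign:
    """Generate subjects, item allocations, and retrieval trials.

    Per subject, distinct scene items are allocated without reuse: a day-0
    pool that splits category-balanced into the day-1 and day-14 remote
    sets, plus a fresh recent set for each retrieval session.  Each run
    holds ``recent_per_run`` recent and ``remote_per_run`` remote items in
    an order without long same-category streaks.
    """
    params = params or DesignParams()
    if params.items_per_subject > catalog.n_scenes:
        raise ConfigurationError(
            f"catalog has {catalog.n_scenes} scenes but the design needs "
            f"{params.items_per_subject} distinct items per subject"
        )

    scene_cat = dict(zip(catalog.scenes["scene_id"], catalog.scenes["category"]))
    subjects = []
    for i in range(params.n_children):
        subjects.append({"subject_id": f"child{i:03d}", "group": "children"})
    for i in range(params.n_adults):
        subjects.append({"subject_id": f"adult{i:03d}", "group": "adults"})
    subjects = pd.DataFrame(subjects)

    root = np.random.SeedSequence(seed)
    child_seqs = root.spawn(len(subjects))

    enc_rows = []
    trial_rows = []
    for (_, subj), seq in zip(subjects.iterrows(), child_seqs):
        rng = np.random.default_rng(seq)
        by_cat = {}
        for sid, cat in scene_cat.items():
            by_cat.setdefault(cat, []).append(sid)
        for cat in by_cat:
            rng.shuffle(by_cat[cat])

        day0 = _balanced_draw(rng, by_cat, params.remote_per_session * 2)
        # split day0 pool into the two remote sets, category-balanced
        day0_by_cat = {}
        for sid in day0:
            day0_by_cat.setdefault(scene_cat[sid], []).append(sid)
        remote_sets = {"day1": [], "day14": []}
        toggle = 0
        for cat in sorted(day0_by_cat):
            for sid in day0_by_cat[cat]:
                remote_sets[RETRIEVAL_SESSIONS[toggle % 2]].append(sid)
                toggle += 1
        recent_sets = {
            ses: _balanced_draw(rng, by_cat, params.recent_per_session)
            for ses in RETRIEVAL_SESSIONS
        }

        for item in day0:
            enc_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "session": "day0",
                    "item_id": item,
                    "category": scene_cat[item],
                }
            )
        for ses in RETRIEVAL_SESSIONS:
            for item in recent_sets[ses]:
                enc_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "session": ses,
                        "item_id": item,
                        "category": scene_cat[item],
                    }
                )

        for ses in RETRIEVAL_SESSIONS:
            remote_cond = "remote_short" if ses == "day1" else "remote_long"
            recent_items = list(recent_sets[ses])
            remote_items = list(remote_sets[ses])
            rng.shuffle(recent_items)
            rng.shuffle(remote_items)
            for run in range(params.runs_per_session):
                run_recent = recent_items[
                    run * params.recent_per_run : (run + 1) * params.recent_per_run
                ]
                run_remote = remote_items[
                    run * params.remote_per_run : (run + 1) * params.remote_per_run
                ]
                item_type = {i: "recent" for i in run_recent}
                item_type.update({i: "remote" for i in run_remote})
                ordered = _order_run(
                    rng,
                    run_recent + run_remote,
                    scene_cat,
                    params.max_consecutive_same_category,
                )
                for t, item in enumerate(ordered):
                    is_recent = item_type[item] == "recent"
                    trial_rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "group": subj.group,
                            "session": ses,
                            "run": run,
                            "trial": t,
                            "item_id": item,
                            "item_type": "recent" if is_recent else "remote",
                            "category": scene_cat[item],
                            "delay_condition": "recent" if is_recent else remote_cond,
                        }
                    )

    return ExperimentalDesign(
        subjects=subjects,
        encoding=pd.DataFrame(enc_rows),
        trials=pd.DataFrame(trial_rows),
        params=params,
    )
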