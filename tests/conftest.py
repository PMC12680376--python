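import numpy as np
import pandas as pd
import pytest

from reinstate.sim import (
    DesignParams,
    PlantedEffects,
    build_catalog,
    build_design,
    simulate_behavior,
    simulate_learning,
    simulate_patterns,
)
from reinstate.sim.patterns import PatternSet

FULL_RETENTION = {
    "children": {"recent": 100.0, "remote_short": 100.0, "remote_long": 100.0},
    "adults": {"recent": 100.0, "remote_short": 100.0, "remote_long": 100.0},
}


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def small_design(catalog):
    return build_design(catalog, DesignParams(n_children=3, n_adults=3), seed=11)


@pytest.fixture(scope="session")
def small_behavior(small_design):
    learning = simulate_learning(small_design, 1.0, seed=11)
    return simulate_behavior(
        small_design, learning, FULL_RETENTION, retention_sd=0.0, seed=11
    )


def make_cohort(
    n_per_group=2,
    rho=0.1,
    gamma=0.0,
    sigma=1.0,
    n_voxels=50,
    rois=("R1",),
    control_rois=(),
    retention=None,
    seed=0,
    catalog=None,
):
    """One-call synthetic cohort for tests."""
    catalog = catalog or build_catalog()
    design = build_design(
        catalog, DesignParams(n_children=n_per_group, n_adults=n_per_group), seed=seed
    )
    learning = simulate_learning(design, 1.0, seed=seed)
    behavior = simulate_behavior(
        design, learning, retention or FULL_RETENTION, retention_sd=0.0, seed=seed
    )
    planted = PlantedEffects(
        rho=rho,
        gamma=gamma,
        sigma=sigma,
        n_voxels=n_voxels,
        rois=rois,
        control_rois=control_rois,
    )
    return simulate_patterns(design, behavior, planted, seed=seed)


def make_patternset(trials: pd.DataFrame, patterns: dict, rois=None) -> PatternSet:
    """Build a PatternSet from hand-written trials and pattern matrices.

    ``patterns`` maps (subject_id, roi, window) -> array whose rows align
    with that subject's trials sorted by (session, run, trial).
    """
    trials = trials.copy()
    for col, default in [
        ("group", "children"),
        ("item_type", "recent"),
        ("category", "cat0"),
        ("timeout", False),
    ]:
        if col not in trials.columns:
            trials[col] = default
    rois = rois or sorted({k[1] for k in patterns})
    return PatternSet(
        patterns={k: np.asarray(v, dtype=float) for k, v in patterns.items()},
        trials=trials,
        mean_activation=pd.DataFrame(
            columns=["subject_id", "roi", "session", "value"]
        ),
        meta={"rois": list(rois)},
    )
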