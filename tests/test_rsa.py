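import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_cohort, make_patternset
from reinstate import rsa
from reinstate.errors import AlignmentError, DegeneratePatternError


# ---------------------------------------------------------------------------
# fisher_z / pattern_similarity
# ---------------------------------------------------------------------------


def test_fisher_z_fixed_point():
    assert rsa.fisher_z(0.0) == 0.0


def test_fisher_z_half():
    assert rsa.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
    assert rsa.fisher_z(0.5) == pytest.approx(0.5 * math.log(1.5 / 0.5), abs=1e-12)


@pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
def test_fisher_z_domain_error(r):
    with pytest.raises(ValueError):
        rsa.fisher_z(r)


@given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
def test_fisher_z_monotone(r1, r2):
    if r1 < r2:
        assert rsa.fisher_z(r1) < rsa.fisher_z(r2)


def test_similarity_identity():
    p = np.array([1.0, 2.0, 5.0, 3.0])
    assert rsa.pattern_similarity(p, p).r == pytest.approx(1.0)


def test_similarity_antisymmetric():
    p = np.array([1.0, -2.0, 3.0, -2.0])  # mean-centered
    s = rsa.pattern_similarity(p, -p)
    assert s.r == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        _ = s.z  # boundary must be caught before the transform


def test_similarity_hand_computed():
    p1 = np.array([1.0, 2.0, 3.0, 4.0])
    p2 = np.array([1.0, 3.0, 2.0, 5.0])
    cov = np.mean((p1 - p1.mean()) * (p2 - p2.mean()))
    expect = cov / (p1.std() * p2.std())
    assert rsa.pattern_similarity(p1, p2).r == pytest.approx(expect, abs=1e-12)


def test_similarity_degenerate():
    with pytest.raises(DegeneratePatternError):
        rsa.pattern_similarity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# oracle fixtures: hand-written small pattern sets
# ---------------------------------------------------------------------------


def _tiny_trials(n_per_run, runs, correct=None, categories=None, condition="recent"):
    rows = []
    i = 0
    for run in range(runs):
        for t in range(n_per_run):
            rows.append(
                {
                    "subject_id": "s0",
                    "session": "day1",
                    "run": run,
                    "trial": t,
                    "item_id": f"it{i}",
                    "delay_condition": condition,
                    "correct": 1 if correct is None else correct[i],
                    "category": "cat0" if categories is None else categories[i],
                }
            )
            i += 1
    return pd.DataFrame(rows)


def _pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(
        np.sum((a - a.mean()) * (b - b.mean()))
        / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
    )


def oracle_reinstatement(trials, fix, evt):
    """Naive double-loop: z per pair, mean within run, then across runs."""
    spec_runs, base_runs = [], []
    for run in sorted(trials["run"].unique()):
        idx = trials.index[(trials["run"] == run) & (trials["correct"] == 1)].tolist()
        if not idx:
            continue
        spec_runs.append(np.mean([math.atanh(_pearson(fix[i], evt[i])) for i in idx]))
        pairs = [
            math.atanh(_pearson(fix[i], evt[j]))
            for i in idx
            for j in idx
            if i != j
        ]
        if pairs:
            base_runs.append(np.mean(pairs))
    specific = float(np.mean(spec_runs))
    baseline = float(np.mean(base_runs))
    return specific, baseline, specific - baseline


def oracle_gist(trials, fix):
    """Naive enumeration of all unordered pairs with per-block Z-scoring."""
    idx = trials.index[trials["correct"] == 1].tolist()
    z = {}
    blocks = {}
    for i, j in itertools.combinations(idx, 2):
        z[(i, j)] = math.atanh(_pearson(fix[i], fix[j]))
        blocks[(i, j)] = trials.loc[i, "run"] == trials.loc[j, "run"]
    zstd = {}
    for block in (True, False):
        keys = [k for k in z if blocks[k] == block]
        if len(keys) < 2:
            continue
        vals = np.array([z[k] for k in keys])
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        for k in keys:
            zstd[k] = (z[k] - mu) / sd
    within = [
        v
        for (i, j), v in zstd.items()
        if trials.loc[i, "category"] == trials.loc[j, "category"]
    ]
    between = [
        v
        for (i, j), v in zstd.items()
        if trials.loc[i, "category"] != trials.loc[j, "category"]
    ]
    return float(np.mean(within)), float(np.mean(between)), float(
        np.mean(within) - np.mean(between)
    )


@pytest.fixture()
def handwritten():
    rng = np.random.default_rng(123)
    trials = _tiny_trials(
        4, 2,
        correct=[1, 1, 1, 0, 1, 1, 1, 1],
        categories=["a", "a", "b", "b", "a", "b", "b", "a"],
    )
    fix = rng.integers(-5, 6, size=(8, 4)).astype(float)
    scene = rng.integers(-5, 6, size=(8, 4)).astype(float)
    obj = rng.integers(-5, 6, size=(8, 4)).astype(float)
    ps = make_patternset(
        trials,
        {
            ("s0", "R", "fixation"): fix,
            ("s0", "R", "scene"): scene,
            ("s0", "R", "object"): obj,
        },
    )
    return ps, trials, fix, scene, obj


def test_reinstatement_matches_double_loop_oracle(handwritten):
    ps, trials, fix, scene, _ = handwritten
    rec = rsa.scene_reinstatement_index(ps, "R", "s0", "recent", session="day1")
    spec, base, value = oracle_reinstatement(trials, fix, scene)
    assert rec.term_specific == pytest.approx(spec, abs=1e-10)
    assert rec.term_baseline == pytest.approx(base, abs=1e-10)
    assert rec.value == pytest.approx(value, abs=1e-10)
    assert rec.n_items == 7


def test_object_control_matches_oracle(handwritten):
    ps, trials, fix, _, obj = handwritten
    rec = rsa.scene_reinstatement_index(
        ps, "R", "s0", "recent", event="object", session="day1"
    )
    spec, base, value = oracle_reinstatement(trials, fix, obj)
    assert rec.value == pytest.approx(value, abs=1e-10)
    assert rec.index_type == "object_control"


def test_gist_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    trials = _tiny_trials(3, 2, categories=["a", "b", "a", "b", "a", "b"])
    fix = rng.normal(size=(6, 5))
    ps = make_patternset(trials, {("s0", "R", "fixation"): fix})
    rec = rsa.gist_index(ps, "R", "s0", "recent", session="day1", min_pairs=1)
    within, between, value = oracle_gist(trials, fix)
    assert rec.term_specific == pytest.approx(within, abs=1e-10)
    assert rec.term_baseline == pytest.approx(between, abs=1e-10)
    assert rec.value == pytest.approx(value, abs=1e-10)


def test_gist_single_category_error():
    rng = np.random.default_rng(8)
    trials = _tiny_trials(3, 1, categories=["a", "a", "a"])
    ps = make_patternset(trials, {("s0", "R", "fixation"): rng.normal(size=(3, 5))})
    with pytest.raises(ValueError, match="categor"):
        rsa.gist_index(ps, "R", "s0", "recent", session="day1")


def test_too_few_trials_gives_nan_record():
    rng = np.random.default_rng(9)
    trials = _tiny_trials(4, 1, correct=[1, 1, 0, 0])
    ps = make_patternset(
        trials,
        {
            ("s0", "R", "fixation"): rng.normal(size=(4, 5)),
            ("s0", "R", "scene"): rng.normal(size=(4, 5)),
        },
    )
    rec = rsa.scene_reinstatement_index(ps, "R", "s0", "recent", session="day1")
    assert math.isnan(rec.value)
    assert rec.reason is not None
    assert rec.n_items == 2


def test_set_based_term_invariant_to_trial_relabeling(handwritten):
    ps, trials, fix, scene, obj = handwritten
    perm = np.random.default_rng(5).permutation(len(trials))
    # permute rows and metadata consistently: trial labels are arbitrary
    trials2 = trials.iloc[perm].reset_index(drop=True)
    trials2["trial"] = trials2.groupby("run").cumcount()
    trials2["orig_row"] = perm
    trials2 = trials2.sort_values(["session", "run", "trial"]).reset_index(drop=True)
    order = trials2.pop("orig_row").to_numpy()
    ps2 = make_patternset(
        trials2,
        {
            ("s0", "R", "fixation"): fix[order],
            ("s0", "R", "scene"): scene[order],
            ("s0", "R", "object"): obj[order],
        },
    )
    a = rsa.scene_reinstatement_index(ps, "R", "s0", "recent", session="day1")
    b = rsa.scene_reinstatement_index(ps2, "R", "s0", "recent", session="day1")
    assert b.term_baseline == pytest.approx(a.term_baseline, abs=1e-10)
    assert b.value == pytest.approx(a.value, abs=1e-10)


def test_degenerate_pattern_excluded_not_fatal():
    rng = np.random.default_rng(11)
    fix = rng.normal(size=(5, 6))
    scene = rng.normal(size=(5, 6))
    fix[2] = 3.14  # constant row -> excluded trial
    trials = _tiny_trials(5, 1)
    ps = make_patternset(
        trials, {("s0", "R", "fixation"): fix, ("s0", "R", "scene"): scene}
    )
    rec = rsa.scene_reinstatement_index(ps, "R", "s0", "recent", session="day1")
    assert rec.n_items == 4
    assert np.isfinite(rec.value)


# ---------------------------------------------------------------------------
# aggregate_recent
# ---------------------------------------------------------------------------


def _records(values, session):
    return [
        rsa.IndexRecord(
            subject_id=f"s{i}",
            roi="R",
            condition="recent",
            index_type="scene_reinstatement",
            term_specific=v,
            term_baseline=0.0,
            value=v,
            n_items=5,
            n_pairs=20,
            session=session,
            group="children",
        )
        for i, v in enumerate(values)
    ]


def test_aggregate_identical_records_is_idempotent():
    vals = [0.1, 0.2, 0.3, 0.15]
    res = rsa.aggregate_recent(_records(vals, "day1"), _records(vals, "day14"))
    assert res.merged
    assert [r.value for r in res.records] == pytest.approx(vals)


def test_aggregate_merges_by_subject_mean():
    res = rsa.aggregate_recent(
        _records([0.1, 0.2, 0.4], "day1"),
        _records([0.3, 0.2, 0.2], "day14"),
        test=lambda a, b: 0.9,
    )
    assert res.merged
    assert [r.value for r in res.records] == pytest.approx([0.2, 0.2, 0.3])


def test_aggregate_keeps_sessions_when_significant():
    res = rsa.aggregate_recent(
        _records([0.1, 0.2, 0.4], "day1"),
        _records([0.9, 1.2, 1.1], "day14"),
        test=lambda a, b: 0.001,
    )
    assert not res.merged
    assert len(res.records) == 6


def test_aggregate_subject_mismatch():
    with pytest.raises(AlignmentError):
        rsa.aggregate_recent(_records([0.1], "day1"), _records([0.1, 0.2], "day14"))


# ---------------------------------------------------------------------------
# cohort-level behavior
# ---------------------------------------------------------------------------


def test_compute_indices_structure():
    ps = make_cohort(n_per_group=2, rho=0.2, n_voxels=40, rois=("R1",), seed=17)
    # tiny alpha: no planted session effect, so recent sessions always merge
    df = rsa.compute_indices(ps, alpha=1e-9)
    assert set(df["index_type"]) == set(rsa.INDEX_TYPES)
    counts = df.groupby(["roi", "condition", "index_type"]).size()
    assert (counts == 4).all()  # one row per subject
    assert set(df["condition"]) == {"recent", "remote_short", "remote_long"}


def test_null_cohort_indices_center_on_zero():
    vals = {"scene_reinstatement": [], "gist": []}
    n_cohorts = 30
    for seed in range(n_cohorts):
        ps = make_cohort(n_per_group=1, rho=0.0, gamma=0.0, n_voxels=80, seed=seed)
        df = rsa.compute_indices(ps, index_types=("scene_reinstatement", "gist"))
        for k in vals:
            vals[k].append(df[df["index_type"] == k]["value"].mean())
    for k, v in vals.items():
        se = np.std(v, ddof=1) / np.sqrt(len(v))
        assert abs(np.mean(v)) < 3 * se + 1e-12, k
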