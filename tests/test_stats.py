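import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reinstate import stats as rs
from reinstate.errors import ConfigurationError, RankDeficientDesignError

# ---------------------------------------------------------------------------
# sign-flip permutation test
# ---------------------------------------------------------------------------


def test_all_positive_exhaustive_p():
    # all 2^10 sign assignments; only the two all-same-sign ones reach |t|
    res = rs.sign_flip_perm_test(np.ones(10), n_perm=5000)
    assert res.exhaustive
    assert res.p == pytest.approx(2 / 1024)


def test_symmetric_values_p_one():
    x = np.array([1.0, -1.0, 2.5, -2.5, 0.3, -0.3])
    res = rs.sign_flip_perm_test(x, n_perm=10000)
    assert res.exhaustive
    assert res.p == 1.0


def test_all_zero_degenerate():
    res = rs.sign_flip_perm_test(np.zeros(8), n_perm=100)
    assert res.degenerate
    assert res.p == 1.0


def test_sampled_p_floor():
    rng = np.random.default_rng(0)
    res = rs.sign_flip_perm_test(rng.normal(5, 0.1, 30), n_perm=999, seed=1)
    assert not res.exhaustive
    assert res.p == pytest.approx(1 / 1000)


def test_one_sided_alternatives():
    x = np.array([0.5, 1.2, 0.8, 1.5, 0.9, 1.1, 0.2, 0.6, 1.3, 0.4, 0.7])
    greater = rs.sign_flip_perm_test(x, n_perm=4000, alternative="greater")
    less = rs.sign_flip_perm_test(x, n_perm=4000, alternative="less")
    assert greater.p < 0.01
    assert less.p > 0.99


def test_calibration_inside_binomial_band():
    """Null rejection rate at alpha=0.05 within the exact binomial band
    (1000 simulations, n=20, 999 sampled flips)."""
    rng = np.random.default_rng(42)
    n_sim = 1000
    rej = 0
    for i in range(n_sim):
        x = rng.standard_normal(20)
        if rs.sign_flip_perm_test(x, n_perm=999, seed=i).p <= 0.05:
            rej += 1
    lo, hi = sps.binom.ppf([0.025, 0.975], n_sim, 0.05)
    assert lo <= rej <= hi


def test_validity_property():
    """P(p <= alpha) <= alpha + 1/(n_perm+1) for several alpha."""
    rng = np.random.default_rng(3)
    ps = np.array(
        [
            rs.sign_flip_perm_test(rng.standard_normal(12), n_perm=499, seed=i).p
            for i in range(400)
        ]
    )
    for alpha in (0.01, 0.05, 0.1, 0.25):
        assert np.mean(ps <= alpha) <= alpha + 1 / 500 + 3 * np.sqrt(alpha / 400)


def test_too_few_values():
    with pytest.raises(ConfigurationError):
        rs.sign_flip_perm_test([1.0, 2.0], n_perm=100)


# ---------------------------------------------------------------------------
# FDR / Sidak / omega^2 / IQR
# ---------------------------------------------------------------------------


def test_fdr_hand_case():
    np.testing.assert_allclose(
        rs.fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_fdr_single_p_unchanged():
    assert rs.fdr_bh([0.2]) == pytest.approx([0.2])


def test_fdr_empty():
    assert rs.fdr_bh([]).size == 0


def test_fdr_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.uniform(size=25)
    _, expected, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(rs.fdr_bh(p), expected, atol=1e-12)


def test_fdr_order_equivariance():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=15)
    perm = rng.permutation(15)
    adjusted = rs.fdr_bh(p)
    np.testing.assert_allclose(rs.fdr_bh(p[perm])[np.argsort(perm)], adjusted)


def test_fdr_never_decreases():
    rng = np.random.default_rng(4)
    p = rng.uniform(size=40)
    assert (rs.fdr_bh(p) >= p - 1e-15).all()


def test_sidak_values():
    assert rs.sidak_adjust(0.05, 1) == pytest.approx(0.05)
    assert rs.sidak_adjust(0.01, 3) == pytest.approx(0.029701)
    assert rs.sidak_adjust(1.0, 7) == 1.0


def test_sidak_first_order_bonferroni():
    for p, m in itertools.product((0.001, 0.005, 0.01), (2, 3, 5)):
        assert abs(rs.sidak_adjust(p, m) - min(1, m * p)) <= m * p**2 * m


def test_sidak_errors():
    with pytest.raises(ConfigurationError):
        rs.sidak_adjust(0.05, 0)


def test_omega_squared_null_effect():
    assert rs.omega_squared(4.0, 2, 2.0, 100.0) == 0.0


def test_omega_squared_noiseless_limit():
    assert rs.omega_squared(50.0, 2, 0.0, 50.0) == 1.0


def test_omega_squared_hand_worked_oneway():
    # balanced one-way: A=(1,2,3), B=(3,4,5), C=(5,6,7)
    data = {"A": [1, 2, 3], "B": [3, 4, 5], "C": [5, 6, 7]}
    all_vals = np.concatenate(list(data.values()))
    grand = all_vals.mean()
    ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
    ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in data.values())
    ss_total = ((all_vals - grand) ** 2).sum()
    ms_error = ss_within / 6
    got = rs.omega_squared(ss_between, 2, ms_error, ss_total)
    assert got == pytest.approx(22.0 / 31.0, abs=1e-12)


def test_omega_squared_undefined():
    assert np.isnan(rs.omega_squared(0.0, 1, 0.0, 0.0))


def test_iqr_flags_hand_case():
    flags = rs.iqr_outlier_flags([1, 2, 3, 4, 100], k=3.0)
    assert list(flags) == [False, False, False, False, True]


def test_iqr_constant_vector():
    assert not rs.iqr_outlier_flags([5.0] * 6).any()


def test_iqr_translation_invariance():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    x[0] = 40.0
    np.testing.assert_array_equal(
        rs.iqr_outlier_flags(x), rs.iqr_outlier_flags(x + 17.3)
    )


def test_iqr_needs_four_values():
    with pytest.raises(ConfigurationError):
        rs.iqr_outlier_flags([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# condition models
# ---------------------------------------------------------------------------


def _balanced_table(n_sub=10, conds=("a", "b", "c"), effect=None, seed=0, sd=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        base = rng.normal(0, 1.0)
        for c in conds:
            mu = 0.0 if effect is None else effect[c]
            rows.append(
                {
                    "subject_id": f"s{s}",
                    "cond": c,
                    "group": "g1" if s < n_sub // 2 else "g2",
                    "y": mu + base + rng.normal(0, sd),
                }
            )
    return pd.DataFrame(rows)


def test_zero_subject_variance_matches_ols_oracle():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = _balanced_table(n_sub=12, effect={"a": 1.0, "b": 2.0, "c": 1.4}, seed=1)
    # remove all between-subject variance so the random intercept fits to 0
    df["y"] -= df.groupby("subject_id")["y"].transform("mean")
    res = rs.fit_condition_model(df, "y", ["cond"])
    assert res.meta["sigma2_subject"] == pytest.approx(0.0, abs=1e-8)
    ols = smf.ols("y ~ C(cond, Sum)", df).fit()
    table = anova_lm(ols, typ=3)
    assert res.effect("cond").F == pytest.approx(
        table.loc["C(cond, Sum)", "F"], abs=1e-6
    )


def test_posthoc_contrasts_and_sidak():
    df = _balanced_table(n_sub=30, effect={"a": 0.0, "b": 1.0, "c": 2.0}, seed=2)
    res = rs.fit_condition_model(df, "y", ["cond"])
    labels = {c.label: c for c in res.posthoc}
    assert set(labels) == {"cond: a - b", "cond: a - c", "cond: b - c"}
    assert labels["cond: a - c"].b == pytest.approx(-2.0, abs=0.3)
    for c in res.posthoc:
        assert c.p_sidak == pytest.approx(rs.sidak_adjust(c.p, 3), abs=1e-12)


def test_group_effect_power():
    """Planted group gap recovered at n=40/group in >=95% of cohorts."""
    hits = 0
    n_cohorts = 100
    for seed in range(n_cohorts):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu in (("children", -0.5), ("adults", 0.5)):
            for s in range(40):
                base = rng.normal(0, 1.0)
                for c in ("a", "b"):
                    rows.append(
                        {
                            "subject_id": f"{g}{s}",
                            "group": g,
                            "cond": c,
                            "y": mu + base + rng.normal(0, 0.8),
                        }
                    )
        res = rs.fit_condition_model(pd.DataFrame(rows), "y", ["cond", "group"])
        if res.effect("group").p < 0.05:
            hits += 1
    assert hits >= 95


def test_group_effect_null_calibration():
    """Null group-effect p-values are uniform (KS p > 0.01, 500 cohorts)."""
    ps = []
    for seed in range(500):
        rng = np.random.default_rng(10_000 + seed)
        rows = []
        for g in ("g1", "g2"):
            for s in range(15):
                base = rng.normal(0, 1.0)
                for c in ("a", "b", "c"):
                    rows.append(
                        {
                            "subject_id": f"{g}{s}",
                            "group": g,
                            "cond": c,
                            "y": base + rng.normal(0, 1.0),
                        }
                    )
        res = rs.fit_condition_model(pd.DataFrame(rows), "y", ["cond", "group"])
        ps.append(res.effect("group").p)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_rank_deficient_design_reported():
    df = _balanced_table(n_sub=8)
    df["cond2"] = df["cond"]  # perfectly aliased factor
    with pytest.raises(RankDeficientDesignError) as err:
        rs.fit_condition_model(df, "y", ["cond", "cond2"], interactions=False)
    assert err.value.aliased


def test_covariate_accepted():
    df = _balanced_table(n_sub=12, effect={"a": 0.0, "b": 0.5, "c": 1.0}, seed=3)
    rng = np.random.default_rng(3)
    df["age"] = rng.normal(30, 5, size=len(df))
    res = rs.fit_condition_model(df, "y", ["cond"], covariates=["age"])
    names = [e.name for e in res.effects]
    assert "age" in names and "cond" in names


def test_omega2_reported_per_effect():
    df = _balanced_table(n_sub=20, effect={"a": 0.0, "b": 2.0, "c": 4.0}, seed=4)
    res = rs.fit_condition_model(df, "y", ["cond"])
    assert res.effect("cond").omega2 > 0.3
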