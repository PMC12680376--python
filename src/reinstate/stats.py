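"""Inferential layer: permutation tests, adjustments, effect sizes, models."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from reinstate.errors import ConfigurationError
from reinstate.lmm import RandomInterceptModel, fit_random_intercept

#: Exhaustive sign-flip enumeration is used when 2^n does not exceed n_perm.


@dataclass
class PermutationResult:
    observed: float
    n_permutations: int
    p: float
    alternative: str = "two-sided"
    exhaustive: bool = False
    degenerate: bool = False
    seed: Optional[int] = None


def _t_statistic(x: np.ndarray) -> float:
    n = x.shape[-1]
    m = x.mean(axis=-1)
    s = x.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / (s / np.sqrt(n))


def sign_flip_perm_test(
    values,
    n_perm: int = 5000,
    alternative: str = "two-sided",
    seed: int = 0,
) -> PermutationResult:
    """One-sample permutation t-test with random sign flips.

    Exhaustive enumeration of all 2^n sign assignments is used when
    2^n <= n_perm (exact proportion); otherwise n_perm random flips with
    the observed statistic counted among the draws (p >= 1/(n_perm+1)).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ConfigurationError("need at least 3 finite values")
    if np.all(x == 0):
        return PermutationResult(
            observed=0.0, n_permutations=0, p=1.0,
            alternative=alternative, degenerate=True, seed=seed,
        )
    t_obs = float(_t_statistic(x))

    def extremity(t_null):
        tol = 1e-12
        if alternative == "two-sided":
            return np.abs(t_null) >= np.abs(t_obs) - tol
        if alternative == "greater":
            return t_null >= t_obs - tol
        return t_null <= t_obs + tol

    n = x.size
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        t_null = _t_statistic(signs * x)
        p = float(np.mean(extremity(t_null)))
        return PermutationResult(
            observed=t_obs, n_permutations=2**n, p=p,
            alternative=alternative, exhaustive=True, seed=seed,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    t_null = _t_statistic(signs * x)
    p = float((1 + np.sum(extremity(t_null))) / (1 + n_perm))
    return PermutationResult(
        observed=t_obs, n_permutations=n_perm, p=p,
        alternative=alternative, seed=seed,
    )


def fdr_bh(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment 1 - (1-p)^m, capped at 1."""
    if m < 1:
        raise ConfigurationError("comparison count m must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError("p must be in [0, 1]")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def omega_squared(ss_effect, df_effect, ms_error, ss_total) -> float:
    """omega^2 = (SS_eff - df_eff * MS_err) / (SS_total + MS_err)."""
    if ss_total < 0 or ms_error < 0:
        raise ConfigurationError("sums of squares must be >= 0")
    denom = ss_total + ms_error
    if denom == 0:
        return float("nan")
    return float((ss_effect - df_effect * ms_error) / denom)


def iqr_outlier_flags(values, k: float = 3.0):
    """Flag extreme values outside [Q1 - k*IQR, Q3 + k*IQR] (strict).

    Quartiles use linear interpolation; default k=3 targets extreme
    outliers only.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ConfigurationError("need at least 4 values for quartiles")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x > q3 + k * iqr) | (x < q1 - k * iqr)


# ---------------------------------------------------------------------------
# Condition models (random-intercept LME with Satterthwaite df)
# ---------------------------------------------------------------------------


@dataclass
class EffectResult:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    omega2: float
    p_adjusted: float = float("nan")


@dataclass
class Contrast:
    label: str
    b: float
    t: float
    df: float
    p: float
    p_sidak: float


@dataclass
class StatResult:
    effects: list = field(default_factory=list)
    posthoc: list = field(default_factory=list)
    model: Optional[RandomInterceptModel] = None
    meta: dict = field(default_factory=dict)

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])

    def posthoc_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.posthoc])


def _reference_grid(table, factors, covariates):
    """Balanced grid over factor levels with covariates fixed at their mean."""
    levels = [sorted(table[f].dropna().unique()) for f in factors]
    rows = []
    for combo in itertools.product(*levels):
        row = dict(zip(factors, combo))
        for c in covariates:
            row[c] = float(table[c].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def fit_condition_model(
    table: pd.DataFrame,
    value_col: str,
    fixed,
    covariates=(),
    subject_col: str = "subject_id",
    interactions: bool = True,
    posthoc_factors=None,
) -> StatResult:
    """Mixed model with a subject random intercept (ML fit).

    Fixed factors use sum-to-zero coding; omnibus Wald F tests per term use
    Satterthwaite denominator degrees of freedom.  Pairwise post hoc
    contrasts between factor levels (averaged over the other factors on a
    balanced reference grid) are Sidak-adjusted with the family size equal
    to the number of contrasts per factor.  omega^2 per term is computed
    from the type-III ANOVA decomposition of the fixed part (an
    approximation for mixed designs).
    """
    from patsy import build_design_matrices, dmatrix

    fixed = list(fixed)
    covariates = list(covariates)
    for f in fixed:
        if table[f].nunique() < 2:
            raise ConfigurationError(f"fixed factor {f!r} needs >= 2 levels")
    data = table.dropna(subset=[value_col, subject_col] + fixed + covariates).copy()

    op = " * " if interactions else " + "
    rhs = op.join(f"C({f}, Sum)" for f in fixed)
    if covariates:
        rhs += " + " + " + ".join(covariates)
    design = dmatrix(rhs, data, return_type="dataframe")
    X = design.to_numpy()
    y = data[value_col].to_numpy(dtype=float)
    groups = data[subject_col].to_numpy()

    model = fit_random_intercept(y, X, groups, column_names=list(design.columns))
    info = design.design_info

    # --- omnibus F per fixed term (type III under sum coding) ---
    effects = []
    ols_rss_full, ols_df_resid, ss_total = _ols_decomposition(X, y)
    ms_error = ols_rss_full / ols_df_resid
    for term in info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = info.term_slices[term]
        L = np.zeros((sl.stop - sl.start, X.shape[1]))
        for i, j in enumerate(range(sl.start, sl.stop)):
            L[i, j] = 1.0
        F, df1, df2, p = model.wald_f(L)
        ss_effect = _type3_ss(X, y, sl, ols_rss_full)
        effects.append(
            EffectResult(
                name=_clean_term_name(name),
                F=F, df1=df1, df2=df2, p=p,
                omega2=omega_squared(ss_effect, df1, ms_error, ss_total),
            )
        )

    # --- post hoc pairwise contrasts via balanced reference grid ---
    posthoc = []
    for factor in (posthoc_factors if posthoc_factors is not None else fixed):
        grid = _reference_grid(data, fixed, covariates)
        (gmat,) = build_design_matrices([info], grid)
        gmat = np.asarray(gmat)
        levels = sorted(data[factor].dropna().unique())
        pairs = list(itertools.combinations(levels, 2))
        m = len(pairs)
        for la, lb in pairs:
            ca = gmat[(grid[factor] == la).to_numpy()].mean(axis=0)
            cb = gmat[(grid[factor] == lb).to_numpy()].mean(axis=0)
            b, t, df, p = model.contrast(ca - cb)
            posthoc.append(
                Contrast(
                    label=f"{factor}: {la} - {lb}",
                    b=b, t=t, df=df, p=p, p_sidak=sidak_adjust(p, m),
                )
            )

    return StatResult(
        effects=effects,
        posthoc=posthoc,
        model=model,
        meta={
            "df_method": "satterthwaite",
            "estimation": "ML",
            "n_obs": int(len(y)),
            "n_subjects": int(pd.unique(groups).size),
            "sigma2_subject": model.sigma2_group,
            "sigma2_resid": model.sigma2_resid,
            "omega2_method": "type-III fixed-part ANOVA approximation",
        },
    )


def _clean_term_name(name: str) -> str:
    return name.replace("C(", "").replace(", Sum)", "")


def _ols_decomposition(X, y):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = len(y) - rank
    ss_total = float(np.sum((y - y.mean()) ** 2))
    return rss, df_resid, ss_total


def _type3_ss(X, y, term_slice, rss_full) -> float:
    keep = np.ones(X.shape[1], dtype=bool)
    keep[term_slice] = False
    rss_reduced, _, _ = _ols_decomposition(X[:, keep], y)
    return max(0.0, rss_reduced - rss_full)
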