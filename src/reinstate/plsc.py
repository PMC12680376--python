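"""Partial least squares correlation between ROI metric profiles and behavior.

With a single behavior variable the behavior x ROI correlation matrix R is a
row vector, so the SVD solution is rank one: the salience vector V is R up
to scale and the singular value is the Euclidean norm of R.  The numeric
decomposition is still taken and asserted against this closed form on every
fit.  Inference follows the permutation (singular value under shuffled
behavior) and bootstrap (salience stability, bootstrap ratios) recipes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from reinstate.errors import ConfigurationError, DegenerateColumnError
from reinstate.sim.metrics import ROIMetricTable


@dataclass(frozen=True)
class PLSCConfig:
    n_perm: int = 5000
    n_boot: int = 5000
    z_threshold: float = 1.96
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 100 or self.n_boot < 100:
            raise ConfigurationError("n_perm and n_boot must be >= 100")
        if self.z_threshold <= 0:
            raise ConfigurationError("z_threshold must be > 0")


@dataclass
class PLSCModel:
    rois: list
    R: np.ndarray  # 1 x k behavior-metric correlations
    singular_value: float
    saliences: np.ndarray  # k, unit norm
    u: float  # behavior-side weight (scalar, +/-1)
    brain_scores: pd.Series
    behavior: pd.Series
    groups: pd.Series
    latent_r: float  # Spearman(brain scores, behavior)
    roi_behavior_r: np.ndarray  # per-ROI Spearman with behavior
    n_dropped: int = 0
    p_perm: Optional[float] = None
    bsr: Optional[np.ndarray] = None
    robust: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)


def _standardize(mat: np.ndarray, names) -> np.ndarray:
    sd = mat.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise DegenerateColumnError(
            "constant metric column(s): " + ", ".join(str(names[j]) for j in bad)
        )
    return (mat - mat.mean(axis=0)) / sd


def _corr_row(zb: np.ndarray, Zm: np.ndarray) -> np.ndarray:
    return (zb @ Zm) / (len(zb) - 1)


def _rank1_svd(R: np.ndarray):
    U, S, Vt = np.linalg.svd(R.reshape(1, -1), full_matrices=False)
    return float(U[0, 0]), float(S[0]), Vt[0]


def plsc_fit(metrics: ROIMetricTable, config: PLSCConfig | None = None) -> PLSCModel:
    """Fit the rank-one PLSC model.

    Metric columns and behavior are z-standardized; R = corr(behavior,
    metrics); the SVD of R yields the salience vector, sign-oriented so the
    latent Spearman correlation between brain scores and behavior is
    non-negative.  Rows with missing values are dropped listwise.
    """
    config = config or PLSCConfig()
    table, n_dropped = metrics.dropna()
    n, k = table.metrics.shape
    if n < k + 2:
        import warnings

        warnings.warn(
            f"n={n} subjects for k={k} ROIs; fewer than k+2 rows", stacklevel=2
        )
    M = table.metrics.to_numpy(dtype=float)
    y = table.behavior.to_numpy(dtype=float)
    Zm = _standardize(M, table.rois)
    if y.std(ddof=1) == 0:
        raise DegenerateColumnError("behavior vector is constant")
    zb = (y - y.mean()) / y.std(ddof=1)

    R = _corr_row(zb, Zm)
    u, S, V = _rank1_svd(R)
    # closed-form rank-1 invariant, asserted on every fit
    np.testing.assert_allclose(abs(S), np.linalg.norm(R), atol=1e-10)
    np.testing.assert_allclose(np.abs(V), np.abs(R) / np.linalg.norm(R), atol=1e-8)

    brain = Zm @ V
    latent_r = float(sps.spearmanr(brain, y).statistic)
    if latent_r < 0:
        V, u, brain, latent_r = -V, -u, -brain, -latent_r

    roi_r = np.array([float(sps.spearmanr(M[:, j], y).statistic) for j in range(k)])
    return PLSCModel(
        rois=list(table.rois),
        R=R,
        singular_value=S,
        saliences=V,
        u=u,
        brain_scores=pd.Series(brain, index=table.metrics.index, name="brain_score"),
        behavior=table.behavior,
        groups=table.groups,
        latent_r=latent_r,
        roi_behavior_r=roi_r,
        n_dropped=n_dropped,
        meta={"n": n, "k": k},
    )


def perm_test(
    model: PLSCModel, metrics: ROIMetricTable, config: PLSCConfig
) -> float:
    """Permutation p for the singular value: behavior shuffled across
    subjects, p = (1 + #{S* >= S_obs}) / (1 + n_perm)."""
    table, _ = metrics.dropna()
    M = table.metrics.to_numpy(dtype=float)
    y = table.behavior.to_numpy(dtype=float)
    if y.std(ddof=1) == 0:
        model.p_perm = 1.0
        model.meta["perm_degenerate"] = True
        return 1.0
    Zm = _standardize(M, table.rois)
    zb = (y - y.mean()) / y.std(ddof=1)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    perms = np.stack([rng.permutation(zb) for _ in range(config.n_perm)])
    S_null = np.linalg.norm((perms @ Zm) / (len(zb) - 1), axis=1)
    p = float((1 + np.sum(S_null >= model.singular_value - 1e-12)) / (1 + config.n_perm))
    model.p_perm = p
    model.meta["n_perm"] = config.n_perm
    return p


def bootstrap_bsr(
    model: PLSCModel,
    metrics: ROIMetricTable,
    config: PLSCConfig,
    max_retries: int = 100,
):
    """Bootstrap ratios: subjects resampled with replacement; per-draw
    saliences sign-aligned to the original (dot-product flip); BSR =
    original salience / bootstrap SD.  Draws with a constant column are
    redrawn (logged, capped)."""
    table, _ = metrics.dropna()
    M = table.metrics.to_numpy(dtype=float)
    y = table.behavior.to_numpy(dtype=float)
    n, k = M.shape
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    V0 = model.saliences
    boot_V = np.empty((config.n_boot, k))
    redraws = 0
    for b in range(config.n_boot):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            Mb = M[idx]
            yb = y[idx]
            if yb.std(ddof=1) == 0 or np.any(Mb.std(axis=0, ddof=1) == 0):
                redraws += 1
                continue
            Zb = _standardize(Mb, table.rois)
            zbb = (yb - yb.mean()) / yb.std(ddof=1)
            Rb = _corr_row(zbb, Zb)
            _, _, Vb = _rank1_svd(Rb)
            if Vb @ V0 < 0:
                Vb = -Vb
            boot_V[b] = Vb
            break
        else:  # pragma: no cover - requires pathological data
            raise RuntimeError("bootstrap draw kept producing constant columns")

    sd = boot_V.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        bsr = np.where(sd > 0, V0 / sd, np.inf * np.sign(V0))
    robust = np.abs(bsr) > config.z_threshold
    model.bsr = bsr
    model.robust = robust
    model.meta["n_boot"] = config.n_boot
    model.meta["bootstrap_redraws"] = redraws
    return bsr, robust


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    group_means: dict
    flagged: bool = False


def compare_brain_scores(model: PLSCModel, groups=None) -> GroupComparison:
    """Welch two-sample t-test on brain scores by group."""
    groups = model.groups if groups is None else groups
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ConfigurationError("exactly two groups are required")
    a = model.brain_scores[np.asarray(groups) == labels[0]].to_numpy()
    b = model.brain_scores[np.asarray(groups) == labels[1]].to_numpy()
    if min(len(a), len(b)) < 3:
        raise ConfigurationError("each group needs n >= 3")
    flagged = bool(a.std(ddof=1) == 0 or b.std(ddof=1) == 0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        group_means={labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        flagged=flagged,
    )
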