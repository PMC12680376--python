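"""Generator for subjects x ROIs metric tables with a planted latent factor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from reinstate.errors import ConfigurationError


@dataclass(frozen=True)
class ROIMetricTable:
    """Subjects x ROIs metric matrix paired with a behavior vector."""

    metrics: pd.DataFrame  # index: subject_id, columns: ROI names
    behavior: pd.Series  # index: subject_id
    groups: pd.Series  # index: subject_id

    def __post_init__(self):
        if len(self.behavior) != len(self.metrics):
            raise ConfigurationError("behavior length must equal metric row count")
        if not self.metrics.index.equals(self.behavior.index):
            raise ConfigurationError("behavior index must match metric rows")

    @property
    def rois(self) -> tuple:
        return tuple(self.metrics.columns)

    def dropna(self) -> tuple["ROIMetricTable", int]:
        """Listwise-delete rows with any missing value; returns (table, n_dropped)."""
        mask = self.metrics.notna().all(axis=1) & self.behavior.notna()
        dropped = int((~mask).sum())
        return (
            ROIMetricTable(
                metrics=self.metrics[mask],
                behavior=self.behavior[mask],
                groups=self.groups[mask],
            ),
            dropped,
        )


def simulate_roi_metrics(
    design,
    saliences,
    latent_strength: float = 0.5,
    noise: float = 1.0,
    seed: int = 0,
    group_offset=None,
    roi_names=None,
) -> ROIMetricTable:
    """Plant a single latent factor shared by metrics and behavior.

    Per subject a latent score f ~ Normal(0, 1) (plus an optional
    per-group offset) drives metric column j as ``saliences[j] * f +
    noise * eps`` and behavior as ``latent_strength * f +
    sqrt(1 - latent_strength^2) * eps`` so corr(behavior, f) equals
    ``latent_strength`` in expectation.

    ``design`` may be an :class:`~reinstate.sim.design.ExperimentalDesign`
    or a plain subject count (all subjects labeled ``"all"``).
    """
    saliences = np.asarray(saliences, dtype=float)
    if saliences.size == 0:
        raise ConfigurationError("salience vector must be non-empty")
    if abs(latent_strength) > 1:
        raise ConfigurationError("|latent_strength| must be <= 1")
    if noise < 0:
        raise ConfigurationError("noise must be >= 0")

    if isinstance(design, (int, np.integer)):
        subject_ids = [f"sub{i:04d}" for i in range(int(design))]
        groups = pd.Series("all", index=subject_ids, name="group")
    else:
        subject_ids = list(design.subjects["subject_id"])
        groups = pd.Series(
            list(design.subjects["group"]), index=subject_ids, name="group"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(subject_ids)
    f = rng.standard_normal(n)
    if group_offset:
        f = f + groups.map(lambda g: float(group_offset.get(g, 0.0))).to_numpy()
    metrics = f[:, None] * saliences[None, :] + noise * rng.standard_normal(
        (n, saliences.size)
    )
    behavior = latent_strength * f + np.sqrt(
        max(0.0, 1.0 - latent_strength**2)
    ) * rng.standard_normal(n)

    if roi_names is None:
        roi_names = [f"roi{j:02d}" for j in range(saliences.size)]
    return ROIMetricTable(
        metrics=pd.DataFrame(metrics, index=subject_ids, columns=list(roi_names)),
        behavior=pd.Series(behavior, index=subject_ids, name="behavior"),
        groups=groups,
    )
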