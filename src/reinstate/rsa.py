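"""Representational similarity indices.

Three per-subject indices are computed from trial-wise voxel patterns:

* corrected scene-specific reinstatement: mean Fisher-z fixation-scene
  similarity of each correct trial with its own scene (specific term) minus
  the mean similarity with every *other* correct trial's scene in the same
  run/condition (set-based term); pairs are Fisher-transformed first, then
  averaged within run, then across runs,
* object-period control: the same computation against the object window,
* gist: mean standardized Fisher-z fixation-fixation similarity of
  same-category correct trial pairs minus different-category pairs, pooling
  within-run and cross-run pair blocks that are each Z-standardized against
  all pair similarities in that block.

Positive corrected reinstatement means the fixation pattern resembles its
own scene more than other scenes; positive gist means same-category trials
are more alike than different-category ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from reinstate.errors import AlignmentError, DegeneratePatternError
from reinstate.sim.patterns import PatternSet

INDEX_TYPES = ("scene_reinstatement", "object_control", "gist")

#: Below these cell sizes a record is emitted as NaN rather than a value.
MIN_ITEMS = 3
MIN_PAIRS = 3


@dataclass(frozen=True)
class SimilarityValue:
    """A Pearson correlation with its Fisher transform."""

    r: float

    @property
    def z(self) -> float:
        return fisher_z(self.r)


@dataclass
class IndexRecord:
    subject_id: str
    roi: str
    condition: str
    index_type: str
    term_specific: float
    term_baseline: float
    value: float
    n_items: int
    n_pairs: int
    session: Optional[str] = None
    group: Optional[str] = None
    reason: Optional[str] = None


def fisher_z(r) -> float:
    """arctanh transform; raises for |r| >= 1 (degenerate correlations must
    be guarded by the caller)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def pattern_similarity(p1, p2) -> SimilarityValue:
    """Pearson correlation between two voxel vectors."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or p1.size < 2:
        raise ValueError("patterns must be 1-D vectors of equal length >= 2")
    d1 = p1 - p1.mean()
    d2 = p2 - p2.mean()
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        raise DegeneratePatternError("constant pattern has undefined correlation")
    return SimilarityValue(r=float(d1 @ d2 / (n1 * n2)))


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation matrix between two (n, v) pattern blocks."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1)
    bn = np.linalg.norm(bz, axis=1)
    if np.any(an == 0) or np.any(bn == 0):
        raise DegeneratePatternError("constant pattern has undefined correlation")
    return (az @ bz.T) / np.outer(an, bn)


def _nonconstant_rows(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of rows with nonzero variance (degenerate rows excluded)."""
    return mat.std(axis=1) > 0


def _select_condition(
    patterns: PatternSet,
    subject_id: str,
    condition: str,
    session: Optional[str],
) -> pd.DataFrame:
    cache_key = (subject_id, "__rowframe__")
    if cache_key not in patterns._trial_cache:
        sub = patterns.subject_trials(subject_id)
        patterns._trial_cache[cache_key] = sub.reset_index().rename(
            columns={"index": "row"}
        )
    sub = patterns._trial_cache[cache_key]
    sel = sub[sub["delay_condition"] == condition]
    if condition == "recent":
        if session is None:
            raise ValueError("recent-condition indices require an explicit session")
        sel = sel[sel["session"] == session]
    elif session is not None:
        sel = sel[sel["session"] == session]
    if "timeout" in sel.columns:
        sel = sel[~sel["timeout"].astype(bool)]
    return sel


def _nan_record(subject_id, roi, condition, index_type, session, group, n_items, reason):
    return IndexRecord(
        subject_id=subject_id,
        roi=roi,
        condition=condition,
        index_type=index_type,
        term_specific=float("nan"),
        term_baseline=float("nan"),
        value=float("nan"),
        n_items=n_items,
        n_pairs=0,
        session=session,
        group=group,
        reason=reason,
    )


def scene_reinstatement_index(
    patterns: PatternSet,
    roi: str,
    subject_id: str,
    condition: str,
    event: str = "scene",
    session: Optional[str] = None,
    min_items: int = MIN_ITEMS,
) -> IndexRecord:
    """Corrected scene-specific reinstatement (or object-period control).

    For each run, every correct trial's fixation pattern is correlated with
    the ``event``-window pattern of its own trial (specific) and of every
    other correct trial in the run and condition (set-based); correlations
    are Fisher-transformed per pair, averaged within run, then across runs.
    The corrected value is specific minus set-based.
    """
    if event not in ("scene", "object"):
        raise ValueError("event must be 'scene' or 'object'")
    index_type = "scene_reinstatement" if event == "scene" else "object_control"
    sel = _select_condition(patterns, subject_id, condition, session)
    group = sel["group"].iloc[0] if len(sel) else None
    correct = sel[sel["correct"] == 1]
    n_items = len(correct)
    if n_items < min_items:
        return _nan_record(
            subject_id, roi, condition, index_type, session, group, n_items,
            f"fewer than {min_items} correct trials",
        )

    fix = patterns.get(subject_id, roi, "fixation")
    evt = patterns.get(subject_id, roi, event)
    ok_rows = _nonconstant_rows(fix) & _nonconstant_rows(evt)
    correct = correct[ok_rows[correct["row"].to_numpy()]]
    n_items = len(correct)
    if n_items < min_items:
        return _nan_record(
            subject_id, roi, condition, index_type, session, group, n_items,
            f"fewer than {min_items} usable trials after degenerate-pattern exclusion",
        )
    spec_runs = []
    base_runs = []
    n_pairs = 0
    for _, block in correct.groupby("run"):
        rows = block["row"].to_numpy()
        C = _cross_correlation(fix[rows], evt[rows])
        Z = fisher_z(np.clip(C, -1 + 1e-15, 1 - 1e-15))
        spec_runs.append(float(np.mean(np.diag(Z))))
        if len(rows) >= 2:
            off = ~np.eye(len(rows), dtype=bool)
            base_runs.append(float(np.mean(Z[off])))
            n_pairs += int(off.sum())
    term_specific = float(np.mean(spec_runs))
    term_baseline = float(np.mean(base_runs)) if base_runs else float("nan")
    return IndexRecord(
        subject_id=subject_id,
        roi=roi,
        condition=condition,
        index_type=index_type,
        term_specific=term_specific,
        term_baseline=term_baseline,
        value=term_specific - term_baseline,
        n_items=n_items,
        n_pairs=n_pairs,
        session=session,
        group=group,
    )


def gist_index(
    patterns: PatternSet,
    roi: str,
    subject_id: str,
    condition: str,
    session: Optional[str] = None,
    min_pairs: int = MIN_PAIRS,
) -> IndexRecord:
    """Within- minus between-category fixation-pattern similarity.

    All unordered pairs of correct trials in the condition enter, pooled
    from a within-run block (both trials in the same run) and a cross-run
    block; each block's Fisher-z similarities are Z-standardized against
    the distribution of all pair similarities in that block before the
    same-category and different-category means are taken.
    """
    sel = _select_condition(patterns, subject_id, condition, session)
    group = sel["group"].iloc[0] if len(sel) else None
    correct = sel[sel["correct"] == 1]
    n_items = len(correct)
    cats = correct["category"].to_numpy()
    if len(set(cats)) < 2:
        raise ValueError(
            "gist index undefined: fewer than 2 categories among correct trials"
        )

    fix = patterns.get(subject_id, roi, "fixation")
    ok_rows = _nonconstant_rows(fix)
    correct = correct[ok_rows[correct["row"].to_numpy()]]
    cats = correct["category"].to_numpy()
    rows = correct["row"].to_numpy()
    runs = correct["run"].to_numpy()
    C = _cross_correlation(fix[rows], fix[rows])
    Z = fisher_z(np.clip(C, -1 + 1e-15, 1 - 1e-15))

    iu, ju = np.triu_indices(len(rows), k=1)
    z_pairs = Z[iu, ju]
    same_cat = cats[iu] == cats[ju]
    same_run = runs[iu] == runs[ju]

    z_std = np.full_like(z_pairs, np.nan)
    for block_mask in (same_run, ~same_run):
        if block_mask.sum() < 2:
            continue
        mu = z_pairs[block_mask].mean()
        sd = z_pairs[block_mask].std(ddof=1)
        if sd == 0:
            continue
        z_std[block_mask] = (z_pairs[block_mask] - mu) / sd

    usable = ~np.isnan(z_std)
    n_within = int((same_cat & usable).sum())
    n_between = int((~same_cat & usable).sum())
    if n_within < min_pairs or n_between < min_pairs:
        return _nan_record(
            subject_id, roi, condition, "gist", session, group, n_items,
            f"fewer than {min_pairs} usable pairs in a category block",
        )
    term_within = float(z_std[same_cat & usable].mean())
    term_between = float(z_std[~same_cat & usable].mean())
    return IndexRecord(
        subject_id=subject_id,
        roi=roi,
        condition=condition,
        index_type="gist",
        term_specific=term_within,
        term_baseline=term_between,
        value=term_within - term_between,
        n_items=n_items,
        n_pairs=n_within + n_between,
        session=session,
        group=group,
    )


@dataclass
class AggregationResult:
    merged: bool
    p: float
    records: list = field(default_factory=list)


def aggregate_recent(
    records_day1,
    records_day14,
    test: Optional[Callable] = None,
    alpha: float = 0.05,
) -> AggregationResult:
    """Merge recent-condition records from the two scanning sessions.

    A session-difference test (default: paired t-test on finite subject
    pairs) decides: non-significant at ``alpha`` -> subject-wise mean of
    the two records; significant -> both returned unmerged with a flag.
    """
    d1 = {r.subject_id: r for r in records_day1}
    d14 = {r.subject_id: r for r in records_day14}
    if set(d1) != set(d14):
        raise AlignmentError("subject sets of the two sessions do not match")
    subjects = sorted(d1)
    v1 = np.array([d1[s].value for s in subjects])
    v14 = np.array([d14[s].value for s in subjects])
    finite = np.isfinite(v1) & np.isfinite(v14)

    if test is None:
        from scipy import stats as sps

        def test(a, b):
            if len(a) < 2 or np.allclose(a, b):
                return 1.0
            return float(sps.ttest_rel(a, b).pvalue)

    p = float(test(v1[finite], v14[finite]))
    if p < alpha:
        return AggregationResult(
            merged=False, p=p, records=list(records_day1) + list(records_day14)
        )

    merged = []
    for s in subjects:
        a, b = d1[s], d14[s]
        merged.append(
            IndexRecord(
                subject_id=s,
                roi=a.roi,
                condition=a.condition,
                index_type=a.index_type,
                term_specific=float(np.nanmean([a.term_specific, b.term_specific])),
                term_baseline=float(np.nanmean([a.term_baseline, b.term_baseline])),
                value=float(np.nanmean([a.value, b.value])),
                n_items=a.n_items + b.n_items,
                n_pairs=a.n_pairs + b.n_pairs,
                session="merged",
                group=a.group,
            )
        )
    return AggregationResult(merged=True, p=p, records=merged)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "roi": r.roi,
                "condition": r.condition,
                "session": r.session,
                "index_type": r.index_type,
                "term_specific": r.term_specific,
                "term_baseline": r.term_baseline,
                "value": r.value,
                "n_items": r.n_items,
                "n_pairs": r.n_pairs,
            }
        )
    return pd.DataFrame(rows)


def compute_indices(
    patterns: PatternSet,
    rois=None,
    index_types=INDEX_TYPES,
    aggregate: bool = True,
    alpha: float = 0.05,
    min_items: int = MIN_ITEMS,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Long-format table of all indices for all subjects x ROIs x conditions.

    The recent condition is computed per scanning session and merged by
    :func:`aggregate_recent` when the session test allows (``aggregate``).
    """
    rois = list(rois) if rois is not None else list(patterns.rois)
    subjects = patterns.subjects
    sessions = list(dict.fromkeys(patterns.trials["session"]))
    all_records = []
    for roi in rois:
        for index_type in index_types:
            def one(subject_id, condition, session):
                if index_type == "gist":
                    try:
                        return gist_index(
                            patterns, roi, subject_id, condition,
                            session=session, min_pairs=min_pairs,
                        )
                    except ValueError:
                        return _nan_record(
                            subject_id, roi, condition, "gist", session,
                            None, 0, "single category",
                        )
                event = "scene" if index_type == "scene_reinstatement" else "object"
                return scene_reinstatement_index(
                    patterns, roi, subject_id, condition,
                    event=event, session=session, min_items=min_items,
                )

            recent_by_session = {
                ses: [one(s, "recent", ses) for s in subjects] for ses in sessions
            }
            if aggregate and len(sessions) == 2:
                agg = aggregate_recent(
                    recent_by_session[sessions[0]],
                    recent_by_session[sessions[1]],
                    alpha=alpha,
                )
                all_records.extend(agg.records)
            else:
                for ses in sessions:
                    all_records.extend(recent_by_session[ses])
            all_records.extend(one(s, "remote_short", None) for s in subjects)
            all_records.extend(one(s, "remote_long", None) for s in subjects)
    return records_to_frame(all_records)
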