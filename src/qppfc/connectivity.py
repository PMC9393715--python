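"""Interhemispheric homotopic, thalamocortical, and seed-based functional
connectivity.

Connectivity between two region-average time series is the zero-lag
Pearson correlation coefficient (CC), equivalently the standardized slope
of an OLS fit of one series on the other.  Sessions are cut into
fixed-length segments (default 10 min) so that transient
session-two effects can be localized: the segment where most regions
reach their maximum CC is taken as the peak-effect segment, while the
baseline session is summarized by the per-region median over segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Dataset4D, LabelAtlas

__all__ = [
    "roi_mean_timeseries",
    "segment",
    "pairwise_cc",
    "ihfc_table",
    "select_peak_segment",
    "baseline_summary",
    "seed_cc_map",
    "reproducibility_fraction",
    "SeedMap",
]

FC_TABLE_COLUMNS = ["subject", "session", "segment_index", "roi_pair", "cc",
                    "n_frames", "missing"]


def roi_mean_timeseries(data: Dataset4D, atlas: LabelAtlas) -> pd.DataFrame:
    """Per-ROI mean time series over in-mask labeled voxels.

    Returns a frames x ROI DataFrame whose columns are ROI label ids.
    ROIs with no in-mask voxel become all-NaN columns (missing, mirroring
    real atlases whose regions can fall outside the acquired volume).
    """
    if atlas.labels.shape != data.mask.shape:
        raise ValueError("atlas grid does not match data grid")
    labels_in_mask = atlas.labels[data.mask]
    out = {}
    for roi_id in atlas.roi_ids:
        cols = np.flatnonzero(labels_in_mask == roi_id)
        if cols.size == 0:
            out[roi_id] = np.full(data.n_frames, np.nan)
        else:
            out[roi_id] = data.values[:, cols].mean(axis=1)
    return pd.DataFrame(out)


def segment(n_frames: int, tr_s: float, segment_min: float) -> list[slice]:
    """Consecutive non-overlapping segments of ``segment_min`` minutes.

    The incomplete final segment is dropped.  Raises if the session is
    shorter than one segment.
    """
    seg_len = int(round(60.0 * segment_min / tr_s))
    if seg_len < 2:
        raise ValueError("segment length must be at least 2 frames")
    n_seg = n_frames // seg_len
    if n_seg == 0:
        raise ValueError(
            f"session of {n_frames} frames is shorter than one "
            f"{segment_min:g}-min segment ({seg_len} frames)"
        )
    return [slice(i * seg_len, (i + 1) * seg_len) for i in range(n_seg)]


def pairwise_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation; NaN (missing) for constant input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0 or y.std() == 0 or np.any(np.isnan(x)) or np.any(np.isnan(y)):
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def ihfc_table(
    datasets: dict,
    atlas: LabelAtlas,
    segment_min: float = 10.0,
) -> pd.DataFrame:
    """Interhemispheric homotopic FC per (subject, session, segment, pair).

    ``datasets`` maps ``(subject, session)`` to a Dataset4D.  Each row
    holds the CC between the left and right ROI mean series of one
    homotopic pair in one segment; rows with a constant or missing ROI
    series are flagged ``missing`` and should be excluded from inference.
    """
    rows = []
    for (subj, sess), ds in sorted(datasets.items()):
        roi_ts = roi_mean_timeseries(ds, atlas)
        segs = segment(ds.n_frames, ds.tr_s, segment_min)
        for si, sl in enumerate(segs):
            for _, pr in atlas.pairs.iterrows():
                left = roi_ts[int(pr.left_id)].to_numpy()[sl]
                right = roi_ts[int(pr.right_id)].to_numpy()[sl]
                cc = pairwise_cc(left, right)
                rows.append({
                    "subject": subj, "session": sess, "segment_index": si,
                    "roi_pair": pr["name"], "cc": cc,
                    "n_frames": sl.stop - sl.start,
                    "missing": bool(np.isnan(cc)),
                })
    return pd.DataFrame(rows, columns=FC_TABLE_COLUMNS)


def select_peak_segment(post_table: pd.DataFrame) -> pd.Series:
    """Per subject, the segment where most regions reach their maximum CC.

    Each region votes for the segment maximizing its CC (earliest wins a
    within-region tie); the segment with the most votes is selected, ties
    broken by the earliest segment.  Missing rows do not vote.
    """
    valid = post_table[~post_table["missing"]]
    if valid.empty:
        raise ValueError("no valid rows to select a segment from")
    chosen = {}
    for subj, sub in valid.groupby("subject"):
        votes: dict[int, int] = {}
        for _, roi_rows in sub.groupby("roi_pair"):
            roi_rows = roi_rows.sort_values("segment_index")
            best_seg = int(roi_rows.loc[roi_rows["cc"].idxmax(), "segment_index"])
            votes[best_seg] = votes.get(best_seg, 0) + 1
        top = max(votes.values())
        chosen[subj] = min(s for s, v in votes.items() if v == top)
    return pd.Series(chosen, name="segment_index")


def baseline_summary(baseline_table: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, region) median CC across all baseline segments.

    An even segment count uses the mean-of-middle-two median convention.
    """
    valid = baseline_table[~baseline_table["missing"]]
    med = (
        valid.groupby(["subject", "roi_pair"])["cc"].median().rename("cc").reset_index()
    )
    return med


@dataclass
class SeedMap:
    """Voxelwise correlation map for one seed region."""

    values: np.ndarray          # 3D volume, NaN off-mask/undefined
    seed_name: str
    mask: np.ndarray

    @property
    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


def seed_cc_map(data: Dataset4D, atlas: LabelAtlas, seed_roi: str) -> SeedMap:
    """Pearson correlation of every in-mask voxel with a seed ROI mean
    series; constant voxels get NaN (flagged undefined)."""
    seed_id = atlas.roi_id(seed_roi) if isinstance(seed_roi, str) else int(seed_roi)
    cols = np.flatnonzero(atlas.labels[data.mask] == seed_id)
    if cols.size == 0:
        raise ValueError(f"seed ROI {seed_roi!r} has no in-mask voxels")
    seed = data.values[:, cols].mean(axis=1)
    seed_c = seed - seed.mean()
    seed_sd = seed_c.std()
    if seed_sd == 0:
        raise ValueError("seed series is constant")
    X = data.values - data.values.mean(axis=0, keepdims=True)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X.T @ seed_c) / (len(seed) * np.where(sd > 0, sd, 1.0) * seed_sd)
    r[sd == 0] = np.nan
    vol = np.full(data.mask.shape, np.nan)
    vol[data.mask] = np.clip(r, -1.0, 1.0)
    name = seed_roi if isinstance(seed_roi, str) else atlas.roi_name(seed_id)
    return SeedMap(values=vol, seed_name=name, mask=data.mask.copy())


def reproducibility_fraction(deltas: pd.DataFrame) -> pd.Series:
    """Fraction of subjects with a CC increase, per region.

    ``deltas`` has columns subject, roi_pair, delta (post minus baseline).
    A delta of exactly zero counts as not increased.
    """
    if deltas.empty:
        raise ValueError("need at least one subject")
    return deltas.groupby("roi_pair")["delta"].apply(
        lambda d: float((d > 0).sum()) / float(d.notna().sum())
    )
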