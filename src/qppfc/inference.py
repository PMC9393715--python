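"""Group statistics: paired / one-sample t-tests (optionally on Fisher-z
transformed correlations), Benjamini-Hochberg FDR, and Monte-Carlo
cluster-extent familywise-error correction for voxelwise maps.

The cluster-extent null emulates the classic AlphaSim recipe: simulate
smooth Gaussian null fields inside the brain mask, threshold at the
voxelwise z cutoff, label connected components, and record the maximum
cluster extent per iteration; a real map's clusters survive if their
extent reaches the (1-alpha) tail of that null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "paired_t",
    "one_sample_t",
    "fdr_bh",
    "ClusterNull",
    "simulate_cluster_null",
    "cluster_correct",
]


@dataclass
class TTestResult:
    t: float
    p: float
    dof: int
    n: int
    transform: str = "none"
    degenerate: bool = False


def _maybe_fisher_z(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "fisher-z":
        if np.any(np.abs(x) >= 1):
            raise ValueError("fisher-z requires |values| < 1")
        return np.arctanh(x)
    if transform != "none":
        raise ValueError("transform must be 'none' or 'fisher-z'")
    return x


def one_sample_t(x: np.ndarray, transform: str = "none") -> TTestResult:
    """Classical one-sample t-test of mean 0; zero-variance input is
    returned flagged degenerate rather than raising."""
    x = np.asarray(x, dtype=np.float64)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    z = _maybe_fisher_z(x, transform)
    sd = z.std(ddof=1)
    if sd == 0:
        return TTestResult(t=np.nan, p=np.nan, dof=n - 1, n=n,
                           transform=transform, degenerate=True)
    t = z.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(max(p, np.finfo(float).tiny)),
                       dof=n - 1, n=n, transform=transform)


def paired_t(x: np.ndarray, y: np.ndarray, transform: str = "none") -> TTestResult:
    """Paired t-test on x - y (after optional Fisher-z of each side)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = _maybe_fisher_z(x, transform) - _maybe_fisher_z(y, transform)
    res = one_sample_t(d, transform="none")
    res.transform = transform
    return res


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted p, rejection mask).

    NaN entries are excluded from the correction and returned as NaN /
    not rejected.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    valid = ~np.isnan(p)
    if np.any((p[valid] <= 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    if valid.sum() > 0:
        r, a, _, _ = multipletests(p[valid], alpha=q, method="fdr_bh")
        adj[valid] = a
        rej[valid] = a <= q
    return adj, rej


@dataclass
class ClusterNull:
    """Null distribution of maximum cluster extents under smooth noise."""

    max_extents: np.ndarray
    voxel_p: float
    z_thresh: float
    connectivity: int
    n_iter: int
    fwhm_mm: float
    mask_shape: tuple = ()
    mask_sum: int = 0

    def extent_threshold(self, alpha: float = 0.05) -> int:
        """Smallest integer k with P(max extent >= k) <= alpha in the null."""
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        ext = np.sort(self.max_extents)
        # fraction of iterations with max extent >= k, scanned upward
        for k in range(0, int(ext.max()) + 2):
            frac = np.mean(ext >= k)
            if frac <= alpha:
                return int(k)
        return int(ext.max()) + 1


def _conn_structure(connectivity: int) -> np.ndarray:
    mapping = {6: 1, 18: 2, 26: 3}
    if connectivity not in mapping:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndi.generate_binary_structure(3, mapping[connectivity])


def simulate_cluster_null(
    mask: np.ndarray,
    voxel_size_mm: float,
    fwhm_mm: float,
    voxel_p: float = 0.01,
    connectivity: int = 6,
    n_iter: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ClusterNull:
    """Monte-Carlo null of the maximum supra-threshold cluster extent.

    Each iteration: white Gaussian noise on the grid, Gaussian smoothing
    at the analysis FWHM, re-standardization to unit variance inside the
    mask, one-sided thresholding at ``z(voxel_p)``, connected-component
    labeling, and recording of the largest component.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    z_thresh = float(stats.norm.isf(voxel_p))
    structure = _conn_structure(connectivity)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    extents = np.zeros(n_iter, dtype=np.int64)
    for i in range(n_iter):
        field_ = rng.standard_normal(mask.shape)
        if sigma > 0:
            field_ = ndi.gaussian_filter(field_, sigma)
        vals = field_[mask]
        vals = (vals - vals.mean()) / vals.std()
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = vals > z_thresh
        if supra.any():
            labeled, n = ndi.label(supra, structure=structure)
            if n:
                extents[i] = np.bincount(labeled.ravel())[1:].max()
    return ClusterNull(
        max_extents=extents, voxel_p=voxel_p, z_thresh=z_thresh,
        connectivity=connectivity, n_iter=n_iter, fwhm_mm=fwhm_mm,
        mask_shape=tuple(mask.shape), mask_sum=int(mask.sum()),
    )


def cluster_correct(
    stat_map: np.ndarray,
    null: ClusterNull,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
):
    """Retain clusters of a z-scaled map that beat the null extent threshold.

    The map is thresholded one-sided at the null's voxelwise z cutoff;
    connected components (same connectivity as the null) survive if their
    extent >= ``null.extent_threshold(alpha)``.  Returns (significant
    mask, cluster table) where the table is a list of dicts with size,
    peak statistic and peak coordinates.
    """
    stat_map = np.asarray(stat_map, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if tuple(mask.shape) != null.mask_shape or int(mask.sum()) != null.mask_sum:
            raise ValueError("mask does not match the one used for the null")
        work = np.where(mask, stat_map, np.nan)
    else:
        work = stat_map
    k_alpha = null.extent_threshold(alpha)
    supra = np.nan_to_num(work, nan=-np.inf) > null.z_thresh
    labeled, n = ndi.label(supra, structure=_conn_structure(null.connectivity))
    sig = np.zeros(stat_map.shape, dtype=bool)
    table = []
    for lab in range(1, n + 1):
        voxels = labeled == lab
        size = int(voxels.sum())
        if size < k_alpha:
            continue
        sig |= voxels
        idx = np.argwhere(voxels)
        peak_local = np.nanargmax(np.where(voxels, work, -np.inf))
        peak_coord = np.unravel_index(peak_local, stat_map.shape)
        table.append({
            "size": size,
            "peak_stat": float(work[peak_coord]),
            "peak_coord": tuple(int(c) for c in peak_coord),
        })
    table.sort(key=lambda r: -r["size"])
    return sig, table
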