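"""Quasi-periodic pattern (QPP) detection and strength scoring.

A QPP is a recurring, propagating spatiotemporal motif in resting-state
fMRI.  Detection follows the iterative template-matching algorithm: seed
a template with a randomly chosen window of the data, slide it along the
whole time-course computing the spatiotemporal correlation (STC) — the
Pearson correlation between the flattened template and each equal-length
data window — collect supra-threshold STC local maxima, average the data
windows at those maxima into a refined template, and repeat to
convergence.  Multiple random initializations are run and the converged
template with the largest summed supra-threshold peak correlation wins.

The per-scan summary statistic ("QPP strength") is the mean of the
positive STC samples, normalized by the subject's maximum STC across all
of their scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import Dataset4D

__all__ = [
    "QPPTemplate",
    "STCCurve",
    "QPPResult",
    "sliding_stc",
    "bootstrap_threshold",
    "detect_qpp",
    "qpp_strength",
    "suppression_percent",
    "group_template",
    "best_lag_correlation",
]


@dataclass
class QPPTemplate:
    """A converged spatiotemporal template: ``values`` is (W, n_voxels)."""

    values: np.ndarray
    origin_offset: int = -1
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("template must be (W >= 2) x voxels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("template values must be finite")
        if self.values.std() == 0:
            raise ValueError("template must have nonzero variance")

    @property
    def window_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class STCCurve:
    """Sliding spatiotemporal correlation of a template against data.

    ``values[tau]`` is the Pearson correlation of the flattened template
    with the flattened data window starting at global frame
    ``frame_index[tau]``; windows never straddle scan boundaries.
    """

    values: np.ndarray
    window_frames: int
    threshold: float = 0.2
    peak_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    frame_index: np.ndarray | None = None
    degenerate_windows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("STC values must lie in [-1, 1]")
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.values))


@dataclass
class QPPResult:
    found: bool
    template: QPPTemplate | None
    stc: STCCurve | None
    occurrences: int
    score: float
    diagnostics: dict = field(default_factory=dict)


def _stc_values(X: np.ndarray, tmpl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of flattened ``tmpl`` (W,V) against every window of ``X`` (T,V).

    Vectorized via per-frame dot products and running window sums; returns
    (values, degenerate_window_indices).
    """
    T, V = X.shape
    W = tmpl.shape[0]
    L = T - W + 1
    n = W * V
    t_sum = tmpl.sum()
    t_ss = (tmpl * tmpl).sum()
    t_var = t_ss - t_sum * t_sum / n

    D = X @ tmpl.T                      # (T, W): frame f . template-frame w
    C = np.zeros(L)
    for w in range(W):
        C += D[w : w + L, w]

    s = X.sum(axis=1)
    q = (X * X).sum(axis=1)
    cs = np.concatenate([[0.0], np.cumsum(s)])
    cq = np.concatenate([[0.0], np.cumsum(q)])
    S = cs[W:] - cs[:-W]                # window sums
    Q = cq[W:] - cq[:-W]                # window sums of squares
    x_var = Q - S * S / n
    cov = C - S * t_sum / n

    denom = np.sqrt(np.maximum(x_var, 0.0) * max(t_var, 0.0))
    degenerate = np.flatnonzero((x_var <= 1e-12 * max(Q.max(), 1.0)) | (t_var <= 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


def _scan_values(data) -> list[np.ndarray]:
    """Normalize input (Dataset4D, array, or list thereof) to a list of (T,V)."""
    if isinstance(data, Dataset4D):
        return [data.values]
    if isinstance(data, np.ndarray):
        return [data]
    out = []
    for d in data:
        out.append(d.values if isinstance(d, Dataset4D) else np.asarray(d))
    return out


def sliding_stc(data, template) -> STCCurve:
    """Sliding-window spatiotemporal correlation curve.

    ``data`` may be one Dataset4D/array or a list of scans; windows that
    would straddle a scan boundary are excluded, so the curve length is
    ``sum(T_i - W + 1)``.
    """
    tmpl = template.values if isinstance(template, QPPTemplate) else np.asarray(template)
    W = tmpl.shape[0]
    scans = _scan_values(data)
    vals, frames, degen = [], [], []
    offset = 0
    for X in scans:
        if X.shape[0] < W:
            raise ValueError("scan shorter than the template window")
        if X.shape[1] != tmpl.shape[1]:
            raise ValueError("template voxel count does not match data")
        r, dg = _stc_values(np.asarray(X, dtype=np.float64), tmpl)
        vals.append(r)
        frames.append(np.arange(X.shape[0] - W + 1) + offset)
        degen.append(dg + len(np.concatenate(vals[:-1])) if vals[:-1] else dg)
        offset += X.shape[0]
    return STCCurve(
        values=np.concatenate(vals),
        window_frames=W,
        frame_index=np.concatenate(frames),
        degenerate_windows=np.concatenate(degen) if degen else np.array([], dtype=int),
    )


def _find_peaks(values: np.ndarray, threshold: float, min_sep: int) -> np.ndarray:
    """Supra-threshold local maxima with a minimum separation, greedy by height."""
    v = values
    n = len(v)
    if n == 0:
        return np.array([], dtype=int)
    is_max = np.ones(n, dtype=bool)
    is_max[1:] &= v[1:] > v[:-1]
    is_max[:-1] &= v[:-1] >= v[1:]
    cand = np.flatnonzero(is_max & (v >= threshold))
    if cand.size == 0:
        return cand
    order = cand[np.argsort(-v[cand], kind="stable")]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_sep for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def find_stc_peaks(stc: STCCurve, threshold: float,
                   min_sep: int | None = None) -> np.ndarray:
    """Indices (into stc.values) of supra-threshold peaks.

    Default minimum separation is one full window (W frames): the STC
    bump of a single event spans up to 2W frames, so a smaller separation
    double-counts events via secondary maxima on the bump's flanks.
    """
    if min_sep is None:
        min_sep = max(1, stc.window_frames)
    return _find_peaks(stc.values, threshold, min_sep)


def bootstrap_threshold(
    data,
    W: int,
    n_boot: int = 500,
    percentile: float = 99.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Null STC threshold by circular-shift bootstrapping.

    Each bootstrap draws a real data window and correlates it against a
    window of a surrogate in which every voxel's series has been
    independently circularly shifted in time — preserving each voxel's
    autocorrelation while destroying spatiotemporal alignment.  Returns
    the given percentile of the absolute null STC values.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    scans = _scan_values(data)
    X = np.concatenate(scans, axis=0)
    T, V = X.shape
    if W >= T:
        raise ValueError("window length must be shorter than the data")
    null = np.empty(n_boot)
    for b in range(n_boot):
        shifts = rng.integers(0, T, size=V)
        tau_t = int(rng.integers(0, T - W + 1))
        tau_s = int(rng.integers(0, T - W + 1))
        rows = (np.arange(tau_s, tau_s + W)[:, None] + shifts[None, :]) % T
        surrogate = X[rows, np.arange(V)[None, :]]
        r, _ = _stc_values(X[tau_t : tau_t + W], surrogate)
        null[b] = abs(r[0])
    return float(np.percentile(null, percentile))


def _iteration_threshold(scheme, iteration: int) -> float:
    """Two-stage convention: lenient early, strict once the template forms."""
    if scheme == "two_stage":
        return 0.1 if iteration < 3 else 0.2
    return float(scheme)


def detect_qpp(
    data,
    W: int = 8,
    thresholds="two_stage",
    n_init: int = 20,
    rng: np.random.Generator | int | None = None,
    max_iter: int = 20,
    conv_corr: float = 0.9999,
) -> QPPResult:
    """Iterative template-matching QPP detection with random restarts.

    ``thresholds`` is ``"two_stage"`` (0.1 for the first 3 iterations,
    0.2 after), or a fixed scalar (e.g. one from
    :func:`bootstrap_threshold`).  Convergence: correlation between
    successive flattened templates >= ``conv_corr`` on two consecutive
    iterations, capped at ``max_iter``.  Among converged starts the
    template maximizing the summed supra-threshold peak STC wins; ties go
    to the earliest initialization offset.  Returns ``found=False`` (not
    an exception) when no start converges with >= 2 occurrences.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    scans = _scan_values(data)
    total_frames = sum(X.shape[0] for X in scans)
    if total_frames < 3 * W:
        raise ValueError("need at least 3 windows of data")

    # valid window starts in global frame coordinates (never straddling scans)
    starts, offset = [], 0
    for X in scans:
        starts.append(np.arange(X.shape[0] - W + 1) + offset)
        offset += X.shape[0]
    starts = np.concatenate(starts)
    concat = np.concatenate([np.asarray(X, dtype=np.float64) for X in scans], axis=0)

    n_init = min(n_init, len(starts))
    init_offsets = rng.choice(starts, size=n_init, replace=False)
    init_offsets = np.sort(init_offsets)

    best: QPPResult | None = None
    n_converged = 0
    for off in init_offsets:
        tmpl = concat[off : off + W].copy()
        if tmpl.std() == 0:
            continue
        conv_streak = 0
        converged = False
        stc = None
        peaks = np.array([], dtype=int)
        for it in range(max_iter):
            thr = _iteration_threshold(thresholds, it)
            stc = sliding_stc(scans, tmpl)
            peaks = find_stc_peaks(stc, thr)
            if len(peaks) < 2:
                break
            windows = np.stack(
                [concat[stc.frame_index[p] : stc.frame_index[p] + W] for p in peaks]
            )
            new_tmpl = windows.mean(axis=0)
            if new_tmpl.std() == 0:
                break
            c = np.corrcoef(new_tmpl.ravel(), tmpl.ravel())[0, 1]
            tmpl = new_tmpl
            conv_streak = conv_streak + 1 if c >= conv_corr else 0
            if conv_streak >= 2:
                converged = True
                break
        if not converged:
            continue
        stc = sliding_stc(scans, tmpl)
        thr = _iteration_threshold(thresholds, max_iter)
        peaks = find_stc_peaks(stc, thr)
        if len(peaks) < 2:
            continue
        n_converged += 1
        score = float(stc.values[peaks].sum())
        stc.threshold = thr
        stc.peak_frames = stc.frame_index[peaks]
        result = QPPResult(
            found=True,
            template=QPPTemplate(tmpl, origin_offset=int(off)),
            stc=stc,
            occurrences=len(peaks),
            score=score,
            diagnostics={"n_init": n_init, "init_offset": int(off)},
        )
        if best is None or score > best.score:
            best = result
    if best is None:
        return QPPResult(
            found=False, template=None, stc=None, occurrences=0, score=0.0,
            diagnostics={"n_init": n_init, "n_converged": n_converged,
                         "reason": "no start converged with >= 2 occurrences"},
        )
    best.diagnostics["n_converged"] = n_converged
    return best


def qpp_strength(stc: STCCurve | np.ndarray, normalizer: float) -> float:
    """Mean of the positive STC samples, divided by ``normalizer``.

    The normalizer is by convention the maximum STC value across the
    subject's concatenated sessions.  Returns 0 when no sample is
    positive.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    values = stc.values if isinstance(stc, STCCurve) else np.asarray(stc)
    pos = values[values > 0]
    if pos.size == 0:
        return 0.0
    return float(pos.mean() / normalizer)


def suppression_percent(strength_pre: float, strength_post: float) -> float:
    """Percent reduction in QPP strength from pre to post (negative =
    enhancement)."""
    if strength_pre <= 0:
        raise ValueError("pre-session strength must be positive")
    return 100.0 * (strength_pre - strength_post) / strength_pre


def group_template(
    datasets: list[Dataset4D],
    W: int = 8,
    thresholds="two_stage",
    n_init: int = 20,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> tuple[QPPResult, list[STCCurve]]:
    """Detect one QPP template from concatenated scans, then score each scan.

    All scans must share mask and TR; each is standardized per scan before
    concatenation (a no-op on already standardized data).  Returns the
    group detection result plus the per-scan STC curves of the group
    template.
    """
    from .preprocess import standardize

    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    mask0, tr0 = datasets[0].mask, datasets[0].tr_s
    for d in datasets[1:]:
        if not np.array_equal(d.mask, mask0):
            raise ValueError("all scans must share the same mask")
        if d.tr_s != tr0:
            raise ValueError("all scans must share the same TR")
    std = [standardize(d) for d in datasets]
    result = detect_qpp(std, W=W, thresholds=thresholds, n_init=n_init, rng=rng, **kwargs)
    per_scan: list[STCCurve] = []
    if result.found:
        for d in std:
            per_scan.append(sliding_stc(d, result.template))
    return result, per_scan


def best_lag_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Max Pearson correlation between two (W,V) templates over circular
    frame lags (and sign), used to compare recovered vs planted templates."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    best = -1.0
    W = a.shape[0]
    for lag in range(W):
        rolled = np.roll(b, lag, axis=0)
        r = np.corrcoef(a.ravel(), rolled.ravel())[0, 1]
        best = max(best, abs(float(r)))
    return best
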