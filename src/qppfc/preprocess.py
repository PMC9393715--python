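"""Time-series conditioning: bandpass, nuisance regression, standardization,
mask-aware spatial smoothing, global-signal regression, and motion QC.

The canonical chain (and the order `preprocess_dataset` enforces) is
bandpass -> nuisance regression -> standardize -> smooth, with
global-signal regression (GSR) as an optional extra step used by the QPP
branch of the analysis.  All operations are mask-closed: voxels outside
the mask never influence in-mask values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import signal as sps

from .datasets import Dataset4D

__all__ = [
    "bandpass",
    "regress_out",
    "standardize",
    "smooth_gaussian",
    "global_signal",
    "gsr",
    "motion_qc",
    "preprocess_dataset",
    "MotionQCReport",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _design_bandpass(f_lo: float, f_hi: float, tr_s: float, order: int):
    nyq = 0.5 / tr_s
    if not (0.0 <= f_lo < f_hi):
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > nyq + 1e-12:
        raise ValueError(f"f_hi={f_hi} Hz exceeds Nyquist {nyq:g} Hz")
    if f_lo <= 0.0 and f_hi >= nyq - 1e-12:
        return None  # all-pass
    if f_lo <= 0.0:
        return sps.butter(order, f_hi / nyq, btype="lowpass", output="sos")
    if f_hi >= nyq - 1e-12:
        return sps.butter(order, f_lo / nyq, btype="highpass", output="sos")
    return sps.butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")


def _bandpass_array(x: np.ndarray, f_lo: float, f_hi: float, tr_s: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass along axis 0; mean-removed first."""
    sos = _design_bandpass(f_lo, f_hi, tr_s, order)
    x = x - x.mean(axis=0, keepdims=True)
    if sos is None:
        return x
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= padlen:
        raise ValueError(
            f"time series too short ({x.shape[0]} frames) for the filter "
            f"warm-up length ({padlen} frames)"
        )
    return sps.sosfiltfilt(sos, x, axis=0)


def _fft_bandpass_array(x: np.ndarray, f_lo: float, f_hi: float, tr_s: float) -> np.ndarray:
    """Ideal (boxcar) bandpass via the FFT: an orthogonal projection onto
    the in-band frequency subspace."""
    nyq = 0.5 / tr_s
    if not (0.0 <= f_lo < f_hi <= nyq + 1e-12):
        raise ValueError("need 0 <= f_lo < f_hi <= Nyquist")
    n = x.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    X = np.fft.rfft(x, axis=0)
    X[~keep] = 0.0
    return np.fft.irfft(X, n=n, axis=0)


def bandpass(ds: Dataset4D, f_lo: float, f_hi: float, order: int = 4,
             method: str = "butter") -> Dataset4D:
    """Zero-phase bandpass filter of every voxel series.

    ``method="butter"`` (default) is a forward-backward Butterworth IIR
    (order doubled, phase cancelled); ``method="fft"`` is an ideal boxcar
    projection, useful when exact linear-operator algebra matters (e.g.
    it commutes exactly with regression on an in-band regressor).
    Per-voxel means are removed first.
    """
    if method == "butter":
        out = _bandpass_array(ds.values, f_lo, f_hi, ds.tr_s, order)
    elif method == "fft":
        out = _fft_bandpass_array(ds.values - ds.values.mean(0), f_lo, f_hi, ds.tr_s)
    else:
        raise ValueError("method must be 'butter' or 'fft'")
    return ds.with_values(out, "bandpass", f_lo=f_lo, f_hi=f_hi, order=order,
                          method=method)


def regress_out(ds: Dataset4D, regressors: np.ndarray) -> Dataset4D:
    """OLS residuals of every voxel series on the given regressors.

    An intercept column is always appended.  Rank-deficient designs are
    handled by the pseudoinverse (with a warning), so duplicate
    regressors are tolerated.
    """
    X = np.asarray(regressors, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != ds.n_frames:
        raise ValueError("regressor frame count does not match data")
    if X.shape[1] >= ds.n_frames:
        raise ValueError("more regressors than frames")
    X = np.column_stack([X, np.ones(ds.n_frames)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient regressor matrix; using pseudoinverse",
                      RuntimeWarning, stacklevel=2)
    beta = np.linalg.pinv(X) @ ds.values
    resid = ds.values - X @ beta
    return ds.with_values(resid, "regress_out", n_regressors=X.shape[1] - 1)


def standardize(ds: Dataset4D) -> Dataset4D:
    """Per-voxel mean 0 / sample sd 1; constant voxels zeroed and flagged."""
    mu = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=1)
    degenerate = sd == 0
    safe = np.where(degenerate, 1.0, sd)
    out = (ds.values - mu) / safe
    out[:, degenerate] = 0.0
    return ds.with_values(out, "standardize",
                          n_degenerate_voxels=int(degenerate.sum()))


def smooth_gaussian(ds: Dataset4D, fwhm_mm: float) -> Dataset4D:
    """Frame-wise isotropic Gaussian smoothing restricted to the mask.

    Uses a mass-conserving mask normalization: each in-mask voxel
    distributes its value over its in-mask neighbours with Gaussian
    weights normalized per *source* voxel, so the frame-wise mean over
    the mask is preserved exactly.  ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return ds.with_values(ds.values.copy(), "smooth_gaussian", fwhm_mm=0.0)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / ds.voxel_size_mm
    mask = ds.mask
    w = ndi.gaussian_filter(mask.astype(np.float64), sigma_vox, mode="constant")
    w_in = w[mask]
    out = np.empty_like(ds.values)
    vol = np.zeros(mask.shape)
    for f in range(ds.n_frames):
        vol[mask] = ds.values[f] / w_in
        sm = ndi.gaussian_filter(vol, sigma_vox, mode="constant")
        out[f] = sm[mask]
    return ds.with_values(out, "smooth_gaussian", fwhm_mm=fwhm_mm)


def global_signal(ds: Dataset4D) -> np.ndarray:
    """Per-frame mean over all mask voxels."""
    if ds.n_voxels == 0:
        raise ValueError("empty mask")
    return ds.values.mean(axis=1)


def gsr(ds: Dataset4D, f_lo: float | None = None, f_hi: float | None = None) -> Dataset4D:
    """Global-signal regression.

    The whole-brain mean signal is filtered with *the same band as the
    data* and regressed out of every voxel.  If no band is given it is
    read from the dataset's bandpass provenance; unfiltered data get the
    raw global mean (filtering the regressor more narrowly than the data
    would leave residual global signal near the band edges).
    """
    if f_lo is None or f_hi is None:
        band = next((p for p in reversed(ds.provenance) if p.get("step") == "bandpass"),
                    None)
        if band is not None:
            f_lo, f_hi = band["f_lo"], band["f_hi"]
    g = global_signal(ds)
    if f_lo is not None and f_hi is not None:
        g = _bandpass_array(g[:, None], f_lo, f_hi, ds.tr_s)[:, 0]
    out = regress_out(ds, g[:, None])
    out.provenance[-1] = {"step": "gsr", "f_lo": f_lo, "f_hi": f_hi}
    return out


def load_motion_trace(path) -> np.ndarray:
    """Read a motion trace TSV: either 6 columns (translations mm,
    rotations rad) or a single precomputed displacement column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 6:
        return df.to_numpy(dtype=np.float64)
    if df.shape[1] == 1:
        return df.to_numpy(dtype=np.float64)[:, 0]
    raise ValueError("motion trace TSV must have 6 columns or 1 column")


@dataclass
class MotionQCReport:
    displacement: np.ndarray   # per frame-transition, mm
    max_displacement: float
    flagged_frames: np.ndarray
    threshold_mm: float

    @property
    def passed(self) -> bool:
        return len(self.flagged_frames) == 0


def motion_qc(trace: np.ndarray, threshold_mm: float = 0.02,
              sphere_radius_mm: float = 5.0,
              n_frames: int | None = None) -> MotionQCReport:
    """Frame-to-frame displacement QC.

    ``trace`` is (frames, 6): three translations in mm, three rotations in
    radians — or (frames,) of precomputed displacements.  Displacement per
    transition = Euclidean norm of the translation deltas plus the arc
    displacement of the rotation deltas on a sphere of
    ``sphere_radius_mm`` (default 5 mm, an approximate rat-brain radius).
    Frames whose incoming transition is >= ``threshold_mm`` are flagged.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if n_frames is not None and trace.shape[0] != n_frames:
        raise ValueError("motion trace length does not match frame count")
    if trace.ndim == 1:
        disp = trace[1:]
    else:
        if trace.shape[1] != 6:
            raise ValueError("motion trace must have 6 columns or be 1D")
        d = np.diff(trace, axis=0)
        disp = np.linalg.norm(d[:, :3], axis=1) + sphere_radius_mm * np.linalg.norm(
            d[:, 3:], axis=1
        )
    flagged = np.flatnonzero(disp >= threshold_mm) + 1
    return MotionQCReport(
        displacement=disp,
        max_displacement=float(disp.max()) if disp.size else 0.0,
        flagged_frames=flagged,
        threshold_mm=threshold_mm,
    )


def preprocess_dataset(
    ds: Dataset4D,
    f_lo: float = 0.01,
    f_hi: float = 0.20,
    fwhm_mm: float = 1.0,
    motion: np.ndarray | None = None,
    apply_gsr: bool = False,
) -> Dataset4D:
    """The full conditioning chain in the canonical order.

    bandpass -> (motion-parameter regression, motion regressors filtered
    with the same band) -> standardize -> smooth; GSR, if requested, runs
    last and is followed by a re-standardization so downstream template
    matching sees unit-variance voxels.
    """
    out = bandpass(ds, f_lo, f_hi)
    if motion is not None:
        motion = np.asarray(motion, dtype=np.float64)
        mfilt = _bandpass_array(motion, f_lo, f_hi, ds.tr_s)
        out = regress_out(out, mfilt)
    out = standardize(out)
    if fwhm_mm > 0:
        out = smooth_gaussian(out, fwhm_mm)
    if apply_gsr:
        out = gsr(out, f_lo, f_hi)
        out = standardize(out)
    return out
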