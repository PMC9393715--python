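"""Ground-truth synthetic resting-state fMRI generator.

Produces multi-subject, two-session 4D datasets carrying the statistical
structure the downstream analysis assumes: band-limited shared signals
between homotopic left/right region pairs (planted functional
connectivity), a common global signal, quasi-periodically recurring
propagating spatiotemporal events (the planted QPP), and voxelwise AR(1)
noise.  Every draw is controlled by a single integer seed, and identical
``(config, seed)`` reproduce bit-identical outputs.

The generative model is additive::

    x_v(t) = s_pair(v)(t) + g(t) + A * template_v(t - onset_k) + e_v(t)

with the shared pair signal scaled so that the correlation between the
left and right ROI *mean* series equals the planted value when global
and event components are off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .datasets import Dataset4D, LabelAtlas

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "make_atlas",
    "make_qpp_template",
    "sample_event_onsets",
    "synthesize_session",
    "simulate_cohort",
]

#: band occupied by the planted network/global signals (Hz); kept inside the
#: 0.01-0.20 Hz analysis band so preprocessing does not remove planted structure
SIGNAL_BAND_HZ = (0.01, 0.10)


@dataclass
class SynthConfig:
    """All knobs of the generator, with desk-scale defaults.

    Amplitudes (``global_amp``, ``qpp_amp``) are expressed relative to the
    stationary standard deviation of the AR(1) noise, so e.g.
    ``qpp_amp=1.5`` plants events whose peak is 1.5x the noise sd.
    """

    grid_dims: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: float = 1.0
    tr_s: float = 2.0
    n_frames: int = 600
    n_subjects: int = 7
    n_roi_pairs: int = 10
    network_r: Sequence[float] | float = 0.5
    global_amp: float = 0.5
    qpp_window_frames: int = 8
    qpp_amp: float = 1.0
    qpp_mean_iei_s: float = 40.0
    qpp_iei_shape: float = 10.0
    ar1_coef: float = 0.3
    session_amp_factor: float = 1.0
    session_fc_delta: float = 0.0
    seed: int = 0
    roi_block_voxels: tuple[int, int, int] = (4, 4, 2)
    qpp_lag_span_frames: int | None = None

    def __post_init__(self) -> None:
        rs = self.network_r_list
        if any(not (0.0 <= r < 1.0) for r in rs):
            raise ValueError("network_r values must lie in [0, 1)")
        if self.global_amp < 0 or self.qpp_amp < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.qpp_window_frames < 2:
            raise ValueError("qpp_window_frames must be >= 2")
        if self.qpp_mean_iei_s <= self.qpp_window_frames * self.tr_s:
            raise ValueError(
                "qpp_mean_iei_s must exceed the event duration "
                f"({self.qpp_window_frames * self.tr_s:g} s)"
            )
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.n_roi_pairs < 1:
            raise ValueError("need at least one ROI pair")

    @property
    def network_r_list(self) -> list[float]:
        if np.isscalar(self.network_r):
            return [float(self.network_r)] * self.n_roi_pairs
        rs = [float(r) for r in self.network_r]
        if len(rs) != self.n_roi_pairs:
            raise ValueError("network_r list length must equal n_roi_pairs")
        return rs

    @property
    def noise_sd(self) -> float:
        """Stationary sd of the AR(1) noise (unit innovation sd)."""
        return 1.0 / np.sqrt(1.0 - self.ar1_coef**2)

    @property
    def lag_span_frames(self) -> int:
        if self.qpp_lag_span_frames is None:
            return self.qpp_window_frames // 2
        return int(self.qpp_lag_span_frames)


@dataclass
class GroundTruth:
    """What was planted: the oracle for recovery tests."""

    template: np.ndarray                      # (W, n_voxels) in-mask
    onsets: list[np.ndarray] = field(default_factory=list)  # one array per session
    planted_r: np.ndarray | None = None       # (n_sessions, n_pairs)
    amp_factors: tuple[float, ...] = (1.0, 1.0)
    atlas_pairing: object | None = None

    def __post_init__(self) -> None:
        W = self.template.shape[0]
        for ons in self.onsets:
            ons = np.asarray(ons)
            if len(ons) > 1 and np.any(np.diff(ons) < W):
                raise ValueError("onsets must be sorted with gaps >= window length")


def make_atlas(config: SynthConfig) -> LabelAtlas:
    """Build a mirror-symmetric block atlas with ``n_roi_pairs`` pairs.

    Left-hemisphere blocks are placed on a regular grid of slots in the
    half-volume ``x < nx//2`` and mirrored voxel-by-voxel about the
    mid-sagittal plane (``x -> nx-1-x``).  Labels: pair ``i`` (0-based)
    gets left id ``2i+1`` and right id ``2i+2``.  Slots are ordered along
    the y axis first, which later serves as the propagation axis.
    """
    import pandas as pd

    nx, ny, nz = config.grid_dims
    bx, by, bz = config.roi_block_voxels
    half = nx // 2
    # slot counts per axis with a 1-voxel gap between blocks
    cx = (half + 1) // (bx + 1)
    cy = (ny + 1) // (by + 1)
    cz = (nz + 1) // (bz + 1)
    capacity = cx * cy * cz
    if capacity < config.n_roi_pairs:
        counts = {"x": cx, "y": cy, "z": cz}
        limiting = min(counts, key=counts.get)
        raise ValueError(
            f"grid {config.grid_dims} holds only {capacity} ROI slots "
            f"(limiting axis: {limiting}); requested {config.n_roi_pairs} pairs"
        )
    slots = [
        (ix, iy, iz) for iy in range(cy) for ix in range(cx) for iz in range(cz)
    ]  # y-major so ROI index increases with anterior-posterior position
    labels = np.zeros(config.grid_dims, dtype=np.int32)
    rows = []
    for i in range(config.n_roi_pairs):
        ix, iy, iz = slots[i]
        x0, y0, z0 = ix * (bx + 1), iy * (by + 1), iz * (bz + 1)
        left_id, right_id = 2 * i + 1, 2 * i + 2
        labels[x0 : x0 + bx, y0 : y0 + by, z0 : z0 + bz] = left_id
        xs = nx - 1 - np.arange(x0, x0 + bx)
        labels[xs[:, None, None], np.arange(y0, y0 + by)[None, :, None],
               np.arange(z0, z0 + bz)[None, None, :]] = right_id
        rows.append({"left_id": left_id, "right_id": right_id, "name": f"roi{i:02d}"})
    pairs = pd.DataFrame(rows)
    return LabelAtlas(labels=labels, pairs=pairs, voxel_size_mm=config.voxel_size_mm)


def make_qpp_template(config: SynthConfig, atlas: LabelAtlas) -> np.ndarray:
    """Planted propagating spatiotemporal template, shape (W, n_voxels).

    Each ROI pair carries one smooth unimodal bump (single-cycle raised
    cosine) whose onset lag increases with the pair's position along the
    y (anterior-posterior) axis, emulating propagation.  Each voxel trace
    is demeaned across the window and the template is normalized to unit
    peak amplitude, so the event's peak equals ``qpp_amp * noise_sd``
    after scaling at synthesis time.
    """
    W = config.qpp_window_frames
    span = min(config.lag_span_frames, W - 2)
    burst = W - span  # bump duration in frames (>= 2)
    mask = atlas.mask
    labels_in_mask = atlas.labels[mask]
    n_vox = int(mask.sum())
    # pair order along the propagation axis = pair index by construction
    ys = np.arange(atlas.labels.shape[1])
    pair_pos = []
    for _, row in atlas.pairs.iterrows():
        inside = np.any(atlas.labels == row.left_id, axis=(0, 2))
        pair_pos.append(float(ys[inside].mean()))
    order = np.argsort(np.asarray(pair_pos), kind="stable")
    lags = np.zeros(len(order))
    if len(order) > 1 and span > 0:
        lags[order] = np.round(np.linspace(0, span, len(order)))
    template = np.zeros((W, n_vox))
    t = np.arange(W, dtype=float)
    for i, (_, row) in enumerate(atlas.pairs.iterrows()):
        lag = lags[i]
        tau = t - lag
        bump = np.where(
            (tau >= 0) & (tau < burst),
            0.5 * (1.0 - np.cos(2.0 * np.pi * tau / burst)),
            0.0,
        )
        bump = bump - bump.mean()
        cols = np.flatnonzero(
            (labels_in_mask == row.left_id) | (labels_in_mask == row.right_id)
        )
        template[:, cols] = bump[:, None]
    peak = np.abs(template).max()
    if peak > 0:
        template = template / peak
    return template


def sample_event_onsets(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic event start frames for one session.

    The first onset is uniform on ``[0, mean IEI)`` (stationary renewal
    start); subsequent inter-event intervals are gamma distributed with
    mean ``qpp_mean_iei_s / tr_s`` frames and shape ``qpp_iei_shape``,
    with draws shorter than the window length resampled so events never
    overlap.  Events whose window would run past the session end are
    dropped.
    """
    W = config.qpp_window_frames
    mean_frames = config.qpp_mean_iei_s / config.tr_s
    if mean_frames <= W:
        raise ValueError("mean inter-event interval must exceed the window length")
    k = config.qpp_iei_shape
    scale = mean_frames / k

    def draw_interval() -> float:
        for _ in range(1000):
            x = rng.gamma(k, scale)
            if x >= W:
                return x
        raise RuntimeError("could not draw a valid inter-event interval")

    onsets = []
    pos = rng.uniform(0.0, mean_frames)
    while pos + W <= config.n_frames:
        onsets.append(int(np.floor(pos)))
        pos += draw_interval()
    # flooring can in principle collapse a gap to W-1; enforce the invariant
    out = []
    for o in onsets:
        if not out or o - out[-1] >= W:
            out.append(o)
    return np.asarray(out, dtype=np.int64)


def _band_limited_series(n: int, tr_s: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-sd Gaussian series band-limited to SIGNAL_BAND_HZ."""
    lo, hi = SIGNAL_BAND_HZ
    nyq = 0.5 / tr_s
    x = rng.standard_normal(n + 200)  # pad to wash out filter transients
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    y = sps.sosfiltfilt(sos, x)[100 : 100 + n]
    sd = y.std(ddof=0)
    return y / sd if sd > 0 else y


def _ar1_noise(shape: tuple[int, int], coef: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise with unit innovation sd, stationary start (burn-in)."""
    burn = 100
    innov = rng.standard_normal((shape[0] + burn, shape[1]))
    if coef == 0.0:
        return innov[burn:]
    out = sps.lfilter([1.0], [1.0, -coef], innov, axis=0)
    return out[burn:]


def synthesize_session(
    config: SynthConfig,
    atlas: LabelAtlas,
    template: np.ndarray,
    onsets: np.ndarray,
    session_index: int,
    rng: np.random.Generator,
) -> tuple[Dataset4D, GroundTruth]:
    """Generate one session's 4D dataset plus its ground truth.

    ``session_index`` 0 is Baseline; session 1 applies
    ``session_amp_factor`` to the event amplitude and ``session_fc_delta``
    to every planted pair correlation (clipped to [0, 0.999]).
    """
    mask = atlas.mask
    n_vox = int(mask.sum())
    T = config.n_frames
    sd_n = config.noise_sd
    labels_in_mask = atlas.labels[mask]

    data = _ar1_noise((T, n_vox), config.ar1_coef, rng)

    rs = np.asarray(config.network_r_list, dtype=float)
    if session_index == 1:
        rs = np.clip(rs + config.session_fc_delta, 0.0, 0.999)
    for i, (_, row) in enumerate(atlas.pairs.iterrows()):
        shared = _band_limited_series(T, config.tr_s, rng)
        cols = np.flatnonzero(
            (labels_in_mask == row.left_id) | (labels_in_mask == row.right_id)
        )
        m = int((labels_in_mask == row.left_id).sum())
        r = rs[i]
        if r > 0 and m > 0:
            sd_s = sd_n * np.sqrt(r / ((1.0 - r) * m))
            data[:, cols] += sd_s * shared[:, None]

    if config.global_amp > 0:
        g = _band_limited_series(T, config.tr_s, rng)
        data += (config.global_amp * sd_n) * g[:, None]

    amp_factor = config.session_amp_factor if session_index == 1 else 1.0
    amp = config.qpp_amp * sd_n * amp_factor
    if amp > 0:
        W = template.shape[0]
        for o in onsets:
            data[o : o + W, :] += amp * template

    ds = Dataset4D(
        values=data,
        mask=mask,
        tr_s=config.tr_s,
        voxel_size_mm=config.voxel_size_mm,
        provenance=[{"step": "synthesize_session", "session": session_index}],
    )
    gt = GroundTruth(
        template=template,
        onsets=[np.asarray(onsets)],
        planted_r=rs[None, :],
        amp_factors=(1.0, config.session_amp_factor),
        atlas_pairing=atlas.pairs,
    )
    return ds, gt


@dataclass
class Cohort:
    """A simulated multi-subject, two-session study."""

    atlas: LabelAtlas
    datasets: dict  # (subject, session) -> Dataset4D
    ground_truth: dict  # (subject, session) -> GroundTruth
    template: np.ndarray
    config: SynthConfig

    @property
    def subjects(self) -> list[int]:
        return sorted({s for s, _ in self.datasets})


def simulate_cohort(config: SynthConfig, n_sessions: int = 2) -> Cohort:
    """Simulate the full study: ``n_subjects`` x ``n_sessions`` datasets.

    Per-subject/session RNG streams are spawned from ``config.seed`` so
    the cohort is reproducible as a whole and per stream.
    """
    atlas = make_atlas(config)
    template = make_qpp_template(config, atlas)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects * n_sessions)
    datasets: dict = {}
    gts: dict = {}
    for subj in range(config.n_subjects):
        for sess in range(n_sessions):
            rng = np.random.default_rng(children[subj * n_sessions + sess])
            onsets = sample_event_onsets(config, rng)
            ds, gt = synthesize_session(config, atlas, template, onsets, sess, rng)
            datasets[(subj, sess)] = ds
            gts[(subj, sess)] = gt
    return Cohort(atlas=atlas, datasets=datasets, ground_truth=gts,
                  template=template, config=config)
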