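# Methods

## The generative model

Every synthetic voxel time series is an additive mixture

    x_v(t) = s_{p(v)}(t) + g(t) + A_sess · Σ_k T_v(t − o_k) + e_v(t)

whose four terms correspond to the four phenomena the analysis measures:

1. **Network signal** `s_p(t)`: one Gaussian series per homotopic ROI pair,
   band-limited to 0.01–0.10 Hz (inside the 0.01–0.20 Hz analysis band, so
   preprocessing cannot remove planted structure), shared by every voxel of
   both members of the pair. It is scaled so that the correlation between the
   *left and right ROI-mean* series equals the planted value `r`: with `m`
   voxels per ROI and AR(1) noise of stationary sd `σ_n`, the signal sd is
   `σ_n · sqrt(r / ((1−r)·m))`. The calibration tests confirm the estimator
   is unbiased to ≲0.005 at 300 frames.
2. **Global signal** `g(t)`: one band-limited series added to *all* in-mask
   voxels with sd `global_amp · σ_n`. This is the confound term: it inflates
   every measured correlation until it is regressed out.
3. **QPP events**: a planted spatiotemporal template `T` (window `W` frames)
   added at quasi-periodic onsets `o_k`, scaled to peak amplitude
   `qpp_amp · σ_n`, times `session_amp_factor` in session 2. Each ROI pair
   carries a single-cycle raised-cosine bump whose onset lag increases along
   the anterior–posterior (y) axis — a propagating wave in miniature. The
   per-voxel traces are demeaned over the window and the template is
   normalized to unit peak.
4. **Noise** `e_v(t)`: independent AR(1) Gaussian noise with unit innovation
   sd and lag-1 coefficient `ar1_coef` (stationary start via burn-in).

Onsets form a renewal process: the first onset is uniform on
`[0, mean IEI)`, subsequent gaps are gamma(shape `qpp_iei_shape`, mean
`qpp_mean_iei_s / TR` frames) with draws shorter than `W` resampled so events
never overlap. Shape 10 makes recurrence "quasi-periodic" (CV ≈ 0.32) and
keeps the resampling bias on the mean interval negligible.

The synthetic **atlas** packs mirror-symmetric rectangular ROI blocks into the
two half-volumes; the brain mask is the union of the labeled blocks, so every
analyzed voxel belongs to a region and the planted template has full support
on the mask. Two things the generator deliberately does *not* emulate:
hemodynamic convolution (events are added directly at BOLD-band timescales)
and head motion / scanner artifacts (a motion-QC routine exists for real
traces, but simulated data are motion-free). Passing tests therefore certify
the *analysis logic* — estimator calibration, detection power, error control —
not robustness to acquisition artifacts.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `tr_s` | 2.0 s | sampling interval |
| `n_frames` | 600 | 20 min per session: two 10-min FC segments |
| `grid_dims` | 32×32×8 | desk-scale volume, 1 mm voxels |
| `n_roi_pairs` | 10 | homotopic pairs (4×4×2-voxel blocks) |
| `qpp_window_frames` | 8 | planted/detected window `W` (16 s) |
| `qpp_mean_iei_s` | 40 s | mean event recurrence interval |
| `qpp_amp` | 1.0 | event peak, units of noise sd |
| `global_amp` | 0.5 | global-signal sd, units of noise sd |
| `ar1_coef` | 0.3 | voxel noise lag-1 autocorrelation |
| `session_amp_factor` | 1.0 | session-2 event-amplitude multiplier (null) |
| `session_fc_delta` | 0.0 | session-2 additive change to planted `r` (null) |

The window length is configurable in frames rather than fixed, because the
natural "8 frames / 10 s" convention is self-inconsistent at TR = 2 s; 8
frames is the default.

## Detection and scoring choices

* **Thresholds.** The two-stage scheme (0.1 for the first three iterations,
  0.2 after) is the classic convention for this algorithm; a circular-shift
  bootstrap null (`bootstrap_threshold`, 99th percentile of |STC| between
  real windows and per-voxel circularly shifted surrogates) is available as a
  data-driven alternative.
* **Convergence.** Successive flattened templates correlating ≥ 0.9999 on two
  consecutive iterations, capped at 20 iterations. Multi-start (`n_init`,
  default 20) with ties broken by earliest initialization offset.
* **Peak separation.** STC peaks must be one full window `W` apart. A single
  event's STC bump spans up to `2W` frames, so a `W/2` separation registers
  flank maxima as extra occurrences (~2× overcounting) and blurs the averaged
  template; with separation `W` the recovered template correlates ≥ 0.94 with
  the planted one under the reference conditions.
* **Strength.** "Mean of positive excursions above zero" is read literally as
  the mean of all positive STC samples (a per-excursion-peak variant would be
  easy to add but is not the default). The normalizer is the maximum STC over
  *all of a subject's scans in the comparison* — both sessions for the
  suppression analysis, all amplitude conditions in the monotonicity test —
  so pre/post strengths share a denominator and their contrast reflects the
  positive-STC mass alone. Strength on pure noise is *not* zero (the search
  always converges on something); this is why all inference is
  session-contrast or generalization based, never existence based.
* **GSR.** The whole-brain mean regressor is filtered with *the same band as
  the data* (read from provenance). Filtering the regressor more narrowly
  than unfiltered data leaves residual global signal near the band edge that
  inflated homotopic correlations by ~0.14 in testing; matched bands remove
  the confound cleanly (restoration to within 0.06 of planted values).
* **Smoothing.** Mask-aware Gaussian smoothing uses per-*source*-voxel
  normalization (`K(x·m / K(m))` on the mask), which conserves the in-mask
  frame mean exactly instead of only approximately as per-target
  renormalization does. FWHM 0 is the identity.
* **Filters.** Zero-phase forward–backward Butterworth, order 4 (effective
  order 8, no phase distortion). An ideal FFT projection filter is available
  (`method="fft"`); being an orthogonal projection it commutes exactly with
  regression on in-band regressors, which the IIR filter only does
  approximately.

## Statistics

* Correlations are Fisher-z transformed before t-tests by default (recorded
  in the output); QPP strengths are compared untransformed.
* Two-sided p-values; paired t equals a one-sample t on differences.
* BH-FDR is the standard step-up (delegated to statsmodels, verified against
  a brute-force largest-k oracle); NaN entries are excluded and reported.
* Cluster-extent FWE control simulates the full map-generation process:
  white noise → smoothing at the analysis FWHM → in-mask re-standardization →
  one-sided threshold at `z(voxel_p)` (default p = 0.01) → 6-connectivity
  labeling (18/26 configurable) → max extent per iteration. The extent
  threshold is the smallest `k` with null `P(max ≥ k) ≤ α`. Because synthetic
  smoothness is known by construction, the applied FWHM is used directly —
  no residual-based smoothness estimation is attempted.
* Segment selection ties break to the earliest segment; a zero FC change
  counts as "not increased" in reproducibility fractions; segment boundaries
  anchor at scan start with incomplete tails dropped.

## Problem sizes

Tests and the acceptance script run on a 16×16×4 grid with four 2×2×2-voxel
ROI pairs (64 in-mask voxels) and 300–600-frame sessions, with 3–5 detection
restarts; replicate counts follow the property being measured (10–50 seeds,
1,000 tables/maps for error-rate calibration). These sizes keep the full
suite in the low minutes while leaving every estimator's sampling error well
inside the asserted tolerances; the defaults in `SynthConfig` describe the
larger reference configuration.

## Known limitations

* The bootstrap null for the STC threshold is this package's documented
  stand-in for the original algorithm's unpublished procedure.
* No lagged cross-correlation, phase-sorted QPP variants, dynamic-FC state
  analysis, partial correlation, or mixed-effects inference.
* The simulator's stationarity (constant amplitudes within a session) means
  transient drug-onset dynamics — which motivate the peak-segment selection —
  are emulated only coarsely: session 2 is homogeneous, so the selected
  segment differs from the others only by sampling noise.
* Voxel-level planted correlations are lower than ROI-mean correlations by
  construction (independent voxel noise); seed-map values are therefore not
  directly comparable to the pairwise ROI targets.
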