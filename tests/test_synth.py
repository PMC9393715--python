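"""Tests of the synthetic-data generator: atlas geometry, planted
template shape, quasi-periodic onset statistics, and signal composition."""

import numpy as np
import pytest

from qppfc import (
    SynthConfig,
    make_atlas,
    make_qpp_template,
    roi_mean_timeseries,
    sample_event_onsets,
    simulate_cohort,
    synthesize_session,
)
from qppfc.synth import _band_limited_series

from conftest import small_config


class TestAtlas:
    def test_mirror_symmetry_bruteforce(self, small_atlas):
        """Reflecting the volume about the midline and swapping left/right
        ids reproduces the labels exactly (brute-force voxel check)."""
        labels = small_atlas.labels
        reflected = labels[::-1]
        swapped = np.zeros_like(reflected)
        for _, row in small_atlas.pairs.iterrows():
            swapped[reflected == row.left_id] = row.right_id
            swapped[reflected == row.right_id] = row.left_id
        assert np.array_equal(swapped, labels)

    def test_pair_table_and_disjoint_rois(self, small_atlas):
        assert len(small_atlas.pairs) == 4
        counts = {}
        for rid in small_atlas.roi_ids:
            counts[rid] = int((small_atlas.labels == rid).sum())
        # equal left/right voxel counts per pair
        for _, row in small_atlas.pairs.iterrows():
            assert counts[int(row.left_id)] == counts[int(row.right_id)]
        # disjoint: total labeled voxels equals sum of ROI counts
        assert sum(counts.values()) == int((small_atlas.labels > 0).sum())

    def test_single_pair_minimal_grid(self):
        cfg = small_config(grid_dims=(8, 8, 2), n_roi_pairs=1,
                           roi_block_voxels=(2, 2, 1))
        atlas = make_atlas(cfg)
        left = (atlas.labels == 1)
        right = (atlas.labels == 2)
        assert left.sum() == right.sum() > 0
        assert np.array_equal(left[::-1], right)

    def test_capacity_error_names_axis(self):
        cfg = small_config(grid_dims=(8, 8, 2), n_roi_pairs=50,
                           roi_block_voxels=(2, 2, 1))
        with pytest.raises(ValueError, match="limiting axis"):
            make_atlas(cfg)


class TestTemplate:
    def test_propagation_monotone_and_zero_mean(self, small_atlas):
        cfg = small_config()
        tpl = make_qpp_template(cfg, small_atlas)
        assert tpl.shape == (cfg.qpp_window_frames, int(small_atlas.mask.sum()))
        assert np.abs(tpl.mean(axis=0)).max() < 1e-12
        labels_in_mask = small_atlas.labels[small_atlas.mask]
        peaks = []
        for _, row in small_atlas.pairs.iterrows():
            cols = np.flatnonzero(labels_in_mask == row.left_id)
            peaks.append(int(np.argmax(tpl[:, cols].mean(axis=1))))
        # ROI pairs are ordered along the propagation axis by construction
        assert all(a <= b for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] > peaks[0]

    def test_zero_lag_span_gives_identical_traces(self, small_atlas):
        cfg = small_config(qpp_lag_span_frames=0)
        tpl = make_qpp_template(cfg, small_atlas)
        in_roi = tpl[:, np.abs(tpl).sum(axis=0) > 0]
        assert np.allclose(in_roi - in_roi[:, [0]], 0.0)


class TestOnsets:
    def test_invariants(self, rng):
        cfg = small_config(n_frames=600)
        W = cfg.qpp_window_frames
        for _ in range(20):
            ons = sample_event_onsets(cfg, rng)
            assert np.all(np.diff(ons) >= W)
            assert np.all(ons + W <= cfg.n_frames)

    def test_sparse_regime(self, rng):
        cfg = small_config(n_frames=60, qpp_mean_iei_s=4000.0)
        counts = [len(sample_event_onsets(cfg, rng)) for _ in range(50)]
        assert max(counts) <= 1

    def test_mean_count_matches_renewal_oracle(self):
        """Observed onset count over 200 seeds matches an independent
        Monte-Carlo simulation of the same renewal process (and is within
        a few percent of the naive n_frames / mean-interval count)."""
        cfg = small_config(n_frames=600, qpp_mean_iei_s=40.0)
        W = cfg.qpp_window_frames
        mean_frames = cfg.qpp_mean_iei_s / cfg.tr_s
        counts = [
            len(sample_event_onsets(cfg, np.random.default_rng(s)))
            for s in range(200)
        ]
        # independent oracle: re-simulate the renewal description directly
        oracle_rng = np.random.default_rng(987654)
        oracle_counts = []
        for _ in range(2000):
            pos = oracle_rng.uniform(0, mean_frames)
            n = 0
            while pos + W <= cfg.n_frames:
                n += 1
                while True:
                    gap = oracle_rng.gamma(cfg.qpp_iei_shape,
                                           mean_frames / cfg.qpp_iei_shape)
                    if gap >= W:
                        break
                pos += gap
            oracle_counts.append(n)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - np.mean(oracle_counts)) < 3 * se + 3 * np.std(
            oracle_counts, ddof=1) / np.sqrt(len(oracle_counts))
        assert abs(np.mean(counts) - cfg.n_frames / mean_frames) < 1.5

    def test_mean_interval_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            small_config(qpp_mean_iei_s=10.0, qpp_window_frames=8, tr_s=2.0)


class TestSessionComposition:
    def test_pure_ar1_noise_has_uncorrelated_rois(self):
        cfg = small_config(network_r=0.0, n_frames=600, seed=7)
        co = simulate_cohort(cfg, n_sessions=1)
        ts = roi_mean_timeseries(co.datasets[(0, 0)], co.atlas).to_numpy()
        cc = np.corrcoef(ts.T)
        off = cc[~np.eye(cc.shape[0], dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_white_noise_lag1_autocorrelation(self):
        cfg = small_config(network_r=0.0, ar1_coef=0.0, n_frames=600, seed=8)
        co = simulate_cohort(cfg, n_sessions=1)
        x = co.datasets[(0, 0)].values
        num = (x[1:] * x[:-1]).sum(axis=0)
        den = (x * x).sum(axis=0)
        ac1 = num / den
        se = 1.0 / np.sqrt(cfg.n_frames)
        assert abs(ac1.mean()) < 3 * se / np.sqrt(x.shape[1]) + 0.01

    @pytest.mark.parametrize("r", [0.2, 0.5, 0.8])
    def test_planted_homotopic_correlation(self, r):
        """Empirical homotopic ROI-mean correlation within 3 Fisher-z
        standard errors of the planted value (confounds off)."""
        ccs = []
        for seed in range(10):
            cfg = small_config(network_r=r, n_frames=600, seed=seed)
            co = simulate_cohort(cfg, n_sessions=1)
            ts = roi_mean_timeseries(co.datasets[(0, 0)], co.atlas)
            for _, row in co.atlas.pairs.iterrows():
                ccs.append(np.corrcoef(ts[int(row.left_id)],
                                       ts[int(row.right_id)])[0, 1])
        # band-limited signals have ~2*B*T effective dof, not n_frames
        eff_dof = 2 * 0.09 * 600 * 2.0
        se = (1 - r**2) / np.sqrt(eff_dof)
        assert abs(np.mean(ccs) - r) < 3 * se / np.sqrt(len(ccs)) + 0.02

    def test_event_amplitude_increases_explained_variance(self, small_atlas):
        cfg0 = small_config(qpp_amp=0.0, network_r=0.0, seed=5)
        var_frac = []
        for amp in (0.5, 1.0, 2.0):
            cfg = small_config(qpp_amp=amp, network_r=0.0, seed=5)
            co = simulate_cohort(cfg, n_sessions=1)
            ds = co.datasets[(0, 0)]
            gt = co.ground_truth[(0, 0)]
            W = co.template.shape[0]
            model = np.zeros_like(ds.values)
            for o in gt.onsets[0]:
                model[o : o + W] += co.template
            num = (ds.values * model).sum() ** 2
            den = (model * model).sum() * (ds.values * ds.values).sum()
            var_frac.append(num / den)
        assert var_frac[0] < var_frac[1] < var_frac[2]

    def test_bit_identical_reproduction(self):
        cfg = small_config(network_r=0.4, global_amp=0.5, qpp_amp=1.0, seed=99)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for key in a.datasets:
            assert np.array_equal(a.datasets[key].values, b.datasets[key].values)
        assert np.array_equal(a.template, b.template)

    def test_session_two_applies_amp_factor(self, rng):
        cfg = small_config(qpp_amp=1.0, network_r=0.0, session_amp_factor=0.5,
                           n_frames=200)
        atlas = simulate_cohort(cfg, n_sessions=1).atlas
        tpl = make_qpp_template(cfg, atlas)
        onsets = np.array([50])
        rng_a = np.random.default_rng(0)
        rng_b = np.random.default_rng(0)
        ds0, _ = synthesize_session(cfg, atlas, tpl, onsets, 0, rng_a)
        ds1, _ = synthesize_session(cfg, atlas, tpl, onsets, 1, rng_b)
        diff = ds0.values - ds1.values  # identical noise, differing event scale
        expected = 0.5 * cfg.qpp_amp * cfg.noise_sd * tpl
        assert np.allclose(diff[50:58], expected, atol=1e-10)


def test_band_limited_series_spectrum(rng):
    x = _band_limited_series(2048, 2.0, rng)
    f = np.fft.rfftfreq(2048, 2.0)
    power = np.abs(np.fft.rfft(x)) ** 2
    in_band = power[(f >= 0.01) & (f <= 0.10)].sum()
    assert in_band / power.sum() > 0.95
    assert abs(x.std() - 1.0) < 1e-9
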