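"""Detect the quasi-periodic pattern planted in one synthetic scan.

Runs the iterative template-matching search (random window seeds,
sliding spatiotemporal correlation, supra-threshold window averaging)
and compares the converged template against the planted ground truth.
"""

import numpy as np

from qppfc import (SynthConfig, best_lag_correlation, detect_qpp,
                   preprocess_dataset, qpp_strength, simulate_cohort)

config = SynthConfig(
    grid_dims=(16, 16, 4), n_roi_pairs=4, roi_block_voxels=(2, 2, 2),
    n_subjects=1, n_frames=600, qpp_amp=1.5, global_amp=0.0,
    network_r=0.3, seed=11)
cohort = simulate_cohort(config, n_sessions=1)

scan = preprocess_dataset(cohort.datasets[(0, 0)], fwhm_mm=0.0)
result = detect_qpp(scan, W=8, n_init=5, rng=21)

recovery = best_lag_correlation(result.template.values, cohort.template)
onsets = cohort.ground_truth[(0, 0)].onsets[0]
hits = np.mean([np.abs(result.stc.peak_frames - o).min() <= 4 for o in onsets])
strength = qpp_strength(result.stc, result.stc.values.max())

print(f"QPP found: {result.found} after {result.diagnostics['n_converged']} "
      f"converged starts")
print(f"occurrences: {result.occurrences} (planted events: {len(onsets)})")
print(f"template recovery correlation (best circular lag): {recovery:.3f}")
print(f"planted-onset hit rate (+-W/2 frames): {hits:.2f}")
print(f"normalized QPP strength of this scan: {strength:.3f}")
# Recovery > 0.9 means the converged template is essentially the planted
# propagating motif; the hit rate shows the STC peaks land on true events.
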