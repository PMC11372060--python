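"""First-peak metrics for a damped, phase-advanced, low-amplitude mutant.

The mutant oscillates with the same 26 h period as the reference but decays
at 0.02/h, peaks 7 h earlier and reaches one third of the reference's
first-peak height.  The script measures what the pipeline's peak detectors
recover: phase shift (hours, negative = earlier) with its error boundary
(sum of the replicate SDs), relative amplitude (height ratio) with its error
boundary (sum of relative SDs), and the first-cycle period (twice the first
trough-to-peak distance).
"""

import dataclasses

from cyanorhythm import (
    ExperimentSpec,
    PeakParams,
    damped_preset,
    first_peak_features,
    first_period_stats,
    phase_shift,
    preprocess_series,
    reference_preset,
    relative_amplitude,
    simulate_experiment,
    summarize_strain,
)

ref = dataclasses.replace(reference_preset(noise_sd=8.0), transient_amplitude=0.0)
mut = damped_preset(noise_sd=8.0, reference=ref)
plate = simulate_experiment(
    ExperimentSpec(strains={"WT": ref, "damped": mut}, replicates=5, seed=1)
)

by = {}
for tr in preprocess_series(plate):
    by.setdefault(tr.strain, []).append(tr)

first_peaks = PeakParams(min_distance=150, min_height=None, min_width=65.0)
summaries = {}
for strain, traces in by.items():
    feats = [first_peak_features(tr.smoothed, plate.times, first_peaks) for tr in traces]
    summaries[strain] = summarize_strain(strain, *zip(*feats))

shift, shift_err = phase_shift(summaries["damped"], summaries["WT"])
ratio, ratio_err = relative_amplitude(summaries["damped"], summaries["WT"])
print(f"phase shift:        {shift:+.2f} +- {shift_err:.2f} h   (generated: -7.00 h)")
print(f"relative amplitude: {ratio:.3f} +- {ratio_err:.3f}    (generated: 0.333)")

period_peaks = PeakParams(min_distance=150, min_height=10.0)
stats = first_period_stats(
    "damped", [tr.smoothed for tr in by["damped"]], plate.times, period_peaks
)
print(
    f"first-cycle period: {stats.mean:.2f} h (median {stats.median:.2f}, "
    f"SD {stats.sd:.2f}, n={len(stats.periods)}; generated: 26.00 h)"
)
print(
    "note: the mutant's true first trough falls inside the detrending edge"
    " region, which biases this estimate low — see docs/methods.md"
)
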