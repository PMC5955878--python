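"""Seizure-aligned participation against a circular-shuffle null.

Activity deviations from each ROI's mean are averaged per seizure in 30
half-second bins spanning -10..+5 s around onset. The null shifts all
seizure times by a common random offset 2000 times (lengths and trace
untouched); each bin is tested with a KS test at p < 0.05/30, and an ROI
"participates" when two neighboring bins are significant.
"""

import numpy as np

import ictalpy as ip

config = ip.SimulationConfig(duration_s=1800.0, seizure_rate_per_min=2.0,
                             n_neurons=40, n_neuropil=0, seed=3)
session = ip.simulate_session(config)
dff = ip.flag_quiet(ip.denoise_dff(ip.compute_dff(
    session.raw, session.frame_rate_hz, frame_times=session.frame_times)))
seizures = ip.filter_seizures(session.truth.true_seizures,
                              recording_duration_s=1800.0)

profile = ip.participation_profile(dff, seizures, "onset",
                                   n_shuffles=1000, seed=0)
print(f"{len(seizures)} seizures; per-bin threshold "
      f"p < {profile.alpha:.4f} (0.05/30)")
truth = np.asarray(session.truth.true_class_per_roi)
for c in ("ictal_low", "neutral"):
    sel = truth == c
    frac = profile.participant[: truth.size][sel].mean()
    print(f"planted {c:<10}: {100 * frac:5.1f}% participants")

r = int(np.flatnonzero(profile.participant[: truth.size]
                       & (truth == "ictal_low"))[0])
sig = np.flatnonzero(profile.significant[r])
print(f"example ictal-low neuron {r}: significant bins at "
      f"{np.round(profile.bin_centers_s[sig], 2).tolist()} s around onset")
print(f"  mean deviation in those bins: "
      f"{profile.mean_dev[r][sig].mean():.2f}% dF/F")
# Suppressed neurons show contiguous below-mean bins locked to seizure
# onset; unmodulated neurons almost never cross the Bonferroni threshold.
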