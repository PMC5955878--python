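"""Simulate a session with planted ground truth and look at what it holds.

A session bundles everything one recording provides: ROI fluorescence at
10 Hz, EEG at 2 kHz with spike-wave bursts, per-frame treadmill velocity,
and — because it is synthetic — the planted truth (seizure times, per-neuron
ictal classes, event trains).
"""

import numpy as np

import ictalpy as ip

config = ip.SimulationConfig(duration_s=600.0, n_neurons=40, n_neuropil=4,
                             seizure_rate_per_min=0.7, seed=1)
session = ip.simulate_session(config)
truth = session.truth

print(f"ROIs: {session.raw.shape[0]} "
      f"({config.n_neurons} neurons + {config.n_neuropil} neuropil patches)")
print(f"frames: {session.raw.shape[1]} at {session.frame_rate_hz:.0f} Hz")
print(f"EEG samples: {session.eeg.samples.size} at "
      f"{session.eeg.rate_hz:.0f} Hz")
print(f"planted seizures: {len(truth.true_seizures)}")
for s in truth.true_seizures[:3]:
    print(f"  onset {s.onset_s:7.2f} s  offset {s.offset_s:7.2f} s  "
          f"{s.spike_times_s.size} spikes at {s.mean_spike_freq_hz:.1f} Hz")
labels, counts = np.unique(np.asarray(truth.true_class_per_roi),
                           return_counts=True)
print("planted classes:", dict(zip(labels.tolist(), counts.tolist())))
# Each neuron's planted class controls how its event rate changes during
# seizures (e.g. ictal_low neurons fire at 20% of their interictal rate).
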