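"""State-resolved pairwise synchrony with two rate-confound corrections.

Lower firing mechanically lowers Pearson correlations, so an ictal
synchrony drop could be an artifact of the ictal activity drop. Correction
one subtracts a circular-shuffle null mean per pair and state; correction
two deletes calcium events from the more active state until the two state
means match, then compares plain correlations.
"""

import numpy as np

import ictalpy as ip
from ictalpy.extraction import DffMatrix

# common input present only between seizures: true synchrony IS lower
# ictally, on top of a 5x rate drop
config = ip.SimulationConfig(
    duration_s=1200.0, n_neurons=30, n_neuropil=0, seed=16,
    shared_signal_fraction=0.4, shared_signal_state="interictal_only",
    class_fractions={"ictal_low": 1.0, "ictal_high": 0.0,
                     "neutral": 0.0, "quiet": 0.0})
session = ip.simulate_session(config)
dff = ip.flag_quiet(ip.denoise_dff(ip.compute_dff(
    session.raw, session.frame_rate_hz, frame_times=session.frame_times)))
mask = ip.build_ictal_mask(session.truth.true_seizures, session.frame_times)

res = ip.state_correlations(dff, mask, bin_s=0.2, min_bins=30)
res = ip.shuffle_correct(res, n_shuffles=1000, seed=4)
iu, ju = np.triu_indices(30, k=1)
print(f"planted interictal pair correlation: "
      f"{session.truth.pairwise_target_corr:.2f}")
for state in ("interictal", "ictal"):
    print(f"{state:<11} raw {np.nanmean(res.raw[state][iu, ju]):+.3f}   "
          f"corrected {np.nanmean(res.corrected[state][iu, ju]):+.3f}")

matched, log = ip.rate_match_by_event_removal(dff, mask, seed=5)
dm = DffMatrix(matched, dff.frame_rate_hz, frame_times=dff.frame_times)
dm.quiet = np.zeros(30, dtype=bool)
res2 = ip.state_correlations(dm, mask, min_bins=30)
print(f"after event-removal rate matching "
      f"(median {int(log.n_removed.median())} events removed/cell):")
for state in ("interictal", "ictal"):
    print(f"  {state:<11} r = {np.nanmean(res2.raw[state][iu, ju]):+.3f}")
# Both corrections agree on the direction: shuffle subtraction recovers the
# planted interictal correlation with ictal pairs at ~0, and even after the
# aggressive event removal (which strips much of the shared signal itself)
# the interictal coefficients remain above the ictal ones.
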