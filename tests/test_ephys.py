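"""Action-potential detection criteria and AP/EEG-spike timing statistics."""

import numpy as np
import pytest

import ictalpy as ip

FS = 10000.0


def _waveform(rise_mv, peak_ms_hold, repol_mv, n=4000, t0=2000, baseline=0.0):
    """Hand-built spike: linear rise over 0.2 ms, plateau, step to repol."""
    v = np.full(n, baseline)
    rise_n = 2
    for k in range(1, rise_n + 1):
        v[t0 + k] = baseline + rise_mv * k / rise_n
    hold_n = int(peak_ms_hold * 10)
    v[t0 + rise_n: t0 + rise_n + hold_n] = baseline + rise_mv
    v[t0 + rise_n + hold_n: t0 + 60] = baseline + repol_mv
    return v


def test_flat_trace_has_no_aps():
    assert ip.detect_aps(np.zeros(5000), FS, "whole_cell").times_s.size == 0
    assert ip.detect_aps(np.zeros(5000), FS, "cell_attached").times_s.size == 0


def test_whole_cell_criteria_hand_evaluated():
    """A 40+ mV rise with plateau and repolarization passes i-iii once."""
    v = _waveform(rise_mv=100.0, peak_ms_hold=0.4, repol_mv=-10.0)
    aps = ip.detect_aps(v, FS, "whole_cell")
    assert aps.times_s.size == 1
    assert aps.times_s[0] == pytest.approx(0.2, abs=5e-4)


def test_whole_cell_threshold_is_38mv():
    """Rising only 30 mV within 0.25 ms fails criterion i (x = 38 mV)."""
    v = _waveform(rise_mv=30.0, peak_ms_hold=0.4, repol_mv=-5.0)
    assert ip.detect_aps(v, FS, "whole_cell").times_s.size == 0
    # 39 mV with proper shape clears it
    v = _waveform(rise_mv=39.0 / (2.0 / 3.0) * (2.0 / 3.0) + 20.0,
                  peak_ms_hold=0.4, repol_mv=-10.0)
    assert ip.detect_aps(v, FS, "whole_cell").times_s.size == 1


def test_missing_repolarization_fails_criterion_iii():
    """A step that stays depolarized violates the post-window criterion."""
    v = np.zeros(4000)
    v[2001] = 50.0
    v[2002:] = 100.0  # never repolarizes below pre-mean + beta*x = 30.4
    assert ip.detect_aps(v, FS, "whole_cell").times_s.size == 0


def test_criterion_ii_literal_inequality():
    """ii: mean(pre) < mean(peak) - alpha*x, exactly as printed.

    Build a waveform passing i and iii but whose peak-window mean sits less
    than alpha*x above the pre-window mean: must be rejected.
    """
    p = ip.APDetectionParams.defaults("whole_cell")
    v = np.zeros(4000)
    t0 = 2000
    v[t0 + 2] = 50.0      # satisfies i at t0 (rise 50 > 38 within 0.25 ms)
    # peak window [t0+0.25, t0+0.35] ms ~ samples t0+2..t0+4: keep its mean
    # just below alpha*x = 19 above the zero pre-mean
    v[t0 + 2: t0 + 5] = 18.0
    v[t0 + 2] = 50.0
    # restore i: v[t0+2] - v[t0] = 50 > 38; peak mean = (50+18+18)/3 = 28.7
    # which exceeds 19 -> make the plateau lower
    v[t0 + 3: t0 + 5] = 0.0   # peak mean = 50/3 = 16.7 < 19 -> ii fails
    v[t0 + 25: t0 + 30] = -5.0
    assert ip.detect_aps(v, FS, "whole_cell").times_s.size == 0


def test_cell_attached_threshold_is_1p9mv():
    """A 1.0 mV deflection never crosses x = 1.9 mV; 5 mV does."""
    cfg = ip.SimulationConfig(duration_s=10.0, seed=2)
    v, truth = ip.simulate_voltage(cfg, "cell_attached", ap_rate_hz=3.0,
                                   amplitude_mv=1.0)
    assert truth.true_ap_times.size > 0
    assert ip.detect_aps(v, FS, "cell_attached").times_s.size == 0
    v, truth = ip.simulate_voltage(cfg, "cell_attached", ap_rate_hz=3.0)
    assert ip.detect_aps(v, FS, "cell_attached").times_s.size \
        == truth.true_ap_times.size


@pytest.mark.parametrize("mode", ["whole_cell", "cell_attached"])
def test_noiseless_templates_detected_exactly(mode):
    cfg = ip.SimulationConfig(duration_s=30.0, seed=4)
    v, truth = ip.simulate_voltage(cfg, mode, ap_rate_hz=5.0)
    aps = ip.detect_aps(v, FS, mode)
    assert aps.times_s.size == truth.true_ap_times.size
    err = np.abs(aps.times_s[:, None]
                 - truth.true_ap_times[None, :]).min(axis=1)
    assert err.max() <= 0.5e-3


def test_f1_at_twice_threshold_snr():
    """Deflection 2x the threshold with noise: F1 >= 0.95 in both modes."""
    cfg = ip.SimulationConfig(duration_s=60.0, seed=4)
    for mode, amp, sigma in (("cell_attached", 3.8, 0.2),
                             ("whole_cell", 76.0, 4.0)):
        v, truth = ip.simulate_voltage(cfg, mode, ap_rate_hz=5.0,
                                       noise_sigma_mv=sigma, amplitude_mv=amp)
        aps = ip.detect_aps(v, FS, mode)
        tp = sum(1 for t in aps.times_s
                 if np.min(np.abs(truth.true_ap_times - t)) < 1e-3)
        precision = tp / max(1, aps.times_s.size)
        recall = tp / truth.true_ap_times.size
        f1 = 2 * precision * recall / max(precision + recall, 1e-12)
        assert f1 >= 0.95


def test_flags_within_1ms_collapse_to_one_ap():
    v = _waveform(rise_mv=100.0, peak_ms_hold=0.4, repol_mv=-10.0)
    aps = ip.detect_aps(v, FS, "whole_cell")
    assert aps.times_s.size == 1  # the rise flags several samples


def test_short_trace_rejected():
    with pytest.raises(ValueError, match="shorter"):
        ip.detect_aps(np.zeros(10), FS, "whole_cell")


def test_state_firing_rates_directions():
    szs = [ip.SeizureInterval(t, t + 8.0) for t in np.arange(20.0, 580.0, 40.0)]
    rng = np.random.default_rng(5)
    # uniform train: no difference
    uniform = ip.APTrain(np.sort(rng.uniform(0.0, 600.0, 3000)))
    res = ip.state_firing_rates(uniform, szs, 600.0)
    assert res["label"] == "neutral"
    # 70% ictal drop
    t = np.sort(rng.uniform(0.0, 600.0, 3000))
    keep = np.ones(t.size, bool)
    for s in szs:
        inside = (t >= s.onset_s) & (t <= s.offset_s)
        keep &= ~inside | (rng.random(t.size) < 0.3)
    res = ip.state_firing_rates(ip.APTrain(t[keep]), szs, 600.0)
    assert res["label"] == "ictal_low"
    assert res["p_value"] < 0.05
    # empty train
    res = ip.state_firing_rates(ip.APTrain(np.empty(0)), szs, 600.0)
    assert res["label"] == "neutral"
    assert res["mean_ictal_hz"] == 0.0


def test_peri_spike_histogram_geometry():
    spikes = np.arange(10.0, 500.0, 0.5)
    with pytest.raises(ValueError, match="empty"):
        ip.peri_eeg_spike_histogram(ip.APTrain(np.array([1.0])), np.empty(0))
    empty = ip.peri_eeg_spike_histogram(ip.APTrain(np.empty(0)), spikes)
    assert empty["counts"].sum() == 0
    assert empty["coincidence_fraction"] == 0.0
    # APs planted 10 ms after every spike: one occupied bin, coincidence 1
    locked = ip.peri_eeg_spike_histogram(ip.APTrain(spikes + 0.010), spikes)
    occupied = np.flatnonzero(locked["counts"] > 0)
    assert occupied.size == 1
    assert locked["edges_ms"][occupied[0]] == pytest.approx(0.0)
    assert locked["coincidence_fraction"] == 1.0
    # histogram total equals APs within +/-100 ms of some spike
    assert locked["counts"].sum() == spikes.size


def test_uniform_train_coincidence_matches_poisson():
    """Independent APs at rate lambda: P(spike has AP within +/-20 ms)
    = 1 - exp(-0.04 lambda)."""
    rng = np.random.default_rng(6)
    lam = 2.0
    spikes = np.sort(rng.uniform(100.0, 1700.0, 500))
    aps = ip.APTrain(np.sort(rng.uniform(0.0, 1800.0, int(lam * 1800))))
    h = ip.peri_eeg_spike_histogram(aps, spikes)
    p = 1.0 - np.exp(-lam * 0.04)
    se = np.sqrt(p * (1 - p) / spikes.size)
    assert abs(h["coincidence_fraction"] - p) <= 3 * se
    assert np.isfinite(h["normality_p"])
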