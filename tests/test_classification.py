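"""Ictal classification, participation nulls, sliding-window stability."""

import numpy as np
import pytest

import ictalpy as ip
from ictalpy.classify import PROFILE_BINS
from ictalpy.extraction import DffMatrix


def _mask_from_bools(ictal):
    ictal = np.asarray(ictal, dtype=bool)
    ft = (np.arange(ictal.size) + 0.5) / 10.0
    return ip.IctalMask(ft, ictal, np.zeros(ictal.size, dtype=bool))


def _dm(dff, quiet=None):
    d = DffMatrix(np.atleast_2d(np.asarray(dff, float)), 10.0)
    d.noise_sigma = np.ones(d.n_rois)
    d.quiet = (np.zeros(d.n_rois, dtype=bool) if quiet is None
               else np.asarray(quiet, dtype=bool))
    return d


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_identically_distributed_states_are_neutral(seed):
    rng = np.random.default_rng(seed)
    dff = rng.exponential(2.0, (5, 4000))
    ictal = rng.random(4000) < 0.2
    # session-scale Bonferroni family, as used on real fields of view
    cls = ip.classify_roi(_dm(dff), _mask_from_bools(ictal), family_size=100)
    assert (cls["label"] == "neutral").all()


def test_classification_recovers_planted_classes(study_classes):
    """Depth -0.8 / +1.5 neurons come back ictal_low / ictal_high."""
    truth = study_classes["truth_classes"]
    lab = study_classes["classifications"]["label"].to_numpy()[: truth.size]
    low, high = truth == "ictal_low", truth == "ictal_high"
    assert lab[low].tolist().count("ictal_low") / low.sum() >= 0.9
    assert lab[high].tolist().count("ictal_high") / high.sum() >= 0.9
    # quiet ROIs carry the quiet label, no statistics
    assert set(lab[truth == "quiet"]) == {"quiet"}


def test_classify_requires_both_states():
    dff = _dm(np.random.default_rng(0).random((2, 1000)))
    with pytest.raises(ValueError, match="no ictal data"):
        ip.classify_roi(dff, _mask_from_bools(np.zeros(1000)))
    with pytest.raises(ValueError, match="no interictal data"):
        ip.classify_roi(dff, _mask_from_bools(np.ones(1000)))


def test_bonferroni_family_scales_alpha():
    rng = np.random.default_rng(3)
    dff = _dm(rng.exponential(1.0, (4, 2000)))
    mask = _mask_from_bools(rng.random(2000) < 0.2)
    a = ip.classify_roi(dff, mask)
    b = ip.classify_roi(dff, mask, family_size=100)
    assert a["corrected_alpha"].iloc[0] == pytest.approx(0.05 / 4)
    assert b["corrected_alpha"].iloc[0] == pytest.approx(0.05 / 100)


def test_profile_window_geometry(small_session):
    """30 bins of 0.5 s; onset window -10..+5 s, offset window -5..+10 s."""
    dff, szs = small_session["dff"], small_session["seizures"]
    on = ip.participation_profile(dff, szs, "onset", n_shuffles=20, seed=0)
    off = ip.participation_profile(dff, szs, "offset", n_shuffles=20, seed=0)
    for prof, lo, hi in ((on, -10.0, 5.0), (off, -5.0, 10.0)):
        assert prof.mean_dev.shape[1] == PROFILE_BINS == 30
        assert prof.bin_centers_s[0] == pytest.approx(lo + 0.25)
        assert prof.bin_centers_s[-1] == pytest.approx(hi - 0.25)
        assert np.allclose(np.diff(prof.bin_centers_s), 0.5)
    # Bonferroni per-bin threshold: a bin at p = 0.002 is not significant
    assert on.alpha == pytest.approx(0.05 / 30)
    assert on.alpha < 0.002
    assert np.array_equal(on.significant, on.p_values < on.alpha)
    # participation needs two adjacent significant bins
    adjacent = np.any(on.significant[:, :-1] & on.significant[:, 1:], axis=1)
    assert np.array_equal(on.participant, adjacent)


def test_participation_null_calibration():
    """Unmodulated ROIs are almost never flagged as participants."""
    cfg = ip.SimulationConfig(
        duration_s=900.0, n_neurons=60, n_neuropil=0, seed=21,
        modulation_depth={"ictal_low": 0.0, "ictal_high": 0.0,
                          "neutral": 0.0, "quiet": 0.0})
    session = ip.simulate_session(cfg)
    dff = ip.flag_quiet(ip.denoise_dff(ip.compute_dff(
        session.raw, 10.0, frame_times=session.frame_times)))
    szs = ip.filter_seizures(session.truth.true_seizures,
                             recording_duration_s=900.0)
    prof = ip.participation_profile(dff, szs, "onset", n_shuffles=300, seed=5)
    assert prof.participant.mean() <= 0.02
    # per-bin false-positive rate stays at/below the Bonferroni level
    assert prof.significant.mean() <= 0.0017 * 3


def test_suppressed_neurons_participate_with_onset_locked_bins(rich_session):
    """Planted pre-onset suppression shows up as adjacent significant bins
    starting around seizure onset."""
    dff, szs = rich_session["dff"], rich_session["seizures"]
    truth = rich_session["truth_classes"]
    prof = ip.participation_profile(dff, szs, "onset", n_shuffles=1000,
                                    seed=11)
    low = np.concatenate([truth == "ictal_low",
                          np.zeros(dff.n_rois - truth.size, bool)])
    neu = np.concatenate([truth == "neutral",
                          np.zeros(dff.n_rois - truth.size, bool)])
    assert prof.participant[low].mean() >= 0.6
    assert prof.participant[neu].mean() <= 0.1
    # first adjacent significant pair sits near onset (suppression leads
    # onset by 2 s; detection latency pushes the first pair a little later)
    firsts = []
    for r in np.flatnonzero(prof.participant & low):
        sig = prof.significant[r]
        pair = np.flatnonzero(sig[:-1] & sig[1:])[0]
        firsts.append(prof.bin_centers_s[pair])
    assert np.median(firsts) >= -3.0
    assert np.median(firsts) <= 1.0
    # suppressed bins deviate downward
    r = np.flatnonzero(prof.participant & low)[0]
    sig_after = prof.significant[r] & (prof.bin_centers_s > 0)
    if sig_after.any():
        assert prof.mean_dev[r][sig_after].mean() < 0


def test_profile_requires_seizures_and_length():
    dff = _dm(np.random.default_rng(0).random((1, 600)))  # 60 s only
    with pytest.raises(ValueError, match="2 min"):
        ip.participation_profile(dff, [ip.SeizureInterval(10.0, 13.0)])
    with pytest.raises(ValueError, match="seizures"):
        ip.participation_profile(_dm(np.random.random((1, 2000))), [])


def test_low_seizure_count_warns_low_power():
    dff = _dm(np.random.default_rng(1).random((1, 3000)))
    with pytest.warns(UserWarning, match="low-power"):
        prof = ip.participation_profile(
            dff, [ip.SeizureInterval(100.0, 105.0),
                  ip.SeizureInterval(200.0, 204.0)], n_shuffles=20)
    assert prof.low_power


def test_sliding_windows_empty_without_seizures():
    dff = _dm(np.random.default_rng(0).random((2, 6000)))
    mask = _mask_from_bools(np.zeros(6000))
    table, summary = ip.sliding_window_classes(dff, [], mask)
    assert len(table) == 0
    assert summary["n_windows"].sum() == 0


def test_stationary_neuron_never_flips(study_classes):
    """A stably suppressed neuron is never classified ictal_high."""
    dff, szs = study_classes["dff"], study_classes["seizures"]
    mask = study_classes["mask"]
    labels = study_classes["classifications"]["label"].to_numpy()
    truth = study_classes["truth_classes"]
    table, summary = ip.sliding_window_classes(dff, szs, mask,
                                               overall_labels=labels)
    low = np.flatnonzero(truth == "ictal_low")
    sub = summary[summary.roi_id.isin(low)]
    assert (sub["frac_flipped"].fillna(0) == 0).all()
    assert sub["frac_predicted"].mean() > 0.5
    # consecutive windows advance by roughly one seizure
    assert table.groupby("window")["n_seizures"].first().min() >= 2


def test_window_classes_track_planted_drift():
    """A mid-recording class flip appears as a clean window-label switch."""
    cfg = ip.SimulationConfig(
        duration_s=1800.0, seizure_rate_per_min=1.5, n_neurons=20,
        n_neuropil=0, seed=12, drift_enabled=True, drift_epoch_s=900.0,
        drift_flip_prob=1.0,
        class_fractions={"ictal_low": 0.5, "ictal_high": 0.2,
                         "neutral": 0.2, "quiet": 0.1})
    session = ip.simulate_session(cfg)
    dff = ip.flag_quiet(ip.denoise_dff(ip.compute_dff(
        session.raw, 10.0, frame_times=session.frame_times)))
    szs = ip.filter_seizures(session.truth.true_seizures,
                             recording_duration_s=1800.0)
    mask = ip.build_ictal_mask(szs, session.frame_times)
    table, _ = ip.sliding_window_classes(dff, szs, mask)
    sched = session.truth.true_class_per_roi
    flipped = np.flatnonzero((sched[0] == "ictal_low")
                             & (sched[1] == "ictal_high"))
    assert flipped.size > 0
    checked = 0
    for r in flipped:
        sub = table[table.roi_id == r]
        before = sub[sub.end_s < 900.0 - 1e-9]
        after = sub[sub.start_s > 900.0 + 1e-9]
        if len(before) < 3 or len(after) < 3:
            continue
        checked += 1
        assert (before.label != "ictal_high").all()
        assert (after.label != "ictal_low").all()
        assert (before.label == "ictal_low").mean() > 0.5
        assert (after.label == "ictal_high").mean() > 0.5
    assert checked > 0
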