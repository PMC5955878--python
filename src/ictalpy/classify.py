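"""Per-ROI ictal classification and seizure-aligned participation testing.

Three complementary views of how each ROI couples to seizures:

* ``classify_roi`` — the overall label. Per-frame dF/F in the ictal state is
  compared against the interictal state with a two-sample Wilcoxon rank-sum
  (Mann-Whitney) test, Bonferroni-corrected across the session's non-quiet
  ROIs; the sign of the state-mean difference gives ictal-low vs ictal-high.
* ``participation_profile`` — the temporal fine structure around seizure
  onset/offset. Activity deviations from the ROI's mean are averaged in 30
  half-second bins per seizure (onset window -10..+5 s, offset window
  -5..+10 s) and compared, bin by bin, against a null built by circularly
  shuffling the seizure times (one uniform offset per shuffle, all seizures
  displaced jointly, durations preserved, trace untouched) with a
  Kolmogorov-Smirnov test at p < 0.05/30. An ROI "participates" when at
  least two neighboring bins reach significance.
* ``sliding_window_classes`` — class stability over time. The rank-sum
  classification is repeated inside 7-min windows advanced one seizure at a
  time, with state samples binned at 2 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import DffMatrix
from .seizures import IctalMask, SeizureInterval

PROFILE_BINS = 30
PROFILE_BIN_S = 0.5
ONSET_WINDOW_S = (-10.0, 5.0)
OFFSET_WINDOW_S = (-5.0, 10.0)


def _dff_array(dff) -> tuple[np.ndarray, float, np.ndarray]:
    if isinstance(dff, DffMatrix):
        return dff.dff, dff.frame_rate_hz, dff.frame_times
    raise TypeError("expected a DffMatrix")


def _ranksum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value with tie correction; 1.0 if degenerate."""
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue)


def classify_roi(dff: DffMatrix, mask: IctalMask,
                 family_size: int | None = None, alpha: float = 0.05,
                 bin_s: float = 2.0) -> pd.DataFrame:
    """Label each ROI ictal_low / ictal_high / neutral / quiet.

    All (non-excluded) ictal activity is compared with all interictal
    activity per ROI using the Wilcoxon rank-sum test at
    ``alpha / family_size``, where the family defaults to the session's
    non-quiet ROIs. The sample unit is a ``bin_s`` mean of each state's
    concatenated frames (2 s by default, as in the windowed analysis):
    individual frames are autocorrelated over the indicator's decay time,
    and testing them directly overstates the evidence several-fold.
    Direction is the sign of the ictal-minus-interictal mean difference.
    """
    X, fr, _ = _dff_array(dff)
    if mask.n_frames != dff.n_frames:
        raise ValueError("mask length does not match dff frames")
    ict_idx = np.flatnonzero(mask.ictal_clean)
    int_idx = np.flatnonzero(mask.interictal)
    if ict_idx.size == 0:
        raise ValueError("no ictal data: cannot classify")
    if int_idx.size == 0:
        raise ValueError("no interictal data: cannot classify")
    bin_frames = max(1, int(round(bin_s * fr)))
    active = dff.active()
    if family_size is None:
        family_size = max(1, int(active.sum()))
    corrected_alpha = alpha / family_size

    rows = []
    for r in range(dff.n_rois):
        if not active[r]:
            rows.append({"roi_id": r, "label": "quiet", "p_value": np.nan,
                         "ictal_mean": np.nan, "interictal_mean": np.nan})
            continue
        x = np.nan_to_num(X[r], nan=0.0)
        xi = _binned_means(x, ict_idx, bin_frames)
        xn = _binned_means(x, int_idx, bin_frames)
        if xi.size == 0 or xn.size == 0:
            raise ValueError(f"state shorter than one {bin_s}-s bin")
        p = _ranksum(xi, xn)
        mi, mn = float(xi.mean()), float(xn.mean())
        if p < corrected_alpha:
            label = "ictal_low" if mi < mn else "ictal_high"
        else:
            label = "neutral"
        rows.append({"roi_id": r, "label": label, "p_value": p,
                     "ictal_mean": mi, "interictal_mean": mn})
    out = pd.DataFrame(rows)
    out["corrected_alpha"] = corrected_alpha
    return out


# ---------------------------------------------------------------------------
# participation profiles

@dataclass
class ParticipationProfile:
    """Seizure-aligned 30-bin activity profile against a circular null."""

    alignment: str
    bin_centers_s: np.ndarray          # (30,) relative to the alignment point
    mean_dev: np.ndarray               # (n_rois, 30) mean Delta(dF/F), percent
    p_values: np.ndarray               # (n_rois, 30)
    significant: np.ndarray            # (n_rois, 30) bool at alpha
    participant: np.ndarray            # (n_rois,) >=2 adjacent significant bins
    alpha: float
    n_shuffles: int
    low_power: bool = False


def participation_profile(dff: DffMatrix, seizures: list[SeizureInterval],
                          alignment: str = "onset", n_shuffles: int = 2000,
                          alpha: float = 0.05 / PROFILE_BINS,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> ParticipationProfile:
    """Seizure-aligned Delta(dF/F) profile with a circular-shuffle null.

    For each ROI and each of the 30 half-second bins the observed sample is
    the per-seizure bin mean of the deviation from the ROI's overall mean
    dF/F. The null pools the same statistic over ``n_shuffles`` circular
    displacements of all seizure times by a common uniform offset (the trace
    and the seizure durations are untouched; time is treated circularly, and
    offsets are quantized to whole frames). Each bin's observed sample is
    compared to its pooled null with a two-sample KS test; an ROI is a
    participant when at least two neighboring bins are significant at
    ``alpha`` (default 0.05/30).
    """
    if alignment not in ("onset", "offset"):
        raise ValueError("alignment must be 'onset' or 'offset'")
    if not seizures:
        raise ValueError("no seizures given")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)

    X, fr, ft = _dff_array(dff)
    T = dff.n_frames
    if T / fr < 120.0:
        raise ValueError("recording must be at least 2 min long")
    low_power = len(seizures) < 3
    if low_power:
        warnings.warn("fewer than 3 seizures: participation profile is low-power")
    dt = 1.0 / fr
    if not np.allclose(np.diff(ft), dt, rtol=1e-6):
        raise ValueError("participation_profile requires uniform frame times")

    X = np.nan_to_num(X, nan=0.0)
    dev = X - X.mean(axis=1, keepdims=True)
    # cumulative sum over the circularly doubled trace: windows may wrap
    C2 = np.concatenate([np.zeros((dev.shape[0], 1)),
                         np.cumsum(np.concatenate([dev, dev], axis=1), axis=1)],
                        axis=1)

    win_lo = ONSET_WINDOW_S[0] if alignment == "onset" else OFFSET_WINDOW_S[0]
    anchors = np.array([s.onset_s if alignment == "onset" else s.offset_s
                        for s in seizures])
    S = anchors.size
    L = max(1, int(round(PROFILE_BIN_S * fr)))
    offsets = win_lo + PROFILE_BIN_S * np.arange(PROFILE_BINS)
    bin_centers = offsets + PROFILE_BIN_S / 2.0

    # base start index of each (seizure, bin) window on the frame grid
    starts = np.ceil((anchors[:, None] + offsets[None, :] - ft[0]) / dt - 1e-9)
    starts = starts.astype(int) % T                       # (S, 30)

    n_rois = dev.shape[0]

    def bin_means(offs: np.ndarray) -> np.ndarray:
        """(R, len(offs), S, 30) per-seizure bin means at the given offsets."""
        idx = (starts[None, :, :] + offs[:, None, None]) % T     # (j, S, 30)
        return (np.take(C2, idx + L, axis=1) - np.take(C2, idx, axis=1)) / L

    obs = bin_means(np.zeros(1, dtype=int))[:, 0]                # (R, S, 30)
    # the null is held in float32; round the observed sample identically so
    # the point mass at "empty bin" stays one exact tie across both samples
    obs32 = obs.astype(np.float32)
    d = rng.integers(1, T, size=n_shuffles)                      # frame-quantized
    null = np.empty((n_rois, PROFILE_BINS, n_shuffles, S), dtype=np.float32)
    chunk = max(1, min(n_shuffles, 200))
    for j0 in range(0, n_shuffles, chunk):
        v = bin_means(d[j0:j0 + chunk])                          # (R, j, S, 30)
        null[:, :, j0:j0 + v.shape[1], :] = v.transpose(0, 3, 1, 2)

    pvals = np.empty((n_rois, PROFILE_BINS))
    for r in range(n_rois):
        for b in range(PROFILE_BINS):
            pvals[r, b] = stats.ks_2samp(obs32[r, :, b], null[r, b].ravel(),
                                         method="asymp").pvalue
    sig = pvals < alpha
    participant = np.any(sig[:, :-1] & sig[:, 1:], axis=1)
    return ParticipationProfile(
        alignment=alignment, bin_centers_s=bin_centers,
        mean_dev=obs.mean(axis=1), p_values=pvals, significant=sig,
        participant=participant, alpha=alpha, n_shuffles=n_shuffles,
        low_power=low_power)


def profile_to_frame(profile: ParticipationProfile) -> pd.DataFrame:
    """Long-format table: one row per (ROI, bin)."""
    n_rois, nb = profile.mean_dev.shape
    r, b = np.divmod(np.arange(n_rois * nb), nb)
    return pd.DataFrame({
        "roi_id": r, "alignment": profile.alignment,
        "bin_center_s": profile.bin_centers_s[b],
        "mean_dev": profile.mean_dev.ravel(),
        "p_value": profile.p_values.ravel(),
        "significant": profile.significant.ravel(),
        "participant": profile.participant[r],
    })


# ---------------------------------------------------------------------------
# sliding-window classification

def _binned_means(x: np.ndarray, idx: np.ndarray, bin_frames: int) -> np.ndarray:
    """Means of consecutive ``bin_frames``-sized chunks of x[idx]."""
    sel = x[idx]
    nb = sel.size // bin_frames
    if nb == 0:
        return np.empty(0)
    return sel[: nb * bin_frames].reshape(nb, bin_frames).mean(axis=1)


def sliding_window_classes(dff: DffMatrix, seizures: list[SeizureInterval],
                           mask: IctalMask, window_min: float = 7.0,
                           bin_s: float = 2.0, alpha: float = 0.05,
                           overall_labels: np.ndarray | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-classify every ROI inside 7-min windows advanced seizure by seizure.

    The first window starts at the recording start; each subsequent window
    starts just after the previous window's earliest seizure ends, so
    successive windows drop their earliest seizure and pick up the next.
    Within a window, ictal and interictal frames are concatenated, binned at
    ``bin_s``, and compared with the rank-sum test at ``alpha`` (per window).
    Windows holding fewer than 2 seizures are skipped.

    Returns ``(window_table, roi_summary)``. ``window_table`` is long-format
    (window x ROI); ``roi_summary`` gives, per ROI, the fraction of windows
    spent in its predicted overall class versus the flipped class.
    """
    X, fr, ft = _dff_array(dff)
    if mask.n_frames != dff.n_frames:
        raise ValueError("mask length does not match dff frames")
    duration = dff.n_frames / fr
    win_len = window_min * 60.0
    bin_frames = max(1, int(round(bin_s * fr)))
    szs = sorted(seizures, key=lambda s: s.onset_s)
    onsets = np.array([s.onset_s for s in szs])

    windows = []
    for k in range(len(szs)):
        start = 0.0 if k == 0 else szs[k - 1].offset_s + 1e-9
        end = min(start + win_len, duration)
        members = np.flatnonzero((onsets >= start) & (onsets < end))
        if members.size < 2:
            continue
        windows.append((start, end, members))

    active = dff.active()
    labels = overall_labels
    rows = []
    Xz = np.nan_to_num(X, nan=0.0)
    for w, (start, end, members) in enumerate(windows):
        in_win = (ft >= start) & (ft < end)
        ict_idx = np.flatnonzero(in_win & mask.ictal_clean)
        int_idx = np.flatnonzero(in_win & mask.interictal)
        for r in range(dff.n_rois):
            if not active[r]:
                continue
            xi = _binned_means(Xz[r], ict_idx, bin_frames)
            xn = _binned_means(Xz[r], int_idx, bin_frames)
            if xi.size == 0 or xn.size == 0:
                continue
            p = _ranksum(xi, xn)
            if p < alpha:
                lab = "ictal_low" if xi.mean() < xn.mean() else "ictal_high"
            else:
                lab = "not_significant"
            rows.append({"window": w, "start_s": start, "end_s": end,
                         "n_seizures": members.size, "roi_id": r, "label": lab,
                         "p_value": p})
    table = pd.DataFrame(rows, columns=["window", "start_s", "end_s", "n_seizures",
                                        "roi_id", "label", "p_value"])

    flip = {"ictal_low": "ictal_high", "ictal_high": "ictal_low"}
    summary_rows = []
    for r in range(dff.n_rois):
        sub = table[table.roi_id == r] if len(table) else table
        n = len(sub)
        pred = labels[r] if labels is not None else None
        frac_pred = frac_flip = np.nan
        if n and pred in flip:
            frac_pred = float((sub.label == pred).mean())
            frac_flip = float((sub.label == flip[pred]).mean())
        summary_rows.append({"roi_id": r, "n_windows": n,
                             "predicted_label": pred,
                             "frac_predicted": frac_pred,
                             "frac_flipped": frac_flip})
    return table, pd.DataFrame(summary_rows)
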