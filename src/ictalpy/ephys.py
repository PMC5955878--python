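"""Action-potential detection in patch-clamp traces and AP/EEG-spike timing.

APs are detected with three explicit criteria evaluated at every sample t of
the membrane-voltage trace V (mV):

  i.   V(t + 0.25 ms) > V(t) + x                       (fast depolarization)
  ii.  mean(V[t-pre1, t-pre2]) < mean(V[t+p1, t+p2]) - alpha * x
                                                        (peak above baseline)
  iii. mean(V[t+post1, t+post2]) < mean(V[t-pre1, t-pre2]) + beta * x
                                                        (repolarization)

with one parameter set for whole-cell recordings (x = 38 mV) and one for
cell-attached recordings (x = 1.9 mV). Criterion ii is implemented exactly
as written above. Runs of flagged samples within 1 ms collapse to their
earliest sample. Window bounds in ms are rounded to the nearest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seizures import SeizureInterval


@dataclass
class APDetectionParams:
    """Threshold and window parameters of the three AP criteria."""

    x_mv: float
    pre1_ms: float
    pre2_ms: float
    p1_ms: float
    p2_ms: float
    post1_ms: float
    post2_ms: float
    alpha: float
    beta: float
    mode: str

    def __post_init__(self) -> None:
        if not (self.pre1_ms > self.pre2_ms > 0):
            raise ValueError("require pre1 > pre2 > 0")
        if not (self.p2_ms > self.p1_ms > 0):
            raise ValueError("require p2 > p1 > 0")
        if not (self.post2_ms > self.post1_ms > 0):
            raise ValueError("require post2 > post1 > 0")

    @classmethod
    def defaults(cls, mode: str) -> "APDetectionParams":
        if mode == "whole_cell":
            return cls(38.0, 1.2, 0.3, 0.25, 0.35, 2.5, 2.9, 0.5, 0.8, mode)
        if mode == "cell_attached":
            return cls(1.9, 0.8, 0.25, 0.15, 0.24, 1.8, 2.1, 0.55, 0.45, mode)
        raise ValueError(f"unknown recording mode: {mode!r}")


@dataclass
class APTrain:
    """Sorted AP times (s) from one recording."""

    times_s: np.ndarray
    mode: str = "cell_attached"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise ValueError("AP times must be sorted")


def _win_mean(C: np.ndarray, t: np.ndarray, a: int, b: int) -> np.ndarray:
    """Mean of v over samples t+a .. t+b inclusive (cumsum C, a <= b)."""
    return (C[t + b + 1] - C[t + a]) / (b - a + 1)


def detect_aps(v: np.ndarray, rate_hz: float,
               params: APDetectionParams | str = "cell_attached") -> APTrain:
    """Detect APs satisfying criteria i-iii; collapse flags within 1 ms."""
    if isinstance(params, str):
        params = APDetectionParams.defaults(params)
    v = np.asarray(v, dtype=float)

    def ms(val: float) -> int:
        return int(np.rint(val * rate_hz / 1000.0))

    n025 = max(1, ms(0.25))
    npre1, npre2 = ms(params.pre1_ms), ms(params.pre2_ms)
    np1, np2 = ms(params.p1_ms), ms(params.p2_ms)
    npost1, npost2 = ms(params.post1_ms), ms(params.post2_ms)
    widest = max(n025, np2, npost2)
    if v.size <= npre1 + widest:
        raise ValueError("trace shorter than the widest detection window")

    t = np.arange(npre1, v.size - widest)
    C = np.concatenate([[0.0], np.cumsum(v)])
    c1 = v[t + n025] > v[t] + params.x_mv
    pre = _win_mean(C, t, -npre1, -npre2)
    peak = _win_mean(C, t, np1, np2)
    post = _win_mean(C, t, npost1, npost2)
    c2 = pre < peak - params.alpha * params.x_mv
    c3 = post < pre + params.beta * params.x_mv
    flagged = t[c1 & c2 & c3]

    gap = int(np.rint(rate_hz / 1000.0))  # 1 ms
    times = []
    last = -np.inf
    for s in flagged:
        if s - last > gap:
            times.append(s)
        last = s
    return APTrain(np.asarray(times, dtype=float) / rate_hz, mode=params.mode)


def state_firing_rates(aps: APTrain, seizures: list[SeizureInterval],
                       duration_s: float) -> dict:
    """Per-seizure ictal vs flanking-interictal firing rates, paired test.

    The interictal rate paired with each seizure is measured over the two
    adjacent half-gaps (from the midpoint of the preceding gap to onset and
    from offset to the midpoint of the following gap), so interictal time is
    partitioned without overlap. The paired comparison is the Wilcoxon
    signed-rank test; the direction label follows the mean rate difference.
    """
    szs = sorted(seizures, key=lambda s: s.onset_s)
    if len(szs) < 2:
        raise ValueError("need at least 2 seizures")
    times = aps.times_s
    ict_rates, int_rates = [], []
    for i, s in enumerate(szs):
        prev_end = szs[i - 1].offset_s if i > 0 else 0.0
        next_start = szs[i + 1].onset_s if i + 1 < len(szs) else duration_s
        flank_lo = (prev_end + s.onset_s) / 2.0
        flank_hi = (s.offset_s + next_start) / 2.0
        n_ict = np.count_nonzero((times >= s.onset_s) & (times <= s.offset_s))
        n_int = (np.count_nonzero((times >= flank_lo) & (times < s.onset_s))
                 + np.count_nonzero((times > s.offset_s) & (times <= flank_hi)))
        dur_int = (s.onset_s - flank_lo) + (flank_hi - s.offset_s)
        ict_rates.append(n_ict / max(s.duration_s, 1e-12))
        int_rates.append(n_int / max(dur_int, 1e-12))
    ict_rates = np.asarray(ict_rates)
    int_rates = np.asarray(int_rates)
    diffs = ict_rates - int_rates
    if times.size == 0 or np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(ict_rates, int_rates).pvalue)
    if p < 0.05 and diffs.mean() != 0:
        label = "ictal_low" if diffs.mean() < 0 else "ictal_high"
    else:
        label = "neutral"
    return {"ictal_rates": ict_rates, "interictal_rates": int_rates,
            "p_value": p, "label": label,
            "mean_ictal_hz": float(ict_rates.mean()),
            "mean_interictal_hz": float(int_rates.mean())}


def peri_eeg_spike_histogram(aps: APTrain, eeg_spike_times: np.ndarray,
                             bin_ms: float = 20.0, span_ms: float = 100.0) -> dict:
    """Peri-EEG-spike time histogram of AP times.

    Each AP is referenced to its *nearest* EEG spike (ties to the earlier
    spike); offsets within +/- ``span_ms`` enter a histogram with ``bin_ms``
    bins. Also reports the coincidence fraction — the proportion of EEG
    spikes with at least one AP within +/- 20 ms — and a D'Agostino-Pearson
    normality test on the offsets (NaN when fewer than 20 offsets).
    """
    spikes = np.sort(np.asarray(eeg_spike_times, dtype=float))
    if spikes.size == 0:
        raise ValueError("empty EEG spike list")
    ap = aps.times_s
    edges = np.arange(-span_ms, span_ms + bin_ms / 2, bin_ms) / 1000.0
    if ap.size == 0:
        return {"edges_ms": edges * 1000.0,
                "counts": np.zeros(edges.size - 1, dtype=int),
                "offsets_ms": np.empty(0), "coincidence_fraction": 0.0,
                "normality_p": np.nan}
    pos = np.searchsorted(spikes, ap)
    left = np.clip(pos - 1, 0, spikes.size - 1)
    right = np.clip(pos, 0, spikes.size - 1)
    d_left = ap - spikes[left]
    d_right = spikes[right] - ap
    # nearest spike; ties (equal distance) go to the earlier spike
    use_left = d_left <= d_right
    offsets = np.where(use_left, ap - spikes[left], ap - spikes[right])
    in_span = np.abs(offsets) <= span_ms / 1000.0
    counts, _ = np.histogram(offsets[in_span], bins=edges)

    # coincidence: EEG spikes with >=1 AP within +/- 20 ms
    w = 0.020
    lo = np.searchsorted(ap, spikes - w, side="left")
    hi = np.searchsorted(ap, spikes + w, side="right")
    coincidence = float(np.mean(hi > lo))

    off_ms = offsets[in_span] * 1000.0
    if off_ms.size >= 20 and np.ptp(off_ms) > 0:
        norm_p = float(stats.normaltest(off_ms).pvalue)
    else:
        norm_p = np.nan
    return {"edges_ms": edges * 1000.0, "counts": counts, "offsets_ms": off_ms,
            "coincidence_fraction": coincidence, "normality_p": norm_p}


def ap_train_to_frame(aps: APTrain) -> pd.DataFrame:
    return pd.DataFrame({"time_s": aps.times_s, "mode": aps.mode,
                         "recording_id": aps.recording_id})
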