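"""State-resolved pairwise correlation with activity-rate corrections.

A drop in mean activity mechanically shrinks Pearson correlations, so an
apparent loss of synchrony during seizures could be an artifact of the lower
ictal firing rate. Two independent corrections address this:

* circular-shuffle subtraction (``shuffle_correct``): for each pair and
  state, one ROI's binned series is circularly rotated many times; the mean
  of the resulting null correlation distribution — which carries the full
  rate structure but no temporal alignment — is subtracted from the raw
  coefficient;
* event-removal rate matching (``rate_match_by_event_removal``): calcium
  events are randomly deleted from whichever state is more active until the
  two state means agree to within 0.1 dF/F percentage points, after which
  plain correlations are comparable across states.

Traces are resampled to 200-ms bins (the effective temporal resolution of
the imaging) and each ROI's ictal amplitude is normalized by its mean
interictal amplitude before correlating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import DffMatrix
from .seizures import IctalMask


@dataclass
class CorrelationResult:
    """Raw / corrected pairwise Pearson coefficients per state."""

    states: tuple = ("interictal", "ictal")
    binned: dict = field(default_factory=dict)        # state -> (R, n_bins)
    raw: dict = field(default_factory=dict)           # state -> (R, R)
    corrected: dict = field(default_factory=dict)     # state -> (R, R)
    null_mean: dict = field(default_factory=dict)
    null_sd: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)       # state -> (R, R) bool
    kinds: np.ndarray | None = None                   # 'neuron' / 'neuropil'
    bin_s: float = 0.2
    n_shuffles: int = 0


def _bin_states(dff: DffMatrix, mask: IctalMask, bin_s: float
                ) -> dict[str, np.ndarray]:
    """Resample to bin_s bins and split into per-state concatenated series.

    Frames are grouped into consecutive bins; a bin enters a state only if
    all its frames share that state and none is excluded (boundary and
    locomotion bins are dropped).
    """
    X = np.nan_to_num(dff.dff, nan=0.0)
    L = max(1, int(round(bin_s * dff.frame_rate_hz)))
    nb = dff.n_frames // L
    Xb = X[:, : nb * L].reshape(X.shape[0], nb, L).mean(axis=2)
    ict = mask.ictal_clean[: nb * L].reshape(nb, L)
    inter = mask.interictal[: nb * L].reshape(nb, L)
    return {"interictal": Xb[:, inter.all(axis=1)],
            "ictal": Xb[:, ict.all(axis=1)]}


def state_correlations(dff: DffMatrix, mask: IctalMask, bin_s: float = 0.2,
                       normalize_ictal: bool = True, min_bins: int = 100,
                       kinds: np.ndarray | None = None) -> CorrelationResult:
    """Pearson coefficients per ROI pair, separately for each state.

    The ictal series of each ROI is divided by the ROI's mean interictal
    amplitude (``normalize_ictal``), then all bins of a state are
    concatenated and correlated. Raises if either state has fewer than
    ``min_bins`` bins. Constant series yield NaN coefficients flagged in
    ``skipped``.
    """
    binned = _bin_states(dff, mask, bin_s)
    for state, Xs in binned.items():
        if Xs.shape[1] < min_bins:
            raise ValueError(
                f"insufficient {state} data: {Xs.shape[1]} bins < {min_bins}")
    if normalize_ictal:
        scale = binned["interictal"].mean(axis=1, keepdims=True)
        scale = np.where(scale > 0, scale, 1.0)
        binned = {"interictal": binned["interictal"],
                  "ictal": binned["ictal"] / scale}
    res = CorrelationResult(binned=binned, bin_s=bin_s, kinds=kinds)
    for state, Xs in binned.items():
        sd = Xs.std(axis=1)
        ok = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            Xc = (Xs - Xs.mean(axis=1, keepdims=True))
            C = (Xc @ Xc.T) / Xs.shape[1]
            R = C / np.outer(sd, sd)
        R[~ok, :] = np.nan
        R[:, ~ok] = np.nan
        res.raw[state] = R
        res.skipped[state] = ~np.isfinite(R)
    return res


def shuffle_correct(result: CorrelationResult, n_shuffles: int = 2000,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> CorrelationResult:
    """Subtract circular-shuffle null means from the raw coefficients.

    For each pair and state, one member's series is circularly rotated by a
    uniform nonzero offset ``n_shuffles`` times; the mean and SD of the null
    correlation distribution are stored and ``corrected = raw - null_mean``.
    The full set of rotations is evaluated exactly via FFT cross-correlation
    and the null offsets are sampled from it. Series shorter than 10 bins,
    or constant series, are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    for state in result.states:
        Xs = result.binned[state]
        Rn, nb = Xs.shape
        raw = result.raw[state]
        null_mean = np.full_like(raw, np.nan)
        null_sd = np.full_like(raw, np.nan)
        if nb < 10:
            result.skipped[state][:] = True
            result.corrected[state] = np.full_like(raw, np.nan)
            result.null_mean[state] = null_mean
            result.null_sd[state] = null_sd
            continue
        Xc = Xs - Xs.mean(axis=1, keepdims=True)
        sd = Xs.std(axis=1)
        F = np.fft.rfft(Xc, axis=1)
        for i in range(Rn):
            for j in range(i + 1, Rn):
                if sd[i] == 0 or sd[j] == 0:
                    continue
                # corr(x_i, roll(x_j, k)) for every k, exactly
                cc = np.fft.irfft(F[i] * np.conj(F[j]), n=nb)
                corr_k = cc / (nb * sd[i] * sd[j])
                offs = rng.integers(1, nb, size=n_shuffles)
                sample = corr_k[offs]
                null_mean[i, j] = null_mean[j, i] = sample.mean()
                null_sd[i, j] = null_sd[j, i] = sample.std()
        result.null_mean[state] = null_mean
        result.null_sd[state] = null_sd
        result.corrected[state] = raw - null_mean
        result.skipped[state] = ~np.isfinite(raw - null_mean)
        np.fill_diagonal(result.corrected[state], np.nan)
    result.n_shuffles = n_shuffles
    return result


def pairs_frame(result: CorrelationResult) -> pd.DataFrame:
    """Long-format table of per-pair coefficients (upper triangle)."""
    n = next(iter(result.raw.values())).shape[0]
    iu, ju = np.triu_indices(n, k=1)
    kinds = result.kinds
    if kinds is None:
        kinds = np.array(["neuron"] * n)
    pt = np.where((kinds[iu] == "neuron") & (kinds[ju] == "neuron"),
                  "neuron-neuron",
                  np.where((kinds[iu] == "neuropil") & (kinds[ju] == "neuropil"),
                           "neuropil-neuropil", "mixed"))
    frames = []
    for state in result.states:
        df = pd.DataFrame({
            "roi_i": iu, "roi_j": ju, "state": state, "pair_type": pt,
            "raw": result.raw[state][iu, ju],
        })
        if state in result.corrected:
            df["corrected"] = result.corrected[state][iu, ju]
            df["null_mean"] = result.null_mean[state][iu, ju]
            df["null_sd"] = result.null_sd[state][iu, ju]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# event-removal rate matching

def _event_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive nonzero samples, as (start, stop)."""
    nz = np.flatnonzero(np.asarray(x) != 0)
    if nz.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(nz) > 1)
    starts = np.concatenate([[nz[0]], nz[breaks + 1]])
    stops = np.concatenate([nz[breaks] + 1, [nz[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def rate_match_by_event_removal(dff: DffMatrix, mask: IctalMask,
                                rng: np.random.Generator | None = None,
                                seed: int | None = None,
                                tol_percent: float = 0.1
                                ) -> tuple[np.ndarray, pd.DataFrame]:
    """Equalize ictal and interictal mean dF/F by deleting calcium events.

    Per ROI, events (maximal runs of nonzero denoised dF/F) assigned to the
    initially more active state are deleted in random order — skipping
    deletions that would move the state means further apart — until the two
    means agree to within ``tol_percent`` dF/F percentage points. ROIs where
    the tolerance is unreachable keep their best attempt and are flagged
    ``matched=False``.

    Returns ``(matched_dff, log)`` where ``matched_dff`` is a new percent
    dF/F array and ``log`` records per ROI the donor state, number of
    removals, achieved gap and matched flag.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    X = np.nan_to_num(dff.dff, nan=0.0).copy()
    ict = mask.ictal_clean
    inter = mask.interictal
    n_ict, n_int = int(ict.sum()), int(inter.sum())
    if n_ict == 0 or n_int == 0:
        raise ValueError("both states must contain frames")
    rows = []
    for r in range(X.shape[0]):
        x = X[r]
        mi = x[ict].mean()
        mn = x[inter].mean()
        diff = mn - mi
        donor = "interictal" if diff > 0 else "ictal"
        donor_mask = inter if diff > 0 else ict
        removed = 0
        if abs(diff) >= tol_percent:
            runs = [(a, b) for a, b in _event_runs(x)
                    if donor_mask[a:b].sum() * 2 > (b - a)]
            order = rng.permutation(len(runs))
            for ri in order:
                a, b = runs[ri]
                # exact effect on both state means (runs may straddle states)
                d_int = x[a:b][inter[a:b]].sum() / n_int
                d_ict = x[a:b][ict[a:b]].sum() / n_ict
                new_diff = diff - d_int + d_ict
                if abs(new_diff) >= abs(diff):
                    continue
                x[a:b] = 0.0
                diff = new_diff
                removed += 1
                if abs(diff) < tol_percent:
                    break
        rows.append({"roi_id": r, "donor_state": donor, "n_removed": removed,
                     "achieved_gap": abs(diff),
                     "matched": bool(abs(diff) < tol_percent)})
    return X, pd.DataFrame(rows)
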