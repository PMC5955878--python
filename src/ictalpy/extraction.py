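"""Fluorescence -> noise-cleaned dF/F, quiet-ROI flagging, ROI segmentation.

The extraction chain mirrors standard practice for GCaMP population imaging:

1. high-pass each raw ROI trace at 0.1 Hz — implemented as subtraction of a
   rolling-median low-pass with window 1/cutoff, which removes drift and
   bleaching without the undershoot ringing of a linear filter — re-adding
   the trace mean so fluorescence stays positive;
2. time-varying baseline F(t) = mean of the bottom decile of samples within
   t +/- 20 s (window truncated at the recording edges), then
   dF/F(t) = (F_hp(t) - F(t)) / F(t);
3. noise removal: the per-ROI noise SD sigma is estimated from the negative
   dF/F samples as a zero-mean half-Gaussian (maximum-likelihood
   sigma^2 = mean of squared negatives); every sample below +0.5 sigma is
   set to zero;
4. quiet flagging: ROIs whose summed (fractional) dF/F per minute falls
   below the indicator-specific threshold (6 for GCaMP6M, 22.5 for GCaMP6S)
   carry too little activity to classify and are excluded downstream.

dF/F is stored and serialized in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates, median_filter

QUIET_THRESHOLDS = {"GCaMP6M": 6.0, "GCaMP6S": 22.5}  # sum(fractional dF/F)/min


@dataclass
class DffMatrix:
    """dF/F traces (percent) with per-ROI noise estimates and quiet flags."""

    dff: np.ndarray                 # (n_rois, n_frames), percent
    frame_rate_hz: float
    frame_times: np.ndarray | None = None
    noise_sigma: np.ndarray | None = None   # percent, set by denoise_dff
    quiet: np.ndarray | None = None         # set by flag_quiet
    indicator: str = "GCaMP6M"
    error_flags: np.ndarray = field(default=None)  # degenerate-baseline ROIs

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2-D (ROIs x frames)")
        if self.frame_times is None:
            self.frame_times = (np.arange(self.n_frames) + 0.5) / self.frame_rate_hz
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.error_flags is None:
            self.error_flags = np.zeros(self.n_rois, dtype=bool)

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration_min(self) -> float:
        return self.n_frames / self.frame_rate_hz / 60.0

    def active(self) -> np.ndarray:
        """Boolean selector of usable ROIs (not quiet, not degenerate)."""
        quiet = self.quiet if self.quiet is not None else np.zeros(self.n_rois, bool)
        return ~quiet & ~self.error_flags


def _rolling_bottom_decile(x: np.ndarray, half_window: int,
                           bottom_frac: float = 0.1, min_k: int = 4) -> np.ndarray:
    """Mean of the k smallest samples in t +/- half_window, per time point.

    k = max(min_k, floor(bottom_frac * window_size)); windows truncate at the
    edges. Exact (matches the brute-force definition to float precision).
    ``x`` is (n_rois, n_frames); returns the same shape.
    """
    n_rois, n = x.shape
    w = 2 * half_window + 1
    out = np.empty_like(x)

    def k_of(m: int) -> int:
        return min(m, max(min_k, int(np.floor(bottom_frac * m))))

    if n >= w:
        k = k_of(w)
        for r in range(n_rois):
            views = np.lib.stride_tricks.sliding_window_view(x[r], w)
            part = np.partition(views, k - 1, axis=1)[:, :k]
            out[r, half_window:n - half_window] = part.mean(axis=1)
        edge_centers = list(range(half_window)) + list(range(n - half_window, n))
    else:
        edge_centers = list(range(n))
    for t in edge_centers:
        lo, hi = max(0, t - half_window), min(n, t + half_window + 1)
        m = hi - lo
        k = k_of(m)
        part = np.partition(x[:, lo:hi], k - 1, axis=1)[:, :k]
        out[:, t] = part.mean(axis=1)
    return out


def compute_dff(raw: np.ndarray, frame_rate_hz: float,
                highpass_hz: float = 0.1, window_s: float = 20.0,
                bottom_frac: float = 0.1, min_k: int = 4,
                frame_times: np.ndarray | None = None,
                indicator: str = "GCaMP6M", recenter: bool = True) -> DffMatrix:
    """High-pass filter and baseline-normalize raw fluorescence to dF/F (%).

    ``raw`` is (n_rois, n_frames), positive-valued; the recording must be
    longer than twice the baseline half-window (40 s) for the rolling
    bottom-decile baseline to be meaningful. ROIs whose baseline F(t)
    touches zero anywhere are flagged degenerate (dff set to NaN).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n = raw.shape[1]
    if n / frame_rate_hz <= 2 * window_s:
        raise ValueError(
            f"recording must be longer than {2 * window_s:.0f} s for baselining")

    # drift removal at the given cutoff, implemented as subtraction of a
    # rolling-median low-pass (window = 1/cutoff). A linear Butterworth
    # high-pass undershoots after every calcium transient, and those
    # undershoots corrupt the bottom-decile baseline and the downstream
    # half-Gaussian noise fit; the median tracker removes drift without
    # ringing because sparse positive transients barely move a median.
    win = max(3, int(round(frame_rate_hz / highpass_hz)) | 1)
    lp = median_filter(raw, size=(1, win), mode="nearest")
    f_work = raw - lp + raw.mean(axis=1, keepdims=True)

    half_window = int(round(window_s * frame_rate_hz))
    baseline = _rolling_bottom_decile(f_work, half_window, bottom_frac, min_k)

    bad = (baseline <= 0).any(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} ROI(s) have a degenerate (<=0) baseline")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = 100.0 * (f_work - baseline) / baseline
    if recenter:
        # The bottom-decile baseline sits ~1.75 noise-SD below the noise
        # mean by construction, leaving the noise floor of dF/F centered
        # above zero. Re-zero each trace at its noise mode so that the
        # half-Gaussian noise model downstream (peak at 0) applies.
        dff -= _noise_mode(dff)[:, None]
    dff[bad] = np.nan
    return DffMatrix(dff, frame_rate_hz, frame_times=frame_times,
                     indicator=indicator, error_flags=bad)


def _noise_mode(dff: np.ndarray) -> np.ndarray:
    """Per-ROI noise-mode estimate via iterative sigma clipping.

    Transients are sparse and strictly positive, so the clipped median
    converges to the center of the noise distribution.
    """
    modes = np.zeros(dff.shape[0])
    for r in range(dff.shape[0]):
        x = dff[r][np.isfinite(dff[r])]
        if x.size == 0:
            continue
        m = np.median(x)
        for _ in range(3):
            mad = np.median(np.abs(x - m))
            if mad == 0:
                break
            sel = np.abs(x - m) < 2.5 * 1.4826 * mad
            if not sel.any():
                break
            m = np.median(x[sel])
        modes[r] = m
    return modes


def denoise_dff(dm: DffMatrix, min_negatives: int = 30) -> DffMatrix:
    """Half-Gaussian noise-floor removal.

    The negative dF/F samples of each ROI are treated as the lower half of a
    zero-mean Gaussian noise distribution; its SD is the maximum-likelihood
    half-normal estimate sigma^2 = mean(negatives^2). All samples below
    +0.5 sigma are set to zero. ROIs with fewer than ``min_negatives``
    negative samples fall back to a robust full-trace SD with a warning.
    """
    dff = dm.dff.copy()
    sigma = np.zeros(dm.n_rois)
    fallback = []
    for r in range(dm.n_rois):
        x = dff[r]
        neg = x[x < 0]
        if neg.size >= min_negatives:
            sigma[r] = np.sqrt(np.mean(neg ** 2))
        else:
            fallback.append(r)
            finite = x[np.isfinite(x)]
            if finite.size:
                med = np.median(finite)
                sigma[r] = 1.4826 * np.median(np.abs(finite - med))
        dff[r] = np.where(x < 0.5 * sigma[r], 0.0, x)
    if fallback:
        warnings.warn(
            f"{len(fallback)} ROI(s) had <{min_negatives} negative samples; "
            "noise SD estimated from the full trace instead")
    dff[dm.error_flags] = np.nan
    return replace(dm, dff=dff, noise_sigma=sigma)


def flag_quiet(dm: DffMatrix, indicator: str | None = None) -> DffMatrix:
    """Flag ROIs whose activity rate is too low to classify.

    The activity rate is the per-frame sum of fractional (not percent) dF/F
    divided by the recording duration in minutes, compared against the
    indicator-specific threshold. Degenerate-baseline ROIs are always quiet.
    """
    indicator = indicator or dm.indicator
    if indicator not in QUIET_THRESHOLDS:
        raise ValueError(f"unknown indicator {indicator!r}; "
                         f"expected one of {sorted(QUIET_THRESHOLDS)}")
    thr = QUIET_THRESHOLDS[indicator]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rate = np.nansum(dm.dff / 100.0, axis=1) / dm.duration_min
    quiet = (rate < thr) | dm.error_flags
    return replace(dm, quiet=quiet, indicator=indicator)


def activity_rate(dm: DffMatrix) -> np.ndarray:
    """sum(fractional dF/F)/min per ROI — the quiet-rule statistic."""
    return np.nansum(dm.dff / 100.0, axis=1) / dm.duration_min


# ---------------------------------------------------------------------------
# ROI segmentation from an average image

def segment_rois(mean_image: np.ndarray, seeds: list[tuple],
                 max_radius: float = 20.0, n_angles: int = 48,
                 boundary_drop: float = 0.5, min_contrast: float = 1.5):
    """Segment somata from a mean-intensity image by polar profiling.

    For each seed an intensity profile is computed along ``n_angles`` polar
    rays. Somata appear as bright disks or rings: along each ray the
    boundary is placed at the outer end of the contiguous run, starting at
    the profile maximum, over which intensity stays above background plus
    ``boundary_drop`` times the peak elevation (the half-maximum edge by
    default). Pixels inside the interpolated boundary form the ROI. Seeds
    on background (boundary at the search limit, or contrast below
    ``min_contrast`` times the image median) are flagged unsegmentable.

    Returns a list of dicts with keys ``seed``, ``mask`` (bool image),
    ``area_px``, ``centroid``, ``flagged``.
    """
    img = np.asarray(mean_image, dtype=float)
    bg = np.median(img)
    radii = np.arange(0.0, max_radius + 0.5, 0.5)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    results = []
    for seed in seeds:
        sy, sx = float(seed[0]), float(seed[1])
        if not (0 <= sy < img.shape[0] and 0 <= sx < img.shape[1]):
            raise ValueError(f"seed {seed} outside the image")
        boundary = np.empty(n_angles)
        peak_vals = np.empty(n_angles)
        for ai, ang in enumerate(angles):
            coords = np.vstack([sy + radii * np.sin(ang), sx + radii * np.cos(ang)])
            prof = map_coordinates(img, coords, order=1, mode="nearest")
            # first sample within float jitter of the maximum (interpolation
            # can exceed lattice values by ~1e-14, relocating a plain argmax)
            tol = 1e-9 * max(1.0, abs(prof.max()))
            p = int(np.flatnonzero(prof >= prof.max() - tol)[0])
            peak_vals[ai] = prof[p]
            thr = bg + boundary_drop * (prof[p] - bg)
            q = p
            while q + 1 < prof.size and prof[q + 1] >= thr:
                q += 1
            boundary[ai] = radii[q]
        flagged = (np.median(boundary) >= 0.95 * max_radius
                   or np.median(peak_vals) < min_contrast * max(bg, 1e-12))
        dy, dx = yy - sy, xx - sx
        r = np.hypot(dy, dx)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        # interpolate the boundary radius at each pixel's angle (circular)
        b_ext = np.concatenate([boundary, boundary[:1]])
        a_ext = np.concatenate([angles, [2 * np.pi]])
        mask = r <= np.interp(theta, a_ext, b_ext)
        if flagged:
            mask = np.zeros_like(mask)
        area = int(mask.sum())
        centroid = ((yy[mask].mean(), xx[mask].mean()) if area else (sy, sx))
        results.append({"seed": (sy, sx), "mask": mask, "area_px": area,
                        "centroid": centroid, "flagged": bool(flagged)})
    return results
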