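"""Event-rate inference from dF/F by smoothing plus exponential inverse filtering.

The calcium indicator integrates firing into fluorescence approximately as a
convolution with a single-exponential kernel exp(-t/tau). Inference proceeds
in two steps: (1) iterative smoothing that removes local low-amplitude peaks
attributable to noise while leaving genuine transients intact, and
(2) inverse filtering with the discrete first-order kernel,
rate(t) proportional to x(t) - exp(-dt/tau) * x(t - dt), rectified at zero.
A noiseless exponential transient therefore deconvolves to a single nonzero
sample at its onset.

Default decay constants: 0.6 s for GCaMP6M, 1.0 s for GCaMP6S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

DEFAULT_TAU_S = {"GCaMP6M": 0.6, "GCaMP6S": 1.0}


@dataclass
class RateTrace:
    """Inferred per-frame event rate (arbitrary units) for one ROI."""

    rate: np.ndarray
    tau_s: float
    frame_rate_hz: float
    smoothing_passes: int = 0


def iterative_smooth(trace: np.ndarray, noise_sigma: float,
                     max_passes: int = 10, restore_factor: float = 5.0
                     ) -> tuple[np.ndarray, int]:
    """Remove local low-amplitude peaks without distorting real transients.

    Repeats {3-point median, then 3-point mean} until no local maximum with
    prominence below ``2 * noise_sigma`` remains, or ``max_passes`` passes.
    After each pass, samples whose original value reaches
    ``restore_factor * noise_sigma`` are restored verbatim: peaks that large
    cannot plausibly be noise, and restoring them keeps transient amplitudes
    undistorted while the surrounding noise floor is flattened.

    Returns ``(smoothed, n_passes)``.
    """
    x = np.asarray(trace, dtype=float).copy()
    if x.size < 3:
        return x, 0
    keep = None
    if noise_sigma > 0:
        keep = x >= restore_factor * noise_sigma
    passes = 0
    for _ in range(max_passes):
        peaks, _ = signal.find_peaks(x)
        if peaks.size == 0:
            break
        prom = signal.peak_prominences(x, peaks)[0]
        if noise_sigma > 0 and not np.any(prom < 2.0 * noise_sigma):
            break
        if noise_sigma <= 0:
            break
        y = signal.medfilt(x, kernel_size=3)
        y = np.convolve(np.pad(y, 1, mode="edge"), np.ones(3) / 3.0, mode="valid")
        if keep is not None:
            y[keep] = trace[keep]
        x = y
        passes += 1
    return x, passes


def inverse_filter(smoothed: np.ndarray, tau_s: float, frame_rate_hz: float
                   ) -> RateTrace:
    """Deconvolve with the discrete exponential kernel; rectify at zero.

    The trace is referenced to its minimum first: a constant offset cannot
    be produced by decaying events and must not register as steady rate.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    x = np.asarray(smoothed, dtype=float)
    if x.size == 0:
        return RateTrace(x.copy(), tau_s, frame_rate_hz)
    x = x - x.min()
    a = np.exp(-1.0 / (tau_s * frame_rate_hz))
    r = np.empty_like(x)
    r[0] = x[0]
    r[1:] = x[1:] - a * x[:-1]
    return RateTrace(np.maximum(r, 0.0), tau_s, frame_rate_hz)


def deconvolve_matrix(dff, tau_s: float | None = None) -> np.ndarray:
    """Smooth and inverse-filter every ROI of a :class:`DffMatrix`.

    ``noise_sigma`` per ROI must be present (run ``denoise_dff`` first).
    Returns an (n_rois, n_frames) rate matrix.
    """
    from .extraction import DffMatrix

    if not isinstance(dff, DffMatrix):
        raise TypeError("expected a DffMatrix")
    if tau_s is None:
        tau_s = DEFAULT_TAU_S.get(dff.indicator, 0.6)
    sigma = dff.noise_sigma
    if sigma is None:
        sigma = np.zeros(dff.n_rois)
    rates = np.zeros_like(dff.dff)
    for r in range(dff.n_rois):
        x = np.nan_to_num(dff.dff[r], nan=0.0)
        sm, _ = iterative_smooth(x, sigma[r])
        rates[r] = inverse_filter(sm, tau_s, dff.frame_rate_hz).rate
    return rates


def smooth_rate(spike_times: np.ndarray, duration_s: float,
                window_ms: float = 100.0, out_rate_hz: float = 100.0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Convert spike times to a firing-rate series with a sliding boxcar.

    The rate at each output sample is the spike count within a centered
    ``window_ms`` window divided by the window length. Returns
    ``(times, rate_hz)``.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    t = (np.arange(int(round(duration_s * out_rate_hz))) + 0.5) / out_rate_hz
    half = window_ms / 2000.0
    lo = np.searchsorted(spike_times, t - half, side="left")
    hi = np.searchsorted(spike_times, t + half, side="right")
    return t, (hi - lo) / (2.0 * half)
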