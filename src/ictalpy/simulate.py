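"""Synthetic sessions with planted ground truth.

Generates the three signal streams the analysis pipeline consumes — EEG with
spike-wave bursts, GCaMP-like ROI fluorescence, and patch-clamp voltage —
together with a :class:`GroundTruth` record of everything that was planted
(seizure intervals and spike times, per-neuron ictal classes and event
trains, pairwise correlation targets, action-potential times). Every
downstream stage can therefore be tested for recovery of known structure
without any recorded data.

Generative model, in brief:

* EEG: pink (1/f) background noise plus spike-wave bursts; each burst is a
  train of biphasic sharp transients at the configured 5-9 Hz rate riding on
  a sub-threshold slow wave, with spike amplitude a configurable multiple of
  the background's MAD-derived envelope (default 4x, comfortably above the
  1.5x detection criterion).
* Calcium: each neuron fires an inhomogeneous Poisson event train whose rate
  is multiplied by ``1 + modulation_depth[class]`` during ictal frames;
  events (amplitude-jittered) are convolved with a single-exponential
  indicator kernel ``exp(-t/tau)``, scaled onto a positive baseline and
  corrupted with Gaussian noise plus slow bleaching. Pairwise correlation is
  injected by letting every neuron accept events from one shared latent
  train with probability ``shared_signal_fraction``; the event-level planted
  correlation between two such neurons is the fraction squared. Neuropil
  patches are means of several random neurons' clean signals plus
  independent noise.
* Voltage: stereotyped spike waveforms (per recording mode) at planted
  times on a noisy baseline, optionally rate-modulated during seizures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .seizures import EEGRecording, SeizureInterval, build_ictal_mask

QUIET_CLASS = "quiet"
CLASSES = ("ictal_low", "ictal_high", "neutral", "quiet")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG substream for a named pipeline stage."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF,
                                  zlib.crc32(stage.encode()) & 0x7FFFFFFF])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic session.

    Defaults describe a 10-min recording at 10 Hz imaging / 2 kHz EEG with
    ~0.7 seizures per minute lasting 2-12 s at a 6 Hz spike rate — the
    regime the analyses assume (frequent short absence seizures, sparse
    GCaMP6M transients). ``class_fractions`` and ``modulation_depth`` plant
    the ictal classes; interictal event rates (0.1-0.5 events/s plausible
    for quiet cortex) default to 0.5 events/s and are exposed here since no
    measured generative statistics exist to pin them down. Rate modulation
    engages ``modulation_onset_lead_s`` before each EEG onset, mirroring the
    observation that population hypoactivity precedes the discharge.
    """

    duration_s: float = 600.0
    frame_rate_hz: float = 10.0
    eeg_rate_hz: float = 2000.0
    seizure_rate_per_min: float = 0.7
    seizure_duration_s: tuple = (2.0, 12.0)
    swd_spike_freq_hz: float = 6.0
    spike_amp_factor: float = 4.0
    class_fractions: dict = field(default_factory=lambda: {
        "ictal_low": 0.70, "ictal_high": 0.06, "neutral": 0.12, "quiet": 0.12})
    modulation_depth: dict = field(default_factory=lambda: {
        "ictal_low": -0.8, "ictal_high": 1.5, "neutral": 0.0, "quiet": 0.0})
    kernel_tau_s: float = 0.6
    noise_sigma_dff: float = 0.01          # fractional dF/F units
    base_event_rate_hz: float = 0.5
    quiet_event_rate_hz: float = 0.0005
    event_amplitude_dff: float = 0.25      # fractional dF/F per event
    event_amplitude_jitter: float = 0.3    # lognormal sigma on amplitudes
    n_neurons: int = 60
    n_neuropil: int = 6
    neuropil_mixing: int = 10
    shared_signal_fraction: float = 0.1
    shared_signal_state: str = "both"      # or "interictal_only"
    modulation_onset_lead_s: float = 2.0
    drift_enabled: bool = False
    drift_epoch_s: float = 300.0
    drift_flip_prob: float = 0.25
    bleach_fraction: float = 0.05
    indicator: str = "GCaMP6M"
    locomotion_bout_rate_per_min: float = 1.0
    locomotion_bout_duration_s: tuple = (2.0, 8.0)
    locomotion_velocity_cm_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate_hz <= 0 or self.eeg_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.seizure_rate_per_min < 0:
            raise ValueError("seizure_rate_per_min must be non-negative")
        if not 5.0 <= self.swd_spike_freq_hz <= 9.0:
            raise ValueError("swd_spike_freq_hz must lie within [5, 9]")
        if self.kernel_tau_s <= 0:
            raise ValueError("kernel_tau_s must be positive")
        total = sum(self.class_fractions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if not 0.0 <= self.shared_signal_fraction < 1.0:
            raise ValueError("shared_signal_fraction must lie in [0, 1)")
        if self.shared_signal_state not in ("both", "interictal_only"):
            raise ValueError("shared_signal_state must be 'both' or 'interictal_only'")


@dataclass
class GroundTruth:
    """Everything planted by the simulator, for recovery tests."""

    true_seizures: list = field(default_factory=list)
    true_class_per_roi: np.ndarray | None = None     # (n_epochs, n_rois) or (n_rois,)
    true_event_trains: list = field(default_factory=list)
    true_ap_times: np.ndarray | None = None
    pairwise_target_corr: float | None = None
    epoch_edges_s: np.ndarray | None = None

    def validate(self, duration_s: float) -> None:
        for s in self.true_seizures:
            if s.onset_s < 0 or s.offset_s > duration_s:
                raise ValueError("planted seizure outside [0, duration]")
        for tr in self.true_event_trains:
            tr = np.asarray(tr)
            if tr.size and (np.any(np.diff(tr) < 0) or tr[0] < 0):
                raise ValueError("event trains must be sorted and non-negative")


# ---------------------------------------------------------------------------
# EEG

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise with unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = 1.0 / np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0))
    spec *= scale
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _place_seizures(config: SimulationConfig, rng: np.random.Generator,
                    edge_pad_s: float = 12.0, min_gap_s: float = 8.0) -> list[tuple]:
    """Choose burst (onset, duration) pairs separated by >= min_gap_s."""
    n = int(round(config.seizure_rate_per_min * config.duration_s / 60.0))
    if n == 0:
        return []
    dmin, dmax = config.seizure_duration_s
    durs = rng.uniform(dmin, dmax, size=n)
    needed = 2 * edge_pad_s + durs.sum() + (n - 1) * min_gap_s
    while n > 0 and needed > config.duration_s:
        n -= 1
        durs = durs[:n]
        needed = 2 * edge_pad_s + durs.sum() + (n - 1) * min_gap_s
    if n == 0:
        return []
    slack = config.duration_s - needed
    extras = rng.dirichlet(np.ones(n + 1)) * slack
    placements = []
    t = edge_pad_s + extras[0]
    for i in range(n):
        placements.append((t, durs[i]))
        t += durs[i] + min_gap_s + extras[i + 1]
    return placements


def _spike_kernel(rate_hz: float) -> tuple[np.ndarray, int]:
    """Biphasic sharp transient (~5-15 ms) used for each SWD spike.

    Returns the kernel (peak amplitude 1) and the index of its peak sample.
    """
    t = np.arange(-0.01, 0.03, 1.0 / rate_hz)
    pos = np.exp(-0.5 * (t / 0.0025) ** 2)
    neg = -0.4 * np.exp(-0.5 * ((t - 0.008) / 0.005) ** 2)
    k = pos + neg
    return k, int(np.argmax(k))


def simulate_eeg(config: SimulationConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[EEGRecording, GroundTruth]:
    """Pink-noise EEG with planted spike-wave bursts.

    Each burst consists of spikes at ``swd_spike_freq_hz`` whose peak
    amplitude is ``spike_amp_factor`` times the MAD-derived envelope of the
    background, riding on a slow wave at the same frequency kept below the
    detection threshold. Bursts are separated by >= 8 s so that planted
    seizures survive the curation rules. Spike peak times are recorded in
    the returned :class:`GroundTruth`.
    """
    if rng is None:
        rng = stage_rng(config.seed, "eeg")
    n = int(round(config.duration_s * config.eeg_rate_hz))
    background_uV = 20.0
    x = background_uV * _pink_noise(n, rng)
    env = 1.4826 * np.median(np.abs(x - np.median(x)))

    kernel, k_peak = _spike_kernel(config.eeg_rate_hz)
    amp = config.spike_amp_factor * env
    seizures = []
    for onset, dur in _place_seizures(config, rng):
        freq = config.swd_spike_freq_hz
        n_spk = int(round(dur * freq)) + 1
        spike_times = onset + np.arange(n_spk) / freq
        # slow wave component, below the amplitude criterion
        i0 = int(round(onset * config.eeg_rate_hz))
        i1 = int(round(spike_times[-1] * config.eeg_rate_hz))
        tt = np.arange(i0, min(i1 + 1, n)) / config.eeg_rate_hz
        x[i0:i0 + tt.size] += 0.8 * env * np.sin(2 * np.pi * freq * (tt - onset))
        for ts in spike_times:
            i = int(round(ts * config.eeg_rate_hz)) - k_peak
            j0, j1 = max(0, i), min(n, i + kernel.size)
            x[j0:j1] += amp * kernel[j0 - i:j1 - i]
        seizures.append(SeizureInterval(spike_times[0], spike_times[-1], spike_times))

    truth = GroundTruth(true_seizures=seizures)
    truth.validate(config.duration_s)
    return EEGRecording(x, config.eeg_rate_hz), truth


# ---------------------------------------------------------------------------
# Calcium

def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of class counts, then a random shuffle."""
    n = config.n_neurons
    fracs = np.array([config.class_fractions[c] for c in CLASSES])
    counts = np.floor(fracs * n).astype(int)
    rem = fracs * n - counts
    for i in np.argsort(rem)[::-1][: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.array(CLASSES, dtype=object), counts)
    return rng.permutation(labels)


def frame_times_for(config: SimulationConfig) -> np.ndarray:
    n_frames = int(round(config.duration_s * config.frame_rate_hz))
    return (np.arange(n_frames) + 0.5) / config.frame_rate_hz


def simulate_calcium(config: SimulationConfig, seizures: list[SeizureInterval],
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray, "pd.DataFrame", GroundTruth]:
    """ROI fluorescence (neurons then neuropil patches) with planted classes.

    Returns ``(raw, frame_times, roi_table, truth)`` where ``raw`` is an
    (n_rois, n_frames) positive fluorescence matrix in arbitrary units.
    """
    import pandas as pd

    if rng is None:
        rng = stage_rng(config.seed, "calcium")
    for s in seizures:
        if s.onset_s < 0 or s.offset_s > config.duration_s:
            raise ValueError("seizure outside the simulated duration")

    ft = frame_times_for(config)
    n_frames = ft.size
    dt = 1.0 / config.frame_rate_hz
    ictal = build_ictal_mask(seizures, ft).ictal
    # rate modulation engages modulation_onset_lead_s before EEG onset:
    # population hypoactivity precedes the electrographic discharge
    lead = config.modulation_onset_lead_s
    modulated = np.zeros(n_frames, dtype=bool)
    for s in seizures:
        modulated |= (ft >= s.onset_s - lead) & (ft <= s.offset_s)

    # class schedule: (n_epochs, n_neurons) labels
    base_labels = _assign_classes(config, rng)
    if config.drift_enabled:
        n_epochs = max(1, int(np.ceil(config.duration_s / config.drift_epoch_s)))
        schedule = np.empty((n_epochs, config.n_neurons), dtype=object)
        schedule[0] = base_labels
        flip = {"ictal_low": "ictal_high", "ictal_high": "ictal_low"}
        for e in range(1, n_epochs):
            prev = schedule[e - 1]
            schedule[e] = prev.copy()
            for i, lab in enumerate(prev):
                if lab in flip and rng.random() < config.drift_flip_prob:
                    schedule[e, i] = flip[lab]
        epoch_edges = np.arange(n_epochs + 1) * config.drift_epoch_s
    else:
        schedule = base_labels[None, :]
        epoch_edges = np.array([0.0, config.duration_s])
    epoch_of_frame = np.clip(
        np.searchsorted(epoch_edges, ft, side="right") - 1, 0, schedule.shape[0] - 1)

    depth = config.modulation_depth
    f = config.shared_signal_fraction
    a = np.exp(-dt / config.kernel_tau_s)

    # shared latent train: expected counts per frame at the base rate
    shared_active = np.ones(n_frames, dtype=bool)
    if config.shared_signal_state == "interictal_only":
        shared_active = ~modulated
    shared_counts = rng.poisson(config.base_event_rate_hz * dt, size=n_frames)
    shared_counts[~shared_active] = 0

    def _amps(k, r):
        return config.event_amplitude_dff * np.exp(
            config.event_amplitude_jitter * r.standard_normal(k)
            - 0.5 * config.event_amplitude_jitter ** 2)

    clean = np.zeros((config.n_neurons, n_frames))
    trains: list[np.ndarray] = []
    for i in range(config.n_neurons):
        labs = schedule[:, i]
        mod = np.array([1.0 + depth.get(l, 0.0) for l in labs])[epoch_of_frame]
        mod = np.where(modulated, mod, 1.0)
        if base_labels[i] == QUIET_CLASS:
            rate = config.quiet_event_rate_hz * np.ones(n_frames)
            own_counts = rng.poisson(rate * dt)
            shared_take = np.zeros(n_frames, dtype=int)
        else:
            rate = config.base_event_rate_hz * mod
            own_counts = rng.poisson((1.0 - f) * rate * dt)
            # accept shared events with probability f * mod (clipped)
            p = np.clip(f * mod, 0.0, 1.0)
            shared_take = rng.binomial(shared_counts, p)
        counts = own_counts + shared_take
        impulses = np.zeros(n_frames)
        ev_frames = np.repeat(np.arange(n_frames), counts)
        if ev_frames.size:
            np.add.at(impulses, ev_frames, _amps(ev_frames.size, rng))
        # first-order AR filter == convolution with exp(-t/tau), peak 1 per event
        from scipy.signal import lfilter
        clean[i] = lfilter([1.0], [1.0, -a], impulses)
        trains.append(ft[ev_frames] if ev_frames.size else np.empty(0))

    # neuropil patches: mixtures of random neurons' clean signals
    npil = np.zeros((config.n_neuropil, n_frames))
    non_quiet = np.flatnonzero(base_labels != QUIET_CLASS)
    for j in range(config.n_neuropil):
        pool = non_quiet if non_quiet.size else np.arange(config.n_neurons)
        k = min(config.neuropil_mixing, pool.size)
        members = rng.choice(pool, size=k, replace=False)
        npil[j] = clean[members].mean(axis=0)

    dff_true = np.vstack([clean, npil]) if config.n_neuropil else clean
    n_rois = dff_true.shape[0]
    f0 = rng.uniform(80.0, 120.0, size=n_rois)[:, None]
    noise_scale = np.concatenate([
        np.full(config.n_neurons, config.noise_sigma_dff),
        np.full(config.n_neuropil, 0.5 * config.noise_sigma_dff)])
    noise = noise_scale[:, None] * rng.standard_normal((n_rois, n_frames))
    bleach = 1.0 - config.bleach_fraction * ft[None, :] / config.duration_s
    raw = f0 * (1.0 + dff_true + noise) * bleach

    roi_table = pd.DataFrame({
        "roi_id": np.arange(n_rois),
        "kind": ["neuron"] * config.n_neurons + ["neuropil"] * config.n_neuropil,
        "layer": "L2/3",
        "area_um2": np.concatenate([
            rng.uniform(100.0, 200.0, config.n_neurons),
            rng.normal(682.0, 96.0, config.n_neuropil) if config.n_neuropil
            else np.empty(0)]),
    })

    truth = GroundTruth(
        true_seizures=list(seizures),
        true_class_per_roi=schedule if config.drift_enabled else base_labels,
        true_event_trains=trains,
        pairwise_target_corr=f * f,
        epoch_edges_s=epoch_edges,
    )
    truth.validate(config.duration_s)
    return raw, ft, roi_table, truth


# ---------------------------------------------------------------------------
# Voltage

VOLTAGE_RATE_HZ = 10000.0


def _ap_template(mode: str, rate_hz: float, amplitude_mv: float | None = None
                 ) -> np.ndarray:
    """Stereotyped spike waveform satisfying the detection criteria.

    Whole-cell: ~100 mV depolarization with a fast (0.2 ms) rise, brief
    plateau and afterhyperpolarization. Cell-attached: the same shape
    compressed in time and scaled to a ~5 mV deflection.
    """
    def shape(rise_n, plateau_n, fall_n, ahp_n, rec_n, ahp_frac):
        seg = [np.linspace(0, 1, rise_n + 1)[1:],
               np.ones(plateau_n),
               np.linspace(1, -ahp_frac, fall_n + 1)[1:],
               np.full(ahp_n, -ahp_frac),
               np.linspace(-ahp_frac, 0, rec_n + 1)[1:]]
        return np.concatenate(seg)

    s = rate_hz / 10000.0
    if mode == "whole_cell":
        amp = 100.0 if amplitude_mv is None else amplitude_mv
        tmpl = shape(int(2 * s), int(3 * s), int(11 * s), int(16 * s), int(30 * s), 0.12)
    elif mode == "cell_attached":
        amp = 5.0 if amplitude_mv is None else amplitude_mv
        tmpl = shape(int(2 * s), int(2 * s), int(8 * s), int(11 * s), int(18 * s), 0.30)
    else:
        raise ValueError(f"unknown recording mode: {mode!r}")
    return amp * tmpl


def simulate_voltage(config: SimulationConfig, mode: str,
                     rng: np.random.Generator | None = None,
                     ap_rate_hz: float = 5.0,
                     seizures: list[SeizureInterval] | None = None,
                     ictal_rate_factor: float = 1.0,
                     noise_sigma_mv: float = 0.0,
                     amplitude_mv: float | None = None,
                     rate_hz: float = VOLTAGE_RATE_HZ,
                     baseline_mv: float | None = None,
                     ) -> tuple[np.ndarray, GroundTruth]:
    """Patch-clamp voltage trace with planted action potentials.

    APs are a Poisson train at ``ap_rate_hz``, optionally multiplied by
    ``ictal_rate_factor`` inside the given seizures, with a 2-ms refractory
    gap enforced. Returns (voltage in mV at ``rate_hz``, truth).
    """
    if mode not in ("whole_cell", "cell_attached"):
        raise ValueError(f"unknown recording mode: {mode!r}")
    if rng is None:
        rng = stage_rng(config.seed, f"voltage-{mode}")
    n = int(round(config.duration_s * rate_hz))
    base = (-65.0 if mode == "whole_cell" else 0.0) if baseline_mv is None else baseline_mv
    v = base + noise_sigma_mv * rng.standard_normal(n)

    # inhomogeneous Poisson via thinning on a fine grid
    grid_dt = 0.001
    grid = np.arange(0.0, config.duration_s, grid_dt)
    rate = np.full(grid.size, float(ap_rate_hz))
    if seizures:
        for s in seizures:
            rate[(grid >= s.onset_s) & (grid <= s.offset_s)] *= ictal_rate_factor
    counts = rng.poisson(rate * grid_dt)
    times = grid[counts > 0]
    # keep detection windows inside the trace: no spikes in the first/last
    # 10 ms, where the criteria's pre/post windows would be truncated
    times = times[(times > 0.01) & (times < config.duration_s - 0.01)]
    if times.size:
        # refractory gap > post2 (2.9 ms): overlapping doublets cannot
        # satisfy the repolarization criterion, so none are planted
        keep = np.ones(times.size, dtype=bool)
        last = -np.inf
        for i, t in enumerate(times):
            if t - last <= 0.004:
                keep[i] = False
            else:
                last = t
        times = times[keep]

    tmpl = _ap_template(mode, rate_hz, amplitude_mv)
    for t in times:
        i = int(round(t * rate_hz))
        j1 = min(n, i + tmpl.size)
        if j1 > i:
            v[i:j1] += tmpl[: j1 - i]

    truth = GroundTruth(true_ap_times=times,
                        true_seizures=list(seizures) if seizures else [])
    return v, truth


# ---------------------------------------------------------------------------
# Locomotion

def simulate_locomotion(config: SimulationConfig, seizures: list[SeizureInterval],
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-frame treadmill velocity; running bouts confined to interictal time.

    Absence seizures arrest behavior, so bouts overlapping a seizure are
    suppressed. Returns cm/s aligned to imaging frames.
    """
    if rng is None:
        rng = stage_rng(config.seed, "locomotion")
    ft = frame_times_for(config)
    v = 0.05 * np.abs(rng.standard_normal(ft.size))
    n_bouts = rng.poisson(config.locomotion_bout_rate_per_min * config.duration_s / 60.0)
    dmin, dmax = config.locomotion_bout_duration_s
    for _ in range(n_bouts):
        start = rng.uniform(0.0, config.duration_s)
        dur = rng.uniform(dmin, dmax)
        if any(s.onset_s - dur < start < s.offset_s + 1.0 for s in seizures):
            continue
        sel = (ft >= start) & (ft < start + dur)
        v[sel] += config.locomotion_velocity_cm_s * (0.8 + 0.4 * rng.random())
    return v
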