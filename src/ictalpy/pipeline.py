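"""Session assembly, end-to-end runs, and result serialization.

A :class:`Session` bundles everything one recording provides: the ROI
fluorescence matrix with frame times and ROI metadata, the time-aligned EEG,
and optional locomotion / patch-clamp streams (plus simulator ground truth
when synthetic). :func:`run_pipeline` executes the full analysis DAG —
seizure annotation, dF/F extraction, classification, participation
profiles, sliding windows, synchrony with both rate corrections, and
deconvolution-based re-classification — and returns a :class:`ResultBundle`
of tables plus a summary. A single seed drives every stochastic stage
through named substreams, so identical config + seed reproduces results
exactly.

On disk a session is a directory of text files: ``traces.csv``,
``frame_times.csv``, ``rois.csv``, ``eeg.csv``, optional ``velocity.csv``,
``meta.yaml`` and optional ``truth.json``. dF/F is serialized in percent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import deconvolve as _deconv
from . import synchrony as _sync
from .extraction import DffMatrix, compute_dff, denoise_dff, flag_quiet
from .seizures import (EEGRecording, IctalMask, SeizureInterval, build_ictal_mask,
                       detect_seizures, filter_seizures, remove_locomotion_frames,
                       seizures_from_frame, seizures_to_frame)
from .simulate import (GroundTruth, SimulationConfig, simulate_calcium,
                       simulate_eeg, simulate_locomotion, stage_rng)


@dataclass
class Session:
    """One aligned recording (possibly synthetic)."""

    raw: np.ndarray                      # (n_rois, n_frames) fluorescence
    frame_times: np.ndarray
    roi_table: pd.DataFrame              # roi_id, kind, layer, area_um2
    eeg: EEGRecording
    velocity: np.ndarray | None = None   # cm/s per frame
    indicator: str = "GCaMP6M"
    session_id: str = "session"
    truth: GroundTruth | None = None

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times)))

    @property
    def duration_s(self) -> float:
        return float(self.frame_times[-1] + 0.5 / self.frame_rate_hz)


def simulate_session(config: SimulationConfig) -> Session:
    """Build a full synthetic session from one configuration + seed."""
    eeg, eeg_truth = simulate_eeg(config)
    raw, ft, roi_table, truth = simulate_calcium(config, eeg_truth.true_seizures)
    velocity = simulate_locomotion(config, eeg_truth.true_seizures)
    return Session(raw=raw, frame_times=ft, roi_table=roi_table, eeg=eeg,
                   velocity=velocity, indicator=config.indicator,
                   session_id=f"sim-seed{config.seed}", truth=truth)


@dataclass
class PipelineParams:
    """Analysis thresholds and sizes, with defaults matching the methods."""

    seed: int = 0
    locomotion_threshold_cm_s: float = 1.0
    alpha: float = 0.05
    n_shuffles_participation: int = 2000
    n_shuffles_synchrony: int = 2000
    window_min: float = 7.0
    window_bin_s: float = 2.0
    corr_bin_s: float = 0.2
    tau_s: float | None = None
    run_participation: bool = True
    run_windows: bool = True
    run_synchrony: bool = True
    run_deconvolution: bool = True
    min_state_bins: int = 30

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class ResultBundle:
    """All tables one pipeline run produces, plus a summary and a run log."""

    seizures: list = field(default_factory=list)
    mask: IctalMask | None = None
    dff: DffMatrix | None = None
    classifications: pd.DataFrame | None = None
    profile_onset: pd.DataFrame | None = None
    profile_offset: pd.DataFrame | None = None
    window_table: pd.DataFrame | None = None
    window_summary: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    rate_match_log: pd.DataFrame | None = None
    rates: np.ndarray | None = None
    rate_classifications: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def _round6(x):
    return float(np.round(float(x), 6)) if np.isfinite(x) else None


def run_pipeline(session: Session, params: PipelineParams | None = None,
                 seizures: list[SeizureInterval] | None = None) -> ResultBundle:
    """Run the analysis DAG on one session.

    ``seizures`` may supply curated annotations, bypassing detection.
    Stage failures in optional stages are isolated and logged; the core
    stages (seizures, dF/F, classification) raise.
    """
    p = params or PipelineParams()
    bundle = ResultBundle(params=asdict(p))
    log = bundle.log

    # --- seizure annotation -------------------------------------------------
    if seizures is None:
        seizures = detect_seizures(session.eeg)
    seizures = filter_seizures(seizures,
                               recording_duration_s=session.duration_s)
    bundle.seizures = seizures
    log.append(f"seizures: {len(seizures)} accepted")

    mask = build_ictal_mask(seizures, session.frame_times)
    if session.velocity is not None:
        mask, dropped = remove_locomotion_frames(
            mask, session.velocity, p.locomotion_threshold_cm_s)
        log.append(f"locomotion: {dropped.size} frames excluded")
    bundle.mask = mask

    # --- dF/F extraction ----------------------------------------------------
    dff = compute_dff(session.raw, session.frame_rate_hz,
                      frame_times=session.frame_times,
                      indicator=session.indicator)
    dff = flag_quiet(denoise_dff(dff))
    bundle.dff = dff
    log.append(f"dff: {int(dff.quiet.sum())} quiet of {dff.n_rois} ROIs")

    # --- overall classification --------------------------------------------
    cls = _classify.classify_roi(dff, mask, alpha=p.alpha)
    bundle.classifications = cls

    kinds = session.roi_table["kind"].to_numpy()
    neuron = kinds == "neuron"
    labels = cls["label"].to_numpy()

    # --- participation profiles --------------------------------------------
    if p.run_participation and len(seizures) >= 1:
        for alignment in ("onset", "offset"):
            try:
                prof = _classify.participation_profile(
                    dff, seizures, alignment=alignment,
                    n_shuffles=p.n_shuffles_participation,
                    rng=stage_rng(p.seed, f"participation-{alignment}"))
                setattr(bundle, f"profile_{alignment}",
                        _classify.profile_to_frame(prof))
            except ValueError as e:
                log.append(f"participation[{alignment}] skipped: {e}")

    # --- sliding windows ----------------------------------------------------
    if p.run_windows:
        try:
            table, summary = _classify.sliding_window_classes(
                dff, seizures, mask, window_min=p.window_min,
                bin_s=p.window_bin_s, alpha=p.alpha, overall_labels=labels)
            bundle.window_table, bundle.window_summary = table, summary
        except ValueError as e:
            log.append(f"windows skipped: {e}")

    # --- synchrony ----------------------------------------------------------
    if p.run_synchrony:
        try:
            res = _sync.state_correlations(dff, mask, bin_s=p.corr_bin_s,
                                           min_bins=p.min_state_bins, kinds=kinds)
            res = _sync.shuffle_correct(res, n_shuffles=p.n_shuffles_synchrony,
                                        rng=stage_rng(p.seed, "synchrony"))
            bundle.correlations = _sync.pairs_frame(res)
            _, match_log = _sync.rate_match_by_event_removal(
                dff, mask, rng=stage_rng(p.seed, "rate-match"))
            bundle.rate_match_log = match_log
        except ValueError as e:
            log.append(f"synchrony skipped: {e}")

    # --- deconvolution ------------------------------------------------------
    if p.run_deconvolution:
        rates = _deconv.deconvolve_matrix(dff, tau_s=p.tau_s)
        bundle.rates = rates
        rate_dm = DffMatrix(rates, dff.frame_rate_hz, frame_times=dff.frame_times,
                            quiet=dff.quiet, indicator=dff.indicator,
                            error_flags=dff.error_flags)
        bundle.rate_classifications = _classify.classify_roi(rate_dm, mask,
                                                             alpha=p.alpha)

    # every table row carries its provenance
    for name in ("classifications", "profile_onset", "profile_offset",
                 "window_table", "window_summary", "correlations",
                 "rate_match_log", "rate_classifications"):
        df = getattr(bundle, name)
        if df is not None and len(df):
            df.insert(0, "session_id", session.session_id)
            df.insert(1, "seed", p.seed)

    bundle.summary = _summarize(session, bundle, neuron)
    return bundle


def _summarize(session: Session, bundle: ResultBundle, neuron: np.ndarray) -> dict:
    cls = bundle.classifications
    dff, mask = bundle.dff, bundle.mask
    active_neuron = neuron & dff.active()
    lab = cls["label"].to_numpy()
    n_act = max(1, int(active_neuron.sum()))
    summary = {
        "session_id": session.session_id,
        "n_seizures": len(bundle.seizures),
        "n_rois": dff.n_rois,
        "n_neurons": int(neuron.sum()),
        "frac_quiet": _round6(dff.quiet[neuron].mean()),
        "frac_ictal_low": _round6((lab[active_neuron] == "ictal_low").sum() / n_act),
        "frac_ictal_high": _round6((lab[active_neuron] == "ictal_high").sum() / n_act),
        "frac_neutral": _round6((lab[active_neuron] == "neutral").sum() / n_act),
        "mean_ictal_dff_pct": _round6(
            np.nanmean(dff.dff[active_neuron][:, mask.ictal_clean])),
        "mean_interictal_dff_pct": _round6(
            np.nanmean(dff.dff[active_neuron][:, mask.interictal])),
    }
    if bundle.correlations is not None:
        c = bundle.correlations
        for state in ("interictal", "ictal"):
            for pt, key in (("neuron-neuron", "neuron"), ("neuropil-neuropil",
                                                          "neuropil")):
                sel = c[(c.state == state) & (c.pair_type == pt)]["corrected"]
                summary[f"corr_{key}_{state}"] = (
                    _round6(sel.mean()) if len(sel) else None)
    for alignment in ("onset", "offset"):
        prof = getattr(bundle, f"profile_{alignment}")
        if prof is not None and len(prof):
            per_roi = prof.groupby("roi_id")["participant"].first()
            summary[f"frac_participants_{alignment}"] = _round6(per_roi.mean())
    if bundle.rate_classifications is not None:
        both = (cls["label"].to_numpy()[active_neuron],
                bundle.rate_classifications["label"].to_numpy()[active_neuron])
        summary["deconv_agreement"] = _round6(np.mean(both[0] == both[1]))
    return summary


# ---------------------------------------------------------------------------
# session bundle I/O

def write_session(session: Session, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    n_frames = session.raw.shape[1]
    cols = [f"f{j}" for j in range(n_frames)]
    traces = pd.DataFrame(session.raw, columns=cols)
    traces.insert(0, "roi_id", session.roi_table["roi_id"].to_numpy())
    traces.to_csv(out / "traces.csv", index=False, float_format="%.4f")
    pd.DataFrame({"frame_time_s": session.frame_times}).to_csv(
        out / "frame_times.csv", index=False)
    session.roi_table.to_csv(out / "rois.csv", index=False)
    pd.DataFrame({"time_s": session.eeg.times,
                  "uV": session.eeg.samples}).to_csv(
        out / "eeg.csv", index=False, float_format="%.3f")
    if session.velocity is not None:
        pd.DataFrame({"velocity_cm_s": session.velocity}).to_csv(
            out / "velocity.csv", index=False, float_format="%.4f")
    meta = {"session_id": session.session_id, "indicator": session.indicator,
            "eeg_rate_hz": float(session.eeg.rate_hz),
            "dff_units": "raw fluorescence (a.u.); derived dF/F is percent"}
    (out / "meta.yaml").write_text(yaml.safe_dump(meta))
    if session.truth is not None:
        t = session.truth
        payload = {
            "true_seizures": seizures_to_frame(t.true_seizures).to_dict("records"),
            "true_class_per_roi": (np.asarray(t.true_class_per_roi).tolist()
                                   if t.true_class_per_roi is not None else None),
            "pairwise_target_corr": t.pairwise_target_corr,
        }
        (out / "truth.json").write_text(json.dumps(payload))


def read_session(indir) -> Session:
    """Load a session bundle; checks EEG/imaging temporal alignment."""
    d = Path(indir)
    for name in ("traces.csv", "frame_times.csv", "rois.csv", "eeg.csv",
                 "meta.yaml"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing session file: {d / name}")
    traces = pd.read_csv(d / "traces.csv")
    raw = traces.drop(columns=["roi_id"]).to_numpy(dtype=float)
    ft = pd.read_csv(d / "frame_times.csv")["frame_time_s"].to_numpy(dtype=float)
    rois = pd.read_csv(d / "rois.csv")
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    eeg_df = pd.read_csv(d / "eeg.csv")
    eeg = EEGRecording(eeg_df["uV"].to_numpy(dtype=float),
                       float(meta["eeg_rate_hz"]),
                       t0_s=float(eeg_df["time_s"].iloc[0]))
    overlap = (min(ft[-1], eeg.times[-1]) - max(ft[0], eeg.times[0]))
    if overlap <= 0:
        raise ValueError(
            f"EEG and imaging do not overlap in time "
            f"(imaging {ft[0]:.2f}-{ft[-1]:.2f} s, "
            f"EEG {eeg.times[0]:.2f}-{eeg.times[-1]:.2f} s)")
    velocity = None
    if (d / "velocity.csv").exists():
        velocity = pd.read_csv(d / "velocity.csv")["velocity_cm_s"].to_numpy(float)
    truth = None
    if (d / "truth.json").exists():
        payload = json.loads((d / "truth.json").read_text())
        truth = GroundTruth(
            true_seizures=seizures_from_frame(
                pd.DataFrame(payload["true_seizures"])),
            true_class_per_roi=(np.asarray(payload["true_class_per_roi"],
                                           dtype=object)
                                if payload.get("true_class_per_roi") else None),
            pairwise_target_corr=payload.get("pairwise_target_corr"))
    return Session(raw=raw, frame_times=ft, roi_table=rois, eeg=eeg,
                   velocity=velocity, indicator=meta.get("indicator", "GCaMP6M"),
                   session_id=meta.get("session_id", "session"), truth=truth)


def write_results(bundle: ResultBundle, outdir) -> None:
    """Serialize every table, the summary, the resolved config and the log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seizures_to_frame(bundle.seizures).to_csv(out / "seizures.csv", index=False)
    for name in ("classifications", "profile_onset", "profile_offset",
                 "window_table", "window_summary", "correlations",
                 "rate_match_log", "rate_classifications"):
        df = getattr(bundle, name)
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
    if bundle.dff is not None:
        np.savetxt(out / "dff_percent.csv", bundle.dff.dff, delimiter=",",
                   fmt="%.5f")
    if bundle.rates is not None:
        np.savetxt(out / "rates.csv", bundle.rates, delimiter=",", fmt="%.6f")
    (out / "summary.json").write_text(json.dumps(bundle.summary, indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(bundle.params))
    (out / "run_log.txt").write_text("\n".join(bundle.log) + "\n")
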