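"""Shared synthetic-session fixtures.

All fixtures are generated programmatically from the simulator with fixed
seeds; the heavier sessions are session-scoped so their extraction cost is
paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

import ictalpy as ip


def _prepared(cfg: ip.SimulationConfig) -> dict:
    """Simulate a session and run it through extraction + masking."""
    session = ip.simulate_session(cfg)
    dff = ip.flag_quiet(ip.denoise_dff(ip.compute_dff(
        session.raw, session.frame_rate_hz, frame_times=session.frame_times,
        indicator=session.indicator)))
    seizures = ip.filter_seizures(session.truth.true_seizures,
                                  recording_duration_s=cfg.duration_s)
    mask = ip.build_ictal_mask(seizures, session.frame_times)
    truth_cls = np.asarray(session.truth.true_class_per_roi)
    return {"config": cfg, "session": session, "dff": dff, "mask": mask,
            "seizures": seizures, "truth_classes": truth_cls}


@pytest.fixture(scope="session")
def small_session() -> dict:
    """5-min field at the paper's lower bounds: 29 neurons, 4 neuropil."""
    return _prepared(ip.SimulationConfig(
        duration_s=300.0, n_neurons=29, n_neuropil=4,
        seizure_rate_per_min=1.2, seed=0))


@pytest.fixture(scope="session")
def study_session() -> dict:
    """30-min, 60 neurons + 6 neuropil, 20 seizures, depths -0.8 / +1.5."""
    return _prepared(ip.SimulationConfig(
        duration_s=1800.0, n_neurons=60, n_neuropil=6,
        seizure_rate_per_min=2.0 / 3.0, seed=7))


@pytest.fixture(scope="session")
def rich_session() -> dict:
    """Seizure-rich 30-min session (~60 seizures) for participation power."""
    return _prepared(ip.SimulationConfig(
        duration_s=1800.0, n_neurons=40, n_neuropil=4,
        seizure_rate_per_min=2.0, seed=3))


@pytest.fixture(scope="session")
def study_classes(study_session) -> dict:
    """Overall classification of the study session, shared across tests."""
    cls = ip.classify_roi(study_session["dff"], study_session["mask"])
    return {**study_session, "classifications": cls}
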