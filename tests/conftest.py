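"""Shared fixtures.  Expensive steady-state simulations at the production
layer count are session-scoped so the morphology tests share them."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pleurasim.mechanics import simulate_breaths
from pleurasim.patient_model import build_patient

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")

PE_VOLUME = 3.0


@pytest.fixture(scope="session")
def default_params():
    return build_patient()


@pytest.fixture(scope="session")
def small_params():
    """Coarse discretization for tests where layer count is not the point."""
    return build_patient("default", {"n_layers": 20})


@pytest.fixture(scope="session")
def stiff_run_3l():
    """Stiff-mediastinum preset breathing on 3 L effusion (full resolution)."""
    params = build_patient("stiff_mediastinum")
    rec, state = simulate_breaths(params, PE_VOLUME, n_breaths=2)
    return params, rec, state


@pytest.fixture(scope="session")
def compliant_run_3l():
    params = build_patient("compliant_mediastinum")
    rec, state = simulate_breaths(params, PE_VOLUME, n_breaths=2)
    return params, rec, state


@pytest.fixture(scope="session")
def baseline_run():
    """Default patient, no effusion, full resolution."""
    params = build_patient()
    rec, state = simulate_breaths(params, 0.0, n_breaths=2)
    return params, rec, state


def last_breath_loop(rec):
    """P-V loop of the last recorded breath (helper shared across tests)."""
    from pleurasim.loop_analysis import loops_from_recording
    return loops_from_recording(rec)[-1]


def lean_delta(loop):
    insp = np.where(loop.phase == "insp")[0]
    return float(loop.P[insp[-1]] - loop.P[-1])
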