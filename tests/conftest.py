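"""Shared fixtures: canonical models, schedules and seeded tracks."""

from __future__ import annotations

import numpy as np
import pytest

from trackdesign import (
    ModelKind,
    MovementModel,
    SamplingSchedule,
    fit,
    simulate_track,
)

HOUR = 3600.0
DAY = 86400.0


@pytest.fixture(scope="session")
def ouf_model() -> MovementModel:
    """Canonical OUF prototype: tau_p = 4 h, tau_v = 1 h, sigma = 1 km^2."""
    return MovementModel(ModelKind.OUF, tau_p=4 * HOUR, tau_v=HOUR, sigma=1e6)


@pytest.fixture(scope="session")
def ou_model() -> MovementModel:
    return MovementModel(ModelKind.OU, tau_p=DAY, sigma=1e6)


@pytest.fixture(scope="session")
def fine_schedule() -> SamplingSchedule:
    """Fine sampling: dt = tau_v / 4, T = 40 tau_p for the canonical OUF."""
    return SamplingSchedule(duration=160 * HOUR, interval=HOUR / 4)


@pytest.fixture(scope="session")
def ouf_track(ouf_model, fine_schedule):
    return simulate_track(ouf_model, fine_schedule, seed=42)


@pytest.fixture(scope="session")
def ouf_fit(ouf_track):
    return fit(ouf_track, candidates=[ModelKind.OU, ModelKind.OUF])
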