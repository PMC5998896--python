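"""Shared fixtures: small random schedules and the reference simulation.

The session-scoped simulated datasets emulate the canonical two-event
study design: 20,000 ancestral genes, a duplication with w = 0.5
followed by a triplication with per-copy survival s = 0.4, expected
similarities 0.70 / 0.87 and gene length G = 1000 — and its mirrored
triplication-first twin.
"""

import numpy as np
import pytest

from wgmfrac import (
    EventSchedule,
    ModelTemplate,
    simulate_dataset,
)

TRUTH = {"w": 0.5, "s": 0.4, "p1": 0.70, "p2": 0.87, "G": 1000.0, "m1": 20000}


def random_schedule(rng, ploidies, m1=1):
    """A valid schedule with survival vectors drawn from the simplex."""
    survival = []
    for r in ploidies:
        x = rng.random(r)
        x /= x.sum()
        survival.append(tuple(x))
    return EventSchedule(
        times=tuple(float(t) for t in range(len(ploidies) + 1)),
        ploidies=tuple(ploidies),
        survival=tuple(survival),
        m1=m1,
    )


def _two_event_schedule(ploidies, modes, params, m1):
    template = ModelTemplate(ploidies=ploidies, survival_modes=modes)
    schedule, div = template.build_model(params)
    schedule = EventSchedule(
        times=schedule.times, ploidies=schedule.ploidies, survival=schedule.survival, m1=m1
    )
    return schedule, div


@pytest.fixture(scope="session")
def dup_then_trip_dataset():
    schedule, div = _two_event_schedule(
        (2, 3),
        ("free", "binomial"),
        {"u2_e1": TRUTH["w"], "s_e2": TRUTH["s"], "p1": TRUTH["p1"], "p2": TRUTH["p2"],
         "G": TRUTH["G"]},
        TRUTH["m1"],
    )
    return simulate_dataset(schedule, div, seed=8)


@pytest.fixture(scope="session")
def trip_then_dup_dataset():
    schedule, div = _two_event_schedule(
        (3, 2),
        ("binomial", "free"),
        {"s_e1": TRUTH["s"], "u2_e2": TRUTH["w"], "p1": TRUTH["p1"], "p2": TRUTH["p2"],
         "G": TRUTH["G"]},
        TRUTH["m1"],
    )
    return simulate_dataset(schedule, div, seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
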