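"""Shared fixtures: analytic fixture systems and a session-scoped cache of
the expensive task solves, so that several tests can interrogate the same
optimal trajectory without re-solving."""

from __future__ import annotations

import numpy as np
import pytest

from sooc._symbolic import vech
from sooc.experiments import build_preset, fixture_generator
from sooc.transcription import OCProblem, SolverOptions, solve


@pytest.fixture(scope="session")
def ou():
    return fixture_generator("ou_process")


@pytest.fixture(scope="session")
def brownian():
    return fixture_generator("pure_brownian")


@pytest.fixture(scope="session")
def lq():
    return fixture_generator("lq_system")


@pytest.fixture(scope="session")
def toy_bilinear():
    return fixture_generator("toy_bilinear")


@pytest.fixture(scope="session")
def kk1_plant():
    from sooc.plants import kk_onejoint

    return kk_onejoint()


@pytest.fixture(scope="session")
def arm_plant():
    from sooc.plants import kk_twojoint

    return kk_twojoint()


class SolveCache:
    """Lazily solve presets once per session; support warm-starting one
    preset's solve from another's solution."""

    def __init__(self):
        self._store = {}

    def trajectory(self, preset: str, warm_from: str | None = None,
                   **overrides):
        key = (preset, tuple(sorted(overrides.items())))
        if key not in self._store:
            bundle = build_preset(preset, **overrides)
            problem = OCProblem.from_task(bundle["plant"], bundle["task"])
            guess = None
            options = bundle["options"]
            if warm_from is not None:
                base = self.trajectory(warm_from, **overrides)
                Z = np.concatenate(
                    [base.mean, vech(base.cov)], axis=1
                )
                guess = np.column_stack([Z, base.u]).ravel()
                options = SolverOptions(
                    **{**vars(options), "method": "slsqp",
                       "max_iterations": 500}
                )
            traj = solve(problem, options, initial_guess=guess)
            traj.bundle = bundle
            self._store[key] = traj
        return self._store[key]


@pytest.fixture(scope="session")
def solves():
    return SolveCache()
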