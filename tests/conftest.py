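"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from prozone import LigandSpec, ScaffoldScenario, canonical_presets


def bisect_pairwise(s_total: float, x_total: float, kd: float,
                    tol: float = 1e-14, max_iter: int = 500) -> float:
    """Independent bisection oracle for the pairwise mass balance.

    Finds the root of f(SX) = (S_T - SX)(X_T - SX) - K_D SX on
    [0, min(S_T, X_T)]; f is strictly decreasing there, so plain bisection
    suffices. Deliberately ignorant of the closed-form quadratic.
    """
    lo, hi = 0.0, min(s_total, x_total)
    if hi == 0.0:
        return 0.0

    def f(sx: float) -> float:
        return (s_total - sx) * (x_total - sx) - kd * sx

    if f(hi) >= 0.0:  # tight binding: root at the upper boundary
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def presets():
    return canonical_presets()


@pytest.fixture
def scenario_2_10_20():
    return ScaffoldScenario(
        s_total=2.0,
        ligands=(LigandSpec("Raf", 2.0, 0.01), LigandSpec("MEK", 10.0, 0.01),
                 LigandSpec("ERK", 20.0, 0.01)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
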