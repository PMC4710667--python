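"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from itlie import EnergyTrajectory, StateSegment, TrajectorySpec, gen_trajectory


def two_segment_changepoint(values: np.ndarray, times: np.ndarray) -> float:
    """Brute-force two-segment piecewise-constant least-squares changepoint.

    Scans every admissible split of the series into two constant segments
    and returns the time of the split minimising the total sum of squared
    residuals.  Independent of the detection pipeline.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    c = np.cumsum(x)
    c2 = np.cumsum(x * x)
    best_sse = np.inf
    best_k = None
    for k in range(2, n - 1):
        s1, s12 = c[k - 1], c2[k - 1]
        s2, s22 = c[-1] - s1, c2[-1] - s12
        sse = (s12 - s1 * s1 / k) + (s22 - s2 * s2 / (n - k))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return float(times[best_k])


def make_step_trajectory(
    t_step: float = 500.0,
    low: float = -160.0,
    high: float = -120.0,
    noise_sd: float = 5.0,
    ramp: float = 20.0,
    seed: int = 0,
    vdw_level: float = -80.0,
    total: float = 1000.0,
) -> tuple[EnergyTrajectory, list[tuple[float, float]]]:
    """One-ramp synthetic trajectory: step in the electrostatic channel only."""
    spec = TrajectorySpec(
        segments=(
            StateSegment(t_step, low, vdw_level),
            StateSegment(total - t_step - ramp, high, vdw_level),
        ),
        noise_sd=noise_sd,
        transition_width=ramp,
        seed=seed,
    )
    return gen_trajectory(spec)


@pytest.fixture
def constant_trajectory() -> EnergyTrajectory:
    times = np.arange(500) * 2.0
    return EnergyTrajectory(
        times=times,
        v_el=np.full(500, -100.0),
        v_vdw=np.full(500, -50.0),
        label="constant",
    )
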