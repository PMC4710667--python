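"""Synthetic data with known ground truth for the whole toolkit.

Real inputs to the workflow would be ~1 ns production MD runs with energies
stored every 2 ps.  The generator emulates the core assumption of the
transition detector — interaction energies fluctuate around constant values
between conformational changes — as piecewise-constant channel means joined
by linear ramps of configurable width, plus Gaussian thermal noise (optionally
AR(1)-correlated, since real MD energies are autocorrelated).  Transition
times, segment means and noise level are all known, so detection, window
selection and averaging can be scored exactly.

For the modeling half, synthetic multi-simulation LIE datasets are built the
other way round: per-simulation ΔV values are drawn at random and each
ligand's "experimental" affinity is set to the Boltzmann-weighted LIE value
at known true (α, β), optionally plus noise, so calibration can be tested as
a parameter-recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lie import LIEDataset, LIEParameters, LigandEntry, lie_weighted
from .protocol import SimulationRecord
from .trajio import EnergyTrajectory, ValidationError

__all__ = [
    "StateSegment",
    "TrajectorySpec",
    "gen_trajectory",
    "gen_lie_dataset",
]


@dataclass(frozen=True)
class StateSegment:
    """One conformational state: constant mean energies for a duration."""

    duration: float  # ps
    mean_el: float  # kJ mol⁻¹
    mean_vdw: float  # kJ mol⁻¹

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError("segment duration must be positive")


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for one synthetic bound-state energy trajectory.

    Defaults mirror a 1 ns production run sampled every 2 ps; noise_sd is
    the per-frame thermal fluctuation of each channel and transition_width
    the length of the linear ramp joining consecutive states.  ``ar1`` adds
    lag-one autocorrelation to the noise (0 = white).
    """

    segments: tuple[StateSegment, ...]
    noise_sd: float = 5.0
    transition_width: float = 20.0
    dt: float = 2.0
    seed: int = 0
    ar1: float = 0.0
    t0: float = 0.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("need at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.transition_width < 0:
            raise ValidationError("transition_width must be >= 0")
        if not self.dt > 0:
            raise ValidationError("dt must be positive")
        if not -1 < self.ar1 < 1:
            raise ValidationError("ar1 must lie in (-1, 1)")

    @property
    def total_duration(self) -> float:
        n_ramps = len(self.segments) - 1
        return sum(s.duration for s in self.segments) + n_ramps * self.transition_width


def _noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, n)
    if ar1 == 0.0 or n < 2:
        return eps
    out = np.empty(n)
    out[0] = eps[0]
    scale = np.sqrt(1.0 - ar1**2)  # keeps the marginal sd at noise_sd
    for i in range(1, n):
        out[i] = ar1 * out[i - 1] + scale * eps[i]
    return out


def gen_trajectory(
    spec: TrajectorySpec,
) -> tuple[EnergyTrajectory, list[tuple[float, float]]]:
    """Generate one trajectory plus its ground-truth transition intervals.

    The mean profile is piecewise constant per segment with linear ramps of
    ``transition_width`` ps between consecutive segments; the returned truth
    intervals are exactly those ramps (half-open).  A fixed seed reproduces
    the trajectory bit for bit.
    """
    # knots of the piecewise-linear mean profile
    xs: list[float] = []
    el: list[float] = []
    vdw: list[float] = []
    truth: list[tuple[float, float]] = []
    t = spec.t0
    for i, seg in enumerate(spec.segments):
        xs += [t, t + seg.duration]
        el += [seg.mean_el, seg.mean_el]
        vdw += [seg.mean_vdw, seg.mean_vdw]
        t += seg.duration
        if i < len(spec.segments) - 1:
            truth.append((t, t + spec.transition_width))
            t += spec.transition_width
    n = int(round(spec.total_duration / spec.dt))
    times = spec.t0 + np.arange(n) * spec.dt
    mean_el = np.interp(times, xs, el)
    mean_vdw = np.interp(times, xs, vdw)
    rng = np.random.default_rng(spec.seed)
    v_el = mean_el + _noise(rng, n, spec.noise_sd, spec.ar1)
    v_vdw = mean_vdw + _noise(rng, n, spec.noise_sd, spec.ar1)
    traj = EnergyTrajectory(
        times=times, v_el=v_el, v_vdw=v_vdw, label=spec.label
    )
    return traj, truth


def gen_lie_dataset(
    n_ligands: int,
    sims_per_ligand: int,
    alpha_true: float,
    beta_true: float,
    dv_vdw_range: tuple[float, float] = (-140.0, -60.0),
    dv_el_range: tuple[float, float] = (-60.0, 0.0),
    noise_sd_dg: float = 0.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> LIEDataset:
    """Synthetic multi-simulation LIE dataset with known true parameters.

    ΔV values are uniform over the stated ranges (defaults span the
    magnitudes typical of drug-like ligands in a CYP active site, giving
    ΔG_calc around −50…−20 kJ mol⁻¹ at α≈0.44, β≈0.09).  Each ligand's
    dg_exp is the weighted LIE value at (alpha_true, beta_true) plus
    Gaussian noise of sd ``noise_sd_dg``; with zero noise, calibration
    should recover the true parameters.
    """
    if n_ligands < 2:
        raise ValidationError("need at least 2 ligands")
    if sims_per_ligand < 1:
        raise ValidationError("need at least 1 simulation per ligand")
    for lo, hi in (dv_vdw_range, dv_el_range):
        if not hi > lo:
            raise ValidationError("ΔV ranges must have positive width")
    if noise_sd_dg < 0:
        raise ValidationError("noise_sd_dg must be >= 0")
    rng = np.random.default_rng(seed)
    params = LIEParameters(alpha_true, beta_true, temperature)
    ligands: dict[str, LigandEntry] = {}
    for i in range(n_ligands):
        lig = f"lig{i:03d}"
        records = tuple(
            SimulationRecord(
                ligand_id=lig,
                sim_id=f"{lig}_sim{j}",
                dv_vdw=float(rng.uniform(*dv_vdw_range)),
                dv_el=float(rng.uniform(*dv_el_range)),
            )
            for j in range(sims_per_ligand)
        )
        dg = lie_weighted(params, records)
        if noise_sd_dg > 0:
            dg += float(rng.normal(0.0, noise_sd_dg))
        ligands[lig] = LigandEntry(records=records, dg_exp=dg)
    return LIEDataset(ligands)
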