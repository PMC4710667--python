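"""Linear interaction energy (LIE) models with Boltzmann-weighted averaging.

The single-simulation LIE estimate of a binding free energy is

    ΔG_calc = α·(⟨V_vdW⟩_bound − ⟨V_vdW⟩_free) + β·(⟨V_el⟩_bound − ⟨V_el⟩_free)

with empirical scaling parameters α (van der Waals) and β (electrostatic)
and no offset term.  When several short parallel simulations i sample
different local parts of the complex's conformational space, their energy
differences are combined with Boltzmann weights

    W_i = exp(−ΔG_calc,i / k_B T) / Σ_j exp(−ΔG_calc,j / k_B T)

so that simulations predicting stronger binding dominate:

    ΔG_calc = α·Σ_i W_i ΔV_vdW,i + β·Σ_i W_i ΔV_el,i.

The weights depend on the candidate (α, β) through ΔG_calc,i, which makes
the calibration against experimental affinities self-consistent: every
objective evaluation recomputes the weights at the candidate parameters.
Calibration minimises the RMSE over ligands with a deterministic coarse
grid search followed by local simplex refinement; generalisation error is
estimated by leave-one-out cross-validation (SDEP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .protocol import SimulationRecord
from .trajio import ValidationError

__all__ = [
    "BOLTZMANN_KJ_PER_MOL_K",
    "LIEParameters",
    "LigandEntry",
    "LIEDataset",
    "ModelReport",
    "LOOResult",
    "lie_single",
    "boltzmann_weights",
    "lie_weighted",
    "rmse",
    "calibrate",
    "sdep_loo",
]

#: Boltzmann constant in kJ mol⁻¹ K⁻¹
BOLTZMANN_KJ_PER_MOL_K = 0.0083145


@dataclass(frozen=True)
class LIEParameters:
    """Scaling parameters and thermodynamic constants of the model."""

    alpha: float = 0.0
    beta: float = 0.0
    temperature: float = 300.0
    k_B: float = BOLTZMANN_KJ_PER_MOL_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive")
        if not self.k_B > 0:
            raise ValidationError("k_B must be positive")

    @property
    def kT(self) -> float:
        return self.k_B * self.temperature


@dataclass(frozen=True)
class LigandEntry:
    """Simulations and experimental affinity for one ligand."""

    records: tuple[SimulationRecord, ...]
    dg_exp: float

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("ligand needs at least one simulation record")
        if not math.isfinite(self.dg_exp):
            raise ValidationError("dg_exp must be finite")


@dataclass(frozen=True)
class LIEDataset:
    """Calibration unit: per-ligand simulation records plus experiment."""

    ligands: Mapping[str, LigandEntry]

    def __post_init__(self) -> None:
        if not self.ligands:
            raise ValidationError("dataset has no ligands")
        object.__setattr__(self, "ligands", dict(self.ligands))

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    def subset(self, keep: Iterable[str]) -> "LIEDataset":
        keep = set(keep)
        return LIEDataset({k: v for k, v in self.ligands.items() if k in keep})

    @staticmethod
    def from_records(
        records: Iterable[SimulationRecord], dg_exp: Mapping[str, float]
    ) -> "LIEDataset":
        """Group records by ligand id and join with experimental affinities."""
        by_lig: dict[str, list[SimulationRecord]] = {}
        for r in records:
            by_lig.setdefault(r.ligand_id, []).append(r)
        missing = set(by_lig) - set(dg_exp)
        if missing:
            raise ValidationError(f"no experimental ΔG for ligand(s) {sorted(missing)}")
        return LIEDataset(
            {
                lig: LigandEntry(tuple(recs), float(dg_exp[lig]))
                for lig, recs in by_lig.items()
            }
        )


@dataclass(frozen=True)
class ModelReport:
    """Outcome of a calibration: parameters, fit quality, per-ligand detail."""

    alpha: float
    beta: float
    rmse: float
    temperature: float
    dg_calc: Mapping[str, float]
    weights: Mapping[str, tuple[float, ...]]
    sdep: float | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValidationError("rmse must be >= 0")
        for lig, w in self.weights.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValidationError(f"weights of {lig} do not sum to 1")

    def parameters(self) -> LIEParameters:
        return LIEParameters(self.alpha, self.beta, self.temperature)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "rmse": self.rmse,
            "sdep": self.sdep,
            "temperature": self.temperature,
            "dg_calc": dict(self.dg_calc),
            "weights": {k: list(v) for k, v in self.weights.items()},
        }


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out cross-validation summary and per-fold detail."""

    sdep: float
    folds: pd.DataFrame


def lie_single(params: LIEParameters, dv_vdw: float, dv_el: float) -> float:
    """Single-simulation LIE estimate α·ΔV_vdW + β·ΔV_el (kJ mol⁻¹)."""
    if not (np.isfinite(dv_vdw) and np.isfinite(dv_el)):
        raise ValidationError("ΔV inputs must be finite")
    return params.alpha * dv_vdw + params.beta * dv_el


def boltzmann_weights(
    dg_list: Sequence[float] | np.ndarray, params: LIEParameters
) -> np.ndarray:
    """Normalised Boltzmann weights of per-simulation ΔG values.

    Uses max-subtraction so that large |ΔG| cannot overflow the exponent.
    """
    dg = np.asarray(dg_list, dtype=float)
    if dg.size == 0:
        raise ValidationError("need at least one ΔG value")
    if not np.all(np.isfinite(dg)):
        raise ValidationError("ΔG values must be finite")
    z = -dg / params.kT
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    assert abs(w.sum() - 1.0) < 1e-12
    return w


def lie_weighted(
    params: LIEParameters, records: Sequence[SimulationRecord]
) -> float:
    """Boltzmann-weighted multi-simulation LIE estimate for one ligand.

    For a single record this reduces exactly to ``lie_single``.
    """
    if not records:
        raise ValidationError("need at least one record")
    if len(records) == 1:
        return lie_single(params, records[0].dv_vdw, records[0].dv_el)
    v = np.array([r.dv_vdw for r in records], dtype=float)
    e = np.array([r.dv_el for r in records], dtype=float)
    dg_i = params.alpha * v + params.beta * e
    w = boltzmann_weights(dg_i, params)
    return float(params.alpha * (w @ v) + params.beta * (w @ e))


def rmse(
    dg_calc: Mapping[str, float], dg_exp: Mapping[str, float]
) -> float:
    """Root-mean-square error between calculated and experimental ΔG."""
    if set(dg_calc) != set(dg_exp):
        raise ValidationError("dg_calc and dg_exp must cover the same ligands")
    if not dg_calc:
        raise ValidationError("need at least one ligand")
    err = np.array([dg_calc[k] - dg_exp[k] for k in dg_calc], dtype=float)
    return float(np.sqrt(np.mean(err**2)))


def _dataset_arrays(
    dataset: LIEDataset,
) -> tuple[list[str], list[np.ndarray], list[np.ndarray], np.ndarray]:
    ligs = sorted(dataset.ligands)
    V = [
        np.array([r.dv_vdw for r in dataset.ligands[l].records], dtype=float)
        for l in ligs
    ]
    E = [
        np.array([r.dv_el for r in dataset.ligands[l].records], dtype=float)
        for l in ligs
    ]
    exp = np.array([dataset.ligands[l].dg_exp for l in ligs], dtype=float)
    return ligs, V, E, exp


def _grid_search(
    V: list[np.ndarray],
    E: list[np.ndarray],
    exp: np.ndarray,
    kT: float,
    bounds: tuple[float, float],
    step: float,
) -> tuple[float, float]:
    """Vectorised coarse scan of the RMSE surface over an (α, β) grid."""
    lo, hi = bounds
    axis = np.arange(lo, hi + step / 2, step)
    A, B = np.meshgrid(axis, axis, indexing="ij")
    A = A.ravel()
    B = B.ravel()
    sse = np.zeros_like(A)
    for v, e, y in zip(V, E, exp):
        D = np.outer(A, v) + np.outer(B, e)  # (grid, n_sims) ΔG_i surface
        D -= D.min(axis=1, keepdims=True)
        W = np.exp(-D / kT)
        W /= W.sum(axis=1, keepdims=True)
        dg = A * (W * v).sum(axis=1) + B * (W * e).sum(axis=1)
        sse += (dg - y) ** 2
    best = int(np.argmin(sse))
    return float(A[best]), float(B[best])


def calibrate(
    dataset: LIEDataset,
    template: LIEParameters | None = None,
    bounds: tuple[float, float] = (-1.0, 1.0),
    grid_step: float = 0.01,
) -> ModelReport:
    """Fit (α, β) by minimising the RMSE of weighted LIE predictions.

    The Boltzmann weights are recomputed from the candidate parameters at
    every objective evaluation, so the fit is self-consistent in (α, β).
    The optimizer is deterministic: a coarse grid over ``bounds`` followed
    by Nelder–Mead refinement to 1e-6 on the parameters.
    """
    if dataset.n_ligands < 2:
        raise ValidationError("calibration needs at least 2 ligands")
    if template is None:
        template = LIEParameters()
    kT = template.kT
    ligs, V, E, exp = _dataset_arrays(dataset)

    def predict(alpha: float, beta: float) -> np.ndarray:
        out = np.empty(len(ligs))
        for i, (v, e) in enumerate(zip(V, E)):
            d = alpha * v + beta * e
            z = -(d - d.min()) / kT
            w = np.exp(z)
            w /= w.sum()
            out[i] = alpha * (w @ v) + beta * (w @ e)
        return out

    def objective(x: np.ndarray) -> float:
        res = predict(x[0], x[1]) - exp
        val = float(np.sqrt(np.mean(res**2)))
        if not np.isfinite(val):
            raise ValidationError("non-finite calibration objective")
        return val

    x0 = np.array(_grid_search(V, E, exp, kT, bounds, grid_step))
    opt = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    alpha, beta = float(opt.x[0]), float(opt.x[1])
    params = replace(template, alpha=alpha, beta=beta)
    dg_calc = {l: lie_weighted(params, dataset.ligands[l].records) for l in ligs}
    weights = {
        l: tuple(
            boltzmann_weights(
                [
                    lie_single(params, r.dv_vdw, r.dv_el)
                    for r in dataset.ligands[l].records
                ],
                params,
            )
        )
        for l in ligs
    }
    return ModelReport(
        alpha=alpha,
        beta=beta,
        rmse=rmse(dg_calc, {l: dataset.ligands[l].dg_exp for l in ligs}),
        temperature=template.temperature,
        dg_calc=dg_calc,
        weights=weights,
    )


def sdep_loo(
    dataset: LIEDataset,
    template: LIEParameters | None = None,
    bounds: tuple[float, float] = (-1.0, 1.0),
    grid_step: float = 0.01,
) -> LOOResult:
    """Leave-one-out cross-validation of the calibrated model.

    Each ligand is held out in turn, the model recalibrated on the rest and
    the held-out affinity predicted; SDEP is the root-mean-square of the N
    prediction errors.  The per-fold parameter table is returned alongside.
    """
    if dataset.n_ligands < 3:
        raise ValidationError("leave-one-out needs at least 3 ligands")
    if template is None:
        template = LIEParameters()
    rows = []
    sq_errors = []
    for lig in sorted(dataset.ligands):
        rest = dataset.subset(k for k in dataset.ligands if k != lig)
        fold = calibrate(rest, template, bounds, grid_step)
        pred = lie_weighted(fold.parameters(), dataset.ligands[lig].records)
        exp_val = dataset.ligands[lig].dg_exp
        sq_errors.append((pred - exp_val) ** 2)
        rows.append(
            {
                "ligand_id": lig,
                "alpha": fold.alpha,
                "beta": fold.beta,
                "rmse_fit": fold.rmse,
                "dg_pred": pred,
                "dg_exp": exp_val,
                "error": pred - exp_val,
            }
        )
    sdep = float(np.sqrt(np.mean(sq_errors)))
    return LOOResult(sdep=sdep, folds=pd.DataFrame(rows))
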