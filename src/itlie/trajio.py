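"""Readers, writers and validated containers for interaction-energy data.

The bound-state input of the LIE workflow is a per-frame time series of the
ligand–surroundings electrostatic and van der Waals interaction energies, as
exported by GROMACS analysis tools in the plain-text XVG dialect ('#' comment
and '@' directive lines followed by whitespace-separated numeric columns).
Free-state averages and experimental binding free energies arrive as CSV
tables.  All energies are in kJ mol⁻¹ and times in ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnergyTrajectory",
    "FreeStateAverages",
    "ExperimentalAffinity",
    "XVGParseError",
    "ValidationError",
    "read_energy_xvg",
    "write_energy_xvg",
    "read_dataset_table",
    "DEFAULT_DT",
    "UNIFORM_TOL",
]

#: default sampling interval (ps) when it cannot be inferred from the data
DEFAULT_DT = 2.0
#: tolerance (ps) on deviations from uniform frame spacing
UNIFORM_TOL = 1e-6


class XVGParseError(ValueError):
    """A data line of an XVG file could not be parsed."""


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


@dataclass(frozen=True)
class EnergyTrajectory:
    """Two-channel interaction-energy time series for one bound-state run.

    Parameters
    ----------
    times
        Frame times in ps, strictly increasing and uniformly spaced.
    v_el
        Electrostatic ligand–surroundings energy per frame (kJ mol⁻¹).
    v_vdw
        Van der Waals ligand–surroundings energy per frame (kJ mol⁻¹).
    label
        Free-form simulation identifier.
    """

    times: np.ndarray
    v_el: np.ndarray
    v_vdw: np.ndarray
    label: str = ""
    dt: float = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        v_el = np.asarray(self.v_el, dtype=float)
        v_vdw = np.asarray(self.v_vdw, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValidationError("trajectory must contain at least one frame")
        if v_el.shape != times.shape or v_vdw.shape != times.shape:
            raise ValidationError(
                "energy channels must have the same length as the time axis"
            )
        for name, arr in (("times", times), ("v_el", v_el), ("v_vdw", v_vdw)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name}")
        if times.size >= 2:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValidationError("frame times must be strictly increasing")
            dt = float(steps[0])
            if np.any(np.abs(steps - dt) > UNIFORM_TOL):
                raise ValidationError(
                    "frame times are not uniformly spaced within "
                    f"{UNIFORM_TOL} ps (dt={dt})"
                )
        else:
            dt = DEFAULT_DT
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "v_el", v_el)
        object.__setattr__(self, "v_vdw", v_vdw)
        object.__setattr__(self, "dt", dt)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        """End of the covered time range: last frame time plus one interval."""
        return float(self.times[-1] + self.dt)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class FreeStateAverages:
    """Mean ligand–solvent energies of the unbound ligand (kJ mol⁻¹)."""

    ligand_id: str
    v_el_free: float
    v_vdw_free: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v_el_free) and math.isfinite(self.v_vdw_free)):
            raise ValidationError(f"non-finite free-state average for {self.ligand_id}")


@dataclass(frozen=True)
class ExperimentalAffinity:
    """Experimental binding free energy of one ligand (kJ mol⁻¹)."""

    ligand_id: str
    dg_exp: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dg_exp):
            raise ValidationError(f"non-finite dg_exp for {self.ligand_id}")


def read_energy_xvg(
    path: str | Path,
    columns: Sequence[int] = (0, 1, 2),
    label: str | None = None,
) -> EnergyTrajectory:
    """Read a two-channel energy trajectory from an XVG-style text file.

    ``columns`` maps file columns to (time, electrostatic, van der Waals);
    the default assumes time, V_el, V_vdW in that order.  GROMACS energy
    extraction column order depends on how the tool was invoked, hence the
    mapping is configurable.  '#' and '@' lines and blank lines are skipped.
    """
    path = Path(path)
    t_col, el_col, vdw_col = columns
    need = max(columns) + 1
    times: list[float] = []
    v_el: list[float] = []
    v_vdw: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            fields = line.split()
            if len(fields) < need:
                raise XVGParseError(
                    f"{path.name}: line {lineno}: expected at least {need} "
                    f"columns, found {len(fields)}"
                )
            try:
                times.append(float(fields[t_col]))
                v_el.append(float(fields[el_col]))
                v_vdw.append(float(fields[vdw_col]))
            except ValueError as exc:
                raise XVGParseError(
                    f"{path.name}: line {lineno}: non-numeric value ({exc})"
                ) from None
    if len(times) < 2:
        raise ValidationError(
            f"{path.name}: need at least 2 data frames, found {len(times)}"
        )
    return EnergyTrajectory(
        times=np.asarray(times),
        v_el=np.asarray(v_el),
        v_vdw=np.asarray(v_vdw),
        label=path.stem if label is None else label,
    )


def write_energy_xvg(traj: EnergyTrajectory, path: str | Path) -> None:
    """Write a trajectory as XVG text; round-trips through ``read_energy_xvg``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# interaction-energy trajectory {traj.label}\n")
        fh.write('@    title "Ligand-surroundings interaction energies"\n')
        fh.write('@    xaxis  label "Time (ps)"\n')
        fh.write('@    yaxis  label "Energy (kJ mol\\S-1\\N)"\n')
        fh.write('@ s0 legend "V el"\n@ s1 legend "V vdW"\n')
        for t, e, v in zip(traj.times, traj.v_el, traj.v_vdw):
            fh.write(f"{t:.10g} {e:.10g} {v:.10g}\n")


def read_dataset_table(
    path: str | Path,
) -> tuple[list[ExperimentalAffinity], list[FreeStateAverages]]:
    """Read the per-ligand calibration table.

    The CSV must carry columns ``ligand_id``, ``dg_exp``, ``v_el_free`` and
    ``v_vdw_free``; one row per ligand, ids unique.  Returns parallel lists of
    experimental affinities and free-state averages (same order as the file).
    """
    df = pd.read_csv(path)
    required = {"ligand_id", "dg_exp", "v_el_free", "v_vdw_free"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    ids = df["ligand_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate ligand_id(s) {dupes}")
    affinities = [
        ExperimentalAffinity(ligand_id=str(r.ligand_id), dg_exp=float(r.dg_exp))
        for r in df.itertuples()
    ]
    free = [
        FreeStateAverages(
            ligand_id=str(r.ligand_id),
            v_el_free=float(r.v_el_free),
            v_vdw_free=float(r.v_vdw_free),
        )
        for r in df.itertuples()
    ]
    return affinities, free
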