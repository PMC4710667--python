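"""Window-selection protocol, span averaging and simulation-time accounting.

Once stationary windows are known, the averaging span for one simulation is
chosen by a three-step protocol parameterised by a minimal window length L:

1. pick the earliest window of length >= L;
2. truncate it to its first L ps ("filtered" mode; the "filter_ext" variant
   skips this step and keeps the full window);
3. if no window reaches L, fall back to the longest available window and
   flag the selection (a warning is logged).

Average interaction energies are then taken from the *raw* energies within
the span, and the bound-minus-free differences feed the LIE model.  The
"used" simulation time of a run is the time from the start of production to
the end of the chosen span; the "corrected" time charges the full run length
whenever the fallback was triggered, since only a complete run can prove
that no window of length L exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .detect import FilterSettings, Interval, detect_transitions
from .trajio import EnergyTrajectory, FreeStateAverages, ValidationError

__all__ = [
    "MODE_FILTERED",
    "MODE_FILTER_EXT",
    "MODE_UNFILTERED",
    "SpanSelection",
    "SimulationRecord",
    "EfficiencyStats",
    "select_span",
    "unfiltered_span",
    "average_over_span",
    "build_record",
    "efficiency_stats",
    "record_to_dict",
    "record_from_dict",
]

logger = logging.getLogger("itlie")

MODE_FILTERED = "filtered"
MODE_FILTER_EXT = "filter_ext"
MODE_UNFILTERED = "unfiltered"
_MODES = (MODE_FILTERED, MODE_FILTER_EXT, MODE_UNFILTERED)

Mode = Literal["filtered", "filter_ext", "unfiltered"]


@dataclass(frozen=True)
class SpanSelection:
    """Averaging span chosen by the protocol, half-open ``[t_start, t_end)``."""

    t_start: float
    t_end: float
    mode: Mode
    L: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not self.t_end > self.t_start:
            raise ValidationError("span must have positive length")
        if not self.L > 0:
            raise ValidationError("L must be positive")
        if self.mode == MODE_FILTERED and not self.fallback:
            if abs((self.t_end - self.t_start) - self.L) > 1e-9:
                raise ValidationError(
                    "filtered span without fallback must have length L"
                )

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SimulationRecord:
    """Bound-minus-free average energy differences for one simulation.

    ``dv_el`` and ``dv_vdw`` are the ΔV terms of the LIE equation
    (kJ mol⁻¹).  ``selection`` and the time accounting are present when the
    record came from the span-selection workflow; synthetic records used for
    calibration experiments may omit them.
    """

    ligand_id: str
    sim_id: str
    dv_el: float
    dv_vdw: float
    selection: SpanSelection | None = None
    used_time: float | None = None
    corrected_time: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dv_el) and np.isfinite(self.dv_vdw)):
            raise ValidationError(f"non-finite ΔV for {self.ligand_id}/{self.sim_id}")
        if self.selection is not None:
            if self.used_time is None or self.corrected_time is None:
                raise ValidationError("records with a selection need time accounting")
            if self.corrected_time < self.used_time - 1e-9:
                raise ValidationError("corrected_time must be >= used_time")


@dataclass(frozen=True)
class EfficiencyStats:
    """Ensemble summary of simulation-time consumption."""

    n: int
    L: float
    mode: str
    mean_used: float
    mean_corrected: float
    fraction_with_window: float


def _validate_windows(windows: Sequence[Interval]) -> list[Interval]:
    if not windows:
        raise ValidationError("window list is empty")
    out = [(float(a), float(b)) for a, b in windows]
    prev_end = -np.inf
    for a, b in out:
        if b <= a:
            raise ValidationError(f"degenerate window ({a}, {b})")
        if a < prev_end:
            raise ValidationError("windows must be sorted and disjoint")
        prev_end = b
    return out


def select_span(
    windows: Sequence[Interval], L: float, mode: Mode = MODE_FILTERED
) -> SpanSelection:
    """Apply protocol steps (1)-(3) to a list of stationary windows.

    "filtered": earliest window of length >= L, truncated to its first L ps.
    "filter_ext": the same window, full extent.
    Fallback (no window reaches L): the longest window in full, earliest on
    ties, with the fallback flag set and a warning logged.
    """
    if mode not in (MODE_FILTERED, MODE_FILTER_EXT):
        raise ValidationError(f"select_span mode must be filtered/filter_ext, got {mode!r}")
    if not L > 0:
        raise ValidationError("L must be positive")
    wins = _validate_windows(windows)
    for a, b in wins:
        if b - a >= L - 1e-9:
            if mode == MODE_FILTERED:
                return SpanSelection(a, a + L, mode, L)
            return SpanSelection(a, b, mode, L)
    # step (3): longest window, earliest wins on ties
    best = max(wins, key=lambda iv: iv[1] - iv[0])
    logger.warning(
        "no stationary window of length >= %g ps; falling back to longest "
        "window (%g-%g ps)",
        L,
        best[0],
        best[1],
    )
    return SpanSelection(best[0], best[1], mode, L, fallback=True)


def unfiltered_span(
    L: float, t_start: float = 0.0, t_total: float | None = None
) -> SpanSelection:
    """Baseline span covering the first L ps of production, no filtering."""
    if not L > 0:
        raise ValidationError("L must be positive")
    if t_total is not None and L > t_total + 1e-9:
        raise ValidationError(f"L={L} ps exceeds trajectory length {t_total} ps")
    return SpanSelection(t_start, t_start + L, MODE_UNFILTERED, L)


def average_over_span(
    traj: EnergyTrajectory, span: SpanSelection
) -> tuple[float, float]:
    """Arithmetic means of the raw energies over frames in ``[t_start, t_end)``."""
    mask = (traj.times >= span.t_start - 1e-9) & (traj.times < span.t_end - 1e-9)
    if not mask.any():
        raise ValidationError(
            f"span ({span.t_start}, {span.t_end}) contains no frames"
        )
    return float(traj.v_el[mask].mean()), float(traj.v_vdw[mask].mean())


def build_record(
    traj: EnergyTrajectory,
    free: FreeStateAverages,
    L: float,
    mode: Mode = MODE_FILTERED,
    settings: FilterSettings | None = None,
    sim_id: str | None = None,
) -> SimulationRecord:
    """Full per-simulation workflow: detect, select, average, difference.

    In "unfiltered" mode the detector is skipped and the span is the first
    L ps of the trajectory.  ``used_time`` counts from the first production
    frame to the end of the chosen span; ``corrected_time`` equals the full
    trajectory length when the fallback was triggered.
    """
    if mode == MODE_UNFILTERED:
        span = unfiltered_span(L, t_start=traj.t_start, t_total=traj.duration)
    else:
        tset = detect_transitions(traj, settings)
        span = select_span(tset.windows, L, mode)
    mean_el, mean_vdw = average_over_span(traj, span)
    used = span.t_end - traj.t_start
    corrected = traj.duration if span.fallback else used
    return SimulationRecord(
        ligand_id=free.ligand_id,
        sim_id=traj.label if sim_id is None else sim_id,
        dv_el=mean_el - free.v_el_free,
        dv_vdw=mean_vdw - free.v_vdw_free,
        selection=span,
        used_time=used,
        corrected_time=corrected,
    )


def efficiency_stats(records: Iterable[SimulationRecord]) -> EfficiencyStats:
    """Mean used/corrected times and the fraction of runs with a window >= L."""
    recs = list(records)
    if not recs:
        raise ValidationError("no records")
    sels = [r.selection for r in recs]
    if any(s is None for s in sels):
        raise ValidationError("all records need a span selection for accounting")
    Ls = {s.L for s in sels}
    modes = {s.mode for s in sels}
    if len(Ls) != 1 or len(modes) != 1:
        raise ValidationError(
            f"records mix L values {sorted(Ls)} or modes {sorted(modes)}"
        )
    n = len(recs)
    n_fallback = sum(1 for s in sels if s.fallback)
    return EfficiencyStats(
        n=n,
        L=Ls.pop(),
        mode=modes.pop(),
        mean_used=float(np.mean([r.used_time for r in recs])),
        mean_corrected=float(np.mean([r.corrected_time for r in recs])),
        fraction_with_window=1.0 - n_fallback / n,
    )


def record_to_dict(record: SimulationRecord) -> dict:
    d = {
        "ligand_id": record.ligand_id,
        "sim_id": record.sim_id,
        "dv_el": record.dv_el,
        "dv_vdw": record.dv_vdw,
    }
    if record.selection is not None:
        s = record.selection
        d["selection"] = {
            "t_start": s.t_start,
            "t_end": s.t_end,
            "mode": s.mode,
            "L": s.L,
            "fallback": s.fallback,
        }
        d["used_time"] = record.used_time
        d["corrected_time"] = record.corrected_time
    return d


def record_from_dict(d: dict) -> SimulationRecord:
    selection = None
    if "selection" in d and d["selection"] is not None:
        selection = SpanSelection(**d["selection"])
    return SimulationRecord(
        ligand_id=d["ligand_id"],
        sim_id=d["sim_id"],
        dv_el=float(d["dv_el"]),
        dv_vdw=float(d["dv_vdw"]),
        selection=selection,
        used_time=d.get("used_time"),
        corrected_time=d.get("corrected_time"),
    )
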