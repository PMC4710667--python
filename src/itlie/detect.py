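"""Detection of configurational transitions in energy trajectories.

A configurational transition of a protein–ligand complex (a change of ligand
orientation, of active-site shape, or both) shows up as a rapid shift in the
mean ligand–surroundings interaction energies.  The detector follows the
energies rather than structural observables:

1. low-pass filter each channel by Fourier truncation, removing the
   high-frequency thermal fluctuations;
2. fit a low-degree smoothing spline to the filtered signal;
3. differentiate the spline; frames where the absolute gradient exceeds a
   cutoff (in either channel) are flagged as transitional.

Maximal runs of transitional frames become transition intervals; the
complementary intervals are the stationary windows over which interaction
energies may safely be averaged.

Defaults: 15 retained Fourier elements, spline degree 1 with smoothing
factor 999 (kJ mol⁻¹)², gradient cutoff 0.2 kJ mol⁻¹ ps⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import fft as _fft
from scipy.interpolate import UnivariateSpline

from .trajio import EnergyTrajectory, ValidationError

__all__ = [
    "FilterSettings",
    "TransitionSet",
    "lowpass_fourier",
    "fit_smoothing_spline",
    "spline_gradient",
    "detect_transitions",
    "detection_diagnostics",
]

logger = logging.getLogger("itlie")

Interval = tuple[float, float]


@dataclass(frozen=True)
class FilterSettings:
    """Tunable knobs of the transition detector.

    n_fourier
        Number of leading low-frequency Fourier coefficients retained
        (the DC term counts; index 0..n_fourier-1 on the one-sided spectrum).
    spline_degree
        Polynomial degree k of the smoothing spline.
    spline_smooth
        Positive smoothing factor s: upper bound on the spline's sum of
        squared residuals, units (kJ mol⁻¹)².
    gradient_cutoff
        Threshold on |dV/dt| in kJ mol⁻¹ ps⁻¹ above which a frame is
        considered transitional.
    channel_rule
        "union": a frame is transitional if either channel exceeds the
        cutoff; "intersection": both channels must exceed it.
    extension
        Boundary handling of the Fourier low-pass; see ``lowpass_fourier``.
    """

    n_fourier: int = 15
    spline_degree: int = 1
    spline_smooth: float = 999.0
    gradient_cutoff: float = 0.2
    channel_rule: Literal["union", "intersection"] = "union"
    extension: Literal["mirror", "periodic"] = "mirror"

    def __post_init__(self) -> None:
        if self.n_fourier < 1:
            raise ValueError("n_fourier must be >= 1")
        if self.spline_degree < 1:
            raise ValueError("spline_degree must be >= 1")
        if not self.spline_smooth > 0:
            raise ValueError("spline_smooth must be positive")
        if not self.gradient_cutoff > 0:
            raise ValueError("gradient_cutoff must be positive")
        if self.channel_rule not in ("union", "intersection"):
            raise ValueError(f"unknown channel_rule {self.channel_rule!r}")
        if self.extension not in ("mirror", "periodic"):
            raise ValueError(f"unknown extension {self.extension!r}")


@dataclass(frozen=True)
class TransitionSet:
    """Detected transitions and the complementary stationary windows.

    All intervals are half-open ``[a, b)`` on the trajectory's own time axis;
    ``transitions`` and ``windows`` interleave and tile ``[t_start, t_end)``
    exactly.
    """

    transitions: tuple[Interval, ...]
    windows: tuple[Interval, ...]
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        merged = sorted(self.transitions + self.windows)
        if not merged:
            raise ValidationError("empty transition set")
        cursor = self.t_start
        for a, b in merged:
            if b <= a:
                raise ValidationError(f"degenerate interval ({a}, {b})")
            if abs(a - cursor) > 1e-9:
                raise ValidationError(
                    f"intervals do not tile the time range: gap at {cursor}"
                )
            cursor = b
        if abs(cursor - self.t_end) > 1e-9:
            raise ValidationError("intervals do not reach the trajectory end")

    @property
    def total_transition_time(self) -> float:
        return float(sum(b - a for a, b in self.transitions))

    def to_dict(self) -> dict:
        return {
            "transitions": [list(iv) for iv in self.transitions],
            "windows": [list(iv) for iv in self.windows],
            "t_start": self.t_start,
            "t_end": self.t_end,
        }


def lowpass_fourier(
    series: Sequence[float] | np.ndarray,
    n_fourier: int = 15,
    extension: Literal["mirror", "periodic"] = "periodic",
) -> np.ndarray:
    """Low-pass filter a real series by truncating its Fourier spectrum.

    ``extension="periodic"`` operates directly on the one-sided spectrum of
    the series: coefficients with index >= ``n_fourier`` are zeroed and the
    real part of the inverse transform is returned.  This treats the series
    as periodic, so a level difference between its two ends behaves like a
    step at the seam and rings into both boundaries.

    ``extension="mirror"`` first reflects the series about its last point
    (even extension), which is continuous at both seams, then truncates the
    doubled spectrum at the same physical cutoff frequency
    (2·n_fourier − 1 bins of the doubled series correspond to n_fourier bins
    of the original).  This is the variant the transition detector uses.

    The DC coefficient is always retained, so the series mean is preserved.
    Series shorter than ``2 * n_fourier`` frames are returned unchanged with
    a logged warning: truncation would not remove anything meaningful.
    """
    x = np.asarray(series, dtype=float)
    if n_fourier < 1:
        raise ValueError("n_fourier must be >= 1")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be one-dimensional with >= 2 samples")
    if x.size < 2 * n_fourier:
        logger.warning(
            "series of %d frames shorter than 2*n_fourier=%d; low-pass is a no-op",
            x.size,
            2 * n_fourier,
        )
        return x.copy()
    if extension == "periodic":
        spec = _fft.rfft(x)
        spec[n_fourier:] = 0.0
        return _fft.irfft(spec, n=x.size)
    if extension == "mirror":
        ext = np.concatenate([x, x[::-1]])
        spec = _fft.rfft(ext)
        keep = 2 * n_fourier - 1  # same passband as n_fourier bins on x
        spec[keep:] = 0.0
        return _fft.irfft(spec, n=ext.size)[: x.size]
    raise ValueError(f"unknown extension {extension!r}")


def fit_smoothing_spline(
    times: np.ndarray,
    values: np.ndarray,
    degree: int = 1,
    smooth: float = 999.0,
) -> np.ndarray:
    """Fit a smoothing spline and evaluate it at the input times.

    The number of knots is chosen so that the sum of squared residuals does
    not exceed ``smooth``; with a very large factor the fit degenerates to
    the single least-squares polynomial of the requested degree.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < degree + 1:
        raise ValidationError(
            f"need at least degree+1={degree + 1} points, got {times.size}"
        )
    spl = UnivariateSpline(times, values, k=degree, s=smooth)
    return np.asarray(spl(times), dtype=float)


def spline_gradient(values: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference gradient: central inside, one-sided at the ends."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 points for a gradient")
    return np.gradient(values, dt)


def _channel_mask(
    times: np.ndarray, values: np.ndarray, dt: float, settings: FilterSettings
) -> np.ndarray:
    filtered = lowpass_fourier(values, settings.n_fourier, settings.extension)
    fitted = fit_smoothing_spline(
        times, filtered, settings.spline_degree, settings.spline_smooth
    )
    grad = spline_gradient(fitted, dt)
    return np.abs(grad) > settings.gradient_cutoff


def _runs_to_intervals(
    mask: np.ndarray, times: np.ndarray, dt: float
) -> list[Interval]:
    """Convert maximal runs of True frames to half-open time intervals."""
    intervals: list[Interval] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return intervals
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for i, j in zip(starts, ends):
        intervals.append((float(times[i]), float(times[j] + dt)))
    return intervals


def detect_transitions(
    traj: EnergyTrajectory, settings: FilterSettings | None = None
) -> TransitionSet:
    """Run the full detection pipeline on both energy channels.

    Each channel passes independently through low-pass filter, smoothing
    spline and gradient; a frame is transitional when the absolute gradient
    exceeds the cutoff in either channel (union rule; an intersection rule
    is available through ``FilterSettings.channel_rule``).  A trajectory
    with no transitional frame yields a single window spanning the whole
    time range.
    """
    if settings is None:
        settings = FilterSettings()
    if traj.n_frames < 4:
        raise ValidationError("need at least 4 frames to detect transitions")
    mask_el = _channel_mask(traj.times, traj.v_el, traj.dt, settings)
    mask_vdw = _channel_mask(traj.times, traj.v_vdw, traj.dt, settings)
    if settings.channel_rule == "union":
        mask = mask_el | mask_vdw
    else:
        mask = mask_el & mask_vdw

    t0, t_end = traj.t_start, traj.t_end
    transitions = _runs_to_intervals(mask, traj.times, traj.dt)
    windows: list[Interval] = []
    cursor = t0
    for a, b in transitions:
        if a > cursor:
            windows.append((cursor, a))
        cursor = b
    if cursor < t_end:
        windows.append((cursor, t_end))
    return TransitionSet(
        transitions=tuple(transitions),
        windows=tuple(windows),
        t_start=t0,
        t_end=t_end,
    )


def detection_diagnostics(
    traj: EnergyTrajectory, settings: FilterSettings | None = None
) -> pd.DataFrame:
    """Per-frame table of every pipeline stage, for plotting or inspection.

    Columns: time, raw/filtered/spline/gradient for both channels, and the
    final transitional flag.
    """
    if settings is None:
        settings = FilterSettings()
    out = {"time": traj.times}
    masks = {}
    for name, values in (("el", traj.v_el), ("vdw", traj.v_vdw)):
        filtered = lowpass_fourier(values, settings.n_fourier, settings.extension)
        fitted = fit_smoothing_spline(
            traj.times, filtered, settings.spline_degree, settings.spline_smooth
        )
        grad = spline_gradient(fitted, traj.dt)
        out[f"raw_{name}"] = values
        out[f"filtered_{name}"] = filtered
        out[f"spline_{name}"] = fitted
        out[f"gradient_{name}"] = grad
        masks[name] = np.abs(grad) > settings.gradient_cutoff
    if settings.channel_rule == "union":
        out["transitional"] = masks["el"] | masks["vdw"]
    else:
        out["transitional"] = masks["el"] & masks["vdw"]
    return pd.DataFrame(out)
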