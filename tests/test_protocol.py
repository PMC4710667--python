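"""Window-selection protocol, span averaging, time accounting."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itlie import (
    EnergyTrajectory,
    FreeStateAverages,
    SimulationRecord,
    SpanSelection,
    ValidationError,
    average_over_span,
    build_record,
    efficiency_stats,
    select_span,
    unfiltered_span,
)
from conftest import make_step_trajectory

FIG1_WINDOWS = [(0.0, 230.0), (500.0, 1000.0)]


# ------------------------------------------------------------ select_span
@pytest.mark.parametrize(
    "L, mode, expected",
    [
        (200.0, "filtered", (0.0, 200.0)),
        (400.0, "filtered", (500.0, 900.0)),
        (400.0, "filter_ext", (500.0, 1000.0)),
    ],
)
def test_select_span_worked_example(L, mode, expected):
    sel = select_span(FIG1_WINDOWS, L, mode)
    assert not sel.fallback
    assert (sel.t_start, sel.t_end) == expected


def test_select_span_L_exceeding_all_windows_falls_back():
    # the longest window (500-1000 ps) is shorter than L=600 ps
    sel = select_span(FIG1_WINDOWS, 600.0, "filtered")
    assert sel.fallback
    assert (sel.t_start, sel.t_end) == (500.0, 1000.0)


def test_select_span_fallback_longest_earliest(caplog):
    with caplog.at_level(logging.WARNING, logger="itlie"):
        sel = select_span([(0.0, 150.0), (300.0, 380.0)], 200.0, "filtered")
    assert sel.fallback
    assert (sel.t_start, sel.t_end) == (0.0, 150.0)
    assert any("falling back" in r.message for r in caplog.records)
    # tie on length: earliest window wins
    tie = select_span([(0.0, 100.0), (300.0, 400.0)], 200.0, "filtered")
    assert (tie.t_start, tie.t_end) == (0.0, 100.0)


def test_select_span_input_validation():
    with pytest.raises(ValidationError):
        select_span([], 200.0)
    with pytest.raises(ValidationError):
        select_span(FIG1_WINDOWS, -1.0)
    with pytest.raises(ValidationError):
        select_span([(0.0, 100.0), (50.0, 200.0)], 10.0)  # overlapping
    with pytest.raises(ValidationError):
        select_span(FIG1_WINDOWS, 100.0, "unfiltered")


def test_select_span_pure_and_idempotent():
    first = select_span(FIG1_WINDOWS, 400.0, "filtered")
    second = select_span(FIG1_WINDOWS, 400.0, "filtered")
    assert first == second


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(min_value=0, max_value=900),
            st.floats(min_value=10, max_value=400),
        ),
        min_size=1,
        max_size=10,
    ),
    L=st.sampled_from([50.0, 100.0, 200.0, 400.0, 600.0]),
)
def test_select_span_matches_exhaustive_search(data, L):
    """Earliest-window-with-length>=L agrees with brute-force enumeration."""
    # build sorted, disjoint windows from (gap, length) pairs
    windows = []
    cursor = 0.0
    for gap, length in data:
        start = cursor + gap
        windows.append((start, start + length))
        cursor = start + length
    sel = select_span(windows, L, "filtered")
    eligible = [w for w in windows if w[1] - w[0] >= L - 1e-9]
    if eligible:
        assert not sel.fallback
        assert sel.t_start == eligible[0][0]
        assert sel.t_end == pytest.approx(eligible[0][0] + L)
    else:
        assert sel.fallback
        longest = max(w[1] - w[0] for w in windows)
        assert sel.t_end - sel.t_start == pytest.approx(longest)


# -------------------------------------------------------- unfiltered_span
def test_unfiltered_span_examples():
    assert (unfiltered_span(200.0).t_start, unfiltered_span(200.0).t_end) == (0.0, 200.0)
    ns = unfiltered_span(1000.0, t_total=1000.0)
    assert (ns.t_start, ns.t_end) == (0.0, 1000.0)
    with pytest.raises(ValidationError):
        unfiltered_span(0.0)
    with pytest.raises(ValidationError):
        unfiltered_span(1200.0, t_total=1000.0)


# ------------------------------------------------------- average_over_span
def test_average_over_span_constant(constant_trajectory):
    span = SpanSelection(100.0, 400.0, "filter_ext", L=200.0)
    assert average_over_span(constant_trajectory, span) == (-100.0, -50.0)


def test_average_over_span_two_level_and_oracle():
    times = np.arange(500) * 2.0
    v_el = np.where(times < 500, -160.0, -120.0)
    v_vdw = np.full(500, -80.0)
    traj = EnergyTrajectory(times=times, v_el=v_el, v_vdw=v_vdw)
    span = SpanSelection(500.0, 900.0, "filter_ext", L=400.0)
    mean_el, _ = average_over_span(traj, span)
    assert mean_el == -120.0
    # brute-force summation oracle on a noisy trajectory, span (0, 200)
    rng = np.random.default_rng(42)
    noisy = EnergyTrajectory(
        times=times, v_el=v_el + rng.normal(0, 5, 500), v_vdw=v_vdw
    )
    span0 = SpanSelection(0.0, 200.0, "filtered", L=200.0)
    mean_el, mean_vdw = average_over_span(noisy, span0)
    assert mean_el == pytest.approx(sum(noisy.v_el[:100]) / 100, abs=1e-12)
    assert mean_vdw == pytest.approx(-80.0)


def test_average_over_empty_span_rejected(constant_trajectory):
    span = SpanSelection(2000.0, 2200.0, "filtered", L=200.0)
    with pytest.raises(ValidationError):
        average_over_span(constant_trajectory, span)


# ------------------------------------------------------------ build_record
def test_build_record_zero_difference(constant_trajectory):
    free = FreeStateAverages("lig1", v_el_free=-100.0, v_vdw_free=-50.0)
    rec = build_record(constant_trajectory, free, L=200.0, mode="filtered")
    assert rec.dv_el == pytest.approx(0.0)
    assert rec.dv_vdw == pytest.approx(0.0)
    assert rec.used_time == 200.0
    assert rec.corrected_time == 200.0


def test_build_record_fallback_charges_full_run():
    # three ramps leave no stationary window of 400 ps in a 1 ns run
    from itlie import StateSegment, TrajectorySpec, gen_trajectory

    spec = TrajectorySpec(
        segments=(
            StateSegment(220.0, -160.0, -80.0),
            StateSegment(220.0, -120.0, -80.0),
            StateSegment(230.0, -170.0, -80.0),
            StateSegment(270.0, -130.0, -80.0),
        ),
        transition_width=20.0,
        noise_sd=2.0,
        seed=1,
    )
    traj, _ = gen_trajectory(spec)
    free = FreeStateAverages("lig1", v_el_free=0.0, v_vdw_free=0.0)
    rec = build_record(traj, free, L=400.0, mode="filtered")
    assert rec.selection.fallback
    assert rec.corrected_time == pytest.approx(traj.duration)
    assert rec.corrected_time == pytest.approx(1000.0)


def test_build_record_unfiltered(constant_trajectory):
    free = FreeStateAverages("lig1", v_el_free=0.0, v_vdw_free=0.0)
    rec = build_record(constant_trajectory, free, L=400.0, mode="unfiltered")
    assert rec.used_time == 400.0
    assert rec.dv_el == pytest.approx(-100.0)


# -------------------------------------------------------- efficiency_stats
def _record(used, corrected, fallback, L=200.0, mode="filtered"):
    # span of length exactly L ending at `used`, as the filtered protocol yields
    span = SpanSelection(used - L, used, mode, L=L, fallback=fallback)
    return SimulationRecord(
        "lig", f"s{used}", 0.0, 0.0, selection=span,
        used_time=used, corrected_time=corrected,
    )


def test_efficiency_stats_examples():
    fallback_rec = SimulationRecord(
        "lig", "s1", 0.0, 0.0,
        selection=SpanSelection(0.0, 150.0, "filtered", L=200.0, fallback=True),
        used_time=150.0, corrected_time=1000.0,
    )
    recs = [fallback_rec, _record(400.0, 400.0, fallback=False)]
    s = efficiency_stats(recs)
    assert s.mean_used == pytest.approx((150.0 + 400.0) / 2)
    assert s.mean_corrected == pytest.approx((1000.0 + 400.0) / 2)
    assert s.fraction_with_window == pytest.approx(0.5)
    assert s.mean_corrected >= s.mean_used


def test_efficiency_stats_no_fallback_equality():
    recs = [_record(200.0, 200.0, False), _record(400.0, 400.0, False)]
    s = efficiency_stats(recs)
    assert s.mean_used == s.mean_corrected == 300.0
    assert s.fraction_with_window == 1.0


def test_efficiency_stats_requires_homogeneous_inputs():
    with pytest.raises(ValidationError):
        efficiency_stats([])
    mixed = [_record(200.0, 200.0, False, L=200.0), _record(400.0, 400.0, False, L=400.0)]
    with pytest.raises(ValidationError, match="mix"):
        efficiency_stats(mixed)
    with pytest.raises(ValidationError):
        efficiency_stats([SimulationRecord("l", "s", 0.0, 0.0)])
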