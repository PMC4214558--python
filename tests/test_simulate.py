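import numpy as np
import pytest

from phosink.model_core import conservation_groups
from phosink.simulate import (
    find_signal_for_level,
    integrate,
    signal_response,
    steady_state,
)
from phosink.scans import multistationarity_scan

from conftest import draw_random_system


def test_no_signal_state_is_stationary(table1):
    """ka=0 from the all-unphosphorylated start: phospho levels stay zero."""
    params, totals = table1
    tc = integrate(params, totals, t_end=100.0, signal=0.0)
    for sp in ("HKp", "RR1p", "RR2p"):
        assert np.max(np.abs(tc[sp])) < 1e-9


def test_conservation_drift_over_long_integration(table1):
    params, totals = table1
    tc = integrate(params, totals, t_end=1e4, signal=2.0)
    for label, total, members in conservation_groups(tc.species, totals):
        sums = sum(tc[m] for m in members)
        assert np.max(np.abs(sums - total)) < 1e-6 * max(total, 1.0)
    assert np.min(tc.y) > -1e-12


def test_steady_state_zero_signal_unphosphorylated(table1):
    params, totals = table1
    st = steady_state(params, totals, 0.0)
    for sp in ("HKp", "RR1p", "RR2p"):
        assert st[sp] == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("ka", [1e-3, 1.0, 1e3])
def test_steady_state_agrees_with_long_integration(table1, ka):
    params, totals = table1
    st = steady_state(params, totals, ka)
    tc = integrate(params, totals, t_end=1e5, signal=ka,
                   rtol=1e-12, atol=1e-14)
    final = tc.y[:, -1]
    assert np.allclose(st.concentrations, final, rtol=1e-6, atol=1e-9)


def test_solver_tolerance_self_convergence(table1):
    params, totals = table1
    end1 = integrate(params, totals, t_end=200.0, signal=1.0,
                     rtol=1e-8, atol=1e-10).y[:, -1]
    end2 = integrate(params, totals, t_end=200.0, signal=1.0,
                     rtol=5e-9, atol=5e-11).y[:, -1]
    assert np.allclose(end1, end2, rtol=1e-6, atol=1e-10)


def test_steady_state_unique_from_many_starts(table1):
    """The bimolecular motif has a single steady state: every random
    start converges to the same fixed point."""
    params, totals = table1
    for sig in (0.5, 5.0):
        report = multistationarity_scan(params, totals, [sig],
                                        n_starts=50, seed=11)[0]
        assert report.count == 1
        ref = steady_state(params, totals, sig).concentrations
        assert np.allclose(report.states[0].concentrations, ref,
                           rtol=1e-6, atol=1e-8)


def test_find_signal_for_level_ninety_percent(table1):
    """Termination-protocol prerequisite: a ka exists that holds the
    output RR at 90% phosphorylation in steady state."""
    params, totals = table1
    ka90 = find_signal_for_level(params, totals, 0.9)
    st = steady_state(params, totals, ka90)
    assert st["RR2p"] / totals.RR2_tot == pytest.approx(0.9, abs=1e-4)


def test_find_signal_for_level_edge_cases(table1):
    params, totals = table1
    assert find_signal_for_level(params, totals, 0.0) == 0.0
    with pytest.raises(ValueError):
        find_signal_for_level(params, totals, 0.9999)  # above plateau


def test_drive_to_ninety_percent_timecourse(table1):
    params, totals = table1
    ka90 = find_signal_for_level(params, totals, 0.9)
    tc = integrate(params, totals, t_end=2000.0, signal=ka90)
    assert tc["RR2p"][-1] == pytest.approx(0.9 * totals.RR2_tot, rel=1e-3)


def test_continuation_matches_cold_starts(table1):
    """Warm-started curve equals independently solved points."""
    params, totals = table1
    grid = np.geomspace(0.01, 100, 15)
    curve = signal_response(params, totals, grid=grid)
    for i in (0, 7, 14):
        cold = steady_state(params, totals, grid[i])
        assert abs(cold["RR2p"] - curve.rr2p[i]) < 1e-8 * max(curve.rr2p[i], 1.0)


def test_curve_shapes_with_and_without_sink(table1):
    """Under the lumped first-order drive the sink-free response is
    concave throughout (hyperbolic) while the sink system's response is
    much smaller at low signal (thresholded)."""
    params, totals = table1
    curve_sink = signal_response(params, totals, "source")
    curve_none = signal_response(params, totals.replace(RR1_tot=0.0), "source")
    # hyperbolic: second divided difference (grid is log-spaced, so use
    # slopes, not raw second differences) never positive
    s, r = curve_none.signals, curve_none.rr2p
    slopes = np.diff(r) / np.diff(s)
    assert np.all(np.diff(slopes) < 1e-9 * max(abs(slopes).max(), 1.0))
    assert curve_sink.response_at(s[0]) < curve_none.response_at(s[0])


def test_sink_suppresses_subthreshold_output(table1, rng):
    """At sub-threshold signal the sink absorbs phosphoryl flux, so
    steady output is lower than in the sink-free system."""
    params, totals = table1
    for sig in (0.01, 0.1, 1.0):
        with_sink = steady_state(params, totals, sig)["RR2p"]
        no_sink = steady_state(params, totals.replace(RR1_tot=0.0), sig)["RR2p"]
        assert with_sink <= no_sink + 1e-9


def test_output_monotone_in_signal_random_draws(rng):
    for _ in range(5):
        params, totals = draw_random_system(rng)
        sigs = np.geomspace(1e-3, 1e3, 13)
        prev = None
        vals = []
        for s in sigs:
            st = steady_state(params, totals, s, x0=prev)
            prev = st
            vals.append(st["RR2p"])
        vals = np.array(vals)
        assert np.all(np.diff(vals) > -1e-8 * max(vals.max(), 1e-12))


def test_curve_invariants(table1):
    params, totals = table1
    curve = signal_response(params, totals)
    assert np.all(np.diff(curve.signals) > 0)
    assert np.all(curve.rr2p >= -1e-12)
    assert np.all(curve.rr2p <= totals.RR2_tot * (1 + 1e-9))
    assert np.all(np.diff(curve.rr2p) > -1e-8)


def test_timecourse_csv_roundtrip(tmp_path, table1):
    params, totals = table1
    tc = integrate(params, totals, t_end=10.0, signal=1.0,
                   t_eval=np.linspace(0, 10, 11))
    path = tmp_path / "tc.csv"
    tc.to_csv(path)
    assert path.exists() and path.with_suffix(".csv.json").exists()
    df = tc.to_frame()
    assert set(df.columns) == {"time", "species", "value"}
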