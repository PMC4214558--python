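import numpy as np
import pytest

from phosink.conditions import (
    check_conditions,
    second_derivative_at_zero,
    second_derivative_fd,
)
from phosink.metrics import hill_coefficient
from phosink.model_core import ExtendedParameters, load_system
from phosink.simulate import signal_response

from conftest import draw_random_system


def test_reference_system_is_sigmoidal(table1):
    params, totals = table1
    verdict = check_conditions(params, totals)
    assert verdict.classification == "sigmoidal"
    assert verdict.second_derivative > 0
    assert verdict.condition_i and verdict.condition_ii


def test_no_sink_is_hyperbolic(table1):
    params, totals = table1
    verdict = check_conditions(params, totals.replace(RR1_tot=0.0))
    assert verdict.classification == "hyperbolic"
    assert verdict.second_derivative <= 0
    assert not verdict.condition_i


def test_no_sink_dephosphorylation_is_hyperbolic(table1):
    """khS=0 breaks condition (i): the sink fills up and stops draining,
    so the curve loses its threshold."""
    params, totals = table1
    verdict = check_conditions(params.replace(khS=0.0), totals)
    assert not verdict.condition_i
    assert verdict.classification == "hyperbolic"


def test_reverse_dominated_sink_is_hyperbolic(table1):
    """kS < krS breaks condition (ii) in the basic model."""
    params, totals = table1
    verdict = check_conditions(params.replace(kS=0.005, krS=0.5), totals)
    assert not verdict.condition_ii
    assert verdict.classification == "hyperbolic"


def test_second_derivative_sign_matches_curve_shape(table1):
    """The analytic zero-signal curvature agrees with the operational
    Hill coefficient: the sink makes both the curvature positive and
    the Hill coefficient clearly super-linear, and removing the sink
    drops both.  (The sink-free operational Hill can still sit slightly
    above 1 under ka drive because HK conservation across the explicit
    ATP-binding step mildly reshapes the signal axis.)"""
    params, totals = table1
    n_sink = hill_coefficient(signal_response(params, totals)).hill
    assert second_derivative_at_zero(params, totals) > 0
    assert n_sink > 1.0
    t0 = totals.replace(RR1_tot=0.0)
    n_free = hill_coefficient(signal_response(params, t0)).hill
    assert second_derivative_at_zero(params, t0) <= 1e-12
    assert n_free < n_sink


def test_implicit_vs_finite_difference_random_draws(rng):
    """Two independent computations of d²(RR2-p)/dka² at zero agree in
    sign and to 1% in value across random systems."""
    for _ in range(10):
        params, totals = draw_random_system(rng)
        imp = second_derivative_at_zero(params, totals, signal_kind="ka")
        fd = second_derivative_fd(params, totals, signal_kind="ka")
        scale = max(abs(imp), abs(fd))
        if scale < 1e-10:
            continue
        assert np.sign(imp) == np.sign(fd)
        assert abs(imp - fd) <= 0.01 * scale


def test_cross_check_flag_runs(table1):
    params, totals = table1
    v = second_derivative_at_zero(params, totals, cross_check=True)
    assert v > 0


def test_source_and_ka_signals_agree_at_low_atp(table1):
    """At ATP far below the binding K_d the explicit binding step is
    quasi-equilibrated, so ka-drive and lumped source-drive give the
    same curvature sign."""
    params, totals = table1
    lo = totals.replace(ATP=1.0)
    d_ka = second_derivative_at_zero(params, lo, signal_kind="ka")
    d_src = second_derivative_at_zero(params, lo, signal_kind="source")
    assert np.sign(d_ka) == np.sign(d_src) == 1.0


def test_extended_fixture_sigmoidal_despite_reverse_sink(datadir_extended):
    """With explicit transfer complexes the basic condition kS > krS is
    no longer necessary: the shipped extended fixture has kS < krS yet a
    positive zero-signal curvature, and its relaxed condition holds."""
    params, totals = datadir_extended
    assert isinstance(params, ExtendedParameters)
    assert params.kS < params.krS
    verdict = check_conditions(params, totals)
    assert verdict.classification == "sigmoidal"
    assert verdict.extended_condition is True
    assert not verdict.condition_ii


@pytest.fixture(scope="session")
def datadir_extended():
    from importlib.resources import files

    return load_system(files("phosink.data") / "extended_complex_sink.yaml")


def test_rejects_unknown_signal_kind(table1):
    params, totals = table1
    with pytest.raises(ValueError):
        second_derivative_at_zero(params, totals, signal_kind="ATP")
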