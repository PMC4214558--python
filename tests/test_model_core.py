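import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosink.model_core import (
    ExtendedParameters,
    KineticParameters,
    SystemState,
    SystemTotals,
    conservation_groups,
    load_system,
    ode_rhs,
    ode_rhs_extended,
    rhs_vector,
    sample_feasible_state,
    save_system,
    species_names,
    unphosphorylated_state,
)
from phosink.simulate import integrate, steady_state

from conftest import draw_random_system


def test_no_flux_without_autophosphorylation(table1):
    """With ka=0 and nothing phosphorylated, no phospho species moves."""
    params, totals = table1
    state = unphosphorylated_state(params, totals)
    dy = ode_rhs(state, params, totals, ka=0.0)
    names = state.species
    for sp in ("HKp", "RR1p", "RR2p"):
        assert dy[names.index(sp)] == 0.0


@given(seed=st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_conservation_sums_vanish_for_random_states(seed):
    """Stoichiometry conserves each protein pool: group sums of the RHS
    cancel for arbitrary feasible states and parameters."""
    rng = np.random.default_rng(seed)
    params, totals = draw_random_system(rng)
    state = sample_feasible_state(params, totals, rng)
    dy = rhs_vector(state.concentrations, params, totals)
    scale = max(np.max(np.abs(dy)), 1.0)
    for label, total, members in conservation_groups(state.species, totals):
        s = sum(dy[state.species.index(m)] for m in members)
        assert abs(s) < 1e-10 * scale


def test_rhs_consistent_with_integrated_trajectory(table1):
    """The RHS equals the central-difference slope of a fine trajectory."""
    params, totals = table1
    t_mid, h = 2.0, 1e-4
    tc = integrate(params, totals, t_end=3.0, signal=1.0,
                   rtol=1e-12, atol=1e-14)
    y_mid = tc.dense(t_mid)
    slope_fd = (tc.dense(t_mid + h) - tc.dense(t_mid - h)) / (2 * h)
    slope_rhs = rhs_vector(y_mid, params, totals, ka=1.0)
    assert np.allclose(slope_fd, slope_rhs, rtol=1e-5, atol=1e-8)


def test_negative_concentration_rejected(table1):
    params, totals = table1
    state = unphosphorylated_state(params, totals)
    state.concentrations[0] = -0.5
    with pytest.raises(ValueError):
        ode_rhs(state, params, totals)


def test_extended_weak_binding_limit_matches_basic(table1):
    """With vanishing complex affinities (ky* -> 0) and matched effective
    bimolecular constants, the extended steady state tracks the basic one."""
    params, totals = table1
    ext = ExtendedParameters(
        **params.to_dict(), kyS=1e-3, kyM=1e-3, kyrS=1e-3, kyrM=1e-3
    )
    s_basic = steady_state(params, totals, 1.0)
    s_ext = steady_state(ext, totals, 1.0)
    for sp in ("HKp", "RR1p", "RR2p"):
        assert s_ext[sp] == pytest.approx(s_basic[sp], rel=0.01)


def test_extended_conservation_includes_complexes(table1, rng):
    params, totals = table1
    ext = ExtendedParameters(
        **params.to_dict(), kyS=5.0, kyM=0.5, kyrS=1.0,
        dead_end=(("HK:RR1", 1.0, 0.5),),
    )
    names = species_names(ext)
    assert "HKp.RR1" in names and "HK:RR1" in names
    state = sample_feasible_state(ext, totals, rng)
    state.validate(totals)
    dy = rhs_vector(state.concentrations, ext, totals)
    scale = max(np.max(np.abs(dy)), 1.0)
    for label, total, members in conservation_groups(names, totals):
        assert abs(sum(dy[names.index(m)] for m in members)) < 1e-10 * scale


def test_transfer_flux_saturates_in_substrate(table1):
    """Michaelis–Menten routing: at saturating sink-RR the forward
    transfer flux becomes zero order in the sink-RR."""
    params, _ = table1
    ext = ExtendedParameters(**params.to_dict(), kyS=10.0)
    from phosink.model_core import _complex_rates

    kon, koff, kcat = _complex_rates(ext, "HKp.RR1")
    Km = (koff + kcat) / kon
    assert Km == pytest.approx(1.0 / ext.kyS, rel=1e-12)

    def forward_flux(rr1_free, hkp_tot=1.0):
        # quasi-steady complex with the HK-p pool conserved:
        # flux = kcat * HKp_tot * S / (Km + S)
        names = species_names(ext)
        cplx = hkp_tot * rr1_free / (Km + rr1_free)
        y = np.zeros(len(names))
        y[names.index("HKp")] = hkp_tot - cplx
        y[names.index("RR1")] = rr1_free
        y[names.index("HKp.RR1")] = cplx
        dy = rhs_vector(y, ext, SystemTotals(HK_tot=hkp_tot,
                                             RR1_tot=rr1_free + cplx,
                                             RR2_tot=0.0, ATP=0.0))
        return dy[names.index("RR1p")]

    f1, f2 = forward_flux(100.0), forward_flux(1000.0)
    assert f2 / f1 < 1.2  # far less than the 10x of a bimolecular step


def test_state_validation_catches_broken_conservation(table1):
    params, totals = table1
    state = unphosphorylated_state(params, totals)
    state.concentrations[state.species.index("RR1")] += 1.0
    with pytest.raises(ValueError, match="conservation"):
        state.validate(totals)


def test_parameter_file_roundtrip(tmp_path, table1):
    params, totals = table1
    for name in ("sys.yaml", "sys.json"):
        path = tmp_path / name
        save_system(path, params, totals)
        p2, t2 = load_system(path)
        assert p2 == params and t2 == totals
    ext = ExtendedParameters(**params.to_dict(), kyS=2.0, kyM=0.1, kyrS=0.5)
    save_system(tmp_path / "ext.yaml", ext, totals)
    p3, _ = load_system(tmp_path / "ext.yaml")
    assert isinstance(p3, ExtendedParameters) and p3.kyS == 2.0


def test_negative_rate_rejected():
    with pytest.raises(ValueError):
        KineticParameters(kS=-1.0)
    with pytest.raises(ValueError):
        SystemTotals(RR1_tot=-0.1)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_sampled_states_are_feasible(seed):
    rng = np.random.default_rng(seed)
    params, totals = draw_random_system(rng)
    state = sample_feasible_state(params, totals, rng)
    state.validate(totals)
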