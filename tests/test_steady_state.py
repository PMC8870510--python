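"""Steady-state solver tests: convergence, conservation, positivity,
two-method agreement and the ATP-yield accounting."""

import numpy as np
import pytest

from warburgsim import (
    SolverOptions,
    atp_yield_per_glucose,
    build_default_network,
    compute_derivatives,
    default_initial_state,
    default_parameters,
    derived_readouts,
    flux_balance_residual,
    integrate_to_steady_state,
)


def test_zero_activity_converges_at_the_initial_state(model, params, init_state):
    for key in params.activity:
        params.activity[key] = 0.0
    res = integrate_to_steady_state(model, params, init=init_state)
    assert res.converged and res.bounded
    for sp, v in init_state.items():
        assert res.state[sp] == pytest.approx(v, abs=1e-9)


def test_default_environment_has_a_bounded_steady_state(default_result):
    assert default_result.converged
    assert default_result.bounded
    assert default_result.residual < 1e-6


def test_independent_flux_balance_audit(default_result, model):
    p = default_parameters()
    assert flux_balance_residual(default_result, model, p) < 1e-6


def test_integrator_and_root_solver_agree(default_result):
    """Two-method agreement: the polished root and the raw integrator state
    coincide to 1e-6 relative in every concentration."""
    for sp, a in default_result.state.items():
        b = default_result.integrator_state[sp]
        assert a == pytest.approx(b, rel=1e-6, abs=1e-9), sp


def test_adenine_pool_closed_at_steady_state(default_result, model, params):
    production = sum(
        model.reactions[r].resolved_atp_stoich(params) * default_result.fluxes[r]
        for r in model.reactions
        if model.reactions[r].resolved_atp_stoich(params) > 0)
    consumption = -sum(
        model.reactions[r].resolved_atp_stoich(params) * default_result.fluxes[r]
        for r in model.reactions
        if model.reactions[r].resolved_atp_stoich(params) < 0)
    assert production == pytest.approx(consumption, rel=1e-6)


def test_carbon_closure_at_steady_state(default_result):
    """Carbon in through glucose and glutamine equals carbon out through the
    lactate/ribose/phospholipid/fatty-acid/AKG sinks and CO2."""
    f = default_result.fluxes
    inflow = 6 * f["R1"] + 5 * f["R14"]
    sinks = 3 * f["R7"] + 5 * f["R2"] + 3 * f["R5"] + 2 * f["R18"] + 5 * f["R22"]
    co2 = (f["R2"] + f["R8"] + f["R10"] - f["R11"] + f["R12"] - f["R15"]
           + f["R16"])
    assert inflow == pytest.approx(sinks + co2, rel=1e-6)


def test_pool_bounds_and_positivity(default_result, params):
    for sp, v in default_result.state.items():
        assert v >= -1e-9, sp
    assert default_result.state["ATP"] <= params.a_tot + 1e-9
    assert default_result.state["NADH_m"] <= params.n_tot_m + 1e-9
    assert default_result.state["FADH2_m"] <= params.f_tot_m + 1e-9


def test_steady_states_are_isolated(default_result, model, params):
    perturbed = dict(default_result.state)
    perturbed["F6P"] *= 1.10
    deriv = compute_derivatives(perturbed, params, model, check=False)
    assert max(abs(v) for v in deriv.values()) > 1e-6


def test_bound_cap_reports_unbounded(model, params):
    res = integrate_to_steady_state(
        model, params, opts=SolverOptions(bound_cap=1.0))
    assert not res.bounded


def test_unconverged_result_still_carries_a_state(model, params):
    # a work budget of nearly zero forces an early stop
    res = integrate_to_steady_state(
        model, params, opts=SolverOptions(max_nfev=1, t_max=5.0, polish=False))
    assert not res.converged
    assert set(res.state) == set(model.dynamic_species)


class TestReadouts:
    def test_anoxia_zeroes_the_ocr_proxy(self, model):
        p = default_parameters().with_env(o2=0.0, k_use=110.0)
        res = integrate_to_steady_state(model, p)
        assert res.readouts.ocr_proxy == 0.0

    def test_no_ldh_no_ecar(self, model):
        p = default_parameters().with_activity(
            LDH=0.0, PC=0.0, RIB=0.0, LIP=0.0, ACC=0.0, ACLY=0.0, ME2=0.0,
            IDH_NADPH=0.0, AKGEXP=0.0, PDH=10.0).with_env(gln_ext=0.0)
        res = integrate_to_steady_state(model, p)
        assert res.readouts.ecar_proxy == 0.0

    def test_atp_adp_ratio_is_one_at_half_pool(self, default_result, params):
        r = derived_readouts(default_result, params)
        atp = default_result.state["ATP"]
        assert r.atp_adp_ratio == pytest.approx(atp / (params.a_tot - atp))

    def test_unconverged_input_rejected(self, model, params):
        res = integrate_to_steady_state(
            model, params, opts=SolverOptions(max_nfev=1, t_max=5.0,
                                              polish=False))
        with pytest.raises(ValueError):
            derived_readouts(res, params)


class TestATPYield:
    def _lactate_only(self, scale=1.0):
        m = build_default_network()
        p = default_parameters().with_activity(
            PDH=0.0, PC=0.0, RIB=0.0, LIP=0.0, ACC=0.0).with_env(gln_ext=0.0)
        if scale != 1.0:
            # the identity is stoichiometric: arbitrary kinetic rescaling
            # must not move it
            for rid in ("R1", "R3", "R4", "R6", "R7"):
                p.vmax[rid] *= scale
        res = integrate_to_steady_state(m, p)
        assert res.converged
        return atp_yield_per_glucose(res, p, m)

    @pytest.mark.parametrize("scale", [1.0, 0.7, 1.6])
    def test_lactate_only_yield_is_parameter_independent(self, scale):
        assert self._lactate_only(scale) == pytest.approx(2.0, abs=1e-5)

    def test_requires_glutamine_free_environment(self, default_result, model):
        p = default_parameters()  # gln_ext = 2
        with pytest.raises(ValueError):
            atp_yield_per_glucose(default_result, p, model)

    def test_rejects_unconverged_input(self, model):
        p = default_parameters().with_env(gln_ext=0.0)
        res = integrate_to_steady_state(
            model, p, opts=SolverOptions(max_nfev=1, t_max=5.0, polish=False))
        with pytest.raises(ValueError):
            atp_yield_per_glucose(res, p, model)


def test_trajectory_stays_nonnegative(model, params):
    """Integrate from a lopsided initial state and confirm the floor."""
    init = default_initial_state()
    init["ATP"] = 0.05
    init["FBP"] = 8.0
    res = integrate_to_steady_state(model, params, init=init)
    assert res.bounded
    assert all(v >= -1e-9 for v in res.state.values())
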