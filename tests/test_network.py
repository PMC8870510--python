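"""Network-catalogue tests: carbon bookkeeping, stoichiometric ledgers,
activity scaling and serialization."""

import dataclasses

import pytest

from warburgsim import (
    build_default_network,
    compute_derivatives,
    compute_fluxes,
    default_initial_state,
    default_parameters,
    reaction_carbon_residuals,
    scale_activity,
)
from warburgsim.network import ModelDefinition, inhibition_factor
from warburgsim.redox import build_extended_network


def test_catalogue_size(model):
    assert len(model.reactions) == 22
    assert len(model.dynamic_species) == 14
    assert list(model.reactions) == [f"R{i}" for i in range(1, 23)]


def test_every_reaction_carbon_balanced(model):
    assert all(v == 0 for v in reaction_carbon_residuals(model).values())
    ext = build_extended_network()
    assert all(v == 0 for v in reaction_carbon_residuals(ext).values())


def test_pyruvate_carboxylase_carbon_arithmetic(model):
    # 3 (PYR) + 1 (CO2) - 4 (OAA) = 0
    r15 = model.reactions["R15"]
    total = sum(coef * model.species[sp].carbons
                for sp, coef in r15.stoich.items())
    assert total == 0
    assert r15.stoich == {"PYR": -1, "CO2": -1, "OAA_m": 1}


def test_corrupted_catalogue_exposes_missing_co2(model):
    broken = ModelDefinition.from_dict(model.to_dict())
    r8 = broken.reactions["R8"]
    stoich = dict(r8.stoich)
    del stoich["CO2"]
    broken.reactions["R8"] = dataclasses.replace(r8, stoich=stoich)
    residuals = reaction_carbon_residuals(broken)
    assert abs(residuals["R8"]) == 1
    assert all(v == 0 for k, v in residuals.items() if k != "R8")


def test_unknown_species_in_stoichiometry_is_an_error(model):
    broken = ModelDefinition.from_dict(model.to_dict())
    r2 = broken.reactions["R2"]
    broken.reactions["R2"] = dataclasses.replace(
        r2, stoich={**r2.stoich, "XYZ": 1})
    with pytest.raises(KeyError):
        reaction_carbon_residuals(broken)


def test_tca_lump_credits_atp_and_both_redox_carriers(model):
    r12 = model.reactions["R12"]
    assert r12.atp_stoich == 1
    assert r12.redox_stoich == {"NADH_m": 1, "FADH2_m": 1}


def test_electron_transport_yields_resolve_to_po_ratios(model, params):
    assert model.reactions["R19"].resolved_atp_stoich(params) == params.n_n
    assert model.reactions["R20"].resolved_atp_stoich(params) == params.n_f
    assert params.n_f <= params.n_n


class TestActivityScaling:
    def test_identity_factor(self, params):
        q = scale_activity(params, "LDH", 1.0)
        assert q.activity == params.activity

    def test_zero_factor_silences_the_reaction(self, model, params, init_state):
        q = scale_activity(params, "PDH", 0.0)
        fluxes = compute_fluxes(init_state, q, model)
        assert fluxes["R8"] == 0.0

    def test_multiplicative_scaling_is_exact(self, model, params, init_state):
        base = compute_fluxes(init_state, params, model)
        q = scale_activity(scale_activity(params, "PDH", 0.0), "LDH", 2.0)
        fluxes = compute_fluxes(init_state, q, model)
        assert fluxes["R8"] == 0.0
        assert fluxes["R7"] == pytest.approx(2.0 * base["R7"], rel=1e-12)
        # unrelated reactions untouched
        assert fluxes["R4"] == pytest.approx(base["R4"], rel=1e-12)

    def test_unknown_key_suggests_nearest(self, params):
        with pytest.raises(KeyError, match="PDH"):
            scale_activity(params, "PHD", 2.0)


def test_all_vmax_zero_gives_zero_fluxes(model, params, init_state):
    for key in params.activity:
        params.activity[key] = 0.0
    fluxes = compute_fluxes(init_state, params, model)
    assert all(v == 0.0 for v in fluxes.values())
    deriv = compute_derivatives(init_state, params, model)
    assert all(v == 0.0 for v in deriv.values())


def test_fluxes_match_hand_evaluated_rate_laws(model, params, init_state):
    """Independent spreadsheet-style evaluation of each rate law at a pinned
    reference state."""
    s = init_state
    p = params
    nad_c = p.n_tot_c * p.r_nad_c / (1 + p.r_nad_c)
    nadh_c = p.n_tot_c / (1 + p.r_nad_c)
    adp = p.a_tot - s["ATP"]
    nad_m = p.n_tot_m - s["NADH_m"]
    fad_m = p.f_tot_m - s["FADH2_m"]

    def sat(x, km):
        return x / (km + x)

    km = p.km
    expected = {
        "R1": p.vmax["R1"] * sat(p.glc_ext, km[("R1", "GLC_EXT")])
        * sat(s["ATP"], km[("R1", "ATP")])
        / (1 + (s["F6P"] / p.k_i_f6p) ** p.n_f6p),
        "R2": p.vmax["R2"] * sat(s["F6P"], km[("R2", "F6P")]),
        "R3": p.vmax["R3"] * sat(s["F6P"], km[("R3", "F6P")])
        * sat(s["ATP"], km[("R3", "ATP")])
        / (1 + (s["ATP"] / p.k_i_atp) ** p.n_atp)
        * (1 + (p.amp_fbp - 1) * s["FBP"] ** p.n_fbp
           / (p.k_a_fbp ** p.n_fbp + s["FBP"] ** p.n_fbp)),
        "R4": p.vmax["R4"] * sat(s["FBP"], km[("R4", "FBP")]),
        "R5": p.vmax["R5"] * sat(s["TP"], km[("R5", "TP")]),
        "R6": p.vmax["R6"] * sat(s["TP"], km[("R6", "TP")])
        * sat(nad_c, km[("R6", "NAD_c")]) * sat(adp, km[("R6", "ADP")]),
        "R7": p.vmax["R7"] * sat(s["PYR"], km[("R7", "PYR")])
        * sat(nadh_c, km[("R7", "NADH_c")]),
        "R8": p.vmax["R8"] * sat(s["PYR"], km[("R8", "PYR")])
        * sat(nad_m, km[("R8", "NAD_m")])
        / (1 + s["ACCOA_m"] / km[("R8", "ACCOA_m")]),
        "R9": p.vmax["R9"] * sat(s["ACCOA_m"], km[("R9", "ACCOA_m")])
        * sat(s["OAA_m"], km[("R9", "OAA_m")]),
        "R10": p.vmax["R10"] * sat(s["CIT_m"], km[("R10", "CIT_m")])
        * sat(nad_m, km[("R10", "NAD_m")]),
        "R11": p.vmax["R11"] * sat(s["AKG_m"], km[("R11", "AKG_m")]),
        "R12": p.vmax["R12"] * sat(s["AKG_m"], km[("R12", "AKG_m")])
        * sat(nad_m, km[("R12", "NAD_m")]) * sat(fad_m, km[("R12", "FAD_m")])
        * sat(adp, km[("R12", "ADP")]),
        "R13": p.mdh_kf * s["MAL_m"] * nad_m - p.mdh_kr * s["OAA_m"] * s["NADH_m"],
        "R14": p.vmax["R14"] * sat(p.gln_ext, km[("R14", "GLN_EXT")])
        * sat(nad_m, km[("R14", "NAD_m")]),
        "R15": p.vmax["R15"] * sat(s["PYR"], km[("R15", "PYR")])
        * sat(s["ATP"], km[("R15", "ATP")])
        * (s["ACCOA_m"] / km[("R15", "ACCOA_m")]) ** 4
        / (1 + (s["ACCOA_m"] / km[("R15", "ACCOA_m")]) ** 4),
        "R16": p.vmax["R16"] * sat(s["MAL_m"], km[("R16", "MAL_m")])
        * sat(nad_m, km[("R16", "NAD_m")]),
        "R17": p.vmax["R17"] * sat(s["CIT_m"], km[("R17", "CIT_m")])
        * sat(s["ATP"], km[("R17", "ATP")]),
        "R18": p.vmax["R18"] * sat(s["ACCOA_c"], km[("R18", "ACCOA_c")])
        * sat(s["ATP"], km[("R18", "ATP")]),
        "R19": p.vmax["R19"] * sat(s["NADH_m"], km[("R19", "NADH_m")])
        * sat(p.o2, km[("R19", "O2")]) * sat(adp, km[("R19", "ADP")]),
        "R20": p.vmax["R20"] * sat(s["FADH2_m"], km[("R20", "FADH2_m")])
        * sat(p.o2, km[("R20", "O2")]) * sat(adp, km[("R20", "ADP")]),
        "R21": p.basal_load * sat(s["ATP"], p.k_basal)
        + p.k_use * sat(s["ATP"], p.k_load),
        "R22": p.vmax["R22"] * sat(s["AKG_m"], km[("R22", "AKG_m")]),
    }
    fluxes = compute_fluxes(s, p, model)
    for rid, want in expected.items():
        assert fluxes[rid] == pytest.approx(want, rel=1e-12), rid


def test_derivatives_equal_stoichiometry_times_fluxes(model, params, init_state):
    from warburgsim import stoich_matrix
    import numpy as np

    fluxes = compute_fluxes(init_state, params, model)
    deriv = compute_derivatives(init_state, params, model, fluxes=fluxes)
    S = stoich_matrix(model, params)
    v = np.array([fluxes[r] for r in model.reactions])
    d2 = S @ v
    for i, sp in enumerate(model.dynamic_species):
        assert deriv[sp] == pytest.approx(d2[i], abs=1e-12)


def test_atp_and_adp_derivatives_cancel_identically(model, params, init_state):
    # ADP is derived by pool conservation, so d(ATP)+d(ADP) = 0 holds by
    # construction; verify the ledger gives the expected signed total.
    deriv = compute_derivatives(init_state, params, model)
    fluxes = compute_fluxes(init_state, params, model)
    ledger = sum(model.reactions[r].resolved_atp_stoich(params) * fluxes[r]
                 for r in model.reactions)
    assert deriv["ATP"] == pytest.approx(ledger, rel=1e-12)


def test_inert_cytosolic_citrate(model, params, init_state):
    deriv = compute_derivatives(init_state, params, model)
    assert deriv["CIT_c"] == 0.0


def test_negative_concentration_rejected(model, params, init_state):
    bad = dict(init_state)
    bad["PYR"] = -0.01
    with pytest.raises(ValueError):
        compute_fluxes(bad, params, model)


def test_clamped_atp_variant_freezes_atp(model, params, init_state):
    clamped = model.variant(clamp_atp=True)
    deriv = compute_derivatives(init_state, params, clamped)
    assert deriv["ATP"] == 0.0
    free = compute_derivatives(init_state, params, model)
    assert free["ATP"] != 0.0


def test_yaml_round_trip_is_lossless(model):
    text = model.to_yaml()
    clone = ModelDefinition.from_yaml(text)
    assert clone.to_dict() == model.to_dict()
    assert clone.to_yaml() == text
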