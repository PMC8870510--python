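"""Sweep machinery, hysteresis detection and phenotype-map tests."""

import numpy as np
import pandas as pd
import pytest

from warburgsim import (
    SweepSpec,
    default_parameters,
    detect_bistability,
    integrate_to_steady_state,
    optimal_phenotype_map,
    run_preset,
    run_sweep,
)
from warburgsim.scenarios import SweepResult, set_param
from warburgsim.steady_state import Readouts, SteadyStateResult


def _toy_sweep(values, curve):
    """Package a readout curve as a SweepResult without running the solver."""
    def fake(v):
        r = Readouts(*([0.0] * 12))
        r.lipid_flux = v
        return SteadyStateResult(state={}, fluxes={}, converged=True,
                                 bounded=True, time_to_converge=0.0,
                                 residual=0.0, readouts=r)
    spec = SweepSpec("activity.LDH", tuple(values))
    return SweepResult(spec, {"up": [fake(v) for v in curve],
                              "down": [fake(v) for v in curve]})


class TestDetectBistability:
    def test_identical_curves_are_not_bistable(self):
        values = np.linspace(1, 10, 10)
        sw = _toy_sweep(values, np.linspace(0, 1, 10))
        rep = detect_bistability(sw, sw, "lipid_flux")
        assert not rep.bistable

    def test_recovers_a_known_window_exactly(self):
        # branches jump at grid values a=4 (down) and b=8 (up)
        values = tuple(range(1, 11))
        up = [0.1 if v < 8 else 1.0 for v in values]
        down = [0.1 if v < 4 else 1.0 for v in values]
        sw_up = _toy_sweep(values, up)
        sw_dn = _toy_sweep(values, down)
        rep = detect_bistability(sw_up, sw_dn, "lipid_flux")
        assert rep.bistable
        assert rep.window == (4.0, 8.0)

    def test_mismatched_grids_are_rejected(self):
        sw1 = _toy_sweep([1, 2, 3], [0, 0, 1])
        sw2 = _toy_sweep([1, 2, 4], [0, 0, 1])
        with pytest.raises(ValueError):
            detect_bistability(sw1, sw2, "lipid_flux")


class TestSweeps:
    def test_single_value_sweep_equals_direct_solve(self, model, params):
        spec = SweepSpec("activity.LDH", (2.0,))
        sw = run_sweep(model, params, spec)
        direct = integrate_to_steady_state(model, set_param(params,
                                                            "activity.LDH", 2.0))
        got = sw.results["up"][0]
        for sp in model.dynamic_species:
            assert got.state[sp] == direct.state[sp]

    def test_grid_must_be_strictly_increasing(self):
        with pytest.raises(ValueError):
            SweepSpec("k_use", (1.0, 1.0, 2.0))
        with pytest.raises(ValueError):
            SweepSpec("k_use", (), direction="up")

    def test_frame_is_tidy(self, model, params):
        spec = SweepSpec("activity.LDH", (0.5, 2.0),
                         readouts_wanted=("lipid_flux", "ecar_proxy"))
        df = run_sweep(model, params, spec).frame()
        assert set(df.columns) >= {"direction", "swept_value", "readout",
                                   "value", "converged"}
        assert len(df) == 2 * 2

    def test_unknown_parameter_path(self, params):
        with pytest.raises(KeyError):
            set_param(params, "activity.NOPE", 1.0)
        with pytest.raises(KeyError):
            set_param(params, "not_an_env", 1.0)


def test_phenotype_map_identical_phenotypes_have_no_crossover(model, params):
    pmap = optimal_phenotype_map(
        model, params, (50.0, 200.0),
        {"a": {"LDH": 2.0}, "b": {"LDH": 2.0}}, "lipid_flux")
    assert pmap.crossovers == []


def test_phenotype_map_requires_two_phenotypes(model, params):
    with pytest.raises(ValueError):
        optimal_phenotype_map(model, params, (50.0,), {"a": {}}, "lipid_flux")


def test_unknown_preset_lists_the_catalogue():
    with pytest.raises(KeyError, match="fig1b"):
        run_preset("no-such-preset")


def test_preset_reruns_are_bit_identical(preset_cache):
    """Continuation determinism: rerunning a preset reproduces its tables
    exactly."""
    first = preset_cache("fig3e")
    again = run_preset("fig3e")
    for name, df in first.tables.items():
        pd.testing.assert_frame_equal(df, again.tables[name],
                                      check_exact=True)
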