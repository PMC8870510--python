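"""Extended model: dynamic cytosolic NAD+/NADH and the glycerol-3-phosphate
shuttle.

The baseline model mimics the redox shuttles by fixing the cytosolic
NAD+:NADH ratio.  Here the assumption is relaxed: NADH_c becomes a dynamic
species (conserved cytosolic pool ``n_tot_c``), lower glycolysis consumes
NAD+_c, lactate dehydrogenase consumes NADH_c, and two reactions are added:

* R23 — glycerol-3-phosphate shuttle: cytosolic NADH is reoxidized with the
  electrons delivered to the mitochondrial FAD pool (FADH2 level, yield
  ``n_f``).  The DHAP/G3P carbon round-trip is net zero and is not tracked.
* R24 — NAD+-use flux: a biosynthetic demand that consumes cytosolic NAD+
  and returns NADH_c.  It serves as a proliferation proxy when NAD+
  availability (rather than carbon) limits growth.  The demand also requires
  ATP, so it reports the joint availability of the two currencies.
"""

from __future__ import annotations

from .network import ModelDefinition, ReactionDef, SpeciesDef, _base_reactions
from .network import _BASE_SPECIES, BASE_DYNAMIC
from .parameters import ParameterSet, default_parameters, default_initial_state
from .steady_state import SteadyStateResult

__all__ = [
    "build_extended_network",
    "extended_parameters",
    "extended_initial_state",
    "nad_readouts",
]


def build_extended_network() -> ModelDefinition:
    """Baseline catalogue plus dynamic NADH_c, the shuttle (R23) and the
    NAD+-use flux (R24)."""
    species = {s.species_id: s for s in _BASE_SPECIES}
    species["NADH_c"] = SpeciesDef("NADH_c", "cytosol", 0, pool_id="cyto_NAD")
    reactions = _base_reactions()
    reactions["R23"] = ReactionDef(
        "R23", "glycerol-3-phosphate shuttle (electrons to FAD)",
        {}, "saturating", ("NADH_c", "FAD_m"), "SHUTTLE",
        redox_stoich={"NADH_c": -1, "FADH2_m": 1})
    reactions["R24"] = ReactionDef(
        "R24", "NAD+-use flux (biosynthetic NAD+ demand)",
        {}, "saturating", ("NAD_c", "ATP"), "NADUSE",
        redox_stoich={"NADH_c": 1})
    return ModelDefinition(
        species=species,
        reactions=reactions,
        dynamic_species=BASE_DYNAMIC + ("NADH_c",),
        dynamic_nadh_c=True,
    )


def extended_parameters() -> ParameterSet:
    """Defaults for the extended model: baseline set plus R23/R24 constants."""
    p = default_parameters()
    p.vmax["R23"] = 60.0
    p.vmax["R24"] = 4.0
    p.km[("R23", "NADH_c")] = 0.02
    p.km[("R23", "FAD_m")] = 0.1
    p.km[("R24", "NAD_c")] = 0.3
    p.km[("R24", "ATP")] = 0.5
    return p


def extended_initial_state() -> dict[str, float]:
    p = default_parameters()
    init = default_initial_state()
    init["NADH_c"] = p.n_tot_c / (1.0 + p.r_nad_c)
    return init


def nad_readouts(res: SteadyStateResult, p, m: ModelDefinition) -> dict[str, float]:
    """Cytosolic NAD+:NADH ratio and the NAD+-use flux at a steady state.

    Only defined for the extended model (baseline input is an error).
    """
    if not m.dynamic_nadh_c or "NADH_c" not in res.state:
        raise ValueError("nad_readouts requires a result from the extended model")
    nadh_c = max(res.state["NADH_c"], 1e-300)
    return {
        "nad_ratio_c": (p.n_tot_c - res.state["NADH_c"]) / nadh_c,
        "nad_use_flux": res.fluxes["R24"],
    }
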