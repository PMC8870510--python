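"""Metabolic network definition and rate-law evaluation.

The model covers glycolysis, the TCA cycle, a simplified electron-transport
treatment, glutaminolysis and the anaplerotic/anabolic branch points that
matter for proliferating tumor cells.  Concentrations are in mM, fluxes in
mM/h, time in h.

Species fall into three groups: dynamic states (integrated), boundary inputs
(extracellular glucose/glutamine, oxygen, CO2) and sinks (lactate, ribose,
phospholipid, fatty acid, exported alpha-ketoglutarate).  Boundary and sink
species carry no dynamic state but participate in the carbon ledger, so every
reaction can be checked for exact carbon balance.

ATP/ADP, mitochondrial NAD+/NADH and FAD/FADH2 are conserved pairs: only
ATP, NADH_m and FADH2_m are stored; the partners are derived from pool
totals.  The baseline model holds the cytosolic NAD+:NADH ratio fixed
(mimicking the net effect of the redox shuttles); the extended model in
:mod:`warburgsim.redox` makes it dynamic.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ModelDefinition",
    "build_default_network",
    "saturating_rate",
    "inhibition_factor",
    "activation_factor",
    "pfk_rate",
    "reversible_mdh_rate",
    "etc_rate",
    "load_rate",
    "compute_fluxes",
    "compute_derivatives",
    "reaction_carbon_residuals",
]

COMPARTMENTS = ("cytosol", "mitochondrion", "boundary", "sink")


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species: id, compartment, carbons per molecule, pool label."""

    species_id: str
    compartment: str
    carbons: int
    pool_id: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for {self.species_id}"
            )
        if self.carbons < 0:
            raise ValueError(f"negative carbon count for {self.species_id}")


@dataclass(frozen=True)
class ReactionDef:
    """One reaction: carbon stoichiometry plus ATP and redox ledgers.

    ``stoich`` holds signed coefficients for carbon-carrying species only.
    ATP made/used per event lives in ``atp_stoich`` (a number, or the string
    ``"n_N"``/``"n_F"`` for the electron-transport steps, resolved against the
    parameter set's P/O yields).  Redox-carrier turnover lives in
    ``redox_stoich`` keyed by NADH_m / FADH2_m / NADH_c.

    ``substrates`` lists the concentrations entering multiplicative
    saturation factors (Michaelis-Menten form); Km values are looked up in
    the parameter set as ``km[(reaction_id, substrate)]``.
    """

    reaction_id: str
    name: str
    stoich: dict[str, int]
    rate_template: str
    substrates: tuple[str, ...]
    activity_key: str
    atp_stoich: float | str = 0
    redox_stoich: dict[str, int] = field(default_factory=dict)
    modifiers: tuple[tuple[str, str], ...] = ()  # (species, role)

    def resolved_atp_stoich(self, p) -> float:
        if self.atp_stoich == "n_N":
            return p.n_n
        if self.atp_stoich == "n_F":
            return p.n_f
        return float(self.atp_stoich)


# Names resolvable in rate laws that are not stored state: derived pool
# partners and environment values.
DERIVED_QUANTITIES = ("ADP", "NAD_m", "FAD_m", "NAD_c", "GLC_EXT", "GLN_EXT", "O2")


@dataclass
class ModelDefinition:
    """Reaction network: species catalogue, reactions, model-variant flags."""

    species: dict[str, SpeciesDef]
    reactions: dict[str, ReactionDef]
    dynamic_species: tuple[str, ...]
    clamp_atp: bool = False
    dynamic_nadh_c: bool = False

    # ------------------------------------------------------------------
    def variant(self, **flags) -> "ModelDefinition":
        """Copy of the model with flags changed (e.g. ``clamp_atp=True``)."""
        return replace(self, **flags)

    def species_index(self, species_id: str) -> int:
        return self.dynamic_species.index(species_id)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": [
                {
                    "species_id": s.species_id,
                    "compartment": s.compartment,
                    "carbons": s.carbons,
                    "pool_id": s.pool_id,
                }
                for s in self.species.values()
            ],
            "reactions": [
                {
                    "reaction_id": r.reaction_id,
                    "name": r.name,
                    "stoich": dict(r.stoich),
                    "rate_template": r.rate_template,
                    "substrates": list(r.substrates),
                    "activity_key": r.activity_key,
                    "atp_stoich": r.atp_stoich,
                    "redox_stoich": dict(r.redox_stoich),
                    "modifiers": [list(m) for m in r.modifiers],
                }
                for r in self.reactions.values()
            ],
            "dynamic_species": list(self.dynamic_species),
            "clamp_atp": self.clamp_atp,
            "dynamic_nadh_c": self.dynamic_nadh_c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDefinition":
        species = {
            s["species_id"]: SpeciesDef(
                s["species_id"], s["compartment"], s["carbons"], s.get("pool_id")
            )
            for s in d["species"]
        }
        reactions = {
            r["reaction_id"]: ReactionDef(
                reaction_id=r["reaction_id"],
                name=r["name"],
                stoich={k: int(v) for k, v in r["stoich"].items()},
                rate_template=r["rate_template"],
                substrates=tuple(r["substrates"]),
                activity_key=r["activity_key"],
                atp_stoich=r["atp_stoich"],
                redox_stoich={k: int(v) for k, v in r["redox_stoich"].items()},
                modifiers=tuple(tuple(m) for m in r.get("modifiers", [])),
            )
            for r in d["reactions"]
        }
        return cls(
            species=species,
            reactions=reactions,
            dynamic_species=tuple(d["dynamic_species"]),
            clamp_atp=bool(d.get("clamp_atp", False)),
            dynamic_nadh_c=bool(d.get("dynamic_nadh_c", False)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelDefinition":
        return cls.from_dict(yaml.safe_load(text))


# ----------------------------------------------------------------------
# Rate-law primitives
# ----------------------------------------------------------------------

def saturating_rate(vmax: float, km: float, s: float) -> float:
    """Michaelis-Menten saturation: vmax*s/(km+s).

    Multi-substrate reactions multiply independent factors of this form.
    """
    if s < 0:
        raise ValueError(f"negative substrate concentration: {s}")
    if km <= 0:
        raise ValueError(f"non-positive Km: {km}")
    if vmax < 0:
        raise ValueError(f"negative Vmax: {vmax}")
    return vmax * s / (km + s)


def inhibition_factor(x: float, ki: float, n: float) -> float:
    """Hill inhibition: 1/(1+(x/ki)^n); 1 at x=0, 1/2 at x=ki, -> 0."""
    if x < 0:
        raise ValueError(f"negative inhibitor concentration: {x}")
    if ki <= 0 or n < 1:
        raise ValueError("require ki > 0 and n >= 1")
    return 1.0 / (1.0 + (x / ki) ** n)


def activation_factor(x: float, ka: float, n: float, amp: float) -> float:
    """Hill activation: 1 + (amp-1)*x^n/(ka^n + x^n); 1 at x=0, -> amp."""
    if x < 0:
        raise ValueError(f"negative activator concentration: {x}")
    if ka <= 0 or n < 1 or amp < 1:
        raise ValueError("require ka > 0, n >= 1 and amp >= 1")
    xn = x**n
    return 1.0 + (amp - 1.0) * xn / (ka**n + xn)


def pfk_rate(f6p: float, atp: float, fbp: float, p) -> float:
    """Phosphofructokinase: saturating in F6P and in its ATP substrate
    (small Km), Hill-inhibited by ATP at the allosteric site, Hill-activated
    by its product FBP (the positive feedback behind bistability)."""
    base = saturating_rate(p.vmax["R3"], p.km[("R3", "F6P")], f6p)
    km_atp = p.km[("R3", "ATP")]
    return (
        p.activity["PFK"]
        * base
        * (atp / (km_atp + atp))
        * inhibition_factor(atp, p.k_i_atp, p.n_atp)
        * activation_factor(fbp, p.k_a_fbp, p.n_fbp, p.amp_fbp)
    )


def reversible_mdh_rate(mal: float, oaa: float, nadh_m: float, nad_m: float, p) -> float:
    """Net malate dehydrogenase rate (signed): kf*MAL*NAD+ - kr*OAA*NADH.

    Positive means net MAL -> OAA.  Zero when the mass-action ratio
    (OAA*NADH)/(MAL*NAD+) equals kf/kr.
    """
    for v, nm in ((mal, "MAL"), (oaa, "OAA"), (nadh_m, "NADH_m"), (nad_m, "NAD_m")):
        if v < 0:
            raise ValueError(f"negative concentration for {nm}: {v}")
    return p.activity["MDH"] * (p.mdh_kf * mal * nad_m - p.mdh_kr * oaa * nadh_m)


def etc_rate(vmax: float, km_carrier: float, carrier: float, o2: float,
             km_o2: float, adp: float, km_adp: float) -> float:
    """Electron-transport step: saturating in the reduced carrier, in oxygen
    saturation (zero under anoxia) and in ADP (no phosphate acceptor, no
    flux)."""
    if not 0.0 <= o2 <= 1.0:
        raise ValueError(f"oxygen saturation outside [0, 1]: {o2}")
    return (
        saturating_rate(vmax, km_carrier, carrier)
        * (o2 / (km_o2 + o2))
        * (adp / (km_adp + adp))
    )


def load_rate(atp: float, p) -> float:
    """ATP-consumption load: basal demand plus a tunable demand ``k_use``.

    Both terms saturate in ATP (and vanish at ATP = 0), so the load cannot
    outrun supply: v = basal*ATP/(K_b+ATP) + k_use*ATP/(K_load+ATP).
    ``k_use`` is the swept "rate of ATP consumption".
    """
    if atp < 0:
        raise ValueError(f"negative ATP: {atp}")
    return p.activity["LOAD"] * (
        p.basal_load * atp / (p.k_basal + atp)
        + p.k_use * atp / (p.k_load + atp)
    )


# ----------------------------------------------------------------------
# Network catalogue
# ----------------------------------------------------------------------

_BASE_SPECIES = [
    # dynamic, cytosol
    SpeciesDef("F6P", "cytosol", 6),
    SpeciesDef("FBP", "cytosol", 6),
    SpeciesDef("TP", "cytosol", 3),
    SpeciesDef("PYR", "cytosol", 3),
    SpeciesDef("ACCOA_c", "cytosol", 2),
    SpeciesDef("CIT_c", "cytosol", 6),
    SpeciesDef("ATP", "cytosol", 0, pool_id="adenine"),
    # dynamic, mitochondrion
    SpeciesDef("ACCOA_m", "mitochondrion", 2),
    SpeciesDef("OAA_m", "mitochondrion", 4),
    SpeciesDef("CIT_m", "mitochondrion", 6),
    SpeciesDef("AKG_m", "mitochondrion", 5),
    SpeciesDef("MAL_m", "mitochondrion", 4),
    SpeciesDef("NADH_m", "mitochondrion", 0, pool_id="mito_NAD"),
    SpeciesDef("FADH2_m", "mitochondrion", 0, pool_id="mito_FAD"),
    # boundary inputs
    SpeciesDef("GLC_EXT", "boundary", 6),
    SpeciesDef("GLN_EXT", "boundary", 5),
    SpeciesDef("CO2", "boundary", 1),
    # sinks
    SpeciesDef("LAC", "sink", 3),
    SpeciesDef("RIBOSE", "sink", 5),
    SpeciesDef("PLIP", "sink", 3),
    SpeciesDef("FA", "sink", 2),
    SpeciesDef("AKG_EXP", "sink", 5),
]

BASE_DYNAMIC = (
    "F6P", "FBP", "TP", "PYR", "ACCOA_c", "CIT_c", "ATP",
    "ACCOA_m", "OAA_m", "CIT_m", "AKG_m", "MAL_m", "NADH_m", "FADH2_m",
)


def _base_reactions() -> dict[str, ReactionDef]:
    defs = [
        ReactionDef("R1", "glucose uptake + hexokinase (lumped)",
                    {"GLC_EXT": -1, "F6P": 1}, "uptake",
                    ("GLC_EXT", "ATP"), "GLUT1", atp_stoich=-1,
                    modifiers=(("F6P", "inhibitor"),)),
        ReactionDef("R2", "ribose-synthesis branch (PPP)",
                    {"F6P": -1, "RIBOSE": 1, "CO2": 1}, "saturating",
                    ("F6P",), "RIB"),
        ReactionDef("R3", "phosphofructokinase",
                    {"F6P": -1, "FBP": 1}, "pfk",
                    ("F6P",), "PFK", atp_stoich=-1,
                    modifiers=(("ATP", "inhibitor"), ("FBP", "activator"))),
        ReactionDef("R4", "aldolase",
                    {"FBP": -1, "TP": 2}, "saturating",
                    ("FBP",), "ALD"),
        ReactionDef("R5", "phospholipid-synthesis branch",
                    {"TP": -1, "PLIP": 1}, "saturating",
                    ("TP",), "LIP"),
        ReactionDef("R6", "lower glycolysis (GAPDH..PK lumped)",
                    {"TP": -1, "PYR": 1}, "saturating",
                    ("TP", "NAD_c", "ADP"), "GAPDH", atp_stoich=2,
                    redox_stoich={"NADH_c": 1}),
        ReactionDef("R7", "lactate dehydrogenase + lactate export",
                    {"PYR": -1, "LAC": 1}, "saturating",
                    ("PYR", "NADH_c"), "LDH",
                    redox_stoich={"NADH_c": -1}),
        ReactionDef("R8", "pyruvate dehydrogenase",
                    {"PYR": -1, "ACCOA_m": 1, "CO2": 1}, "pdh",
                    ("PYR", "NAD_m"), "PDH",
                    redox_stoich={"NADH_m": 1},
                    modifiers=(("ACCOA_m", "inhibitor"),)),
        ReactionDef("R9", "citrate synthase",
                    {"ACCOA_m": -1, "OAA_m": -1, "CIT_m": 1}, "saturating2",
                    ("ACCOA_m", "OAA_m"), "CS"),
        ReactionDef("R10", "oxidative NAD+-dependent isocitrate dehydrogenase",
                    {"CIT_m": -1, "AKG_m": 1, "CO2": 1}, "saturating",
                    ("CIT_m", "NAD_m"), "IDH",
                    redox_stoich={"NADH_m": 1}),
        ReactionDef("R11", "reductive carboxylation (NADPH-dependent IDH)",
                    {"AKG_m": -1, "CO2": -1, "CIT_m": 1}, "saturating",
                    ("AKG_m",), "IDH_NADPH"),
        ReactionDef("R12", "AKG dehydrogenase + SCS + SDH + fumarase (lumped)",
                    {"AKG_m": -1, "MAL_m": 1, "CO2": 1}, "saturating",
                    ("AKG_m", "NAD_m", "FAD_m", "ADP"), "AKGDH",
                    atp_stoich=1, redox_stoich={"NADH_m": 1, "FADH2_m": 1}),
        ReactionDef("R13", "malate dehydrogenase (reversible)",
                    {"MAL_m": -1, "OAA_m": 1}, "reversible_mdh",
                    ("MAL_m", "OAA_m", "NADH_m", "NAD_m"), "MDH",
                    redox_stoich={"NADH_m": 1}),
        ReactionDef("R14", "glutaminase + glutamate dehydrogenase (lumped)",
                    {"GLN_EXT": -1, "AKG_m": 1}, "saturating",
                    ("GLN_EXT", "NAD_m"), "GLS",
                    redox_stoich={"NADH_m": 1}),
        ReactionDef("R15", "pyruvate carboxylase",
                    {"PYR": -1, "CO2": -1, "OAA_m": 1}, "pc",
                    ("PYR", "ATP"), "PC", atp_stoich=-1,
                    modifiers=(("ACCOA_m", "activator"),)),
        ReactionDef("R16", "malic enzyme 2",
                    {"MAL_m": -1, "PYR": 1, "CO2": 1}, "saturating",
                    ("MAL_m", "NAD_m"), "ME2",
                    redox_stoich={"NADH_m": 1}),
        ReactionDef("R17", "citrate export + ATP-citrate lyase "
                           "(cytosolic OAA returned as malate)",
                    {"CIT_m": -1, "ACCOA_c": 1, "MAL_m": 1}, "saturating",
                    ("CIT_m", "ATP"), "ACLY", atp_stoich=-1),
        ReactionDef("R18", "acetyl-CoA carboxylase + fatty-acid synthase",
                    {"ACCOA_c": -1, "FA": 1}, "saturating",
                    ("ACCOA_c", "ATP"), "ACC", atp_stoich=-1),
        ReactionDef("R19", "electron transport, NADH-fed",
                    {}, "etc", ("NADH_m",), "ETC",
                    atp_stoich="n_N", redox_stoich={"NADH_m": -1}),
        ReactionDef("R20", "electron transport, FADH2-fed",
                    {}, "etc", ("FADH2_m",), "ETC",
                    atp_stoich="n_F", redox_stoich={"FADH2_m": -1}),
        ReactionDef("R21", "ATP-consumption load",
                    {}, "load", ("ATP",), "LOAD", atp_stoich=-1),
        ReactionDef("R22", "alpha-ketoglutarate export",
                    {"AKG_m": -1, "AKG_EXP": 1}, "saturating",
                    ("AKG_m",), "AKGEXP"),
    ]
    return {r.reaction_id: r for r in defs}


def build_default_network() -> ModelDefinition:
    """Baseline network: 22 reactions over 14 dynamic species.

    Cytosolic NAD+/NADH is held at the fixed ratio ``r_nad_c`` (the
    functional stand-in for the redox shuttles); cytosolic citrate is carried
    as a state but the citrate-export lump R17 leaves it untouched.
    """
    return ModelDefinition(
        species={s.species_id: s for s in _BASE_SPECIES},
        reactions=_base_reactions(),
        dynamic_species=BASE_DYNAMIC,
    )


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

def _resolve(name: str, conc: dict[str, float], p, m: ModelDefinition) -> float:
    """Concentration of a species or derived quantity at the given state."""
    if name in conc:
        return conc[name]
    if name == "ADP":
        return p.a_tot - conc["ATP"]
    if name == "NAD_m":
        return p.n_tot_m - conc["NADH_m"]
    if name == "FAD_m":
        return p.f_tot_m - conc["FADH2_m"]
    if name == "NAD_c":
        if m.dynamic_nadh_c:
            return p.n_tot_c - conc["NADH_c"]
        return p.n_tot_c * p.r_nad_c / (1.0 + p.r_nad_c)
    if name == "NADH_c":
        # only reached in baseline mode (fixed ratio)
        return p.n_tot_c / (1.0 + p.r_nad_c)
    if name == "GLC_EXT":
        return p.glc_ext
    if name == "GLN_EXT":
        return p.gln_ext
    if name == "O2":
        return p.o2
    raise KeyError(f"cannot resolve concentration of {name!r}")


def _check_state(conc: dict[str, float], p, m: ModelDefinition) -> None:
    floor = -1e-9
    for sp in m.dynamic_species:
        v = conc[sp]
        if v < floor:
            raise ValueError(f"negative concentration for {sp}: {v}")
    if conc["ATP"] > p.a_tot * (1 + 1e-9):
        raise ValueError("ATP exceeds adenine pool total")
    if conc["NADH_m"] > p.n_tot_m * (1 + 1e-9):
        raise ValueError("NADH_m exceeds mitochondrial NAD pool total")
    if conc["FADH2_m"] > p.f_tot_m * (1 + 1e-9):
        raise ValueError("FADH2_m exceeds mitochondrial FAD pool total")


def _reaction_rate(r: ReactionDef, conc: dict[str, float], p, m: ModelDefinition) -> float:
    a = p.activity[r.activity_key]
    if a == 0.0:
        return 0.0
    t = r.rate_template
    if t in ("saturating", "saturating2"):
        v = a * p.vmax[r.reaction_id]
        for s in r.substrates:
            x = max(_resolve(s, conc, p, m), 0.0)
            v *= x / (p.km[(r.reaction_id, s)] + x)
        return v
    if t == "pc":
        # saturating in PYR and ATP; allosteric acetyl-CoA activation is
        # cooperative (Hill 4), so PC is fully silent when PDH is off
        v = a * p.vmax[r.reaction_id]
        for s_ in r.substrates:
            x = max(_resolve(s_, conc, p, m), 0.0)
            v *= x / (p.km[(r.reaction_id, s_)] + x)
        acc = max(conc["ACCOA_m"], 0.0)
        ka = p.km[(r.reaction_id, "ACCOA_m")]
        h = (acc / ka) ** 4
        return v * h / (1.0 + h)
    if t == "pdh":
        # saturating in PYR and NAD+_m, product-inhibited by acetyl-CoA
        v = a * p.vmax[r.reaction_id]
        for s_ in r.substrates:
            x = max(_resolve(s_, conc, p, m), 0.0)
            v *= x / (p.km[(r.reaction_id, s_)] + x)
        acc = max(conc["ACCOA_m"], 0.0)
        return v / (1.0 + acc / p.km[(r.reaction_id, "ACCOA_m")])
    if t == "uptake":
        # saturating in Glc_ext and ATP, product-inhibited by F6P
        # (hexokinase inhibition by its hexose-phosphate product)
        v = a * p.vmax[r.reaction_id]
        for s in r.substrates:
            x = max(_resolve(s, conc, p, m), 0.0)
            v *= x / (p.km[(r.reaction_id, s)] + x)
        return v * inhibition_factor(max(conc["F6P"], 0.0), p.k_i_f6p, p.n_f6p)
    if t == "pfk":
        return pfk_rate(max(conc["F6P"], 0.0), max(conc["ATP"], 0.0),
                        max(conc["FBP"], 0.0), p)
    if t == "reversible_mdh":
        return reversible_mdh_rate(
            max(conc["MAL_m"], 0.0), max(conc["OAA_m"], 0.0),
            max(conc["NADH_m"], 0.0),
            max(_resolve("NAD_m", conc, p, m), 0.0), p)
    if t == "etc":
        carrier = r.substrates[0]
        return a * etc_rate(
            p.vmax[r.reaction_id], p.km[(r.reaction_id, carrier)],
            max(_resolve(carrier, conc, p, m), 0.0), p.o2,
            p.km[(r.reaction_id, "O2")],
            max(_resolve("ADP", conc, p, m), 0.0),
            p.km[(r.reaction_id, "ADP")])
    if t == "load":
        return load_rate(max(conc["ATP"], 0.0), p)
    raise ValueError(f"unknown rate template {t!r} for {r.reaction_id}")


def compute_fluxes(state: dict[str, float], p, m: ModelDefinition,
                   check: bool = True) -> dict[str, float]:
    """Evaluate every reaction's rate law at the given state (mM/h).

    All fluxes are non-negative except R13 (reversible MDH), which is signed.
    """
    if check:
        _check_state(state, p, m)
    return {rid: _reaction_rate(r, state, p, m) for rid, r in m.reactions.items()}


def compute_derivatives(state: dict[str, float], p, m: ModelDefinition,
                        fluxes: dict[str, float] | None = None,
                        check: bool = True) -> dict[str, float]:
    """Time derivatives dC/dt (mM/h) for every dynamic species.

    Carbon species follow the stoichiometric ledger; ATP adds the ATP ledger
    (with the P/O yields resolved for the electron-transport steps); NADH_m,
    FADH2_m and (extended model) NADH_c follow the redox ledger.  With
    ``clamp_atp`` the ATP derivative is zeroed (the constant-ATP variant).
    """
    if fluxes is None:
        fluxes = compute_fluxes(state, p, m, check=check)
    deriv = {sp: 0.0 for sp in m.dynamic_species}
    for rid, r in m.reactions.items():
        v = fluxes[rid]
        if v == 0.0:
            continue
        for sp, coef in r.stoich.items():
            if sp in deriv:
                deriv[sp] += coef * v
        if r.atp_stoich != 0:
            deriv["ATP"] += r.resolved_atp_stoich(p) * v
        for carrier, coef in r.redox_stoich.items():
            if carrier in deriv:
                deriv[carrier] += coef * v
    if m.clamp_atp:
        deriv["ATP"] = 0.0
    return deriv


def reaction_carbon_residuals(m: ModelDefinition) -> dict[str, int]:
    """Per-reaction signed carbon residual (sum of coefficient*carbons).

    Zero everywhere for a balanced catalogue; CO2 and the sink species count.
    """
    res: dict[str, int] = {}
    for rid, r in m.reactions.items():
        total = 0
        for sp, coef in r.stoich.items():
            if sp not in m.species:
                raise KeyError(f"{rid} references unknown species {sp!r}")
            total += coef * m.species[sp].carbons
        res[rid] = total
    return res


def suggest_key(key: str, valid: list[str]) -> str | None:
    """Closest valid key for an unknown one (used in error messages)."""
    matches = difflib.get_close_matches(key, valid, n=1, cutoff=0.5)
    return matches[0] if matches else None
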