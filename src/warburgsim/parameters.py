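"""Kinetic constants, activity multipliers, environment and pool totals.

Default values are a calibrated set, chosen once so that the model exhibits a
bounded steady state in the reference environment and the documented
qualitative behaviours (PFK bistability, ATP-demand crossover, anaplerotic
switching) at the documented activity multipliers.  They are frozen here and
versioned with the package; see docs/methods.md for the calibration
rationale.  Up/down-regulation of an enzyme is always expressed through its
dimensionless ``activity`` multiplier, never by editing Vmax.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

from .network import suggest_key

__all__ = ["ParameterSet", "default_parameters", "default_initial_state",
           "scale_activity", "ACTIVITY_KEYS"]

ACTIVITY_KEYS = (
    "GLUT1", "RIB", "PFK", "ALD", "LIP", "GAPDH", "LDH", "PDH", "CS", "IDH",
    "IDH_NADPH", "AKGDH", "MDH", "GLS", "PC", "ME2", "ACLY", "ACC", "ETC",
    "LOAD", "AKGEXP", "SHUTTLE", "NADUSE",
)

ENV_KEYS = ("glc_ext", "gln_ext", "o2", "k_use", "basal_load")


@dataclass
class ParameterSet:
    """All kinetic constants and settings for one model configuration.

    Units: concentrations and Km in mM, Vmax and fluxes in mM/h, time in h;
    oxygen is a dimensionless saturation in [0, 1]; activity multipliers are
    dimensionless folds.
    """

    # maximal rates, mM/h (R13 uses mdh_kf/mdh_kr instead)
    vmax: dict[str, float]
    # half-saturation constants, mM, keyed (reaction_id, substrate)
    km: dict[tuple[str, str], float]
    # PFK allosteric regulation
    k_i_atp: float
    n_atp: float
    k_a_fbp: float
    n_fbp: float
    amp_fbp: float
    # hexokinase product inhibition (uptake lump R1)
    k_i_f6p: float
    n_f6p: float
    # reversible MDH mass-action constants (mM^-1 h^-1)
    mdh_kf: float
    mdh_kr: float
    # ATP load
    k_load: float
    k_basal: float
    # environment
    glc_ext: float
    gln_ext: float
    o2: float
    k_use: float
    basal_load: float
    # conserved pools (mM) and fixed cytosolic redox ratio
    a_tot: float
    n_tot_m: float
    f_tot_m: float
    n_tot_c: float
    r_nad_c: float
    # ATP-yield coefficients (P/O ratios) and shuttle credit
    n_n: float
    n_f: float
    n_shuttle: float
    # per-enzyme activity multipliers
    activity: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in ACTIVITY_KEYS})

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if not 0.0 <= self.o2 <= 1.0:
            raise ValueError(f"o2 must lie in [0, 1], got {self.o2}")
        if self.n_f > self.n_n:
            raise ValueError("require n_F <= n_N")
        for name in ("k_i_atp", "k_a_fbp", "k_i_f6p", "k_load", "k_basal", "a_tot",
                     "n_tot_m", "f_tot_m", "n_tot_c", "r_nad_c", "mdh_kf",
                     "mdh_kr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k_use", "basal_load", "glc_ext", "gln_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_atp < 1 or self.n_fbp < 1 or self.amp_fbp < 1:
            raise ValueError("Hill exponents must be >= 1 and amp_fbp >= 1")
        for k, v in self.vmax.items():
            if v < 0:
                raise ValueError(f"vmax[{k}] must be non-negative")
        for k, v in self.km.items():
            if v <= 0:
                raise ValueError(f"km[{k}] must be positive")
        for k, v in self.activity.items():
            if v < 0:
                raise ValueError(f"activity[{k}] must be non-negative")

    # ------------------------------------------------------------------
    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def with_activity(self, **factors: float) -> "ParameterSet":
        """New ParameterSet with activity multipliers *multiplied* by the
        given factors (unknown keys rejected with a suggestion)."""
        p = self.copy()
        for key, f in factors.items():
            if key not in p.activity:
                hint = suggest_key(key, list(p.activity))
                msg = f"unknown activity key {key!r}"
                if hint:
                    msg += f"; did you mean {hint!r}?"
                raise KeyError(msg + f" (valid keys: {', '.join(ACTIVITY_KEYS)})")
            if f < 0:
                raise ValueError(f"activity factor for {key} must be >= 0")
            p.activity[key] *= f
        return p

    def with_env(self, **env: float) -> "ParameterSet":
        """New ParameterSet with environment values replaced."""
        p = self.copy()
        for key, v in env.items():
            if key not in ENV_KEYS:
                hint = suggest_key(key, list(ENV_KEYS))
                msg = f"unknown environment key {key!r}"
                if hint:
                    msg += f"; did you mean {hint!r}?"
                raise KeyError(msg)
            setattr(p, key, float(v))
        p.validate()
        return p

    def param_hash(self) -> str:
        """Deterministic hash of the full parameter set (for run metadata)."""
        payload = {
            "vmax": sorted(self.vmax.items()),
            "km": sorted((f"{r}:{s}", v) for (r, s), v in self.km.items()),
            "activity": sorted(self.activity.items()),
            "scalars": [
                self.k_i_atp, self.n_atp, self.k_a_fbp, self.n_fbp,
                self.amp_fbp, self.k_i_f6p, self.n_f6p,
                self.mdh_kf, self.mdh_kr, self.k_load,
                self.k_basal, self.glc_ext, self.gln_ext, self.o2,
                self.k_use, self.basal_load, self.a_tot, self.n_tot_m,
                self.f_tot_m, self.n_tot_c, self.r_nad_c, self.n_n,
                self.n_f, self.n_shuttle,
            ],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def scale_activity(p: ParameterSet, activity_key: str, factor: float) -> ParameterSet:
    """Multiply one enzyme's activity multiplier; returns a new ParameterSet."""
    return p.with_activity(**{activity_key: factor})


# ----------------------------------------------------------------------
# Frozen defaults
# ----------------------------------------------------------------------

def default_parameters() -> ParameterSet:
    """The calibrated, frozen default parameter set (baseline model).

    The reference environment is glucose-replete (5 mM), glutamine-replete
    (2 mM), normoxic, with a mid-range ATP demand.
    """
    vmax = {
        "R1": 12.0,    # glucose uptake + HK
        "R2": 1.0,     # ribose branch
        "R3": 12.0,    # PFK
        "R4": 16.0,    # aldolase
        "R5": 4.5,     # phospholipid branch
        "R6": 60.0,    # lower glycolysis (per triose)
        "R7": 30.0,    # LDH
        "R8": 24.0,    # PDH
        "R9": 100.0,   # citrate synthase
        "R10": 20.0,   # oxidative IDH
        "R11": 0.2,    # NADPH-dependent IDH (reductive carboxylation)
        "R12": 20.0,   # AKGDH..FH lump
        "R14": 3.0,    # GLS + GDH
        "R15": 2.0,    # pyruvate carboxylase
        "R16": 6.0,    # malic enzyme 2
        "R17": 8.0,    # citrate export + ACLY
        "R18": 8.0,    # ACC + FAS
        "R19": 120.0,  # ETC, NADH-fed
        "R20": 60.0,   # ETC, FADH2-fed
        "R22": 3.0,    # AKG export
    }
    km = {
        ("R1", "GLC_EXT"): 1.0, ("R1", "ATP"): 0.1,
        ("R2", "F6P"): 0.5,
        ("R3", "F6P"): 0.1, ("R3", "ATP"): 0.01,
        ("R4", "FBP"): 5.0,
        ("R5", "TP"): 0.3,
        ("R6", "TP"): 0.2, ("R6", "NAD_c"): 0.05, ("R6", "ADP"): 1.0,
        ("R7", "PYR"): 2.0, ("R7", "NADH_c"): 0.01,
        ("R8", "PYR"): 0.15, ("R8", "NAD_m"): 2.0, ("R8", "ACCOA_m"): 0.1,
        ("R9", "ACCOA_m"): 0.01, ("R9", "OAA_m"): 0.01,
        ("R10", "CIT_m"): 1.0, ("R10", "NAD_m"): 0.3,
        ("R11", "AKG_m"): 1.0,
        ("R12", "AKG_m"): 1.0, ("R12", "NAD_m"): 0.3,
        ("R12", "FAD_m"): 0.1, ("R12", "ADP"): 0.3,
        ("R14", "GLN_EXT"): 1.0, ("R14", "NAD_m"): 0.01,
        ("R15", "PYR"): 0.5, ("R15", "ATP"): 0.3, ("R15", "ACCOA_m"): 0.02,
        ("R16", "MAL_m"): 2.0, ("R16", "NAD_m"): 0.01,
        ("R17", "CIT_m"): 0.1, ("R17", "ATP"): 0.3,
        ("R18", "ACCOA_c"): 0.1, ("R18", "ATP"): 0.3,
        ("R19", "NADH_m"): 0.1, ("R19", "O2"): 0.3, ("R19", "ADP"): 1.0,
        ("R20", "FADH2_m"): 0.1, ("R20", "O2"): 0.3, ("R20", "ADP"): 1.0,
        ("R22", "AKG_m"): 0.1,
    }
    return ParameterSet(
        vmax=vmax,
        km=km,
        k_i_atp=2.5, n_atp=6.0,
        k_a_fbp=4.5, n_fbp=8.0, amp_fbp=20.0,
        k_i_f6p=0.3, n_f6p=2.0,
        mdh_kf=400.0, mdh_kr=4000.0,
        k_load=20.0, k_basal=0.05,
        glc_ext=5.0, gln_ext=2.0, o2=1.0,
        k_use=320.0, basal_load=0.5,
        a_tot=5.0, n_tot_m=1.5, f_tot_m=1.0, n_tot_c=1.0, r_nad_c=10.0,
        n_n=2.5, n_f=1.5, n_shuttle=1.5,
    )


def default_initial_state() -> dict[str, float]:
    """Reference initial concentrations (mM) for the baseline model."""
    return {
        "F6P": 0.5, "FBP": 0.5, "TP": 0.3, "PYR": 0.5,
        "ACCOA_c": 0.05, "CIT_c": 0.1, "ATP": 2.5,
        "ACCOA_m": 0.05, "OAA_m": 0.01, "CIT_m": 0.3, "AKG_m": 0.3,
        "MAL_m": 0.3, "NADH_m": 0.15, "FADH2_m": 0.1,
    }
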