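"""Steady-state solving and derived phenotype readouts.

The system is integrated with a stiff-capable method (BDF) in growing time
chunks until the maximum absolute derivative falls below ``ss_tol``, then the
answer is polished with a bounded least-squares root solve seeded at the
integrator's state.  Long integration first makes the procedure robust to the
bistability of the glycolytic switch: the basin of the supplied initial state
is the one reported.  Convergence and boundedness are always reported
honestly; an unconverged run still carries its final state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .network import ModelDefinition, compute_derivatives, compute_fluxes

__all__ = [
    "SolverOptions",
    "Readouts",
    "SteadyStateResult",
    "integrate_to_steady_state",
    "flux_balance_residual",
    "derived_readouts",
    "atp_yield_per_glucose",
    "stoich_matrix",
]


@dataclass(frozen=True)
class SolverOptions:
    """Integration and convergence settings.

    ``ss_tol`` is the steady-state criterion on max|dC/dt| (mM/h);
    ``bound_cap`` declares a run unbounded once any concentration exceeds it.
    """

    abs_tol: float = 1e-10
    rel_tol: float = 1e-8
    ss_tol: float = 1e-6
    t_max: float = 1e4
    bound_cap: float = 1e4
    polish: bool = True
    max_nfev: int = 150_000  # work budget; exceeded -> honest unconverged

    def __post_init__(self) -> None:
        for name in ("abs_tol", "rel_tol", "ss_tol", "t_max", "bound_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Readouts:
    """Phenotype readouts derived from a steady state.

    OCR and ECAR proxies mirror the respirometry readouts: total
    oxygen-consuming electron-transport flux and the lactate-export flux.
    ``tca_flux_akgdh`` is the flux through the alpha-ketoglutarate
    dehydrogenase span; ``tca_flux_etc`` the oxygen-dependent reoxidation of
    TCA-generated NADH (both are used as "TCA cycle flux" in different
    contexts).
    """

    ocr_proxy: float
    ecar_proxy: float
    atp_adp_ratio: float
    lipid_flux: float
    ribose_flux: float
    fa_flux: float
    atp_use_flux: float
    tca_flux_akgdh: float
    tca_flux_etc: float
    glucose_uptake: float
    akg_export_flux: float
    nad_ratio_m: float

    def as_dict(self) -> dict[str, float]:
        return dict(vars(self))


@dataclass
class SteadyStateResult:
    """Converged (or honestly-flagged) state, fluxes and readouts."""

    state: dict[str, float]
    fluxes: dict[str, float]
    converged: bool
    bounded: bool
    time_to_converge: float
    residual: float
    readouts: Readouts
    integrator_state: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict[str, float]:
        """Flat record: concentrations, fluxes, readouts, flags."""
        row: dict[str, float] = {}
        row.update({f"conc_{k}": v for k, v in self.state.items()})
        row.update({f"flux_{k}": v for k, v in self.fluxes.items()})
        row.update({f"readout_{k}": v for k, v in self.readouts.as_dict().items()})
        row["converged"] = bool(self.converged)
        row["bounded"] = bool(self.bounded)
        row["residual"] = self.residual
        row["time_to_converge"] = self.time_to_converge
        return row


# ----------------------------------------------------------------------
# Compiled right-hand side (closure-based, avoids per-call dict traffic)
# ----------------------------------------------------------------------

def _compile_model(m: ModelDefinition, p):
    """Build fast flux/derivative evaluators over the state vector."""
    idx = {sp: i for i, sp in enumerate(m.dynamic_species)}
    n = len(m.dynamic_species)
    a_tot, n_tot_m, f_tot_m = p.a_tot, p.n_tot_m, p.f_tot_m
    nad_c_fix = p.n_tot_c * p.r_nad_c / (1.0 + p.r_nad_c)
    nadh_c_fix = p.n_tot_c / (1.0 + p.r_nad_c)
    dynamic_nadh_c = m.dynamic_nadh_c
    i_atp = idx["ATP"]
    i_nadh_m = idx["NADH_m"]
    i_fadh2 = idx["FADH2_m"]
    i_nadh_c = idx.get("NADH_c")

    def getter(name):
        if name in idx:
            i = idx[name]
            return lambda y: y[i] if y[i] > 0.0 else 0.0
        if name == "ADP":
            return lambda y: max(a_tot - y[i_atp], 0.0)
        if name == "NAD_m":
            return lambda y: max(n_tot_m - y[i_nadh_m], 0.0)
        if name == "FAD_m":
            return lambda y: max(f_tot_m - y[i_fadh2], 0.0)
        if name == "NAD_c":
            if dynamic_nadh_c:
                n_tot_c = p.n_tot_c
                return lambda y: max(n_tot_c - y[i_nadh_c], 0.0)
            return lambda y: nad_c_fix
        if name == "NADH_c":
            if dynamic_nadh_c:
                return lambda y: y[i_nadh_c] if y[i_nadh_c] > 0.0 else 0.0
            return lambda y: nadh_c_fix
        if name == "GLC_EXT":
            v = p.glc_ext
            return lambda y: v
        if name == "GLN_EXT":
            v = p.gln_ext
            return lambda y: v
        if name == "O2":
            v = p.o2
            return lambda y: v
        raise KeyError(name)

    rate_fns = []
    for rid, r in m.reactions.items():
        a = p.activity[r.activity_key]
        t = r.rate_template
        if a == 0.0:
            rate_fns.append(lambda y: 0.0)
        elif t in ("saturating", "saturating2"):
            v0 = a * p.vmax[rid]
            factors = [(getter(s), p.km[(rid, s)]) for s in r.substrates]
            def fn(y, v0=v0, factors=factors):
                v = v0
                for g, km in factors:
                    x = g(y)
                    v *= x / (km + x)
                return v
            rate_fns.append(fn)
        elif t == "pc":
            v0 = a * p.vmax[rid]
            factors = [(getter(s), p.km[(rid, s)]) for s in r.substrates]
            i_acc = idx["ACCOA_m"]
            ka_acc = p.km[(rid, "ACCOA_m")]
            def fn(y, v0=v0, factors=factors, i_acc=i_acc, ka_acc=ka_acc):
                v = v0
                for g, km in factors:
                    x = g(y)
                    v *= x / (km + x)
                acc = y[i_acc] if y[i_acc] > 0 else 0.0
                h = (acc / ka_acc) ** 4
                return v * h / (1.0 + h)
            rate_fns.append(fn)
        elif t == "pdh":
            v0 = a * p.vmax[rid]
            factors = [(getter(s), p.km[(rid, s)]) for s in r.substrates]
            i_acc = idx["ACCOA_m"]
            ki_acc = p.km[(rid, "ACCOA_m")]
            def fn(y, v0=v0, factors=factors, i_acc=i_acc, ki_acc=ki_acc):
                v = v0
                for g, km in factors:
                    x = g(y)
                    v *= x / (km + x)
                acc = y[i_acc] if y[i_acc] > 0 else 0.0
                return v / (1.0 + acc / ki_acc)
            rate_fns.append(fn)
        elif t == "uptake":
            v0 = a * p.vmax[rid]
            factors = [(getter(s), p.km[(rid, s)]) for s in r.substrates]
            i_f6p = idx["F6P"]
            ki_f, n_f = p.k_i_f6p, p.n_f6p
            def fn(y, v0=v0, factors=factors):
                v = v0
                for g, km in factors:
                    x = g(y)
                    v *= x / (km + x)
                f6p = y[i_f6p] if y[i_f6p] > 0 else 0.0
                return v / (1.0 + (f6p / ki_f) ** n_f)
            rate_fns.append(fn)
        elif t == "pfk":
            v0 = a * p.vmax[rid]
            km_f6p = p.km[(rid, "F6P")]
            km_atp3 = p.km[(rid, "ATP")]
            ki, n_i = p.k_i_atp, p.n_atp
            ka_n = p.k_a_fbp ** p.n_fbp
            n_a, amp = p.n_fbp, p.amp_fbp
            i_f6p, i_fbp = idx["F6P"], idx["FBP"]
            def fn(y, v0=v0):
                f6p = y[i_f6p] if y[i_f6p] > 0 else 0.0
                atp = y[i_atp] if y[i_atp] > 0 else 0.0
                fbp = y[i_fbp] if y[i_fbp] > 0 else 0.0
                fbp_n = fbp ** n_a
                return (v0 * f6p / (km_f6p + f6p)
                        * atp / (km_atp3 + atp)
                        / (1.0 + (atp / ki) ** n_i)
                        * (1.0 + (amp - 1.0) * fbp_n / (ka_n + fbp_n)))
            rate_fns.append(fn)
        elif t == "reversible_mdh":
            kf, kr = a * p.mdh_kf, a * p.mdh_kr
            i_mal, i_oaa = idx["MAL_m"], idx["OAA_m"]
            def fn(y, kf=kf, kr=kr):
                mal = y[i_mal] if y[i_mal] > 0 else 0.0
                oaa = y[i_oaa] if y[i_oaa] > 0 else 0.0
                nadh = y[i_nadh_m] if y[i_nadh_m] > 0 else 0.0
                nad = max(n_tot_m - nadh, 0.0)
                return kf * mal * nad - kr * oaa * nadh
            rate_fns.append(fn)
        elif t == "etc":
            carrier = r.substrates[0]
            v0 = a * p.vmax[rid]
            g_c = getter(carrier)
            km_c = p.km[(rid, carrier)]
            km_o2 = p.km[(rid, "O2")]
            km_adp = p.km[(rid, "ADP")]
            o2f = p.o2 / (km_o2 + p.o2) if p.o2 > 0 else 0.0
            def fn(y, v0=v0, g_c=g_c, km_c=km_c, km_adp=km_adp, o2f=o2f):
                c = g_c(y)
                adp = max(a_tot - y[i_atp], 0.0)
                return v0 * c / (km_c + c) * o2f * adp / (km_adp + adp)
            rate_fns.append(fn)
        elif t == "load":
            basal, k_use = p.basal_load, p.k_use
            k_b, k_l = p.k_basal, p.k_load
            def fn(y, a=a):
                atp = y[i_atp] if y[i_atp] > 0 else 0.0
                return a * (basal * atp / (k_b + atp) + k_use * atp / (k_l + atp))
            rate_fns.append(fn)
        else:
            raise ValueError(f"unknown rate template {t!r}")

    # stoichiometric application lists: (state index, coefficient) per reaction
    apply_lists = []
    for rid, r in m.reactions.items():
        entries = [(idx[sp], float(c)) for sp, c in r.stoich.items() if sp in idx]
        if r.atp_stoich != 0:
            entries.append((i_atp, r.resolved_atp_stoich(p)))
        for carrier, c in r.redox_stoich.items():
            if carrier in idx:
                entries.append((idx[carrier], float(c)))
        apply_lists.append(entries)

    clamp_atp = m.clamp_atp

    def flux_vec(y):
        return np.array([fn(y) for fn in rate_fns])

    def rhs(t, y):
        out = np.zeros(n)
        for fn, entries in zip(rate_fns, apply_lists):
            v = fn(y)
            if v != 0.0:
                for i, c in entries:
                    out[i] += c * v
        if clamp_atp:
            out[i_atp] = 0.0
        return out

    return rhs, flux_vec, idx


def stoich_matrix(m: ModelDefinition, p) -> np.ndarray:
    """Full stoichiometric matrix over dynamic species (ATP and redox ledgers
    resolved), shape (n_species, n_reactions); derivatives = S @ fluxes."""
    idx = {sp: i for i, sp in enumerate(m.dynamic_species)}
    S = np.zeros((len(m.dynamic_species), len(m.reactions)))
    for j, (rid, r) in enumerate(m.reactions.items()):
        for sp, c in r.stoich.items():
            if sp in idx:
                S[idx[sp], j] += c
        if r.atp_stoich != 0:
            S[idx["ATP"], j] += r.resolved_atp_stoich(p)
        for carrier, c in r.redox_stoich.items():
            if carrier in idx:
                S[idx[carrier], j] += c
    if m.clamp_atp:
        S[idx["ATP"], :] = 0.0
    return S


# ----------------------------------------------------------------------

def _pool_caps(m: ModelDefinition, p) -> np.ndarray:
    caps = np.full(len(m.dynamic_species), np.inf)
    idx = {sp: i for i, sp in enumerate(m.dynamic_species)}
    caps[idx["ATP"]] = p.a_tot
    caps[idx["NADH_m"]] = p.n_tot_m
    caps[idx["FADH2_m"]] = p.f_tot_m
    if "NADH_c" in idx:
        caps[idx["NADH_c"]] = p.n_tot_c
    return caps


def integrate_to_steady_state(
    m: ModelDefinition,
    p,
    init: dict[str, float] | None = None,
    opts: SolverOptions | None = None,
) -> SteadyStateResult:
    """Integrate the ODE system to steady state and polish by root solve.

    Returns a result with honest ``converged``/``bounded`` flags; the final
    state is carried even when unconverged.  An invariant violation during
    integration is reported as an unbounded/failed result.
    """
    from .parameters import default_initial_state

    opts = opts or SolverOptions()
    if init is None:
        init = default_initial_state()
    y0 = np.array([init[sp] for sp in m.dynamic_species], dtype=float)
    if np.any(y0 < -1e-9):
        raise ValueError("initial state has negative concentrations")
    caps = _pool_caps(m, p)
    if np.any(y0 > caps * (1 + 1e-9)):
        raise ValueError("initial state violates a conserved-pool bound")

    rhs, flux_vec, idx = _compile_model(m, p)
    cap = opts.bound_cap

    def bound_event(t, y):
        return cap - np.max(y)
    bound_event.terminal = True
    bound_event.direction = -1

    t_now, y = 0.0, y0.copy()
    converged = bounded = True
    if float(np.max(y)) >= cap:
        bounded = False
    t_converged = 0.0
    residual = float(np.max(np.abs(rhs(0.0, y))))
    if bounded and residual >= opts.ss_tol:
        converged = False
        t_chunk = 20.0
        nfev_total = 0
        try:
            while t_now < opts.t_max:
                t_end = min(t_now + t_chunk, opts.t_max)
                with np.errstate(over="ignore", invalid="ignore"):
                    sol = solve_ivp(
                        rhs, (t_now, t_end), y, method="BDF",
                        rtol=opts.rel_tol, atol=opts.abs_tol,
                        events=bound_event, dense_output=False)
                if not sol.success:
                    bounded = False
                    break
                y = sol.y[:, -1]
                t_now = float(sol.t[-1])
                nfev_total += int(sol.nfev)
                if sol.status == 1:  # bound_cap hit
                    bounded = False
                    break
                residual = float(np.max(np.abs(rhs(0.0, y))))
                if residual < opts.ss_tol:
                    converged = True
                    t_converged = t_now
                    break
                if nfev_total > opts.max_nfev:
                    break  # stalled (e.g. a limit cycle); reported unconverged
                t_chunk *= 5.0
        except (ValueError, FloatingPointError):
            bounded = False
    integ_y = y.copy()

    # polish with a bounded least-squares root solve seeded at the answer;
    # when the integrator stopped short of ss_tol (slowly damped approach),
    # a polished root is accepted only if it is nearby and verifiably stable
    # (a short re-integration from it must not drift away), so an unstable
    # fixed point inside a limit cycle is never reported as converged.
    if bounded and opts.polish:
        lo = np.zeros_like(y)
        hi = caps.copy()
        y_seed = np.clip(y, lo, np.where(np.isfinite(hi), hi, y + 1.0))
        try:
            ls = least_squares(
                lambda v: rhs(0.0, v), y_seed, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, method="trf")
            res_ls = float(np.max(np.abs(rhs(0.0, ls.x))))
            scale = 1.0 + float(np.max(np.abs(y)))
            nearby = float(np.max(np.abs(ls.x - y))) / scale < 0.25
            if converged:
                if res_ls <= residual:
                    y = ls.x
                    residual = res_ls
            elif res_ls < opts.ss_tol and nearby:
                with np.errstate(over="ignore", invalid="ignore"):
                    check = solve_ivp(rhs, (0.0, 50.0), ls.x, method="BDF",
                                      rtol=opts.rel_tol, atol=opts.abs_tol)
                drift = float(np.max(np.abs(rhs(0.0, check.y[:, -1]))))
                if check.success and drift < 10.0 * opts.ss_tol:
                    y = ls.x
                    residual = res_ls
                    converged = True
                    t_converged = t_now
        except Exception:
            pass  # keep the integrator's state

    y = np.maximum(y, 0.0)
    state = {sp: float(y[i]) for sp, i in idx.items()}
    fluxes_arr = flux_vec(y)
    fluxes = {rid: float(v) for rid, v in zip(m.reactions, fluxes_arr)}
    readouts = _readouts_from(state, fluxes, p)
    return SteadyStateResult(
        state=state, fluxes=fluxes, converged=converged, bounded=bounded,
        time_to_converge=t_converged, residual=residual, readouts=readouts,
        integrator_state={sp: float(integ_y[i]) for sp, i in idx.items()})


def flux_balance_residual(res: SteadyStateResult, m: ModelDefinition, p) -> float:
    """Max |dC/dt| at res.state, recomputed independently of the integrator."""
    deriv = compute_derivatives(res.state, p, m, check=False)
    return max(abs(v) for v in deriv.values())


# ----------------------------------------------------------------------
# Readouts and yield accounting
# ----------------------------------------------------------------------

def _readouts_from(state: dict[str, float], fluxes: dict[str, float], p) -> Readouts:
    atp = state["ATP"]
    adp = max(p.a_tot - atp, 0.0)
    nadh_m = max(state["NADH_m"], 1e-300)
    return Readouts(
        ocr_proxy=fluxes["R19"] + fluxes["R20"],
        ecar_proxy=fluxes["R7"],
        atp_adp_ratio=atp / adp if adp > 0 else math.inf,
        lipid_flux=fluxes["R5"],
        ribose_flux=fluxes["R2"],
        fa_flux=fluxes["R18"],
        atp_use_flux=fluxes["R21"],
        tca_flux_akgdh=fluxes["R12"],
        tca_flux_etc=fluxes["R19"],
        glucose_uptake=fluxes["R1"],
        akg_export_flux=fluxes["R22"],
        nad_ratio_m=max(p.n_tot_m - state["NADH_m"], 0.0) / nadh_m,
    )


def derived_readouts(res: SteadyStateResult, p, allow_unconverged: bool = False) -> Readouts:
    """Recompute the phenotype readouts from a steady-state result."""
    if not res.converged and not allow_unconverged:
        raise ValueError("readouts requested for an unconverged result")
    return _readouts_from(res.state, res.fluxes, p)


def atp_yield_per_glucose(res: SteadyStateResult, p, m: ModelDefinition) -> float:
    """ATP produced per glucose taken up, by steady-state flux accounting.

    gross ATP production (all positive ATP-ledger terms, with the electron
    transport steps credited at the P/O yields) minus the ATP invested in
    glucose processing (uptake/HK and PFK), plus a shuttle credit of
    ``n_shuttle`` per net cytosolic NADH oxidized in the mitochondrion
    (max(0, R6 - R7); zero when lactate export consumes all glycolytic
    NADH), divided by the glucose uptake flux.  Requires a converged state
    with no glutamine (so every ATP traces to glucose).
    """
    if not res.converged:
        raise ValueError("yield accounting requires a converged steady state")
    if p.gln_ext != 0:
        raise ValueError("yield per glucose is only defined with gln_ext = 0")
    uptake = res.fluxes["R1"]
    if uptake <= 0:
        raise ValueError("zero glucose uptake; yield undefined")
    gross = 0.0
    for rid, r in m.reactions.items():
        coef = r.resolved_atp_stoich(p)
        if coef > 0:
            gross += coef * res.fluxes[rid]
    invested = res.fluxes["R1"] + res.fluxes["R3"]
    shuttle = p.n_shuttle * max(0.0, res.fluxes["R6"] - res.fluxes["R7"])
    return (gross - invested + shuttle) / uptake
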