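# Model and methods

`warburgsim` is a mechanistic kinetic model of the central-carbon metabolism
of a proliferating (tumor) cell: glycolysis with its ribose- and
phospholipid-synthesis branches, the TCA cycle, a simplified
electron-transport / oxidative-phosphorylation treatment, glutaminolysis,
and the anaplerotic and lipogenic branch points (pyruvate carboxylase,
NADPH-dependent IDH, malic enzyme, citrate export/ACLY/ACC).  The model is a
deliberately small ODE system — 22 reactions over 14 dynamic metabolite
concentrations (24 over 15 in the extended variant) — built to expose the
feedback structure that shapes tumor metabolic phenotypes, not to fit any
particular cell line.

## The ODE system

Concentrations are in mM, fluxes in mM h⁻¹, time in h.  Each dynamic species
obeys dC/dt = Σᵣ sᵣ·vᵣ with integer carbon stoichiometries sᵣ; ATP and the
redox carriers are tracked through separate ledgers attached to each
reaction (ATP made/used per event; NADH_m, FADH₂_m, NADH_c turnover).  Three
conserved pairs are represented by a single state each: ATP (ADP = A_tot −
ATP), NADH_m (NAD⁺_m = N_tot_m − NADH_m) and FADH₂_m; the extended model
adds NADH_c with pool N_tot_c.  Extracellular glucose and glutamine, oxygen
(a dimensionless saturation in [0,1]) and CO₂ are boundary conditions;
lactate, ribose, phospholipid, fatty acid and exported α-ketoglutarate are
sinks.  Every reaction is exactly carbon-balanced once CO₂ and the sinks are
counted, which makes the whole network auditable by a carbon ledger
(`reaction_carbon_residuals`, and the steady-state closure check: carbon in
through glucose and glutamine equals carbon out through the sinks and CO₂).

Rate laws are products of Michaelis–Menten saturation factors, with four
regulatory elements that carry the model's scientific content:

* **PFK** is saturating in F6P and its ATP substrate (Km 0.01 mM), Hill-
  inhibited by ATP at the allosteric site (K_I 2.5 mM, n 6) and Hill-
  activated by its product FBP (K_A 4.5 mM, n 8, maximal fold-activation
  20).  The product activation is the positive feedback that makes the
  glycolytic switch bistable; the ATP inhibition couples the switch to the
  cell's energy state.
* **Glucose uptake + hexokinase** (lumped) is saturating in extracellular
  glucose and ATP and product-inhibited by F6P (the classical
  hexose-phosphate inhibition of hexokinase).  This feedback transmits PFK
  throttling upstream to uptake; without it the hexose-phosphate pool has no
  ceiling and the model has no bounded steady state once PFK is inhibited.
* **PDH** is saturating in pyruvate and NAD⁺_m (Km 2.0 mM, so it is the
  NADH-ratio sensor of the mitochondrion) and product-inhibited by
  acetyl-CoA (K_I 0.1 mM) — its canonical regulation.  Without the product
  inhibition, acetyl-CoA grows without bound whenever citrate synthase is
  oxaloacetate-starved.
* **Pyruvate carboxylase** requires its obligate allosteric activator
  acetyl-CoA (cooperative, Hill 4, K_A 0.02 mM).  This silences PC when PDH
  is off (e.g. under anoxia), which closes off an otherwise unbounded
  pyruvate→oxaloacetate→malate pump driven by reverse MDH.

MDH is the one reversible step, mass-action in both directions
(k_f·MAL·NAD⁺ − k_r·OAA·NADH); its poise transmits the mitochondrial redox
state into the C4 pool.  The electron-transport steps are saturating in
their reduced carrier, in oxygen saturation and in ADP (acceptor control),
following the spirit of simplified oxidative-phosphorylation treatments;
ATP is credited at textbook P/O ratios, n_N = 2.5 per NADH and n_F = 1.5
per FADH₂.  The ATP load is `basal·ATP/(K_b+ATP) + k_use·ATP/(K_load+ATP)`;
`k_use` is the tunable "rate of ATP consumption" swept in the demand
scenarios, and both terms vanish at ATP = 0 so demand can never drive ATP
negative.  Lower glycolysis carries an ADP saturation factor for the same
reason in the other direction: substrate-level phosphorylation cannot push
ATP above the adenine pool.

Enzyme up/down-regulation is always a dimensionless multiplicative factor
on the reaction's maximal rate (`activity[...]`); the kinetic constants
themselves are never edited by scenarios.

The baseline model holds the cytosolic NAD⁺:NADH ratio fixed at r = 10,
mimicking the net effect of the redox shuttles; net cytosolic NADH beyond
what lactate export consumes is treated as handled outside the ATP economy
(it is credited only in the yield *accounting*, below).  The extended model
(`redox` module) makes NADH_c dynamic and adds the glycerol-3-phosphate
shuttle (electrons delivered at the FADH₂ level; the DHAP/G3P carbon
round-trip is net zero and not tracked) and an NAD⁺-use flux — a
biosynthetic demand consuming NAD⁺_c (and ATP) that serves as the
proliferation proxy when redox capacity, not carbon, is limiting.  Because
the shuttle is irreversible and converts shuttled electrons into ATP
dynamically, the extended model is not exactly the baseline's limit: with
the shuttle sized to hold the cytosolic ratio near the baseline's fixed
value, the two agree in phospholipid flux to ~15–20%, the offset being the
shuttle's ATP contribution.

Cytosolic citrate is carried as a state for completeness of the species
set, but the citrate-export lump (R17: CIT_m → acetyl-CoA_c + malate_m,
with the cytosolic OAA returned to the mitochondrial malate pool) gives it
no net turnover; it is inert.

## Steady-state solving

The stiff system is integrated with BDF in growing time chunks until
max|dC/dt| < 10⁻⁶ mM h⁻¹ (default `ss_tol`), up to t_max = 10⁴ h, with a
concentration ceiling of 10⁴ mM declaring a run unbounded and a work budget
declaring it stalled (e.g. on a limit cycle).  The integrator's answer is
then polished by a bounded least-squares root solve.  When the integration
stops short of `ss_tol` (slowly damped approaches), a polished root is
accepted only if it is nearby and verifiably stable — a short
re-integration from it must not drift away — so an unstable fixed point
inside a limit cycle is never reported as converged.  Long integration
first makes the procedure respect basins of attraction: in the bistable
regime the reported state is the one reached from the supplied initial
state, which is what lets up/down continuation sweeps trace hysteresis.
There is no randomness anywhere; re-running any computation is
bit-identical.

## Yield accounting

`atp_yield_per_glucose` computes, at a converged glutamine-free steady
state, [gross ATP production (all positive ATP-ledger terms, with the
electron-transport steps at their P/O yields) − ATP invested in glucose
processing (uptake/HK and PFK) + n_shuttle·max(0, v_lower-glycolysis −
v_LDH)] / glucose uptake.  The shuttle credit covers the cytosolic NADH
that is not consumed by lactate export, at n_F = 1.5 (glycerol-3-phosphate
accounting) or n_N = 2.5 (malate–aspartate accounting).  Two identities are
forced by stoichiometry alone and serve as the package's hard numerical
anchors:

* lactate-only regime (PDH, PC and anabolic branches off, no glutamine):
  exactly **2** ATP per glucose, independent of every kinetic constant;
* full oxidation (LDH and every branch/bypass off — ribose, phospholipid,
  ACLY/ACC, malic enzyme, reductive IDH, AKG export — PDH high, normoxia):
  **30** ATP per glucose with the FADH₂-level shuttle credit and **32**
  with the NADH-level credit (ledger: 2 glycolytic + 2 GTP + 8 NADH·2.5 +
  2 FADH₂·1.5 + 2 shuttled·1.5 or ·2.5).

The full-oxidation protocol must disable *all* branch reactions, not only
the anabolic ones: each of ACLY, malic enzyme, reductive IDH and AKG export
drains or bypasses the C4 pool, and with no anaplerotic source a bounded
pure-oxidation steady state provably does not exist while any of them is
active.

## Calibrated defaults

The literature does not pin this lumped network's constants, so the default
parameter set was calibrated once — in the spirit of adjusting kinetic
constants until the model exhibits a bounded steady state — and then
frozen (`parameters.default_parameters`).  The choices that matter:

* Reference environment: glucose 5 mM, glutamine 2 mM, normoxia, ATP
  demand k_use = 320 mM h⁻¹ against K_load = 20 mM.  The large K_load makes
  the load nearly linear in ATP over the physiological range, which damps
  the PFK–ATP relaxation oscillation (the glycolytic oscillator) that
  otherwise replaces bistability near the switch.
* LDH is the low-affinity overflow valve for pyruvate (Km 2.0 mM) and PDH
  the high-affinity route (Km 0.15 mM).  This ordering is what stabilizes
  both branches of the glycolytic switch: at low flux pyruvate is oxidized
  (high yield keeps ATP up, PFK shut), at high flux the overflow goes to
  lactate (low marginal yield keeps ATP down, PFK open).
* The FBP pool is made slow (aldolase Km 5 mM) so the positive feedback
  variable is the slowest in the loop — a bistable switch rather than a
  relaxation oscillator.
* Default glutamine influx (GLS Vmax 3 mM h⁻¹) is sized below the
  anaplerotic disposal capacity (malic enzyme plus AKG export), so the
  reference state is bounded; the AKG exporter is a genuine relief valve
  (Vmax 3, Km 0.1 mM).
* Pool totals: adenine 5 mM, mito NAD 1.5 mM, mito FAD 1 mM, cytosolic NAD
  1 mM.

With these defaults the model shows a clean hysteresis window in the LDH
sweep (activity ≈ 4.5–9.5, relative branch separation ≈ 0.6) that
disappears when the FBP activation is removed, and a single
Warburg→OXPHOS crossover in the phospholipid flux as ATP demand is swept.

## Scenario presets

Each named preset freezes an in-silico experiment: grids, activity
configurations, environment, and the qualitative checks it must satisfy
(`run_preset`, or `warburgsim preset <name>`; `warburgsim validate` runs
everything).  Scenario constants were fixed together with the defaults:

* Hypoxia is O₂ = 0.015 with the electron-transport oxygen Km at 0.3, and
  the reductive scenarios upregulate glutamine uptake (GLS ×3.5) — hypoxic
  glutaminolysis then saturates the oxygen-limited electron transport and
  starves the NAD-hungry oxidative span, which is what makes
  fatty-acid synthesis depend on NADPH-IDH (reductive carboxylation)
  rather than on the PDH/MDH route.
* The anoxic demand sweep spans k_use 95–130, the regime in which ATP
  inhibition of PFK is partially engaged; below it the anoxic glycolytic
  switch is oscillatory (no steady state exists), above it lactate output
  saturates at transporter-limited capacity.  Lactate production rises
  strictly with demand on that regulated band.
* The anaplerosis-signature comparison (PC-reliant vs glutamine-reliant at
  matched fatty-acid flux) runs at high demand (k_use 600) where glycolysis
  is transporter-limited, so the lactate difference reflects pyruvate
  competition (two pyruvates per PC-derived citrate) rather than ATP
  feedback.  The PC multiplier is found by deterministic bisection on the
  fatty-acid flux.
* The glucose-deprivation scenario (glucose 0.002 mM, glutamine 0.5 mM)
  runs without AKG export, matching the glutamine-driven-TCA network it
  reproduces.  In this catalogue every *converged* flux pattern is
  independent of the malic-enzyme activity level (the ME2 flux is
  demand-determined), so the dependence on ME2 appears as a viability
  threshold: below it no bounded steady state exists (reported honestly as
  unconverged, with depressed ATP-use values), above it the cycle runs.
  "ATP use rises with ME2" is therefore a threshold statement here, as it
  is in the underlying biology.
* The redox-limited scenarios (extended model) run at low demand
  (k_use 44): ATP accumulation then throttles the ADP-limited electron
  transport, the FAD pool fills, the shuttle stalls and cytosolic NADH
  accumulates — the mechanism behind the falling cytosolic NAD⁺:NADH ratio
  and NAD⁺-use flux as PDH rises, and behind the reappearance of the
  demand crossover for the NAD⁺-use readout.
* In the narrow window where the Warburg configuration's glycolytic switch
  is on but the OXPHOS configuration's is not, their ATP-use fluxes come
  within ~1%; the "high PDH maximizes ATP-consuming flux" check therefore
  allows a 3% tolerance there while requiring strict dominance at ≥85% of
  grid points and at both ends of the demand range.
* Under the constant-ATP clamp (the protocol for the uptake-vs-branch-
  activity grids) glucose uptake in this lumped catalogue is structurally
  insensitive to LDH/PDH activity — the only coupling from pyruvate back to
  upper glycolysis runs through ATP, which the clamp freezes.  The preset
  reports the clamped grid and, alongside it, the unclamped grid in which
  the LDH-driven uptake increase (via relief of PFK inhibition) does
  appear.

## Hysteresis detection

`detect_bistability` compares paired up/down continuation sweeps: the
largest adjacent jump on each branch marks its transition; the system is
called bistable when the transitions are separated by more than one grid
step and the branches differ by more than 20% (relative) between them.
Default sweep grids are 25 log-spaced points.

## What the scenarios do and do not show

All inputs are synthetic by construction — the model *is* the study object,
and the presets are in-silico experiments on it.  Passing checks show that
the implemented feedback structure reproduces the documented qualitative
behaviours under the frozen defaults; they do not show that the defaults
describe any real cell line (no data are fitted), and the absolute flux
and concentration scales are nominal.  Known limitations: no β-oxidation,
ROS/glutathione, ammonia recycling or explicit malate–aspartate shuttle;
NADPH is an untracked resource; oxygen is an environmental parameter, not
a transported species; a single adenine pool spans both compartments; and
the citrate-export lump returns cytosolic OAA to the mitochondrial malate
pool, which gives the network an oxygen-cheap oxidative bypass that the
hypoxia scenarios must out-compete (see above) and keeps cytosolic citrate
inert.  Strict anoxia (O₂ = 0) at low demand leaves the glycolytic switch
oscillatory; the solver reports such points honestly as unconverged rather
than averaging over the cycle.
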