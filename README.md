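# warburgsim

A mechanistic kinetic model of tumor central-carbon metabolism, built for
exploring why proliferating cells adopt the metabolic phenotypes they do:
aerobic glycolysis (the Warburg effect), glutamine- versus pyruvate-
carboxylase-driven anaplerosis, reductive carboxylation under hypoxia, and
glutamine-fuelled survival without glucose.

The package is aimed at systems-biology researchers who want a small,
interpretable ODE model of glycolysis + TCA cycle + simplified oxidative
phosphorylation + glutaminolysis — with the regulatory feedbacks that
matter — rather than a genome-scale reconstruction.

## The model in brief

22 reactions over 14 dynamic metabolite concentrations (mM; fluxes in
mM h⁻¹):

* glycolysis lumped into uptake+hexokinase, PFK, aldolase and a lower
  span yielding 2 ATP per triose, with ribose- and phospholipid-synthesis
  branches;
* the LDH/PDH branch point for pyruvate (lactate excretion vs
  mitochondrial oxidation);
* the TCA cycle with reversible MDH, NADPH-dependent IDH (reductive
  carboxylation), citrate export + ACLY + ACC (de novo fatty-acid
  synthesis), glutaminolysis, pyruvate carboxylase, malic enzyme and an
  α-ketoglutarate exporter;
* electron transport saturating in carrier, oxygen and ADP, credited at
  P/O ratios n_N = 2.5, n_F = 1.5;
* a tunable ATP load v = basal·ATP/(K_b+ATP) + k_use·ATP/(K_load+ATP).

The central regulatory element is PFK: Hill-inhibited by ATP and
allosterically activated by its product FBP,

v_PFK = a·V·(F6P/(K+F6P))·(ATP/(K_ATP+ATP))·1/(1+(ATP/K_I)ⁿ)·[1+(α−1)·FBPᵐ/(K_Aᵐ+FBPᵐ)]

The FBP positive feedback makes the glycolytic switch bistable; the ATP
inhibition couples it to the cell's energy state, so the rate of ATP
consumption decides which phenotype wins.  An extended variant makes the
cytosolic NAD⁺/NADH pool dynamic and adds the glycerol-3-phosphate shuttle
and an NAD⁺-use flux, for the regime where redox capacity rather than
carbon limits proliferation.  `docs/methods.md` has the full account.

## Worked example

```python
from warburgsim import (build_default_network, default_parameters,
                        integrate_to_steady_state)

m = build_default_network()
p = default_parameters()                      # frozen calibrated defaults
res = integrate_to_steady_state(m, p)
print(f"converged={res.converged}  ATP={res.state['ATP']:.2f} mM")
print(f"glucose uptake={res.readouts.glucose_uptake:.2f} mM/h  "
      f"ECAR={res.readouts.ecar_proxy:.2f}  OCR={res.readouts.ocr_proxy:.2f}")

# upregulate LDH tenfold, knock PDH down: the Warburg configuration
warburg = p.with_activity(LDH=10.0, PDH=0.1)
res_w = integrate_to_steady_state(m, warburg)
print(f"Warburg: ECAR={res_w.readouts.ecar_proxy:.2f}  "
      f"OCR={res_w.readouts.ocr_proxy:.2f}  "
      f"phospholipid flux={res_w.readouts.lipid_flux:.2f}")
```

prints

```
converged=True  ATP=2.76 mM
glucose uptake=3.78 mM/h  ECAR=1.69  OCR=16.35
Warburg: ECAR=17.86  OCR=5.60  phospholipid flux=1.43
```

— the default state respires and keeps lactate export low; the
high-LDH/low-PDH configuration switches to high glucose uptake with most
carbon excreted as lactate (ECAR up tenfold, OCR down threefold) and a
higher phospholipid-synthesis flux, the aerobic-glycolysis phenotype.

From the shell, the same experiment as a hysteresis sweep:

```
warburgsim sweep --param activity.LDH --from 0.05 --to 20 --points 25 \
    --direction both -o out/ldh_sweep
warburgsim preset fig1fg -o out/fig1fg     # the frozen scenario version
warburgsim validate                        # the full property suite
warburgsim list-presets
```

Presets are frozen in-silico experiments (bistability of the glycolytic
switch, the ATP-demand phenotype crossover, glutamine/PC anaplerosis,
hypoxic reductive carboxylation, glucose deprivation, the redox extension),
each with embedded qualitative checks; `validate` runs the structural
audits (carbon balance, pool conservation, solver cross-checks), the
stoichiometric yield identities and every preset.

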