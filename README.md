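# tdikin — kinetics of time-dependent enzyme inhibition

`tdikin` models what happens when an enzyme inhibitor binds or unbinds
*slowly* on the timescale of an activity assay, and why the conventional
steady-state analysis of initial velocities then misreads both the potency
and the mechanism of inhibition. The case study is the inhibition of
*Torpedo californica* acetylcholinesterase (AChE) by galantamine, an
anti-Alzheimer drug whose potency was underestimated ~100-fold for decades
because of exactly this artifact.

The package is aimed at enzymologists and medicinal chemists who want to

* simulate inhibited progress curves for arbitrary one- and two-step
  mass-action schemes (stiff ODE integration with multi-phase protocols:
  pre-incubation, reagent addition, sequential substrate additions);
* emulate complete initial-velocity experiments — dead time, order of
  reagent addition, Ellman-assay absorbance detection, replicate noise —
  and push them through the classic Lineweaver–Burk / Dixon /
  Cornish–Bowden workflow;
* fit full progress curves globally by repeated ODE integration, which
  recovers the inhibition constant *K*ᵢ together with the microscopic
  binding rates *k*₍on₎ and *k*₍off₎ that initial velocities cannot see.

## The model

Substrate hydrolysis by AChE follows the van Slyke–Cullen two-step scheme
with competitive product inhibition and a one-step competitive inhibitor:

    E + S  →  EA + P      (k1 = kcat/Km, apparent bimolecular constant)
    EA     →  E  + A      (k2 = kcat)
    E + P  ⇌  EP          (k3 / k4;  product Ki = k4/k3)
    E + I  ⇌  EI          (k5 / k6;  inhibitor Ki = k6/k5 = koff/kon)

P is thiocholine-TNB, the 412 nm chromophore of the Ellman assay
(ε = 13 600 M⁻¹cm⁻¹) — the detected species is itself a competitive
inhibitor. The drug–target **residence time** is τ = 1/k₍off₎.

Two closed-form limits explain the initial-velocity artifact for a
competitive inhibitor at rapid equilibrium,

    v_ss   = Vmax·S / (S + Km·(1 + I/Ki)),

versus a pre-incubated enzyme whose EI complex cannot dissociate during
the measurement,

    v_meas = Vmax·(1/(1 + I/Ki)) · S/(S + Km),

which is precisely the *pure noncompetitive* rate law. Intermediate
off-rates interpolate between the two, producing apparent mixed-type
inhibition from a purely competitive mechanism.

## Worked example

```python
from tdikin import (build_scheme, gal_design, generate_curves,
                    tcache_reference_rates, fit_curves_from_progress,
                    fit_stage1, fit_stage2)

truth = tcache_reference_rates()          # published TcAChE/galantamine constants

# stage 1: five sequential 35 uM substrate additions in one cuvette
design = gal_design("product_series")
curves = generate_curves(design, build_scheme("slyke_cullen_product"), truth)
s1 = fit_stage1(fit_curves_from_progress(curves, design),
                guesses={"k1": truth["k1"]*3, "k2": truth["k2"]/3, "k4": truth["k4"]*3})

# stage 2: galantamine series (50 uM ATCh, GAL 15-180 nM), stage-1 constants frozen
design2 = gal_design("gal_fit_series")
curves2 = generate_curves(design2, build_scheme("slyke_cullen_product_inhibitor"), truth)
s2 = fit_stage2(fit_curves_from_progress(curves2, design2), s1,
                guesses={"k5": truth["k5"]*3, "k6": truth["k6"]/3})
print(s2.derived())
```

Running `python analysis/03_global_fit.py` performs exactly this round
trip and prints:

```
stage 1 (hydrolysis + product inhibition):
  kcat      =    2965.0 1/s        (generated with 2965)
  kcat/Km   = 3.730e+08 1/(M s) (generated with 3.73e8)
  product Ki=     21.54 uM        (generated with 21.54)
stage 2 (galantamine binding kinetics):
  kon       = 1.900e+06 1/(M s) (generated with 1.9e6)
  koff      = 1.6055e-02 1/s     (generated with 1.6055e-2)
  Ki        =     8.450 nM        (generated with 8.45)
  residence =      62.3 s
```

i.e. starting from guesses a factor of three off, the global fit recovers
every generating constant from the curve shapes alone — including the
nanomolar galantamine *K*ᵢ and its ~60 s residence time, which no
initial-velocity analysis of the same curves can deliver.

The other drivers tell the cautionary half of the story:
`analysis/01_koff_scan.py` scans the off-rate of a competitive inhibitor
(true *K*ᵢ = 1 µM at every point) and tabulates how the replot analysis
reports competitive inhibition for fast unbinders, apparently mixed-type
inhibition for k₍off₎ between ~3×10⁻⁴ and 3×10⁻² s⁻¹, and apparently
pure noncompetitive inhibition below; `analysis/02_initiation_order.py`
shows that the same galantamine assay yields an apparent *K*ᵢ of ~90 nM
(a 10-fold overestimate) when enzyme-initiated and an apparent mixed
pattern when substrate-initiated after pre-incubation.

A `tdikin` command-line interface wraps the same computations
(`tdikin simulate|scan-koff|steady-state|globalfit --out DIR [--seed N]`).

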