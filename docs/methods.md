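# Methods

## Model and assumptions

All kinetics are elementary mass action over named species; no
steady-state, rapid-equilibrium or free-ligand assumption enters the
simulations (those approximations exist in the package only as the
closed-form rate laws `v_ss_competitive` and `v_meas_preincubated`, used
as analysis references and oracles). Four schemes are built in:

* `competitive_mm` — E+S ⇌ ES → E+P with E+I ⇌ EI. Used for the
  generic slow-unbinder study: ES association/dissociation 10⁸ M⁻¹s⁻¹ /
  1 s⁻¹ and kcat = 1000 s⁻¹, hence Km = (1+1000)/10⁸ ≈ 10 µM; the
  inhibitor on-rate is slaved to k_off/Ki with Ki = 1 µM so that a scan
  over k_off varies only the binding *kinetics*, never the potency.
* `mixed_mm` — adds ES+I ⇌ ESI (available for completeness; the study's
  generating truth is always competitive).
* `slyke_cullen_product` — the acetylcholinesterase hydrolysis scheme:
  E+S → EA+P (k1 = kcat/Km), EA → E+A (k2 = kcat), E+P ⇌ EP (k3/k4).
  The irreversible first step makes k1 an *apparent* bimolecular
  constant; only k1, k2 and the ratio k4/k3 are identifiable, so k3 is
  conventionally pinned at the diffusion limit 2×10⁸ M⁻¹s⁻¹.
* `slyke_cullen_product_inhibitor` — adds E+I ⇌ EI (k5/k6) for the
  one-step galantamine interaction. Ki = k6/k5, residence time τ = 1/k6.

Detection is treated as stoichiometric and instantaneous: the Ellman
chromophore thiocholine-TNB is identified with the first hydrolysis
product P (A = ε·l·[P], ε = 13 600 M⁻¹cm⁻¹, l = 1 cm). DTNB chemistry,
pipetting artifacts and cuvette dilution by the 2 µL substrate additions
(~0.2% per addition) are not modelled.

## Numerical integration

The schemes mix rates spanning ~10⁻⁴–10⁸, so the default integrator is
implicit (`scipy.integrate.solve_ivp`, BDF) with the analytic mass-action
Jacobian. Defaults: rtol 10⁻⁸, atol 10⁻¹⁴ M — the absolute tolerance
sits four decades below the 100 pM enzyme concentrations so enzyme
species keep ~4 significant digits; both are configurable through
`IntegratorOptions`. Linear conserved moieties (total enzyme, total
substrate-derived material) are preserved by the multistep method up to
the nonlinear-solver tolerance; the test suite checks < 10⁻⁶ relative
drift over a full 10⁶ s protocol. Concentrations in [−10·atol, 0) are
clamped to zero; anything more negative aborts with a diagnostic. Units
are fixed to molar and seconds internally; all conversions (absorbance,
µM/nM design constants) are explicit at the boundaries.

Protocols are sequences of phases (instantaneous additions, then a fixed
duration). An unsampled phase in which the only active chemistry is one
reversible bimolecular association — the canonical 10⁶ s or 20 min
enzyme–inhibitor pre-incubation — is fast-forwarded analytically to the
depletion-aware binding equilibrium
EI = 2·e₀·i₀ / (b + √(b² − 4·e₀·i₀)), b = e₀+i₀+K_d,
whenever the relaxation time 1/(k_on·(e₀+i₀) + k_off) is under 1/20 of
the phase duration; otherwise it is integrated. This avoids integrating
10⁶ s of an already-equilibrated system while remaining exact for
genuinely slow binders.

## The synthetic-data generator

`assays.py` turns assay designs into progress curves. The built-in
designs are the study conditions themselves:

* pre-incubation scan design: e₀ = 100 pM, S ∈ {1, 2, 5, 10, 20, 50,
  100, 150, 200} µM, I ∈ {0, 0.5, 1, 2, 5, 10, 20, 50} µM, 10⁶ s
  pre-incubation, substrate-initiated, 10 s dead time;
* TcAChE/galantamine designs: enzyme-initiated (200 pM enzyme, GAL
  0–400 nM, 60 s), substrate-initiated (50 pM, GAL 0–30 nM, 20 min
  pre-incubation), the five-sequential-addition product series (35 µM
  ATCh per addition, accumulated product 0 → 175 µM) and the long
  galantamine series (50 µM ATCh, GAL 0–180 nM, 33 min).

Choices the sources leave open, fixed here once: the substrate grid of
the enzyme-/substrate-initiated emulations is {10, 20, 50, 100, 200} µM
(only the 10–200 µM range is stated); each product-series addition phase
lasts 600 s, long enough that even the most product-inhibited reaction
exceeds 99% conversion; sampling intervals are 0.5 s for the 20–60 s
assays, 2 s for the product series and 3 s for the 33 min series —
comparable to a bench spectrophotometer and small enough that windowed
velocity estimates are quadrature-limited, not sampling-limited.

Noise is additive Gaussian on the detected signal, parameterised by an
absolute sd (absorbance units) and a relative sd combined in quadrature.
The reference studies are noiseless, so the default is zero noise and
every headline number is deterministic; noise exists for robustness
tests. Per-curve noise streams are derived from a master seed plus the
condition identity (s₀, i₀, replicate), so datasets are reproducible and
independent of generation order. The generator emulates dead time, order
of addition and detection, but not real-world drift, baseline offsets,
enzyme inactivation or temperature effects — passing round trips
therefore demonstrate correctness of the estimator under the stated
model, not robustness to un-modelled systematics.

## Initial velocities and the dead-time reading

`initial_velocity` offers three readings of "initial velocity":

* `chord` (default): the mean rate from mixing to the first usable
  reading, (P(t₁) − P(0))/t₁, with t₁ the dead time (or the window
  length when recording starts at mixing). This is the physically
  faithful dead-time artifact — the product formed during the unrecorded
  seconds accumulates into the first reading, so the hidden burst or lag
  is averaged in rather than discarded. It reproduces the
  "slope of the first 10 s" construction used for the Ellman curves and,
  applied to the pre-incubation study, yields the apparent-mechanism
  transition band quoted below.
* `window_slope`: OLS slope on [dead time, dead time + window], i.e. the
  dead-time stretch is discarded entirely. This reading *underweights*
  the hidden relaxation and shifts the apparent artifact band roughly
  threefold toward smaller k_off.
* `instantaneous`: finite-difference derivative at the dead time.

The double-reciprocal fits assume var(v) = (c·v)² (constant percentage
error), which propagates to var(1/v) ≈ (c/v)² and hence weights ∝ v² in
reciprocal space; the Dixon (LB slopes vs [I]) and Cornish–Bowden
(apparent 1/Vmax vs [I]) replots are unweighted straight lines whose
negated x-intercepts give K_ic and K_iu. A replot slope that is
non-positive, or below 10⁻³ of intercept/I_max, is reported as an absent
component (+∞, flagged — never a numeric sentinel in output tables).
Classification thresholds (competitive when K_iu/K_ic ≥ 10,
noncompetitive when ≤ 1.25, mixed between) are labelling conventions,
config-exposed and never used inside numeric fits.

With these defaults the k_off scan of a purely competitive 1 µM
inhibitor classifies k_off = 10² s⁻¹ as competitive and 10⁻⁴ s⁻¹ as
noncompetitive, with the apparent K_iu/K_ic ratio rising through ~20 at
k_off = 3×10⁻² s⁻¹ — the fast edge of the apparent mixed-type band.

## Recovery after pre-incubation

`approach_to_steady_state` compares the ES occupancy (instantaneous rate
/ kcat) of a pre-incubated slow unbinder against a fast-dissociating
reference of identical Ki, both at 200 µM substrate and 1 µM inhibitor.
The default criterion is the decay of the activity *deficit* to 3% of
its initial value (recovery 97% complete), matching the first-order
expectation that losing ~97% of the excess bound inhibitor takes
~3.5 residence times; an absolute within-3%-of-reference criterion is
also available. For k_off = 10⁻² s⁻¹ the default reads ~310 s,
consistent with "~350 s / completed in about six minutes" to within the
rebinding correction. Note the related first-order identity: 3.5τ
corresponds to 1 − e^(−3.5) ≈ 97% dissociation (95% takes ln 20 ≈ 3.0τ);
`fraction_dissociated` reports the analytic value.

## Global fitting

`global_fit` minimises the unweighted sum of squared residuals on the
detected-signal scale, simultaneously over all curves, by trust-region
reflective least squares (`scipy.optimize.least_squares`, ftol = xtol =
gtol = 10⁻¹²). Rate constants are optimised in natural-log space (they
span ~10 decades); concentration scale factors (shared e₀, per-curve s₀,
bounded ±20% of nominal) are linear. Standard errors come from the
linearised Jacobian at the optimum, s²(JᵀJ)⁻¹ with s² = RSS/(n−p); they
vanish for noiseless data, and `profile_uncertainty` provides 1-D
profiles (re-optimising all other parameters per grid point) where the
linearisation is suspect. A Jacobian condition number above 10⁸ flags a
structurally unidentifiable combination; parameters at their bounds are
flagged in the result message. Identical inputs give bit-identical
results.

The two-stage analysis mirrors practice: stage 1 fits k1, k2, k4 (k3
fixed at 2×10⁸ M⁻¹s⁻¹) to the product series — fitted as *one*
continuous five-phase trajectory, because the accumulated cuvette state
is the point of the design — and stage 2 freezes those values and fits
k5, k6 plus the concentration scales to the inhibited series. Whether
the original analysis fitted e₀ per curve or shared is not stated;
shared is assumed. Both stages recover their generating constants to
better than 0.1% from threefold-perturbed guesses on noiseless data.

## Known limitations

* One-step inhibitor binding only; the two-step induced-fit isomerisation
  mechanism is out of scope.
* No thermodynamic-cycle consistency checks for user-defined schemes, no
  spatial or temperature effects, termolecular steps unsupported.
* The chord velocity reading uses a single first reading; with heavy
  noise, replicate averaging (or `window_slope`) is the robust choice.
* Profile uncertainty is 1-D only; no Bayesian posterior sampling.
* The printed case-study constants are mutually inconsistent at rounding
  level (k_on·Ki = 1.9×10⁶ × 8.45 nM = 1.606×10⁻² s⁻¹ vs a quoted k_off
  of 1.57×10⁻² s⁻¹, whose reciprocal is 63.7 s, quoted as 63.8 s).
  Round trips generate with (k_on, Ki) and derive k_off from them.
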