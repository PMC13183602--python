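# Methods

## The mechanistic cell model

`episurf.cellmodel` implements a reduced steady-state model of a renal
epithelial cell between two prescribed compartments, the tubular lumen and
the interstitium, with a paracellular shunt connecting them directly. Two
variants are shipped:

* **PCT** (proximal convoluted tubule): five solutes (Na⁺, K⁺, Cl⁻, HCO₃⁻,
  glucose), osmotic water transport and a variable cell volume. Apical
  NHE3 (electroneutral 1:1 Na⁺/H⁺ exchange) and SGLT2 (electrogenic
  1 Na⁺ : 1 glucose), basolateral Na⁺/K⁺-ATPase, NBCe1
  (1 Na⁺ : 3 HCO₃⁻, net charge −2 per cycle), K⁺/Cl⁻/HCO₃⁻ channels and a
  passive glucose carrier.
* **mTAL** (medullary thick ascending limb): three solutes (Na⁺, K⁺,
  Cl⁻), water-impermeable with fixed volume. Apical NKCC2
  (electroneutral 1 Na⁺ : 1 K⁺ : 2 Cl⁻) and a K⁺ channel (luminal K⁺
  recycling), basolateral pump, K⁺ and Cl⁻ channels.

Protons are clamped in every compartment (fixed pH), which collapses the
acid–base system onto a single HCO₃⁻ balance: in the PCT, every H⁺
secreted by NHE3 leaves behind one HCO₃⁻ produced by CO₂ hydration, so the
intracellular HCO₃⁻ source rate equals the NHE3 flux. The lateral
intercellular space is not represented; the paracellular pathway is a
direct lumen→interstitium shunt. These reductions keep the model a smooth,
electroneutral, stiff steady-state map with the named transporters — the
properties the surrogate framework actually exercises — without the full
acid–base chemistry of comprehensive nephron cell models.

### Flux laws

* Channels: Goldman–Hodgkin–Katz constant-field flux
  `J = P ξ (C_i − C_e e^{−ξ})/(1 − e^{−ξ})`, `ξ = zFV/RT`, with the regular
  series limit below |ξ| = 10⁻⁶ and plain Fick diffusion for z = 0.
* Na⁺/K⁺-ATPase: cycle rate `Jmax · (Na/(Na+K_Na))³ · (K/(K+K_K))²`
  exporting 3 Na⁺ and importing 2 K⁺ per cycle (K_Na = 15 mM on cytosolic
  Na⁺, K_K = 2.5 mM on interstitial K⁺).
* NHE3: symmetric mass-action antiport,
  `J = x (Na_L H_C − Na_C H_L) / ((Na_L+Na_C)(H_L+H_C))`.
* Cotransporters (NKCC2, NBCe1, SGLT2): linear nonequilibrium
  thermodynamics, `J = x · Δμ` with
  `Δμ = Σ_k s_k RT ln(C_k,i/C_k,e) + z_net F (V_i − V_e)`. The electrical
  term always uses the potential of the *from* side minus the *to* side;
  for the apical SGLT2 that is `V_lumen − V_cell = −Va`.
* Water: `Jv = Pf·Vw·(osm_e − osm_i)`, toward higher osmolarity.

Units: concentrations mM, potentials mV (interstitium = 0), permeabilities
cm/s, solute fluxes mM·cm·s⁻¹ (≡ 10⁻³ mmol s⁻¹ cm⁻²), volume cm³ per cm²
of epithelium. Fluxes are positive in the reabsorptive direction. `Va` is
defined as `V_cell − V_lumen` and `Vb` as `V_cell` (cell minus
interstitium).

### Governing system and solver

Unknowns: cytosolic concentrations, cell volume (PCT), `V_cell`,
`V_lumen`. Equations: one mass balance per solute (apical influx +
intracellular source − basolateral efflux), water balance (PCT),
cytosolic electroneutrality including the fixed impermeant anion, and the
open-circuit condition (transcellular plus paracellular current zero).
Residuals are scaled — mass balances by the baseline pump throughput
3·Jmax, the water balance additionally by Vw, electroneutrality by 1 mM,
current by F·3·Jmax — so a single ∞-norm tolerance of 10⁻¹⁰ is meaningful
across equations.

The solver is a damped Newton iteration on log-concentrations and
log-volume (guaranteeing positivity) with raw potentials, a forward
finite-difference Jacobian (relative step 10⁻⁷), and a trust-region-style
step cap (≤ 0.7 log-units on concentrations, ≤ 20 mV on potentials). Step
acceptance uses the affine-invariant (natural) monotonicity test: a trial
point is accepted when the simplified Newton correction computed from the
current Jacobian shrinks. This matters because electroneutrality is
quadratic in the log variables, so the residual norm can transiently grow
along an essentially exact Newton step; a plain residual-norm line search
stalls exactly there. Cold starts use the interstitial composition with
Na⁺/K⁺ moved to typical cytosolic values (15/130 mM), Cl⁻ adjusted for
electroneutrality, V_cell = −70 mV, V_lumen = −1 mV. Failures raise an
explicit error carrying the last iterate — never a silent wrong answer.

An independent pseudo-transient relaxation integrator
(`relax_to_steady_state`) serves as a test-time oracle: explicit Euler on
the solute amounts with both potentials re-resolved algebraically at every
step (zero net cell charge flux + open circuit, an inner two-variable
Newton), an explicit-Euler stability cap estimated from the diagonal of
the amount-space rate Jacobian, and adaptive step halving. It shares the
flux laws but none of the solver machinery, and the suite requires
agreement with Newton to 10⁻⁶ relative on random parameter sets.

### Baseline parameterization

Baselines are not hand-tuned: `scripts/calibrate.py` fixes boundary
compositions and a physiologically plausible target cytosolic state
(PCT: Na 15, K 130, HCO₃ 25 mM, V_cell −70 mV, V_lumen −1 mV; mTAL: Na 13,
K 130, Cl 25 mM, V_lumen +3 mV) and solves in closed form for the
transporter activities and remaining permeabilities that make that state
an exact steady state — K⁺ channels carry the pump's K⁺ uptake, NBCe1
disposes of NHE3-generated HCO₃⁻, basolateral Cl⁻ follows NKCC2 input, and
one paracellular permeability closes the open-circuit condition. Cytosolic
Cl⁻ in the PCT settles at its passive double-membrane balance point
(≈ 8 mM at these potentials; there is no secondary-active Cl⁻ entry in the
reduced model). The PCT water permeability is an effective value chosen so
volume equilibrates much faster than solutes without dominating the
stiffness. The resulting YAML files under `src/episurf/config/` are frozen
and shipped; the female variants apply multiplicative factors to the four
varied parameters (PCT: NHE3 ×0.70, Na⁺/K⁺-ATPase ×0.85, NBCe1 ×0.85,
basolateral P_K ×1.00; mTAL: NKCC2 ×1.15, pump ×0.90, apical P_K ×1.10,
basolateral P_K ×0.90). These factors are sized to produce measurable
cross-sex surrogate error with the mTAL sexes closer together than the PCT
sexes; they are plausible placeholders, not fitted rodent values.

## Data generation

The four varied transport parameters per variant (PCT: NHE3, pump, NBCe1,
basolateral P_K; mTAL: NKCC2, pump, apical P_K, basolateral P_K) sweep
50%–200% of baseline. The default training design is a full-factorial grid
with 8 log-spaced levels per parameter (8⁴ = 4096 points) ordered along a
boustrophedon path, so consecutive points differ in one parameter by one
level and every solve warm-starts from its neighbour — the continuation
scheme that eliminates convergence failures in practice. Validation
designs sample log-uniformly (multiplicative, symmetric in log space);
inhibition designs draw the named parameter uniformly on
[mean − 0.2, mean + 0.2]×baseline around the reduced mean (NHE3 −40% for
PCT, NKCC2 −70% for mTAL), leaving the others at their training
distributions. Random designs warm-start from the nearest already-solved
point in log-parameter space, with cold-start and relaxation fallbacks.

## Surrogates

Networks are 4→16→16→4 multilayer perceptrons (ReLU hidden layers,
inverted dropout 0.1 during training only), implemented directly in numpy
so trained bundles are a portable JSON manifest plus CSV weight table.
Forward surrogates map the four parameters, encoded as fractions of the
variant's own baseline, to cytosolic [Na⁺], [K⁺], Va and Vb; inverse
surrogates map observables ([Na⁺], [K⁺], transcellular Na⁺ and K⁺ fluxes)
back to the four parameter fractions. The fraction encoding is what makes
the two sexes genuinely different learning problems over a shared input
box: the sexes differ exactly in the baselines of the varied parameters,
so absolute-value features would make male and female induce the same
input→output function and no cross-sex transfer gap could exist.

Training: seeded 80:20 train–test split, per-column standardization fitted
on the training split only, mean squared error on standardized outputs (so
mM and mV targets contribute comparably), Adam (lr 10⁻³, batch 64, up to
2000 epochs), early stopping with patience 100 restoring the best
test-loss weights. One seeded generator drives the split, initialization,
batch order and dropout masks, so identical configurations reproduce
identical weights bit for bit. Dropout is off at inference.

## Evaluation and experiments

Accuracy is the fractional mean squared error per output,
`fMSE = 100 · Σ(ŷ−y)² / Σy²` (scale-free, robust to near-zero individual
entries); aggregate reports average the per-output values. Ground truth
for every validation is freshly solved by the mechanistic model;
unconverged truth rows are excluded and counted, and more than 5% of them
aborts the validation as a solver regression.

`experiments` reproduces the study design: the forward accuracy matrix
(male-, female- and jointly-trained surrogates, each validated on both
sexes), the inhibition scenarios (validation below the training range),
and the inverse identifiability experiment. PCT inverse datasets jitter
the unobserved SGLT2 activity ±10% (log-uniform, seeded) so NHE3 competes
with a nuisance apical Na⁺ pathway. NBCe1 unidentifiability needs no added
mechanism: with clamped pH its cycle flux is pinned by the HCO₃⁻ balance
to the NHE3-driven source, so varying its activity mostly moves cytosolic
HCO₃⁻, which the Na⁺/K⁺ observables barely see.

## Problem sizes and determinism

The shipped experiment defaults are the study sizes: 4096-sample training
sets, 250-point validations, both sexes, both cell types. The full
replication (`episurf replicate-all`) runs in a few minutes on one CPU;
unit tests use smaller designs (3³–5⁴ grids, 40–100-point validations)
where the property under test does not depend on scale. All randomness
flows from explicit integer seeds through `numpy` generators; per-stage
sub-seeds are derived from the base seed and a stage tag, and stay below
2³¹.

## What the synthetic setting does and does not show

All data here are generated by the reduced mechanistic model itself, so
passing tests demonstrate properties of the surrogate *framework* —
learnability of a smooth electroneutral steady-state map, continuation
robustness, the sex-transfer and identifiability orderings — not fidelity
to any particular published parameter set. The reduced model is smoother
and lower-dimensional than comprehensive 15-solute epithelial models:
surrogate errors are accordingly much smaller (same-distribution aggregate
fMSE of order 0.01–0.1% rather than a few percent), and error *structure*
that depends on strong acid–base or voltage nonlinearities (for example,
which output degrades most under transporter inhibition) need not
transfer. Real tubular data would additionally contain measurement noise,
axial heterogeneity and regulation (flow-dependent transport, hormonal
modulation) that no part of this generator emulates.

## Known limitations

* Three compartments only; no lateral intercellular space, so paracellular
  coupling to transcellular water flux is absent.
* Clamped pH removes buffering dynamics; HCO₃⁻ behaves as a single slaved
  species.
* Linear thermodynamic cotransporter kinetics are sign-correct and smooth
  but saturate nowhere; extreme parameter corners can produce cytosolic
  glucose or HCO₃⁻ excursions beyond physiological ranges.
* The mTAL cell volume is fixed; volume regulation is not modelled.
* Sex differences are multiplicative factors on four parameters; tubular
  geometry and the many other sexually dimorphic transporters are not
  represented.
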