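# episurf

Neural-network surrogates for steady-state models of renal epithelial
solute transport.

Mechanistic models of tubular epithelial cells — coupled nonlinear
differential-algebraic systems of mass balances, electroneutrality and
membrane flux laws — are powerful but brittle: Newton-type solvers need
initial guesses close to the solution, and parameter changes that
represent new physiological scenarios routinely push them outside the
basin of convergence. `episurf` packages the alternative workflow: solve
the mechanistic model robustly over a parameter sweep *once*, using
continuation so every solve warm-starts from a neighbour, then train a
small feed-forward network as a fast, failure-free surrogate of the
steady-state map. The surrogate can also be trained in the inverse
direction, inferring membrane transport properties from measurable
cellular quantities.

The package is aimed at renal physiologists and modellers who want to
explore transporter perturbations (sex differences, pharmacological
inhibition, parameter inference) without wrestling with stiff solvers.

## What is inside

* `episurf.cellmodel` — a reduced steady-state model of a proximal
  convoluted tubule (PCT) cell (Na⁺, K⁺, Cl⁻, HCO₃⁻, glucose; NHE3,
  SGLT2, NBCe1, Na⁺/K⁺-ATPase; osmotic water flow) and a medullary thick
  ascending limb (mTAL) cell (Na⁺, K⁺, Cl⁻; NKCC2, Na⁺/K⁺-ATPase, K⁺
  recycling), each between a lumen and interstitium of prescribed
  composition with a paracellular shunt. Channel fluxes follow the
  Goldman–Hodgkin–Katz constant-field equation, the pump follows
  cubic/squared Michaelis–Menten kinetics, and cotransporters use linear
  thermodynamic driving forces. The steady state (cytosolic composition,
  cell volume, membrane potentials Va and Vb) is found by a damped Newton
  method on log-transformed unknowns with an affine-invariant line
  search; an independent pseudo-transient relaxation integrator verifies
  it in the test suite.
* `episurf.datagen` — parameter designs (snake-ordered full-factorial
  grids for continuation, log-uniform random samples, inhibition-shifted
  distributions) over 50%–200% of baseline for four transport parameters
  per cell type, plus CSV+JSON dataset I/O.
* `episurf.surrogate` — a from-scratch numpy MLP (4→16→16→4, ReLU,
  dropout 0.1, Adam, 80:20 split, early stopping), forward
  (parameters → cellular state) or inverse (observables → parameters),
  with portable JSON+CSV serialization.
* `episurf.evaluate` — fractional mean squared error,
  `fMSE = 100·Σ(ŷ−y)²/Σy²` per output variable, validation against
  freshly solved ground truth, and scatter tables.
* `episurf.experiments` — one-command replication of the study design:
  sex-specific / cross-sex / sex-inclusive accuracy matrices, transporter
  inhibition (NHE3 −40% in PCT, NKCC2 −70% in mTAL, sampled below the
  training range), and inverse identifiability.

See `docs/methods.md` for the model equations, solver details, and the
reasoning behind the defaults.

## Worked example

Generate a 4⁴ training grid for the male mTAL cell, train a forward
surrogate, and validate it on 100 previously unseen parameter sets:

```sh
$ episurf generate --cell mtal --sex m --mode grid --levels 4 --seed 7 --out demo_ds
wrote 256 rows for mtal_male -> demo_ds.csv

$ episurf train --data demo_ds --direction forward --seed 7 --out demo_surr
trained forward surrogate: best test loss 2.112e-02 at epoch 955; saved to demo_surr

$ episurf validate --surrogate demo_surr --cell mtal --sex m -n 100 --seed 8
{
 "per_output": {
  "Na_cell": 0.26008416510214616,
  "K_cell": 0.0034884135892134707,
  "Va": 0.0031254393418905587,
  "Vb": 0.0025766210511971644
 },
 "aggregate": 0.06731865977111184,
 "n_samples": 100,
 "direction": "forward",
 "scenario": "random",
 "n_excluded": 0
}
```

Each `per_output` entry is the fractional MSE (%) of one predicted
variable against the mechanistic model on fresh samples: here the
surrogate predicts cytosolic [Na⁺] to 0.26% fractional error and the
membrane potentials to ~0.003%, for an aggregate of 0.067% — even from a
coarse 256-point training grid, and with every ground-truth solve
converging (`n_excluded: 0`). The full study uses 8-level grids (4096
samples, `--levels 8`) and 250-point validations; `episurf replicate-all
--seed 1 --out results` runs the complete suite (both cell types, all
sex-pairing, inhibition and inverse scenarios) and writes datasets,
surrogate bundles, metric tables and a provenance manifest.

The same objects are available as a library:

```python
from episurf import load_variant, solve_steady_state

pct = load_variant("pct_male")
state = solve_steady_state(pct)          # cold start, converges in ~5 steps
state.cytosol.concentrations["Na"]       # 15.0 mM
state.Va, state.Vb                       # (-69.0, -70.0) mV
```

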