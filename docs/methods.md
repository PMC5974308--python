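# Methods

## The learning problem

`pathdyn` treats a metabolic pathway as a dynamical system

    dm/dt = f(m(t), p(t)),

where `m` is the vector of `n` pathway metabolite concentrations and `p`
the vector of `l` pathway enzyme concentrations. Instead of positing a rate
law for `f` (the kinetic-modelling route), `f` is learned by supervised
regression from time-series multiomics observations: each retained time
point of each training strain contributes one example mapping the
concatenated state `(m, p)` (length `n + l`) to the estimated metabolite
derivative `dm/dt`. Prediction for an unseen strain then solves the initial
value problem `dm/dt = f(m, p̃(t))`, `m(t0) = m̃(t0)`, where `p̃(t)`
interpolates that strain's measured protein series — the proteins are
exogenous inputs, the metabolites are the evolving state.

Assumptions inherited by everything downstream:

* all dynamically relevant metabolites and proteins are measured — the
  instantaneous `(m, p)` determines `dm/dt` (no hidden memory states);
* concentrations vary smoothly between samples, so filtering/interpolation
  of sparse series is meaningful;
* units are consistent across strains (the method is otherwise
  unit-agnostic).

## Training-set construction

Observed series (typically 7 points over 72 h, mimicking fermentation
sampling practice) are processed per strain:

1. **Savitzky–Golay filtering** of every metabolite and protein column,
   window 7, polynomial order 2. With exactly seven samples this degenerates
   to a single global quadratic fit — accepted, since it is the stated
   operating point of the procedure. Smoothed values are clipped at zero.
2. **Augmentation**: each filtered column is interpolated (cubic spline;
   monotone-preserving PCHIP for columns whose spline overshoots below
   zero; clipped at zero) onto a uniform grid of 200 points spanning the
   observed window. No extrapolation beyond the first/last sample.
3. **Differentiation** of the metabolite columns on the augmented grid:
   central differences with the nonuniform-grid weights at interior points,
   one-sided differences at the two endpoints, so every grid point keeps a
   training example.

Order of operations (smooth → interpolate → differentiate on the dense
grid) maximises the number of state–derivative pairs; with `q` training
strains the training set has `200 q` rows.

## Model selection

One scalar regressor per metabolite is chosen by cross-validated RMSE and
refit on all rows. Two choices deserve emphasis:

* **Fold assignment groups rows by strain.** Augmented time points within
  one strain are near-duplicates; random row folds would score a pure
  interpolator (k-nearest-neighbours) at near-zero RMSE regardless of how
  it behaves on unseen strains. Grouped folds (one or more whole strains
  per fold; tenfold when ≥ 10 strains, one fold per strain below that,
  shuffled row folds only for single-strain sets) make the CV score measure
  exactly the cross-strain transfer that trajectory prediction requires.
  This mattered more than any other design choice: with row-shuffled folds
  the selected models ranked held-out strains no better than Spearman ~0.3.
* **The default candidate space is small and extrapolation-aware**: ridge
  (α=0.01), quadratic polynomial ridge (α=1), quadratic ridge on
  log1p-scaled features (α=3), and distance-weighted 5-NN, each behind a
  feature standardiser; `SearchSpace.extended()` adds a small random
  forest, gradient boosting, and RBF kernel ridge. Concentrations span
  decades, which is why a log-scaled candidate earns its place; the ridge
  penalties are deliberately non-negligible because quadratic features
  extrapolate violently outside the training hull. Ties break toward fewer
  pipeline steps, then fewer hyperparameters, then declaration order. An
  evolutionary search backend can be plugged in by supplying candidates
  built by an external optimiser; selection stays argmin-of-CV-RMSE.

Derivative-level accuracy is assessed by repeated shuffle splits (Pearson
R² of predicted vs. estimated derivatives on train and test rows), the same
protocol used to report aggregate derivative correlations.

## Trajectory prediction

The learned field is integrated with adaptive RK45 (default rtol 1e-6,
atol 1e-9; the scaling/ranking experiments use 1e-4/1e-7, which changes
final states by well under the learned field's own error). Guards, all
logged in the prediction diagnostics:

* the state passed to `f` is clipped at zero (learned regressors know
  nothing about nonnegativity);
* predicted rates are clipped to the per-metabolite training-target
  interval expanded by one span on each side — quadratic winners otherwise
  extrapolate to rates orders of magnitude beyond anything observed and
  either trip the divergence guard or corrupt the trajectory;
* integration aborts (with the last valid time) if any state exceeds 1e6
  times that feature's training maximum.

Error compounding is real: derivative-level accuracy does not bound
trajectory accuracy, because every prediction feeds the next state. The
closed-loop tests, not the derivative R², are the meaningful check.

## The ground-truth simulator

The virtual-strain generator is a 10-state Michaelis–Menten model of the
limonene-producing mevalonate pathway (acetyl-CoA, acetoacetyl-CoA,
HMG-CoA, mevalonate, mevalonate-P, mevalonate-PP, IPP, DMAPP, GPP,
limonene) driven by nine enzymes (AtoB, HMGS, HMGR, MK, PMK, PMD, Idi,
GPPS, LS). Every reaction is `v = kcat·E·S/(Km+S)`; AtoB consumes two
acetyl-CoA per condensation, Idi is reversible, GPPS carries a
dual-saturation term in IPP and DMAPP, and host central metabolism enters
as a constant acetyl-CoA source plus a first-order drain (without the
drain, any supply beyond pathway demand would accumulate without bound).

The reference constants (`src/pathdyn/data/reference_model.yaml`, arbitrary
concentration units of order mM, hours) are a documented surrogate for
literature-derived values, chosen for two properties:

* **non-trivial dynamics** — at the reference expression profiles every
  intermediate shows a rise–peak–decline over 72 h, and limonene is a
  monotone terminal sink;
* **concentrated production control** — the terpene synthase step (LS) is
  strongly rate-limiting and AtoB secondary, with the mevalonate trunk
  carrying excess capacity. Real engineered pathways show exactly this
  driver structure (a few enzymes dominate production), and it is what
  makes a ten-strain training set informative: with all nine steps
  comparably limiting, final titre becomes a nine-dimensional function
  that no regressor — not even a nearest-neighbour oracle — can rank from
  ten examples.

Virtual strains share these constants and differ only in protein
expression: each enzyme gets a leaky Hill profile `p(t) = k_f·t/(k_m+t) +
k_l` with coefficients drawn log-uniformly — amplitudes over one decade
around the reference level (`k_f ∈ ref·[1/3, 3]`), half-saturation times
`k_m ∈ [4, 16]` h, leaks `k_l ∈ [0.02, 0.2]`. Under these defaults a pool's
final limonene titres span roughly eightfold (coefficient of variation
~0.6). Strains are sampled at 7 evenly spaced points over 0–72 h by
default; integration is RK45 at rtol 1e-8 with output clipped at zero.

What the generator does **not** emulate: measurement noise (pools are
noise-free; the pipeline's smoothing stage is exercised but not stressed),
replicate variability, missing values, unit heterogeneity between omics
platforms, and any host-level regulation beyond the acetyl-CoA source/drain
proxy. Passing tests therefore demonstrate the machinery and its scaling
behaviour under clean conditions, not robustness to real measurement error.

## Evaluation

* **Integral trajectory RMSE** per strain:
  `RMSE = sqrt((1/n) Σ_j ∫ (m̄_j(t) − m_j(t))² dt)` with the reference
  interpolated (cubic spline; linear below four points) and the integral
  taken by the trapezoid rule on a 1001-point common grid.
* **Percent error** per metabolite: time-averaged |error| divided by
  time-averaged reference magnitude, ×100. The normalisation is a choice;
  absolute percent numbers are only comparable under the same definition.
  Identically-zero reference metabolites are reported as undefined and
  excluded from averages.
* **Ranking experiment**: for each training-set size and repeat, train on a
  random subset of the pool, predict final limonene for random triples of
  unseen strains by full forward integration, and count a triple as a
  success only when the complete predicted order matches the truth (a
  uniformly random ranker succeeds with probability 1/6). A diverged
  prediction fails its triple. The top-producer failure rate (argmax only)
  is reported alongside.
* **Scaling experiment**: integral RMSE on one fixed held-out strain as a
  function of training-set size, repeated over independent training draws;
  the held-out strain never contributes training rows.

Desk-scale experiment sizes (a package choice): pools of 300 strains,
training sizes {2, 10}, 10 repeats, 10 triples per repeat.

## Kinetic-model fitting baseline

The comparator fits all 23 kinetic constants to strain data by differential
evolution (scipy) over the box [1e-12, 1e9] per constant, searched in log10
space — a 21-decade box is not navigable linearly. The objective is the
summed squared deviation between simulated and observed metabolite values
at the observed times across training strains, with candidate simulations
that fail receiving a large finite penalty (1e12). Population-best
objective is nonincreasing by construction; `maxiter=0` returns the best
member of the initial (Sobol) population. Self-consistency — refitting data
the model itself generated, inside a tight box, with an L-BFGS-B polish —
recovers the trajectories to machine-level misfit.

## Insight analysis

Final-time proteomics for a set of strains (standardised per column, since
enzymes span scales) are regressed against final production by two-block
PLS. Component 1's unit-norm weight vector is the over/under-expression
recipe; strains are proposed by displacing the base strain's final protein
targets along the (raw-unit) direction and scaling whole expression
profiles multiplicatively to hit the displaced targets, then predicting all
metabolite trajectories with the learned model. Proposed profiles are
clipped at zero.

## Known limitations

* Cross-strain generalisation is the binding constraint everywhere. A
  regressor trained on a handful of strain trajectories sees a
  measure-zero sliver of the `(m, p)` space; prediction quality on an
  unseen strain depends on how close its trajectory passes to the training
  manifold. The ranking-success gain from 2 to 10 training strains is real
  in expectation but noisy across draws at desk scale, and held-out
  aggregate derivative R² plateaus near ~0.8 under the default conditions
  — below the ≥0.9 that within-strain (shuffle-split) assessment readily
  reports. The two protocols measure different things; the package reports
  both.
* The kinetic-fit baseline at full bounds is a hard global-optimisation
  problem; desk-scale budgets find qualitative, not converged, fits.
* Percent-error magnitudes depend on the normalisation definition above.
* The simulator's arbitrary units mean learned models do not transfer
  between datasets with different unit conventions.
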