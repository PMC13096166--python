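# Methods

`phbo` implements parallelized Bayesian optimization over hybrid
categorical-continuous spaces for iterative experimental campaigns. The
motivating application is enzyme-immobilization carrier discovery: choose a
zinc salt and an organic ligand (categorical) plus precursor concentrations
and reaction time (continuous) to maximize activity recovery (AR), the
apparent activity of the immobilized enzyme over the total activity of the
free enzyme input. AR is stored as a fraction and may exceed 1.

## Surrogate model

The objective is modeled by a Gaussian process on normalized coordinates
(continuous variables affinely mapped to [0, 1], categorical levels as
indices). The kernel combines

* a categorical kernel per variable: `k_cat(z, z') = 1` if the levels are
  equal and `exp(-1/l)` otherwise, with a learnable lengthscale `l > 0` per
  variable; multiple categorical variables compose by product,
* an ARD Matern 5/2 kernel `k_con` on the continuous block,

into the hybrid kernel

```
k_hyb = (1 - lambda) * (k_con + k_cat) + lambda * (k_con * k_cat),
```

with a single mixing weight `lambda in [0, 1]`. The sum term lets the model
share a continuous response profile across categorical assignments when
data are scarce (the early-campaign regime); the product term lets each
assignment carry its own profile. The kernel is kept exactly in this form,
so the prior variance at any point is `amplitude^2 * (2 - lambda)`; no
renormalization by `(2 - lambda)` is applied.

Observation noise is homoscedastic Gaussian; records imported from a source
campaign can carry a per-record noise scale that multiplies the noise
variance on the Gram diagonal. Objectives are z-scored before fitting and
predictions are mapped back.

All hyperparameters — continuous and categorical lengthscales, `lambda`,
amplitude, noise, constant prior mean — are fitted jointly by maximizing
the log marginal likelihood with multistart L-BFGS-B in unconstrained
transforms (log for positive parameters, logit for `lambda`), using
analytic gradients (verified against finite differences in the tests).
Defaults: 8 restarts, initial lengthscales log-uniform in [0.05, 2]
normalized units, `lambda` initialized at 0.5, transformed parameters
box-bounded to [-6, 6] (this implies a noise-variance floor of `e^-12`
standardized, which supersedes the nominal 1e-6 floor), base jitter 1e-8
escalating tenfold to 1e-4 before erroring. GP training is O(n^3) in the
number of observations; campaigns here stay below ~150 points.

## Acquisition and probabilistic reparameterization

The acquisition is the upper confidence bound `alpha = mu + sqrt(beta) *
sigma`. To optimize over the discontinuous categorical dimensions with
gradient methods, each categorical variable is reparameterized as an
independent softmax distribution over its levels with logits `theta`, and
the optimized objective becomes `E_z[alpha(x, z)]`. The continuous gradient
is the probability-weighted average of `d alpha/dx`; the logit gradient is
the REINFORCE score-function estimator

```
(1/N) sum_i (alpha(x, z_i) - beta_cv) * (I(z_i) - p(.|theta)),
```

with `N = 128` Monte Carlo draws by default and a control-variate baseline
`beta_cv = B *` (running mean of sampled acquisition values within the
current optimization call), `B = 1`. The estimator is unbiased for any
constant baseline because the score has zero mean; the baseline only
reduces variance. Exact enumeration of the expectation (feasible when the
level-count product is below a cap, default 10^4) serves as the oracle in
tests; the acquisition-optimization complexity is O(T M n^2) for T L-BFGS
iterations and M draws.

Joint optimization runs multistart L-BFGS-B over (x in its box, logits
clipped to +/-10). Each restart freezes one matrix of uniform draws and
transforms it through the current policy by inverse CDF (common random
numbers), making the Monte Carlo objective and gradient deterministic
functions of the parameters, so L-BFGS is well posed. Restart starts are
random (x uniform, logits standard normal) except restart 0, which starts
from the incumbent-best training point with logits leaning toward its
categorical assignment — a standard multistart heuristic that measurably
tightens the gap to an enumeration oracle. The final categorical assignment
is the per-variable argmax of the optimized probabilities (ties to the
lowest index; sampling is available behind a flag), followed by a
deterministic continuous L-BFGS polish at that fixed assignment, so the
returned value is `alpha` at the returned point. On fully enumerable toy
problems the optimum is attained at a degenerate policy and matches the
per-level continuous optimum to 1e-3 (verified).

`beta` defaults to 4. For campaign-scale categorical domains a larger
exploration weight is advisable: with ~10^2 categorical combinations, a
single mediocre discovery can otherwise outweigh the `2 sigma` bonus of
every unvisited combination and freeze exploration. The benchmark
configuration uses `beta = 9 ~ 2 ln|Z|` for the 7x17 landscape, following
the domain-size scaling of GP-UCB-style rules.

The continuous derivative of the posterior is computed analytically
(kernel gradients); a central finite-difference route (step 1e-5) backs the
public expectation-gradient function and any non-GP acquisition callable,
and the two routes are cross-checked in tests.

## Nearby-liar parallel batching

Batches of `q` conditions (default 8, matching parallel reactor capacity)
are built sequentially: fit hyperparameters once per round on the true
data; then, q times, optimize the acquisition on the current working set,
impute the suggestion's objective as the mean of its `N_NL` nearest
non-liar neighbors (default 3; all available if fewer) in the hybrid
distance, append it as a liar record, and recondition the posterior with
unchanged hyperparameters. Liar records never survive the call; measured
results replace them at integration. The hybrid distance is Euclidean on
normalized continuous coordinates plus one unit per mismatched categorical
level, under a joint square root — the metric is pluggable since other
weightings are defensible. Suggestions within 1e-6 of a pending batch point
trigger up to 5 re-optimizations with fresh restarts, then a random
continuous perturbation.

With fewer than two true observations the batch falls back to a seeded
space-filling design: scrambled Sobol points over the continuous box with
balanced (stratified round-robin, independently shuffled) categorical
levels, emulating a designed prior screen.

## Transfer learning

Two switchable mechanisms carry a finished source campaign into a new one
on the same variable schema: (i) warm-up — source records join the target
dataset with round index -1 and observation noise inflated by a
multiplier (default 2.0), hedging against cross-enzyme shift while keeping
the data informative; (ii) prior update — the target GP's constant prior
mean is initialized at the source fit's value and the full source
hyperparameter vector is added as one extra MLE restart. Both are soft
initializations; the extra restart can only improve the fitted likelihood
because the default restarts consume the RNG stream identically. Disabling
both reproduces cold-start behavior bit for bit.

## Baselines

* Local search: the alternating scheme — L-BFGS over the continuous part at
  a fixed categorical assignment, then greedy best-improvement
  single-variable level swaps at fixed continuous settings, up to 20
  alternations, accepting only improvements, with the same multistart
  count. It shares the surrogate and the nearby-liar batching, so campaign
  comparisons isolate the acquisition-optimization strategy.
* Random search: uniform over the box and the level sets; the scripted
  stand-in for expert one-variable-at-a-time exploration, which is
  human-driven and not reproducible as an algorithm.

## Synthetic landscape

The generator emulates a co-precipitation immobilization campaign over 7
zinc salts x 17 ligands with zinc concentration, ligand concentration and
reaction time as continuous settings. The noiseless response is

```
AR = cap * w[s,l]
      * exp(-(log(c_lig/c_zn) - r*[s,l])^2 / (2 * width^2))   # ratio optimum
      * (1 - exp(-t / tau))                                    # time saturation
      * sigmoid((thr - c_lig) / steep)                         # high-ligand loss
```

and exactly 0 when `c_lig/c_zn` falls below a precipitation floor.
Defaults and rationale:

* `cap = 1.1` — AR above 100% occurs in real campaigns; the optimizer must
  handle super-unit objectives.
* compatibility `w`: multiplicative salt x ligand main effects scaled into
  a mediocre band [0.05, 0.55], with 6 elite pairs drawn preferentially
  from the good-salt x good-ligand block and boosted into [0.9, 1.0]. Only
  a few combinations excel, but their location is learnable from the main
  effects — in real screens the same salts and ligands recur among the
  productive groups. (With elite pairs placed independently of any
  structure, identifying them at an ~90-experiment budget is
  information-theoretically hopeless for any method, which contradicts
  what such campaigns demonstrably achieve.)
* optimal log-ratios `r*`: one landscape-wide center, log-uniform in
  [0.8, 8], plus pair-specific Gaussian jitter (sd 0.6 in log units),
  clipped to [0.5, 16] — each enzyme system has a characteristic
  ligand/zinc ratio vicinity where high activity concentrates, with
  pair-level variation.
* `width = 0.8` log units — active ratios span roughly a 2-5x band around
  the optimum, matching the broad active ranges such syntheses show.
* `tau = 90` min over t in [1, 720] min; concentrations span
  [0.02, 2] mol/L (zinc) and [0.02, 8] mol/L (ligand), exposed to the
  optimizer on a log10 scale because they cover about two decades and the
  response ridge `log(c_lig/c_zn) = r*` is planar in log coordinates.
* ligand penalty threshold 6 mol/L with steepness 0.5 mol/L; precipitation
  floor at ratio 0.2.
* noise sd 0.03 (the few-percent scatter of triplicate assays), Gaussian,
  truncated at zero; failed precipitations score exactly 0, as a campaign
  records them.

The near-optimal basin of the best pair occupies ~4% of the continuous
volume (asserted <5% in tests), so matched-budget random search
underperforms. What passing benchmarks does NOT show: the landscape is
smooth, stationary and noiseless apart from i.i.d. Gaussian error — real
campaigns face batch effects, drifting reagents, heteroscedastic assays
and model misspecification that no synthetic check exercises.

## Benchmark protocol and problem sizes

Campaigns in tests and the acceptance script initialize with a 48-point
balanced space-filling screen (the prior-database stage a real campaign
starts from), then run 10 rounds of 8-condition batches — 128 reactions
total per campaign, for every method. The optimizer-comparison check uses
20 campaign seeds against the seed-7 landscape with surrogate MLE restarts
4 and acquisition restarts 8 (maxiter 50); the acceptance script reports a
5-seed version of the same comparison plus estimator/oracle agreement
gaps, chosen to keep a full run in a few minutes. "Best found" is the
campaign's own best measured objective.

## Numerical choices and edge cases

* Bounds are closed; values exactly at bounds are valid; the affine
  denormalization clamps 1-ulp overshoot.
* Gram factorizations add 1e-8 jitter, escalating tenfold to 1e-4.
* Duplicated rows remain factorizable through noise plus jitter.
* Constant objectives standardize with unit scale (guard against zero sd).
* Posterior variances are clipped at zero; the UCB gradient guards
  division by near-zero posterior sd.
* Monte Carlo draw deduplication uses mixed-radix bincount up to 10^6
  combinations and falls back to sorting-based uniqueness beyond.
* EE values with supernatant exceeding input clamp to 0 with a logged
  warning (assay noise), rather than erroring.
* Campaign state serializes to canonical JSON (sorted keys); save -> load
  -> save is byte-identical, and all CLI paths derive their randomness
  from the stored seed and round index.

## Known limitations

* Homoscedastic noise only; replicate SDs are stored but not used for
  heteroscedastic weighting.
* No conditional/hierarchical spaces, integer variables, or multi-task
  kernels; transfer is warm-up plus soft prior initialization.
* The liar working set holds hyperparameters fixed within a round;
  refitting per suggestion would cost O(q) extra MLE runs for little gain
  at these batch sizes.
* Dense GP algebra throughout; not intended beyond a few hundred
  observations.
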