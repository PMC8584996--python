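# Methods

`kolamkit` analyses kolam drawings — ritual loop patterns drawn by Tamil
women — as realisations of a Markov process over a finite lexicon of
drawing gestures, and asks how much of the variation in transition
behaviour is attributable to individual artists, their expertise, their
migration background, their caste community, and their neighborhood.
This note records the model, the numerical choices, and what the
synthetic-data machinery does and does not demonstrate.

## The state space and its grammar

The gesture lexicon contains 29 entries: 26 loop gestures plus 3 purely
decorative single gestures that never occur inside a loop.  Mirror-image
(left/right) gesture variants are distinct raw codes but are drawn the
same way up to reflection, so they collapse onto 14 model states: 6
orthogonal (O), 4 diagonal (D) and 4 transitional (T).  Orthogonal and
diagonal gestures have disjoint start/end positions and orientations and
can only be joined through transitional gestures; a valid loop therefore
never places an O state next to a D state, including across the closing
(last, first) pair.  The packaged lexicon file uses canonical raw codes
(o1l/o1r … t4, x1–x3) because the field lexicon's exact spellings are an
artefact of the transcription campaign; any 29-row file with the same
columns can be substituted to reproduce a particular transcription
convention.

## Counting

Every loop of every drawing contributes one transition per gesture,
including the wrap-around transition from the last gesture back to the
first (the starting gesture of a closed loop is unobservable, so the
loop is treated as a cycle).  Counts are aggregated per artist into a
14×14 matrix and then factored, mirroring the model's decomposition
P(next gesture | current) = P(next space | current space) × P(next
gesture | current gesture, within space), into a 3×3 between-space
matrix S (row/column order O, T, D) and within-space matrices 6×6 (O),
4×4 (D) and 4×4 (T).  Cross-space transitions contribute only to S —
the within matrices are the same-space diagonal blocks — which is the
only reading consistent with the factorisation and the matrix
dimensions.  A `wrap=False` counting mode drops the closure transition;
it exists for validation studies against generators that emit linear
sequences (see below).

## The hierarchical model

Each matrix row j for artist i is a multinomial over next states k with
softmax-linked cell probabilities,

    eta[i,j,k] = alpha[j,k] + beta_prac[j,k] z_i + beta_nat[j,k] native_i
               + a[i,j,k] + c[caste(i),j,k] + u[nbhd(i),j,k],

where z_i is practice duration standardised to mean 0, sd 1 (denominator
n−1), native_i is 0 for native and 1 for relocated artists, and a, c, u
are artist, caste and neighborhood varying effects.  Each term's offsets
share one standard deviation per (term, matrix, row) — matching one
display of group spread per "from" row — with an optional equality
constraint sharing it across the rows of a matrix.  Neighborhoods come
from complete-linkage agglomerative clustering of the haversine
distance matrix (Earth radius 6,371 km) cut at 500 m; at the ≤ 3 km
extents involved, spherical-versus-ellipsoidal error is far below a
metre, and the linkage method is configurable (single/average/complete)
since reasonable analysts differ here.

Priors are weakly informative on the logit scale: Normal(0, 1) on
intercepts and slopes, half-Normal(0, 1) on group standard deviations,
all configurable through `PriorSpec`.  Identifiability: one category per
row is the reference with logit 0.  The reference is chosen as the row's
most-visited category (pooled over artists) rather than a fixed
position: with a rare reference every logit in the row is weakly
identified individually even when the row's probabilities are sharply
determined, which degrades both interpretation and sampling geometry.
Columns are permuted internally so this choice is invisible in the
reported probability matrices.

Seven model variants are registered (m1 intercepts-only; m2 +artist; m3
+practice; m4 +nativity; m5 artist+caste; m6 +neighborhood; m7 = full);
the ladder is this package's own, chosen to nest each additional
question inside the previous one.

### Sampling

The four matrices are conditionally independent given their parameters,
so each is sampled separately by NUTS (multinomial tree sampling,
doubling expansion, generalized U-turn criterion, divergence threshold
1000 on the energy error) with analytic gradients, dual-averaging step
size (target acceptance 0.9), and a diagonal mass matrix re-estimated in
Stan-style expanding warmup windows.  The step size is jittered
uniformly in [0.5, 1.5]× per iteration, which guards against locally
varying curvature in the hierarchical funnels.  Three further design
choices matter for the geometry:

* **Per-cell parameterization.**  An artist-offset cell is centered when
  its expected count per artist is at least 5 (the likelihood then
  dominates the conditional prior) and non-centered otherwise; caste and
  neighborhood offsets are always non-centered under the automatic rule
  because, with the artist term present, each group offset is informed
  only through the few artists in the group.  Both extremes can be
  forced via `ModelSpec.parameterization`.
* **Interweaved exact updates.**  After every NUTS transition each group
  scale takes two likelihood-cheap Gibbs-type updates: a slice-sampling
  move of log sigma holding the actual offsets fixed (exact conditional
  `−S2 e^{−2t}/2 − (n−1)t − e^{2t}/(2s²)`), and a joint rescaling move
  of sigma together with its offsets whose 1-D target is the row's
  multinomial likelihood plus the hyperprior (offset prior and proposal
  Jacobian cancel).  Intercepts and slopes additionally exchange mass
  with the artist offsets along their flat translation ridges via exact
  Gaussian conditionals.  These moves traverse exactly the directions
  hierarchical posteriors mix slowly in.
* **Data-informed initialisation.**  Chains start from pooled empirical
  row logits with count-shrunk per-artist deviations (jittered per
  chain), which keeps them out of the metastable collapsed-scale region.

The sampler was validated three ways: analytic gradients against finite
differences on every model variant; prior recovery on zero-count
designs (posterior quantiles of intercepts, slopes and scales match
Normal(0,1) and half-Normal(0,1)); and posterior marginals against an
independent affine-invariant ensemble sampler (emcee) on a small
instance, agreeing to Monte-Carlo error.  Convergence is monitored by
split R-hat and bulk ESS (via ArviZ) plus the divergence count; `fit`
raises by default when R-hat ≥ 1.01 or divergences exceed a configured
cap (default 20).

## Evaluation

**PSIS-LOO.**  The observation unit for pointwise log-likelihood is one
(artist, matrix, row) multinomial row, including the combinatorial
coefficient; rows with zero total are excluded (they contribute exactly
zero and break Pareto tail fitting).  Pareto-smoothed importance
sampling is computed by ArviZ; observations with k > 0.7 are reported,
never silently refit.  Note that with per-artist varying effects each
observation has dedicated parameters, so high-k warnings are expected
for flexible variants — the desk-scale validation therefore compares
PSIS against exact re-fit LOO on an intercept-only instance, where the
approximation is reliable.

**Weights.**  Stacking weights maximise the summed log of the
weight-mixed pointwise predictive densities over the simplex (SLSQP
from the uniform start; for exactly tied models the projected gradient
vanishes at the uniform point, which implements the tie-break toward
uniform).  Pseudo-BMA weights use the Bayesian bootstrap with 1,000
seeded Dirichlet replicates over observations.

**ICC.**  For each posterior draw and each transition-matrix cell (a
row × non-reference-category pair on the logit scale), each term's
isolated contribution is computed per artist — artist offset; slope ×
covariate; caste/neighborhood offset through membership — the variance
is taken across artists, and the shares are normalised across terms, so
they are non-negative and sum to one by construction.  Shares are then
averaged over draws and, unweighted, over the cells of each matrix
(a count-weighted average is available).  Cells whose term variances
are all exactly zero are excluded from the average; this cannot occur
in a sampled fit.

**Equilibrium.**  Stationary distributions solve πP = π, Σπ = 1 by a
dense linear solve, after verifying the chain has exactly one recurrent
communicating class (strong components of the positive-entry graph);
otherwise a non-uniqueness error is raised.  The solution is checked to
satisfy ‖πP − π‖∞ < 1e−10 and, in tests, to match a damped
power-iteration oracle to 1e−8.  Artist-level occupancies use the
artist's posterior-mean 3×3 space matrix; averaging per-draw stationary
laws instead is available as an option, since the order of averaging is
a free choice.

## Synthetic data

The generator is the model run forward.  Defaults emulate the field
study's shape: 192 artists, 19 caste categories, 8 neighborhood
clusters, 16 drawings per artist (one loop each), about 18% non-native,
practice duration Normal(15, 5) years truncated at zero, and GPS
positions as neighborhood grid centers 1 km apart with ≤ 100 m jitter,
so clustering at 500 m recovers the true neighborhoods exactly.  The
default effect hierarchy is artist-dominant: sigma_artist = 1.0,
sigma_caste = sigma_neigh = 0.2, practice slope 0.5 and nativity slope
0.25 on all non-reference cells.  The default population between-space
matrix follows the reported population tendencies (orthogonal rows stay
orthogonal with probability 0.99); within-space rows are
self-transition-heavy with geometric decay, a plain but plausible
stand-in since no within-space population matrix is printed anywhere.
Loop lengths are shifted-geometric with mean 8 gestures (min 1); the
generative covariate is the realised standardised practice, so a refit
standardising the same years recovers exactly the generative z.

Sequences are emitted linearly — initial space from the artist's
between-space stationary law, initial gesture from the within-space
stationary law, same-space steps from the within row, space switches
landing via the destination space's stationary law — while counting
applies cyclic closure; this is a mild, documented model mismatch that
`wrap=False` counting removes.  When a sequence would close with an
O–D wrap pair it is extended with further ordinary Markov steps until
the closure is legal; because the extension steps are unbiased draws
from the transition law, conditional transition frequencies are
unaffected (verified by the law-of-large-numbers tests), only the
length distribution acquires a slightly heavier tail.

What passing tests on synthetic corpora do **not** show: real
transcriptions contain noise the grammar validator would reject (hence
the permissive flag), real drawings have correlated loops within a
drawing and temporal structure across days, real caste/neighborhood
memberships are spatially confounded, and real within-space preferences
are not geometric-decay rows.  Synthetic validation demonstrates the
estimator and pipeline are correct under the model, not that the model
is adequate for field data.

## Problem sizes used in validation

Validation runs are scaled to the smallest sizes that make the checks
statistically meaningful rather than to the field corpus: structural
checks (ICC simplexes, diagnostics plumbing) use a 40-artist corpus with
2 chains × 250 draws; the convergence contract uses a 10-artist corpus
with 4 chains × 1,200 draws at target acceptance 0.95; parameter
recovery uses 10 replicates of 80 artists × 30 loops on the
between-space matrix (2 × 200 draws, replicates with R-hat ≥ 1.1 or > 50
divergences are flagged, excluded from scoring and counted);
law-of-large-numbers checks use ~150,000 transitions under a
balanced-occupancy truth, because under the field-like matrix the
diagonal space is visited too rarely for ±0.02 comparisons.  The exact
re-fit LOO oracle uses 4 artists × 3 rows = 12 observations and 12
refits.

## Known limitations

* The likelihood treats loops as exchangeable within artist; drawing-
  level grouping (several loops of one drawing) is not modelled.
* The cross-space landing rule (stationary law of the destination
  space) is an assumption used only for full-chain reconstruction and
  simulation, never by the likelihood.
* PSIS-LOO at the (artist, row) observation level is anti-conservative
  for variants with per-artist parameters (high Pareto k); exact or
  grouped cross-validation should be preferred for serious comparison
  of such variants.
* Divergent transitions are monitored but not eliminated at every
  setting; raising `target_accept` (0.95 is a good next notch) trades
  speed for robustness, as usual with Hamiltonian samplers.
* The seven-variant ladder and the prior constants are this package's
  defaults; both are configurable where a replication needs the exact
  deposited choices.
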