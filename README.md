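# kolamkit

Hierarchical Bayesian Markov-chain analysis of *kolam* gesture
sequences.

Kolam are ritual loop drawings made daily by Tamil women on a dot grid.
Every loop can be transcribed as a sequence of standardized drawing
gestures, and because each gesture constrains the next, a drawing is
naturally a realisation of a Markov chain over a 14-state gesture space
(6 orthogonal, 4 diagonal, 4 transitional states; orthogonal and
diagonal gestures can only be joined through transitional ones).  The
scientific question this package addresses — for cultural-evolution
researchers studying ethnic markers and social coordination — is how
much of the variation in artists' transition behaviour maps onto group
identity (caste, neighborhood, migration history) versus individual
identity and expertise.

## The model

Per artist *i*, transition counts are aggregated into four matrices: a
3×3 between-space matrix (order O, T, D) and within-space matrices 6×6,
4×4, 4×4, following the factorisation

> P(g₂ | g₁) = P(space(g₂) | space(g₁)) · P(g₂ | g₁, within space).

Each matrix row *j* is multinomial with softmax-linked cell logits

> η<sub>ijk</sub> = α<sub>jk</sub> + β<sup>prac</sup><sub>jk</sub> z<sub>i</sub> + β<sup>nat</sup><sub>jk</sub> nat<sub>i</sub> + a<sub>ijk</sub> + c<sub>caste(i),jk</sub> + u<sub>nbhd(i),jk</sub>

with partially pooled varying effects for artist, caste (19 categories)
and neighborhood (clusters of the GPS haversine distance matrix cut at
500 m), standardized practice duration, and a 0/1 nativity indicator.
Weakly informative priors live on the logit scale: Normal(0, 1) for
intercepts and slopes, half-Normal(0, 1) for group standard deviations.
Posteriors are sampled by a built-in NUTS engine with analytic
gradients plus interweaved exact Gibbs updates of the group scales (see
`docs/methods.md`).  Model variants (intercepts-only up to the full
five-term model) are compared by PSIS-LOO with stacking and pseudo-BMA
weights; explained variation is partitioned into per-term ICC shares by
variance decomposition of per-artist predictions on the logit scale;
and long-run drawing style is summarised by the stationary law of each
artist's between-space matrix ("equilibrium occupancy").

## Worked example

```python
import kolamkit as kk

dataset, truth = kk.simulate_dataset(config=kk.SimConfig(n_artists=40, seed=1))
model = kk.KolamTransitionModel.from_dataset(dataset)   # clusters GPS itself
results = model.fit(chains=2, draws=300, warmup=300, seed=1, check=False)

print(dataset.summary())
print(results.transition_matrix(key="space").round(2))
print(results.equilibrium().round(3))
print(results.icc().round(2))
```

prints (reduced-draw demonstration run):

```
40 artists, 640 drawings, 640 loops
[[0.93 0.06 0.01]
 [0.52 0.29 0.19]
 [0.06 0.41 0.53]]
[0.837 0.102 0.062]
               individual  expertise  nativity  caste  residence
across_spaces        0.21       0.26      0.09   0.22       0.21
orthogonal           0.64       0.16      0.04   0.07       0.08
diagonal             0.25       0.30      0.07   0.24       0.13
transitional         0.26       0.24      0.05   0.25       0.20
```

Reading the output: the population between-space matrix says drawings
that are in orthogonal space stay there with probability 0.93, and at
equilibrium this artist population spends 84% of its gestures in
orthogonal space.  The ICC table splits across-artist prediction
variance among the five model terms per matrix; each row sums to 1.  In
the orthogonal row — where every artist contributes many transitions —
the generator's artist-dominant hierarchy (σ_artist = 1.0 versus caste
and neighborhood at 0.2) is already visible (individual share 0.64); in
sparsely visited rows, 40 artists are not yet enough to pull the group
scales away from their priors, so those shares stay diffuse.  Larger
corpora sharpen the ranking (see the recovery tests at 80 artists).

Fitting the same full model to the field corpus of 3,139 drawings by
192 artists reproduces the published population space-transition matrix
(orthogonal row ≈ 0.99/0.01/0.00) and ICC shares dominated by
individual variation (0.63 across spaces) and expertise (0.25); that
corpus is not redistributable here, and `tests/test_acceptance.py`
documents where to place it (`data/deposited/`) to run the headline
reproduction.

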