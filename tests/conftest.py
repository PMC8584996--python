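"""Shared fixtures: synthetic corpora and reusable (slow) model fits."""

import numpy as np
import pytest

from kolamkit import (
    KolamTransitionModel,
    SimConfig,
    default_truth,
    load_lexicon,
    recovery_experiment,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """12 artists x 6 drawings: fast enough for counting/IO tests."""
    return simulate_dataset(
        config=SimConfig(n_artists=12, drawings_per_artist=6, seed=42)
    )


@pytest.fixture(scope="session")
def fitted_small():
    """Full-model fit on a 40-artist corpus with reduced draws.

    Shared by the ICC, transition-matrix, LOO and summary tests; chains
    and draw counts are kept small because those tests check structural
    properties (simplexes, shapes, invariants), not estimation accuracy.
    """
    dataset, sim_truth = simulate_dataset(config=SimConfig(n_artists=40, seed=1))
    model = KolamTransitionModel.from_dataset(dataset)
    results = model.fit(chains=2, draws=250, warmup=250, seed=1, check=False)
    return results, sim_truth


@pytest.fixture(scope="session")
def recovery_report():
    """Ten simulate-fit-score replicates at the recovery study scale
    (80 artists x 30 loops, between-space matrix)."""
    cfg = SimConfig(n_artists=80, drawings_per_artist=30, seed=0)
    return recovery_experiment(
        default_truth(), cfg, n_replicates=10, seed=202,
        matrices=("space",), chains=2, draws=250, warmup=250,
    )


@pytest.fixture(scope="session")
def prior_fit():
    """Posterior of the full model on an all-zero count table: the fit
    must return its priors (no-data limit)."""
    from dataclasses import replace

    from kolamkit import MODEL_VARIANTS

    dataset, _ = simulate_dataset(
        config=SimConfig(n_artists=8, drawings_per_artist=2, seed=5)
    )
    model = KolamTransitionModel.from_dataset(
        dataset, spec=replace(MODEL_VARIANTS["full"], matrices=("space",))
    )
    zeroed = {k: np.zeros_like(v) for k, v in model.design.Y.items()}
    model = KolamTransitionModel(
        replace(model.design, Y=zeroed), spec=model.spec
    )
    return model.fit(chains=2, draws=1500, warmup=400, seed=3, check=False)


@pytest.fixture(scope="session")
def tiny_loo_case():
    """Intercept-only fit with 12 observation rows plus its exact-LOO
    oracle, obtained by 12 leave-one-out refits."""
    from dataclasses import replace

    from scipy.special import gammaln, xlogy

    from kolamkit import MODEL_VARIANTS
    from kolamkit.evaluation import exact_loo_elpd

    dataset, _ = simulate_dataset(
        config=SimConfig(n_artists=4, drawings_per_artist=12, seed=6)
    )
    spec = replace(MODEL_VARIANTS["m1"], matrices=("space",))
    model = KolamTransitionModel.from_dataset(dataset, spec=spec)
    fit_kw = dict(chains=2, draws=700, warmup=300, check=False)
    res = model.fit(seed=10, **fit_kw)
    ll, index = res.pointwise_loglik()
    n = ll.shape[-1]
    exact = np.empty(n)
    for i in range(n):
        row_label = index.iloc[i]
        a_idx = list(model.design.artist_ids).index(row_label.artist_id)
        r_idx = ["O", "T", "D"].index(row_label.row)
        Y = {k: v.copy() for k, v in model.design.Y.items()}
        held = Y["space"][a_idx, r_idx, :].copy()
        Y["space"][a_idx, r_idx, :] = 0
        refit = KolamTransitionModel(
            replace(model.design, Y=Y), spec=spec
        ).fit(seed=10 + i, **fit_kw)
        p = refit._row_prob_draws("space", r_idx, None)
        ll_i = xlogy(held, p).sum(axis=-1)
        ll_i += gammaln(held.sum() + 1) - gammaln(held + 1).sum()
        exact[i] = exact_loo_elpd(ll_i[..., None])[0]
    return res, exact


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
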