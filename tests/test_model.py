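"""Design construction, likelihood primitives, and MCMC behaviour of the
hierarchical multinomial-logit transition model."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from kolamkit import (
    MODEL_VARIANTS,
    KolamTransitionModel,
    ModelSpec,
    SimConfig,
    build_design,
    default_truth,
    multinomial_loglik,
    row_probability,
    simulate_dataset,
)
from kolamkit.geography import NeighborhoodAssignment
from kolamkit.model import ConvergenceError, DesignError, make_logp_grad
from kolamkit.results import TransitionModelResults


class TestRowProbability:
    def test_uniform_at_zero(self):
        assert row_probability(np.zeros(3)) == pytest.approx([1 / 3] * 3)

    def test_closed_form(self):
        p = row_probability(np.array([np.log(4.0), 0.0, 0.0]))
        assert p == pytest.approx([2 / 3, 1 / 6, 1 / 6])

    def test_shift_invariance(self, rng):
        eta = rng.standard_normal(5)
        assert row_probability(eta) == pytest.approx(
            row_probability(eta + 3.7)
        )

    def test_structural_zero_cells(self):
        p = row_probability(np.array([0.0, -np.inf, 0.0]))
        assert p == pytest.approx([0.5, 0.0, 0.5])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            row_probability(np.array([np.nan, 0.0]))


class TestMultinomialLoglik:
    def test_two_fair_categories(self):
        assert multinomial_loglik([1, 1], [0.5, 0.5]) == pytest.approx(
            np.log(0.5)
        )

    def test_zero_total_contributes_zero(self):
        assert multinomial_loglik([0, 0, 0], [0.2, 0.3, 0.5]) == 0.0

    def test_certain_outcome(self):
        assert multinomial_loglik([2, 0], [1.0, 0.0]) == 0.0

    def test_conflict_is_minus_inf(self):
        assert multinomial_loglik([0, 1], [1.0, 0.0]) == -np.inf

    def test_matches_scipy(self, rng):
        y = rng.integers(0, 10, size=4)
        p = rng.dirichlet(np.ones(4))
        assert multinomial_loglik(y, p) == pytest.approx(
            stats.multinomial.logpmf(y, int(y.sum()), p)
        )


class TestBuildDesign:
    def test_practice_standardization(self, small_corpus):
        dataset, _ = small_corpus
        artists = sorted(dataset.artists, key=lambda a: a.artist_id)[:3]
        for a, years in zip(artists, (4.0, 6.0, 8.0)):
            object.__setattr__(a, "practice_years", years)
        sub = replace_dataset_artists(dataset, artists)
        nb = NeighborhoodAssignment(
            labels={a.artist_id: 1 for a in artists}, threshold_m=500,
            linkage_method="complete",
        )
        d = build_design(sub, nb)
        assert d.z_practice == pytest.approx([-1.0, 0.0, 1.0])
        assert abs(d.z_practice.mean()) < 1e-12
        assert d.z_practice.std(ddof=1) == pytest.approx(1.0)

    def test_native_coding_passthrough(self, small_corpus):
        dataset, sim_truth = small_corpus
        m = KolamTransitionModel.from_dataset(dataset)
        artists = sorted(dataset.artists, key=lambda a: a.artist_id)
        for a, flag in zip(artists, m.design.native):
            assert a.native == int(flag)  # 1 = non-native

    def test_missing_neighborhood_label_names_artist(self, small_corpus):
        dataset, _ = small_corpus
        nb = NeighborhoodAssignment(
            labels={}, threshold_m=500, linkage_method="complete"
        )
        with pytest.raises(DesignError, match="a0"):
            build_design(dataset, nb)

    def test_counts_shapes(self, small_corpus):
        dataset, _ = small_corpus
        d = KolamTransitionModel.from_dataset(dataset).design
        n = len(dataset.artists)
        assert d.Y["space"].shape == (n, 3, 3)
        assert d.Y["O"].shape == (n, 6, 6)
        assert d.Y["D"].shape == (n, 4, 4)
        assert d.Y["T"].shape == (n, 4, 4)


class TestModelSpec:
    def test_registered_ladder(self):
        assert set(MODEL_VARIANTS) == {
            "m1", "m2", "m3", "m4", "m5", "m6", "m7", "full"
        }
        assert MODEL_VARIANTS["full"].terms == frozenset(
            {"artist", "practice", "nativity", "caste", "neighborhood"}
        )
        assert MODEL_VARIANTS["m1"].terms == frozenset()

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", frozenset({"horoscope"}))

    def test_structural_zero_layout(self, small_corpus):
        dataset, _ = small_corpus
        spec = replace(MODEL_VARIANTS["full"], structural_zeros=True)
        m = KolamTransitionModel.from_dataset(dataset, spec=spec)
        layout = m.layouts["space"]
        assert not layout.allowed[0, 2] and not layout.allowed[2, 0]
        assert layout.F == [1, 2, 1]


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self, small_corpus):
        dataset, _ = small_corpus
        m = KolamTransitionModel.from_dataset(dataset)
        rng = np.random.default_rng(3)
        for key in ("space", "O"):
            layout = m.layouts[key]
            lg = make_logp_grad(layout, m.design, m.priors)
            x = 0.3 * rng.standard_normal(layout.dim)
            _, g = lg(x)
            for i in rng.choice(layout.dim, size=20, replace=False):
                h = 1e-6
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                num = (lg(xp)[0] - lg(xm)[0]) / (2 * h)
                assert num == pytest.approx(g[i], rel=1e-4, abs=1e-5)


class TestPriorRecovery:
    def test_intercepts_match_their_prior(self, prior_fit):
        """With no data the intercept posterior is its Normal(0,1) prior."""
        draws = prior_fit.get("space", "alpha", 0)[..., 0].ravel()
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(draws, q) == pytest.approx(
                stats.norm.ppf(q), abs=0.12
            )

    def test_group_sd_matches_half_normal(self, prior_fit):
        sig = prior_fit.sigma("space", "artist").ravel()
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(sig, q) == pytest.approx(
                stats.halfnorm.ppf(q), abs=0.12
            )

    def test_slopes_match_their_prior(self, prior_fit):
        draws = prior_fit.get("space", "beta_prac", 1)[..., 0].ravel()
        assert np.quantile(draws, 0.5) == pytest.approx(0.0, abs=0.1)
        assert draws.std() == pytest.approx(1.0, abs=0.12)


class TestFitBehaviour:
    def test_population_matrix_recovered_without_heterogeneity(self):
        """Intercept-only fit on sigma=0 data recovers the generator's
        between-space matrix to within +/-0.03 (50 artists x 20 loops;
        a balanced truth so every row accrues enough transitions, and
        wrap-free counting to drop the cyclic-closure mismatch)."""
        from .test_simulate import _balanced_homogeneous_truth

        truth = _balanced_homogeneous_truth()
        dataset, _ = simulate_dataset(
            truth, SimConfig(n_artists=50, drawings_per_artist=20,
                             mean_loop_length=12.0, seed=9)
        )
        model = KolamTransitionModel.from_dataset(
            dataset, spec=MODEL_VARIANTS["m1"], wrap=False
        )
        res = model.fit(chains=2, draws=400, warmup=300, seed=2, check=False)
        est = res.transition_matrix(key="space")
        assert np.abs(est - truth.population_probs("space")).max() < 0.03
        # within-space rows are also consistent, at their smaller counts
        for key in ("O", "D", "T"):
            est = res.transition_matrix(key=key)
            assert np.abs(est - truth.population_probs(key)).max() < 0.06

    def test_default_fixture_converges(self):
        """Full model on the default synthetic fixture: all split R-hat
        below 1.01 and divergences under the cap (seed 1)."""
        dataset, _ = simulate_dataset(
            config=SimConfig(n_artists=10, drawings_per_artist=16, seed=1)
        )
        spec = replace(MODEL_VARIANTS["full"], matrices=("space",))
        model = KolamTransitionModel.from_dataset(dataset, spec=spec)
        res = model.fit(chains=4, draws=1200, warmup=400, seed=1,
                        target_accept=0.95, check=True)
        assert max(res.rhat().values()) < 1.01

    def test_check_convergence_fails_loudly(self, fitted_small):
        res, _ = fitted_small
        with pytest.raises(ConvergenceError):
            res.check_convergence(rhat_threshold=1.0000001)

    def test_transition_rows_are_simplexes(self, fitted_small):
        res, _ = fitted_small
        for level in ("population", res.design.artist_ids[0]):
            mats = res.transition_matrix(level=level)
            for key, P in mats.items():
                assert P.shape[0] == P.shape[1] or key == "space"
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
                assert (P >= 0).all()

    def test_uniform_rows_when_parameters_are_zero(self, fitted_small):
        res, _ = fitted_small
        zero = {k: np.zeros_like(v) for k, v in res.draws.items()}
        frozen = TransitionModelResults(
            model=res.model, draws=zero, sampler_stats=res.sampler_stats,
            seed=0,
        )
        P = frozen.transition_matrix(key="space")
        assert P == pytest.approx(np.full((3, 3), 1 / 3))

    def test_factored_reconstruction_is_stochastic(self, fitted_small):
        res, _ = fitted_small
        P14 = res.full_transition_matrix()
        assert P14.shape == (14, 14)
        assert np.allclose(P14.sum(axis=1), 1.0, atol=1e-9)
        assert (P14 >= 0).all()

    def test_unknown_artist_rejected(self, fitted_small):
        res, _ = fitted_small
        with pytest.raises(KeyError):
            res.transition_matrix(level="nobody")


def replace_dataset_artists(dataset, artists):
    from kolamkit.dataio import Dataset

    ids = {a.artist_id for a in artists}
    return Dataset(
        lexicon=dataset.lexicon,
        artists=list(artists),
        drawings=[d for d in dataset.drawings if d.artist_id in ids],
        n_castes=dataset.n_castes,
    )
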