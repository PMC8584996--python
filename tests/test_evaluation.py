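"""Model comparison (PSIS-LOO, weights), ICC decomposition and
stationary-distribution analysis."""

from dataclasses import replace

import numpy as np
import pytest

from kolamkit import (
    MODEL_VARIANTS,
    KolamTransitionModel,
    SimConfig,
    default_truth,
    model_weights,
    psis_loo,
    simulate_dataset,
    stationary_distribution,
)
from kolamkit.evaluation import (
    LooResult,
    NonUniqueStationaryError,
    exact_loo_elpd,
)
from kolamkit.results import TransitionModelResults


# ----------------------------------------------------------------------
# stationary distributions


def power_iteration_oracle(P, iters=200_000, tol=1e-14):
    """Independent oracle: damped power iteration (lazy chain)."""
    Q = 0.5 * (P + np.eye(P.shape[0]))  # same stationary law, aperiodic
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(iters):
        nxt = pi @ Q
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    return pi


class TestStationary:
    def test_doubly_stochastic(self):
        out = stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert out.pi == pytest.approx([0.5, 0.5])

    def test_closed_form_balance(self):
        out = stationary_distribution(np.array([[0.9, 0.1], [0.5, 0.5]]))
        assert out.pi == pytest.approx([5 / 6, 1 / 6])

    def test_identity_has_no_unique_law(self):
        with pytest.raises(NonUniqueStationaryError):
            stationary_distribution(np.eye(3))

    def test_absorbing_chain_rejected(self):
        P = np.array([[1.0, 0.0, 0.0], [0.2, 0.5, 0.3], [0.0, 0.0, 1.0]])
        with pytest.raises(NonUniqueStationaryError):
            stationary_distribution(P)

    def test_matches_power_iteration_on_200_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 7))
            P = rng.dirichlet(np.full(n, 0.5), size=n)
            out = stationary_distribution(P)
            assert np.abs(out.pi @ P - out.pi).max() < 1e-10
            assert np.abs(out.pi - power_iteration_oracle(P)).max() < 1e-8

    def test_not_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.2], [0.5, 0.5]]))


# ----------------------------------------------------------------------
# PSIS-LOO


class TestPsisLoo:
    def test_point_mass_posterior(self):
        ll = np.tile(np.linspace(-2, -1, 5)[None, None, :], (2, 60, 1))
        res = psis_loo(ll)
        assert res.elpd_loo == pytest.approx(ll[0, 0].sum())
        assert res.p_loo == pytest.approx(0.0, abs=1e-6)

    def test_identical_tables_have_zero_elpd_difference(self, rng):
        ll = rng.normal(-2, 0.3, size=(2, 80, 10))
        assert psis_loo(ll).elpd_loo == pytest.approx(psis_loo(ll).elpd_loo)

    def test_too_few_draws_rejected(self, rng):
        with pytest.raises(ValueError, match="100 draws"):
            psis_loo(rng.normal(size=(2, 40, 5)))

    def test_pareto_k_reported_per_observation(self, fitted_small):
        res, _ = fitted_small
        loo = psis_loo(res)
        assert loo.pareto_k.shape == (loo.n_obs,)
        assert np.isfinite(loo.elpd_loo)

    def test_psis_matches_exact_refit_loo(self, tiny_loo_case):
        """|elpd_PSIS - elpd_exact| < 0.05 * n on a 12-row fit."""
        res, exact = tiny_loo_case
        loo = psis_loo(res)
        assert abs(loo.elpd_loo - exact.sum()) < 0.05 * loo.n_obs


# ----------------------------------------------------------------------
# model weights


def _loo_from_pointwise(pw):
    pw = np.asarray(pw, dtype=float)
    return LooResult(
        elpd_loo=float(pw.sum()), se=0.0, p_loo=0.0, pointwise=pw,
        pareto_k=np.zeros_like(pw), n_obs=pw.size,
    )


class TestModelWeights:
    def test_dominant_model_takes_all_stacking_weight(self):
        good = _loo_from_pointwise(np.full(20, -1.0))
        bad = _loo_from_pointwise(np.full(20, -3.0))
        w = model_weights({"good": good, "bad": bad}, seed=1)
        assert w.stacking[0] == pytest.approx(1.0, abs=1e-6)
        assert w.stacking[1] == pytest.approx(0.0, abs=1e-6)

    def test_identical_models_tie_to_uniform(self):
        pw = np.linspace(-2, -1, 15)
        w = model_weights([_loo_from_pointwise(pw)] * 2, seed=1)
        assert w.stacking == pytest.approx([0.5, 0.5], abs=1e-9)
        assert w.pseudo_bma == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_weights_on_simplex(self, rng):
        loos = {
            f"m{i}": _loo_from_pointwise(rng.normal(-2, 0.5, size=30))
            for i in range(4)
        }
        w = model_weights(loos, seed=2)
        for vec in (w.stacking, w.pseudo_bma):
            assert (vec >= 0).all()
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_stacking_beats_every_vertex(self, rng):
        pw = rng.normal(-2, 1.0, size=(25, 3))
        loos = [_loo_from_pointwise(pw[:, i]) for i in range(3)]
        w = model_weights(loos, seed=3)

        def objective(wvec):
            ref = pw.max(axis=1, keepdims=True)
            return float(
                np.sum(np.log((np.exp(pw - ref) @ wvec)) + ref.ravel())
            )

        best_vertex = max(objective(v) for v in np.eye(3))
        assert objective(w.stacking) >= best_vertex - 1e-9

    def test_pseudo_bma_is_seeded(self):
        loos = [
            _loo_from_pointwise(np.linspace(-3, -1, 20)),
            _loo_from_pointwise(np.linspace(-2.5, -1.5, 20)),
        ]
        a = model_weights(loos, seed=7).pseudo_bma
        b = model_weights(loos, seed=7).pseudo_bma
        assert a == pytest.approx(b, abs=0.0)

    def test_mismatched_observations_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            model_weights(
                [_loo_from_pointwise(np.zeros(5)),
                 _loo_from_pointwise(np.zeros(6))]
            )

    def test_arviz_agrees_on_stacking(self, rng):
        """Independent cross-check of the stacking optimizer."""
        import arviz as az

        ll = {m: rng.normal(-2, 0.6, size=(2, 200, 15)) for m in ("a", "b")}
        elpds = {
            m: az.loo(
                az.from_dict(log_likelihood={"obs": v}), pointwise=True,
                reff=1.0,
            )
            for m, v in ll.items()
        }
        cmp = az.compare(elpds, ic="loo", method="stacking")
        ours = model_weights({m: psis_loo(v) for m, v in ll.items()}, seed=0)
        ref = {m: float(cmp.loc[m, "weight"]) for m in ll}
        assert ours.stacking[0] == pytest.approx(ref["a"], abs=0.05)

    def test_generating_model_wins_stacking(self):
        """Data simulated with artist heterogeneity prefer the model that
        has artist effects, across 10 seeded replicates."""
        wins = 0
        spec1 = replace(MODEL_VARIANTS["m1"], matrices=("space",))
        spec2 = replace(MODEL_VARIANTS["m2"], matrices=("space",))
        for seed in range(10):
            dataset, _ = simulate_dataset(
                default_truth(),
                SimConfig(n_artists=8, drawings_per_artist=20, seed=100 + seed),
            )
            loos = {}
            for name, spec in (("m1", spec1), ("m2", spec2)):
                fit = KolamTransitionModel.from_dataset(
                    dataset, spec=spec
                ).fit(chains=2, draws=250, warmup=200, seed=seed,
                      check=False, target_accept=0.8, max_depth=7)
                loos[name] = psis_loo(fit)
            w = model_weights(loos, seed=seed)
            wins += w.stacking[list(w.names).index("m2")] > 0.5
        assert wins >= 9


# ----------------------------------------------------------------------
# ICC decomposition


def _synthetic_results(draw_setter, n_artists=6, seed=0):
    """Full-model results whose draws are constructed, not sampled."""
    dataset, _ = simulate_dataset(
        config=SimConfig(n_artists=n_artists, drawings_per_artist=2, seed=seed)
    )
    spec = replace(MODEL_VARIANTS["full"], matrices=("space",),
                   parameterization="noncentered")
    model = KolamTransitionModel.from_dataset(dataset, spec=spec)
    layout = model.layouts["space"]
    draws = np.zeros((1, 40, layout.dim))
    draw_setter(layout, draws, model.design)
    return TransitionModelResults(
        model=model, draws={"space": draws},
        sampler_stats={"space": {"divergences": 0, "accept_rate": [1.0],
                                 "step_size": [0.1]}},
        seed=0,
    )


class TestIccDecomposition:
    def test_single_source_gets_full_share(self, rng):
        def setter(layout, draws, design):
            for r in range(3):
                sl, shape = layout.slices[("a_tilde", r)]
                draws[..., sl] = rng.standard_normal(draws.shape[:2] + (sl.stop - sl.start,))

        res = _synthetic_results(setter)
        icc = res.icc()
        assert float(icc["individual"].iloc[0]) == pytest.approx(1.0, abs=1e-12)
        for col in ("expertise", "nativity", "caste", "residence"):
            assert (icc[col] == 0).all()

    def test_two_equal_sources_split_evenly(self, rng):
        def setter(layout, draws, design):
            # one artist per caste makes artist and caste contributions
            # identical in distribution; use the same deviates for both
            for r in range(3):
                x = rng.standard_normal(
                    draws.shape[:2] + layout.slices[("a_tilde", r)][1]
                )
                sl, shape = layout.slices[("a_tilde", r)]
                draws[..., sl] = x.reshape(draws.shape[:2] + (-1,))
                slc, shapec = layout.slices[("c_tilde", r)]
                full = np.zeros(draws.shape[:2] + shapec)
                full[:, :, : shape[0], :] = x
                draws[..., slc] = full.reshape(draws.shape[:2] + (-1,))

        res = _synthetic_results(setter)
        d = res.design
        # valid only when every artist is alone in their caste slot
        if len(set(d.caste_index.tolist())) != d.n_artists:
            pytest.skip("fixture assigned shared castes for this seed")
        icc = res.icc()
        assert float(icc["individual"].iloc[0]) == pytest.approx(0.5, abs=1e-9)
        assert float(icc["caste"].iloc[0]) == pytest.approx(0.5, abs=1e-9)

    def test_rows_sum_to_one_on_fitted_model(self, fitted_small):
        res, _ = fitted_small
        icc = res.icc()
        assert icc.shape == (4, 5)
        assert icc.to_numpy().min() >= 0
        assert icc.sum(axis=1).to_numpy() == pytest.approx(
            np.ones(4), abs=1e-9
        )

    def test_count_weighted_variant_also_simplex(self, fitted_small):
        res, _ = fitted_small
        icc = res.icc(count_weighted=True)
        assert icc.sum(axis=1).to_numpy() == pytest.approx(
            np.ones(4), abs=1e-9
        )

    def test_individual_dominates_under_truth_hierarchy(self, recovery_report):
        """With sigma_artist >> sigma_caste in truth, the estimated share
        ranks individual above caste in >= 9/10 replicates."""
        rep = recovery_report
        scored = rep.dropna(subset=["icc_individual"])
        wins = int((rep["icc_individual_gt_caste"] == True).sum())
        assert wins >= 9
        assert (scored["icc_individual"] > scored["icc_caste"]).all()
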