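"""The synthetic-corpus generator and recovery harness."""

import numpy as np
import pytest

from kolamkit import (
    SimConfig,
    default_truth,
    simulate_dataset,
    write_dataset,
)
from kolamkit.counts import dataset_counts
from kolamkit.lexicon import validate_state_sequence


class TestGeneratorBasics:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(n_artists=6, drawings_per_artist=3, seed=17)
        for run in ("x", "y"):
            ds, _ = simulate_dataset(config=cfg)
            write_dataset(
                ds,
                tmp_path / f"{run}.tsv",
                tmp_path / f"{run}_s.csv",
                tmp_path / f"{run}_g.csv",
            )
        for suffix in (".tsv", "_s.csv", "_g.csv"):
            assert (tmp_path / f"x{suffix}").read_bytes() == (
                tmp_path / f"y{suffix}"
            ).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = simulate_dataset(config=SimConfig(n_artists=4, seed=1))
        b, _ = simulate_dataset(config=SimConfig(n_artists=4, seed=2))
        assert [lp.states for d in a.drawings for lp in d.loops] != [
            lp.states for d in b.drawings for lp in d.loops
        ]

    def test_all_loops_grammar_valid(self, small_corpus):
        dataset, _ = small_corpus
        for d in dataset.drawings:
            for loop in d.loops:
                assert validate_state_sequence(loop.states) == []

    def test_corpus_shape_matches_config(self, small_corpus):
        dataset, sim_truth = small_corpus
        cfg = sim_truth.config
        assert len(dataset.artists) == cfg.n_artists
        assert len(dataset.drawings) == cfg.n_artists * cfg.drawings_per_artist

    def test_default_config_nonnative_fraction(self):
        """The default corpus emulates roughly 18% non-native artists."""
        ds, _ = simulate_dataset(
            config=SimConfig(drawings_per_artist=1, mean_loop_length=1, seed=0)
        )
        n = len(ds.artists)
        frac = sum(a.native for a in ds.artists) / n
        half_width = 1.96 * np.sqrt(0.18 * 0.82 / n)
        assert abs(frac - 0.18) <= half_width

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_artists=0)
        with pytest.raises(ValueError):
            SimConfig(mean_loop_length=0.5)


def _balanced_homogeneous_truth():
    """sigma = 0, slopes = 0, and a space matrix whose equilibrium visits
    every space often enough for tight frequency checks."""
    from kolamkit import truth_from_probs

    def within(K):
        P = np.empty((K, K))
        for j in range(K):
            w = 0.6 ** np.abs(np.arange(K) - j)
            P[j] = w / w.sum()
        return P

    space = np.array(
        [[0.60, 0.40, 0.00], [0.30, 0.40, 0.30], [0.00, 0.40, 0.60]]
    )
    return truth_from_probs(
        {"space": space, "O": within(6), "D": within(4), "T": within(4)},
        sigma_artist=0.0, sigma_caste=0.0, sigma_neigh=0.0,
        beta_practice=0.0, beta_nativity=0.0,
    )


@pytest.fixture(scope="module")
def homogeneous_corpus():
    truth = _balanced_homogeneous_truth()
    cfg = SimConfig(n_artists=6, drawings_per_artist=3500,
                    mean_loop_length=8.0, seed=3)
    dataset, _ = simulate_dataset(truth, cfg)
    return truth, dataset_counts(dataset, wrap=False)


class TestGeneratorFrequencies:
    def test_homogeneous_truth_frequencies_converge(self, homogeneous_corpus):
        """With all sigma = 0 and slopes 0, empirical conditional
        transition frequencies approach the population rows (law of
        large numbers; ~50,000 transitions, +/-0.02).  Wrap-free
        counting removes the cyclic-closure mismatch."""
        truth, counts = homogeneous_corpus
        S = sum(fc.S for fc in counts.values())
        assert S.sum() > 40_000
        emp = S / S.sum(axis=1, keepdims=True)
        assert np.abs(emp - truth.population_probs("space")).max() < 0.02

    def test_within_space_frequencies_converge(self, homogeneous_corpus):
        truth, counts = homogeneous_corpus
        W = sum(fc.W_O for fc in counts.values())
        emp = W / W.sum(axis=1, keepdims=True)
        # same-space pairs are exactly the within-row draws, so the
        # conditional frequencies converge to the within matrix itself
        assert np.abs(emp - truth.population_probs("O")).max() < 0.02

    def test_artist_rows_recoverable_from_counts(self, small_corpus):
        """Renormalized per-artist counts correlate with the artist's true
        rows (finite-sample check on the most-visited space row)."""
        dataset, sim_truth = small_corpus
        counts = dataset_counts(dataset, wrap=False)
        ids = sorted(counts)
        errs = []
        for i, aid in enumerate(ids):
            S = counts[aid].S.astype(float)
            if S[0].sum() < 30:
                continue
            emp = S[0] / S[0].sum()
            errs.append(np.abs(emp - sim_truth.artist_row_probs["space"][i][0]).max())
        assert errs and np.median(errs) < 0.15


class TestRecoveryHarness:
    def test_report_columns_and_convergence_accounting(self, recovery_report):
        rep = recovery_report
        assert len(rep) == 10
        assert {"replicate", "seed", "converged",
                "sigma_artist_mean", "sigma_artist_covered"} <= set(rep.columns)
        # non-convergent replicates are flagged but still counted
        assert rep["converged"].dtype == bool

    def test_group_sd_point_recovery(self, recovery_report):
        """Posterior mean of sigma_artist lands in [0.8, 1.2] when the
        generative value is 1.0 (80 artists x 30 loops)."""
        ok = recovery_report.dropna(subset=["sigma_artist_mean"])
        assert len(ok) >= 8
        assert 0.8 <= ok["sigma_artist_mean"].mean() <= 1.2
        assert int(ok["sigma_artist_mean"].between(0.8, 1.2).sum()) >= 8

    def test_interval_coverage(self, recovery_report):
        """90% intervals cover the generative sigma_artist in >= 7/10."""
        covered = (recovery_report["sigma_artist_covered"] == True)
        assert int(covered.sum()) >= 7

    def test_sigma_ordering_posterior_probability(self, recovery_report):
        """The posterior puts > 0.9 probability on sigma_artist exceeding
        sigma_caste when the generative gap is 1.0 vs 0.2."""
        ok = recovery_report.dropna(subset=["p_sigma_artist_gt_caste"])
        assert not ok.empty
        assert (ok["p_sigma_artist_gt_caste"] > 0.9).mean() >= 0.9

    def test_summary_helper_reports_bias_rmse_coverage(self, recovery_report):
        from kolamkit import summarize_recovery

        summary = summarize_recovery(recovery_report)
        art = summary.set_index("term").loc["artist"]
        assert abs(art["bias"]) < 0.2
        assert art["rmse"] < 0.25
        assert 0.0 <= art["coverage_90"] <= 1.0
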