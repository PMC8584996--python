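"""Posterior results of the transition model.

``TransitionModelResults`` wraps the raw HMC draws together with the
model and design that produced them, and exposes the quantities the
analysis reports: convergence diagnostics, posterior transition
matrices at the population or artist level, sigma summaries, pointwise
log-likelihood tables for cross-validation, equilibrium occupancies and
the ICC variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .counts import MATRIX_LABELS
from .model import ConvergenceError, KolamTransitionModel, row_probability

_SIGMA_NAMES = {"t_artist": "sigma_artist", "t_caste": "sigma_caste",
                "t_neigh": "sigma_neigh"}


def _hdi(x: np.ndarray, prob: float = 0.9) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` posterior mass."""
    xs = np.sort(np.asarray(x).ravel())
    n = xs.size
    m = max(1, int(np.floor(prob * n)))
    widths = xs[m:] - xs[: n - m]
    i = int(np.argmin(widths)) if widths.size else 0
    return float(xs[i]), float(xs[min(i + m, n - 1)])


@dataclass
class TransitionModelResults:
    model: KolamTransitionModel
    draws: dict  # matrix key -> (chains, n_draws, dim)
    sampler_stats: dict
    seed: int
    _rhat_cache: dict = field(default_factory=dict, repr=False)
    _ll_cache: tuple | None = field(default=None, repr=False)

    # -- basics -------------------------------------------------------

    @property
    def design(self):
        return self.model.design

    @property
    def spec(self):
        return self.model.spec

    def n_draws_total(self, key: str | None = None) -> int:
        key = key or next(iter(self.draws))
        c, d, _ = self.draws[key].shape
        return c * d

    def get(self, key: str, name: str, r: int = -1) -> np.ndarray:
        """Draws of one parameter: shape (chains, draws) + parameter shape."""
        return self.model.layouts[key].get(self.draws[key], name, r)

    def sigma(self, key: str, term: str) -> np.ndarray:
        """Group-sd draws for a term, shape (chains, draws, R)."""
        pname = {"artist": "t_artist", "caste": "t_caste",
                 "neighborhood": "t_neigh"}[term]
        layout = self.model.layouts[key]
        t = layout.get(self.draws[key], pname, -1)
        sig = np.exp(t)
        if self.spec.sigma_sharing == "matrix":
            sig = np.repeat(sig, layout.R, axis=-1)
        return sig

    # -- diagnostics ---------------------------------------------------

    def rhat(self) -> dict[str, float]:
        """Maximum split R-hat over all parameters, per matrix."""
        if not self._rhat_cache:
            for key, arr in self.draws.items():
                ds = az.convert_to_dataset(arr[:, :, :])
                self._rhat_cache[key] = float(
                    az.rhat(ds)["x"].max().item()
                )
        return dict(self._rhat_cache)

    def ess_bulk_min(self) -> dict[str, float]:
        out = {}
        for key, arr in self.draws.items():
            ds = az.convert_to_dataset(arr)
            out[key] = float(az.ess(ds)["x"].min().item())
        return out

    @property
    def divergences(self) -> int:
        return int(sum(s["divergences"] for s in self.sampler_stats.values()))

    def check_convergence(
        self, rhat_threshold: float = 1.01, max_divergences: int = 20
    ) -> None:
        worst = max(self.rhat().values())
        if worst >= rhat_threshold:
            raise ConvergenceError(
                f"max split R-hat {worst:.4f} >= {rhat_threshold}"
            )
        if self.divergences > max_divergences:
            raise ConvergenceError(
                f"{self.divergences} divergent transitions (cap "
                f"{max_divergences})"
            )

    def diagnostics(self) -> dict:
        return {
            "rhat_max": self.rhat(),
            "divergences": self.divergences,
            "accept_rate": {
                k: list(map(float, s["accept_rate"]))
                for k, s in self.sampler_stats.items()
            },
            "ess_bulk_min": self.ess_bulk_min(),
        }

    # -- linear predictors and probabilities ---------------------------

    def offset_draws(self, key: str, term: str, r: int) -> np.ndarray:
        """Actual group offsets for one matrix row, shape
        (chains, draws, n_groups, F) — resolves the sampling
        parameterization (centered draws store offsets directly,
        non-centered ones store standard-normal deviates scaled by
        sigma)."""
        pname = {"artist": "a_tilde", "caste": "c_tilde",
                 "neighborhood": "u_tilde"}[term]
        layout = self.model.layouts[key]
        B = self.get(key, pname, r)
        cen = layout.centered[term][r]  # (F,) bool, per free category
        sig = self.sigma(key, term)[..., r]
        return np.where(cen, B, sig[..., None, None] * B)

    def _eta_draws(self, key: str, r: int, artist: int | None) -> np.ndarray:
        """Linear-predictor draws (chains, draws, F) for one matrix row.

        ``artist=None`` gives the population level: all offsets zero and
        covariates at zero.  An integer index plugs in that artist's
        offsets and covariates.
        """
        spec = self.spec
        eta = self.get(key, "alpha", r).copy()
        if artist is None:
            return eta
        d = self.design
        if spec.has("practice"):
            eta = eta + d.z_practice[artist] * self.get(key, "beta_prac", r)
        if spec.has("nativity"):
            eta = eta + d.native[artist] * self.get(key, "beta_nat", r)
        if spec.has("artist"):
            eta = eta + self.offset_draws(key, "artist", r)[..., artist, :]
        if spec.has("caste"):
            g = d.caste_index[artist]
            eta = eta + self.offset_draws(key, "caste", r)[..., g, :]
        if spec.has("neighborhood"):
            k = d.neighborhood_index[artist]
            eta = eta + self.offset_draws(key, "neighborhood", r)[..., k, :]
        return eta

    def _row_prob_draws(self, key: str, r: int, artist: int | None) -> np.ndarray:
        """Per-draw probability rows (chains, draws, K)."""
        layout = self.model.layouts[key]
        eta = self._eta_draws(key, r, artist)
        logits = np.full(eta.shape[:-1] + (layout.K,), -np.inf)
        logits[..., layout.free_cols[r]] = eta
        logits[..., layout.ref_col[r]] = 0.0
        return row_probability(logits)

    def transition_matrix(
        self, level: str = "population", key: str | None = None
    ) -> dict[str, np.ndarray] | np.ndarray:
        """Posterior-mean transition matrices.

        ``level`` is "population" (offsets zero, covariates at zero) or
        an artist_id.  Returns a dict over matrix keys, or one matrix if
        ``key`` is given.  Every row is a probability simplex.
        """
        if level == "population":
            artist = None
        else:
            try:
                artist = self.design.artist_ids.index(level)
            except ValueError:
                raise KeyError(f"unknown artist {level!r}") from None
        keys = [key] if key else list(self.model.layouts)
        out = {}
        for k in keys:
            layout = self.model.layouts[k]
            rows = [
                self._row_prob_draws(k, r, artist).mean(axis=(0, 1))
                for r in range(layout.R)
            ]
            out[k] = np.vstack(rows)
        return out[key] if key else out

    def full_transition_matrix(self, level: str = "population") -> np.ndarray:
        """Reconstruct the 14x14 gesture-level stochastic matrix.

        P(k | j) = P(space(k) | space(j)) times the within-space row for
        same-space moves; a cross-space move lands on a gesture of the
        destination space according to that space's within-matrix
        stationary distribution (modelling assumption for full-chain
        reconstruction; the likelihood never uses it).
        """
        from .evaluation import stationary_distribution
        from .lexicon import SPACES, Lexicon

        mats = self.transition_matrix(level=level)
        S = mats["space"]
        sidx = {s: i for i, s in enumerate(SPACES)}
        pi_within = {
            s: stationary_distribution(mats[s]).pi for s in ("O", "D", "T")
        }
        P = np.zeros((14, 14))
        for j in range(14):
            sj = Lexicon.state_space(j)
            jl = Lexicon.states_in_space(sj).index(j)
            for k in range(14):
                sk = Lexicon.state_space(k)
                kl = Lexicon.states_in_space(sk).index(k)
                s_prob = S[sidx[sj], sidx[sk]]
                if sj == sk:
                    P[j, k] = s_prob * mats[sj][jl, kl]
                else:
                    P[j, k] = s_prob * pi_within[sk][kl]
        return P

    # -- summaries ------------------------------------------------------

    def sigma_table(self) -> pd.DataFrame:
        """Posterior mean/sd and 90% HDI of every group sd, per matrix row."""
        rows = []
        for key, layout in self.model.layouts.items():
            for term in ("artist", "caste", "neighborhood"):
                if not self.spec.has(term):
                    continue
                sig = self.sigma(key, term)
                for r in range(layout.R):
                    s = sig[..., r].reshape(-1)
                    lo, hi = _hdi(sig[..., r], 0.9)
                    rows.append(
                        (key, MATRIX_LABELS[key][r], term, s.mean(), s.std(),
                         float(lo), float(hi))
                    )
        return pd.DataFrame(
            rows,
            columns=["matrix", "row", "term", "mean", "sd", "hdi5", "hdi95"],
        )

    def summary(self) -> pd.DataFrame:
        """Compact posterior summary: intercepts, slopes and sigmas."""
        rows = []
        for key, layout in self.model.layouts.items():
            labels = MATRIX_LABELS[key]
            for r in range(layout.R):
                fc = layout.free_cols[r]
                for name, pretty in (
                    ("alpha", "alpha"),
                    ("beta_prac", "beta_practice"),
                    ("beta_nat", "beta_nativity"),
                ):
                    if not layout.has(name):
                        continue
                    d = self.get(key, name, r)
                    for f, col in enumerate(fc):
                        x = d[..., f].reshape(-1)
                        lo, hi = _hdi(d[..., f], 0.9)
                        rows.append(
                            (f"{pretty}[{key}:{labels[r]}->{labels[col]}]",
                             x.mean(), x.std(), float(lo), float(hi))
                        )
        sig = self.sigma_table()
        for t in sig.itertuples(index=False):
            rows.append(
                (f"sigma_{t.term}[{t.matrix}:{t.row}]",
                 t.mean, t.sd, t.hdi5, t.hdi95)
            )
        df = pd.DataFrame(rows, columns=["parameter", "mean", "sd", "hdi5", "hdi95"])
        return df

    # -- pointwise log-likelihood --------------------------------------

    def _row_prob_draws_all(self, key: str, r: int) -> np.ndarray:
        """Probability rows for every artist at once: (chains, draws, N, K)."""
        layout = self.model.layouts[key]
        d = self.design
        eta = self.get(key, "alpha", r)[..., None, :].copy()  # (c, s, 1, F)
        eta = np.broadcast_to(
            eta, eta.shape[:2] + (d.n_artists, eta.shape[-1])
        ).copy()
        if self.spec.has("practice"):
            eta += d.z_practice[:, None] * self.get(key, "beta_prac", r)[
                ..., None, :
            ]
        if self.spec.has("nativity"):
            eta += d.native[:, None] * self.get(key, "beta_nat", r)[
                ..., None, :
            ]
        if self.spec.has("artist"):
            eta += self.offset_draws(key, "artist", r)
        if self.spec.has("caste"):
            eta += self.offset_draws(key, "caste", r)[..., d.caste_index, :]
        if self.spec.has("neighborhood"):
            eta += self.offset_draws(key, "neighborhood", r)[
                ..., d.neighborhood_index, :
            ]
        logits = np.full(eta.shape[:-1] + (layout.K,), -np.inf)
        logits[..., layout.free_cols[r]] = eta
        logits[..., layout.ref_col[r]] = 0.0
        return row_probability(logits)

    def pointwise_loglik(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Log-likelihood per (artist, matrix, row) observation unit.

        Returns (ll, index): ``ll`` has shape (chains, draws, n_obs);
        ``index`` labels each observation.  Rows with zero total count
        are excluded (they contribute identically zero).
        """
        if self._ll_cache is not None:
            return self._ll_cache
        cols_ll = []
        idx = []
        d = self.design
        for key, layout in self.model.layouts.items():
            Y = d.Y[key]
            n_tot = Y.sum(axis=2)
            for r in range(layout.R):
                keep = np.flatnonzero(n_tot[:, r] > 0)
                if keep.size == 0:
                    continue
                p = self._row_prob_draws_all(key, r)  # (c, s, N, K)
                ll = xlogy(Y[None, None, :, r, :], p).sum(axis=-1)
                ll += gammaln(n_tot[:, r] + 1) - gammaln(Y[:, r, :] + 1).sum(
                    axis=1
                )
                for i in keep:
                    cols_ll.append(ll[..., i])
                    idx.append((d.artist_ids[int(i)], key, MATRIX_LABELS[key][r]))
        ll = np.stack(cols_ll, axis=-1)
        index = pd.DataFrame(idx, columns=["artist_id", "matrix", "row"])
        self._ll_cache = (ll, index)
        return self._ll_cache

    def to_inference_data(self) -> az.InferenceData:
        """ArviZ InferenceData with posterior and log_likelihood groups."""
        ll, index = self.pointwise_loglik()
        post = {}
        for key in self.draws:
            post[f"theta_{key}"] = self.draws[key]
        return az.from_dict(
            posterior=post,
            log_likelihood={"obs": ll},
            coords={"obs_id": index.index.to_numpy()},
            dims={"obs": ["obs_id"]},
        )

    # -- derived analyses ----------------------------------------------

    def icc(self, count_weighted: bool = False) -> pd.DataFrame:
        from .evaluation import icc_decompose

        return icc_decompose(self, count_weighted=count_weighted)

    def equilibrium(self, level: str = "population") -> np.ndarray:
        """Stationary occupancy over geometric spaces (order O, T, D)
        of the posterior-mean between-space matrix."""
        from .evaluation import stationary_distribution

        S = self.transition_matrix(level=level, key="space")
        return stationary_distribution(S).pi

    def equilibrium_table(self) -> pd.DataFrame:
        """Per-artist equilibrium occupancies of the three spaces."""
        rows = []
        for aid in self.design.artist_ids:
            pi = self.equilibrium(level=aid)
            rows.append((aid, *pi))
        return pd.DataFrame(rows, columns=["artist_id", "O", "T", "D"])

    def loo(self):
        from .evaluation import psis_loo

        return psis_loo(self)

    # -- plotting -------------------------------------------------------

    def plot_sigmas(self, ax=None):
        """Posterior mean and 90% HDI of every group sd (diagnostic plot)."""
        import matplotlib.pyplot as plt

        tab = self.sigma_table()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1))
        labels = [f"{t.term} [{t.matrix}:{t.row}]"
                  for t in tab.itertuples(index=False)]
        y = np.arange(len(tab))
        ax.errorbar(
            tab["mean"], y,
            xerr=[tab["mean"] - tab["hdi5"], tab["hdi95"] - tab["mean"]],
            fmt="o", markersize=3, capsize=2,
        )
        ax.set_yticks(y, labels, fontsize=7)
        ax.set_xlabel("group standard deviation (logit scale)")
        ax.figure.tight_layout()
        return ax
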