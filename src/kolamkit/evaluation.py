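"""Model evaluation: cross-validation, model weights, variance
partitioning (ICC) and equilibrium analysis.

The ICC here is the share of across-artist prediction variance, on the
logit scale, attributable to each model term.  For each posterior draw
and each transition-matrix cell, the linear-predictor contribution of a
term *in isolation* is computed for every artist (artist offset;
practice slope times the artist's standardized practice; nativity slope
times the indicator; caste and neighborhood offsets through
membership); the variance of that contribution across artists, divided
by the sum over terms, is the term's share.  Shares are averaged over
draws and over cells within each matrix, so each matrix row of the
table sums to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.sparse import csgraph
from scipy.special import logsumexp

#: Display names of the model terms, in table column order.
ICC_COLUMNS = {
    "artist": "individual",
    "practice": "expertise",
    "nativity": "nativity",
    "caste": "caste",
    "neighborhood": "residence",
}

#: Display names of the transition matrices, in table row order.
ICC_ROWS = {
    "space": "across_spaces",
    "O": "orthogonal",
    "D": "diagonal",
    "T": "transitional",
}


# ----------------------------------------------------------------------
# PSIS-LOO


@dataclass
class LooResult:
    elpd_loo: float
    se: float
    p_loo: float
    pointwise: np.ndarray  # per-observation elpd contributions
    pareto_k: np.ndarray
    n_obs: int
    index: pd.DataFrame | None = None

    @property
    def n_high_k(self) -> int:
        return int((self.pareto_k > 0.7).sum())


def psis_loo(results_or_ll, index: pd.DataFrame | None = None) -> LooResult:
    """Pareto-smoothed importance-sampling LOO.

    Accepts either fitted ``TransitionModelResults`` or a raw pointwise
    log-likelihood array of shape (chains, draws, n_obs).  Requires at
    least 100 posterior draws for stable tail fitting.  Observations
    with Pareto k > 0.7 are reported in the result, never refit
    silently.
    """
    reff = None
    if hasattr(results_or_ll, "pointwise_loglik"):
        ll, index = results_or_ll.pointwise_loglik()
        idata = results_or_ll.to_inference_data()
    else:
        ll = np.asarray(results_or_ll, dtype=float)
        if ll.ndim != 3:
            raise ValueError("log-likelihood must be (chains, draws, n_obs)")
        idata = az.from_dict(log_likelihood={"obs": ll})
        reff = 1.0  # no posterior group to estimate relative efficiency from
    if not np.isfinite(ll).all():
        raise ValueError("log-likelihood table contains non-finite entries")
    c, d, n = ll.shape
    if c * d < 100:
        raise ValueError("need at least 100 draws for PSIS tail fitting")
    res = az.loo(idata, pointwise=True, reff=reff)
    return LooResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        p_loo=float(res.p_loo),
        pointwise=np.asarray(res.loo_i.values, dtype=float),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
        n_obs=n,
        index=index,
    )


# ----------------------------------------------------------------------
# model weights


@dataclass
class ModelWeights:
    names: tuple[str, ...]
    stacking: np.ndarray
    pseudo_bma: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": self.names, "stacking": self.stacking,
             "pseudo_bma": self.pseudo_bma}
        )


def _stacking_weights(lpd: np.ndarray) -> np.ndarray:
    """Maximize sum_n log sum_m w_m exp(lpd_nm) over the simplex.

    The objective is concave in w; SLSQP from the uniform start with the
    simplex constraint converges to the optimum, and for exactly tied
    models the projected gradient vanishes at the uniform point, which
    implements the tie-break toward uniform weights.
    """
    n, m = lpd.shape
    ref = lpd.max(axis=1, keepdims=True)
    ex = np.exp(lpd - ref)  # (n, m)

    def neg_obj(w):
        mix = ex @ w
        return -np.sum(np.log(np.maximum(mix, 1e-300)))

    def neg_grad(w):
        mix = np.maximum(ex @ w, 1e-300)
        return -(ex / mix[:, None]).sum(axis=0)

    w0 = np.full(m, 1.0 / m)
    res = optimize.minimize(
        neg_obj, w0, jac=neg_grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(m)}],
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def _pseudo_bma_weights(
    pointwise: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Pseudo-BMA+ weights via the Bayesian bootstrap over observations."""
    n, m = pointwise.shape
    alpha = np.ones(n)
    w_acc = np.zeros(m)
    for _ in range(n_boot):
        omega = rng.dirichlet(alpha)
        z = n * (omega @ pointwise)  # (m,)
        z = z - z.max()
        e = np.exp(z)
        w_acc += e / e.sum()
    w = w_acc / n_boot
    return w / w.sum()


def model_weights(
    loos: dict[str, LooResult] | list[LooResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> ModelWeights:
    """Stacking and pseudo-BMA+ weights from per-model LOO results.

    All models must share the same observation units (same count, same
    order).  Stacking maximizes the combined leave-one-out predictive
    density over the simplex; pseudo-BMA+ regularizes elpd-proportional
    weights with a seeded Bayesian bootstrap (default 1,000 replicates).
    """
    if isinstance(loos, dict):
        names = tuple(loos)
        items = list(loos.values())
    else:
        names = tuple(f"model_{i}" for i in range(len(loos)))
        items = list(loos)
    n_obs = {r.n_obs for r in items}
    if len(n_obs) != 1:
        raise ValueError("models have mismatched observation sets")
    pointwise = np.column_stack([r.pointwise for r in items])  # (n, m)
    rng = np.random.default_rng(seed)
    return ModelWeights(
        names=names,
        stacking=_stacking_weights(pointwise),
        pseudo_bma=_pseudo_bma_weights(pointwise, n_boot, rng),
    )


# ----------------------------------------------------------------------
# ICC variance decomposition


def icc_decompose(results, count_weighted: bool = False) -> pd.DataFrame:
    """Per-term shares of across-artist prediction variance, per matrix.

    Rows: the four transition matrices; columns: the model's terms
    (individual, expertise, nativity, caste, residence for the full
    model).  Each row sums to 1 and entries are non-negative by
    construction.  With ``count_weighted`` the per-cell shares are
    averaged weighted by the total transition count in the cell's row
    instead of uniformly.
    """
    d = results.design
    spec = results.spec
    terms = [t for t in ICC_COLUMNS if spec.has(t)]
    if not terms:
        raise ValueError("the fitted model has no artist-varying terms to decompose")
    N = d.n_artists
    table = []
    for key, layout in results.model.layouts.items():
        share_sum = np.zeros(len(terms))
        weight_sum = 0.0
        Y = d.Y[key]
        for r in range(layout.R):
            F = layout.F[r]
            contrib = {}
            if spec.has("artist"):
                contrib["artist"] = results.offset_draws(key, "artist", r)
            if spec.has("practice"):
                bp = results.get(key, "beta_prac", r)  # (c, s, F)
                contrib["practice"] = (
                    d.z_practice[None, None, :, None] * bp[..., None, :]
                )
            if spec.has("nativity"):
                bn = results.get(key, "beta_nat", r)
                contrib["nativity"] = (
                    d.native[None, None, :, None] * bn[..., None, :]
                )
            if spec.has("caste"):
                contrib["caste"] = results.offset_draws(key, "caste", r)[
                    ..., d.caste_index, :
                ]
            if spec.has("neighborhood"):
                contrib["neighborhood"] = results.offset_draws(
                    key, "neighborhood", r
                )[..., d.neighborhood_index, :]
            # variance across artists, per draw and per cell: (c, s, F)
            var = np.stack(
                [contrib[t].var(axis=-2) for t in terms], axis=0
            )  # (T, c, s, F)
            total = var.sum(axis=0)
            ok = total > 0  # draws x cells with any term variance
            if not ok.any():
                continue
            shares = var / np.where(ok, total, 1.0)[None]
            w_cell = float(Y[:, r, :].sum()) if count_weighted else 1.0
            # per-cell mean over the draws with positive total variance
            n_ok = ok.sum(axis=(0, 1))  # (F,)
            valid = n_ok > 0
            cell_mean = (shares * ok[None]).sum(axis=(1, 2))[:, valid] / n_ok[valid]
            share_sum += cell_mean.sum(axis=1) * w_cell
            weight_sum += w_cell * int(valid.sum())
        if weight_sum == 0:
            raise ValueError(
                f"matrix {key}: all cells have zero total term variance"
            )
        table.append(share_sum / weight_sum)
    df = pd.DataFrame(
        table,
        index=[ICC_ROWS[k] for k in results.model.layouts],
        columns=[ICC_COLUMNS[t] for t in terms],
    )
    return df


# ----------------------------------------------------------------------
# stationary distributions


@dataclass
class StationaryDistribution:
    pi: np.ndarray
    residual: float  # max |pi P - pi|
    n_recurrent_classes: int


class NonUniqueStationaryError(ValueError):
    """The chain has several recurrent classes; no unique stationary law."""


def _n_recurrent_classes(P: np.ndarray, tol: float = 1e-12) -> int:
    adj = (P > tol).astype(np.int8)
    n_comp, labels = csgraph.connected_components(adj, connection="strong")
    recurrent = 0
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        outside = np.setdiff1d(np.arange(P.shape[0]), members)
        if outside.size == 0 or P[np.ix_(members, outside)].sum() <= tol:
            recurrent += 1
    return recurrent


def stationary_distribution(
    P: np.ndarray, tol: float = 1e-10
) -> StationaryDistribution:
    """Solve pi P = pi, sum(pi) = 1 for a row-stochastic matrix.

    Uses a dense linear solve of the balance equations; uniqueness is
    checked via the chain's recurrent communicating classes (exactly one
    required).  The returned law satisfies ``max|pi P - pi| < tol``.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if (P < -1e-12).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("P must be row-stochastic")
    n = P.shape[0]
    n_rec = _n_recurrent_classes(P)
    if n_rec != 1:
        raise NonUniqueStationaryError(
            f"chain has {n_rec} recurrent classes; stationary law not unique"
        )
    A = P.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    resid = float(np.max(np.abs(pi @ P - pi)))
    if resid >= tol:
        raise RuntimeError(f"stationary solve residual {resid:.2e} >= {tol}")
    return StationaryDistribution(
        pi=pi, residual=resid, n_recurrent_classes=n_rec
    )


def exact_loo_elpd(ll_pointwise_draws: np.ndarray) -> np.ndarray:
    """elpd of held-out observations given draws from LOO posteriors.

    Helper for exact re-fit LOO: for each observation, given (chains,
    draws) log-likelihood values evaluated under the posterior fitted
    WITHOUT that observation, the exact elpd contribution is
    log mean_s exp(ll_s).
    """
    ll = np.asarray(ll_pointwise_draws, dtype=float)
    flat = ll.reshape(-1, ll.shape[-1]) if ll.ndim == 3 else ll
    s = flat.shape[0]
    return logsumexp(flat, axis=0) - np.log(s)
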