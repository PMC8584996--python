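"""Hierarchical Bayesian multinomial-logit transition model.

Each artist i contributes four transition-count matrices (between-space
3x3 and within-space 6x6/4x4/4x4).  Every matrix row j is modelled as a
multinomial over next states k with probabilities given by a softmax
over linear predictors on the logit scale:

    eta[i, j, k] = alpha[j, k]
                 + beta_prac[j, k] * z_i + beta_nat[j, k] * native_i
                 + a[i, j, k] + c[caste(i), j, k] + u[nbhd(i), j, k]

with the last (reference) category's eta fixed at 0.  Artist, caste and
neighborhood offsets are varying effects partially pooled through group
standard deviations sigma (one sigma per term per matrix row, shared
across that row's non-reference categories; optionally shared across
rows of a matrix).  Sampling runs NUTS with analytic gradients
(:mod:`kolamkit.hmc`); group offsets use the centered parameterisation
when their groups are data-rich and the non-centered one (offset =
sigma * standard-normal deviate) when weakly informed, which keeps the
posterior geometry well-conditioned at both extremes.

The rows of the four matrices are conditionally independent given the
model parameters, so the joint fit factorises over matrices; all rows
of a matrix are sampled jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy

from .counts import MATRICES, MATRIX_LABELS, dataset_counts
from .dataio import Dataset
from .geography import (
    NeighborhoodAssignment,
    cluster_neighborhoods,
    distance_matrix,
)

#: Model terms in canonical order (also the ICC column order, by their
#: display names individual/expertise/nativity/caste/residence).
TERMS = ("artist", "practice", "nativity", "caste", "neighborhood")

GROUP_TERMS = ("artist", "caste", "neighborhood")
FIXED_TERMS = ("practice", "nativity")


class ConvergenceError(RuntimeError):
    """MCMC diagnostics exceeded the configured thresholds."""


class DesignError(ValueError):
    """Invalid or incomplete design data."""


@dataclass(frozen=True)
class ModelSpec:
    """Which terms the model includes and how sigmas are constrained."""

    name: str
    terms: frozenset = frozenset(TERMS)
    sigma_sharing: str = "row"  # "row": one sigma per (term, matrix, row);
    #                             "matrix": shared across rows of a matrix
    structural_zeros: bool = False  # forbid O<->D cells of the space matrix
    matrices: tuple[str, ...] = MATRICES
    # sampling parameterization of group offsets: "auto" picks centered for
    # data-rich terms and non-centered for weakly informed ones
    parameterization: str = "auto"

    def __post_init__(self) -> None:
        unknown = self.terms - set(TERMS)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        if self.sigma_sharing not in ("row", "matrix"):
            raise ValueError("sigma_sharing must be 'row' or 'matrix'")
        if self.parameterization not in ("auto", "centered", "noncentered"):
            raise ValueError(
                "parameterization must be auto/centered/noncentered"
            )

    def has(self, term: str) -> bool:
        return term in self.terms


#: The registered model ladder: intercepts-only up to the full model.
MODEL_VARIANTS: dict[str, ModelSpec] = {
    "m1": ModelSpec("m1", frozenset()),
    "m2": ModelSpec("m2", frozenset({"artist"})),
    "m3": ModelSpec("m3", frozenset({"artist", "practice"})),
    "m4": ModelSpec("m4", frozenset({"artist", "practice", "nativity"})),
    "m5": ModelSpec("m5", frozenset({"artist", "caste"})),
    "m6": ModelSpec("m6", frozenset({"artist", "caste", "neighborhood"})),
    "m7": ModelSpec("m7", frozenset(TERMS)),
}
MODEL_VARIANTS["full"] = replace(MODEL_VARIANTS["m7"], name="full")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors on the logit scale.

    Intercepts and slopes get Normal(0, scale); group standard
    deviations get half-Normal(0, scale).
    """

    intercept_scale: float = 1.0
    slope_scale: float = 1.0
    sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.intercept_scale, self.slope_scale, self.sigma_scale) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class DesignData:
    """Model-ready arrays: counts and covariates in artist order."""

    artist_ids: tuple[str, ...]
    Y: dict  # matrix key -> (N, R, K) int counts
    z_practice: np.ndarray
    native: np.ndarray
    caste_index: np.ndarray  # 0-based
    neighborhood_index: np.ndarray  # 0-based
    caste_levels: tuple
    neighborhood_levels: tuple

    @property
    def n_artists(self) -> int:
        return len(self.artist_ids)

    @property
    def n_castes(self) -> int:
        return len(self.caste_levels)

    @property
    def n_neighborhoods(self) -> int:
        return len(self.neighborhood_levels)


def build_design(
    dataset: Dataset,
    neighborhoods: NeighborhoodAssignment,
    wrap: bool = True,
) -> DesignData:
    """Assemble counts and covariates for model fitting.

    Artists are ordered by sorted artist_id; caste and neighborhood
    category indices are assigned by first appearance in that order.
    Practice duration is standardised to mean 0, sd 1 (denominator n-1).
    """
    artists = sorted(dataset.artists, key=lambda a: a.artist_id)
    if not artists:
        raise DesignError("empty dataset")
    for a in artists:
        if a.artist_id not in neighborhoods.labels:
            raise DesignError(f"artist {a.artist_id}: no neighborhood label")

    practice = np.array([a.practice_years for a in artists], dtype=float)
    sd = practice.std(ddof=1) if len(artists) > 1 else 0.0
    if sd == 0:
        raise DesignError("practice duration has zero variance; cannot standardize")
    z = (practice - practice.mean()) / sd

    caste_levels: list[int] = []
    caste_index = []
    for a in artists:
        if a.caste_id not in caste_levels:
            caste_levels.append(a.caste_id)
        caste_index.append(caste_levels.index(a.caste_id))
    nbhd_levels: list[int] = []
    nbhd_index = []
    for a in artists:
        lab = neighborhoods.labels[a.artist_id]
        if lab not in nbhd_levels:
            nbhd_levels.append(lab)
        nbhd_index.append(nbhd_levels.index(lab))

    counts = dataset_counts(dataset, wrap=wrap)
    Y = {}
    for key in MATRICES:
        K = len(MATRIX_LABELS[key])
        Y[key] = np.stack(
            [counts[a.artist_id].matrix(key) for a in artists]
        ).reshape(len(artists), K, K)
    return DesignData(
        artist_ids=tuple(a.artist_id for a in artists),
        Y=Y,
        z_practice=z,
        native=np.array([a.native for a in artists], dtype=float),
        caste_index=np.array(caste_index, dtype=int),
        neighborhood_index=np.array(nbhd_index, dtype=int),
        caste_levels=tuple(caste_levels),
        neighborhood_levels=tuple(nbhd_levels),
    )


# ----------------------------------------------------------------------
# elementary model operations


def row_probability(eta: np.ndarray) -> np.ndarray:
    """Softmax of a row's linear predictors (reference category's eta is 0).

    ``-inf`` entries encode structurally impossible cells (probability 0).
    """
    eta = np.asarray(eta, dtype=float)
    if np.isnan(eta).any() or np.isposinf(eta).any():
        raise ValueError("linear predictors must be finite (or -inf)")
    return np.exp(eta - logsumexp(eta, axis=-1, keepdims=True))


def multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log pmf including the combinatorial coefficient.

    A zero-total row contributes 0; a positive count on a zero
    probability yields -inf (data/model conflict).
    """
    y = np.asarray(counts, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("counts and probs must have the same length")
    if (y < 0).any():
        raise ValueError("negative counts")
    if not np.isclose(p.sum(), 1.0, atol=1e-8) or (p < -1e-12).any():
        raise ValueError("probs must lie on the simplex")
    n = y.sum()
    if n == 0:
        return 0.0
    if ((y > 0) & (p <= 0)).any():
        return -np.inf
    return float(gammaln(n + 1) - gammaln(y + 1).sum() + xlogy(y, p).sum())


# ----------------------------------------------------------------------
# parameter layout for one matrix


class MatrixLayout:
    """Flat-vector layout of all parameters attached to one matrix."""

    def __init__(
        self,
        key: str,
        Y: np.ndarray,
        spec: ModelSpec,
        design: DesignData,
    ) -> None:
        self.key = key
        self.spec = spec
        N, R, K = Y.shape
        self.N, self.R, self.K = N, R, K
        allowed = np.ones((R, K), dtype=bool)
        if spec.structural_zeros and key == "space":
            allowed[0, 2] = False  # O -> D
            allowed[2, 0] = False  # D -> O
        self.allowed = allowed
        if (Y[:, ~allowed] != 0).any():
            raise DesignError(
                f"{key}: counts present in structurally-forbidden cells"
            )
        # Reference category per row: the most-visited allowed category
        # (pooled over artists).  A rare reference would leave every logit
        # in the row weakly identified; pivoting to the modal category
        # conditions the posterior and makes per-cell information
        # proportional to the cell's own counts.
        self.free_cols = []
        self.ref_col = []
        pooled = Y.sum(axis=0)  # (R, K)
        for r in range(R):
            cols = np.flatnonzero(allowed[r])
            ref = int(cols[np.argmax(pooled[r, cols])])
            self.ref_col.append(ref)
            self.free_cols.append(cols[cols != ref])
        self.F = [len(fc) for fc in self.free_cols]
        # permutation per row: free columns in order, reference last
        self.perm = [
            np.concatenate([self.free_cols[r], [self.ref_col[r]]])
            for r in range(R)
        ]

        self.slices: dict[tuple[str, int], tuple[slice, tuple]] = {}
        pos = 0

        def add(name: str, r: int, shape: tuple) -> None:
            nonlocal pos
            size = int(np.prod(shape))
            self.slices[(name, r)] = (slice(pos, pos + size), shape)
            pos += size

        for r in range(R):
            add("alpha", r, (self.F[r],))
        if spec.has("practice"):
            for r in range(R):
                add("beta_prac", r, (self.F[r],))
        if spec.has("nativity"):
            for r in range(R):
                add("beta_nat", r, (self.F[r],))
        if spec.has("artist"):
            for r in range(R):
                add("a_tilde", r, (N, self.F[r]))
        if spec.has("caste"):
            for r in range(R):
                add("c_tilde", r, (design.n_castes, self.F[r]))
        if spec.has("neighborhood"):
            for r in range(R):
                add("u_tilde", r, (design.n_neighborhoods, self.F[r]))
        n_sig = 1 if spec.sigma_sharing == "matrix" else R
        for term, pname in (("artist", "t_artist"), ("caste", "t_caste"),
                            ("neighborhood", "t_neigh")):
            if spec.has(term):
                add(pname, -1, (n_sig,))
        self.dim = pos

        # group-term metadata: (term, offsets name, log-sigma name,
        # n_groups, membership index)
        self.group_terms: list[tuple[str, str, str, int, np.ndarray]] = []
        if spec.has("artist"):
            self.group_terms.append(
                ("artist", "a_tilde", "t_artist", N, np.arange(N))
            )
        if spec.has("caste"):
            self.group_terms.append(
                ("caste", "c_tilde", "t_caste", design.n_castes,
                 design.caste_index)
            )
        if spec.has("neighborhood"):
            self.group_terms.append(
                ("neighborhood", "u_tilde", "t_neigh",
                 design.n_neighborhoods, design.neighborhood_index)
            )
        # Parameterization choice, per matrix row.  Artist offsets are
        # informed directly by that artist's counts in the row, so a row is
        # centered when counts are plentiful (>= 30 per artist on average in
        # that row).  Caste/neighborhood offsets are informed only through
        # the handful of artists per group (their own counts are absorbed by
        # the artist term), so they stay non-centered under "auto".
        # Per-cell masks over (row, free category): an artist offset is
        # centered when its cell carries enough data per artist (mean count
        # >= 5, the per-cell Fisher information scale); data-poor cells stay
        # non-centered, as do caste/neighborhood offsets, which are informed
        # only through the few artists per group.
        self.centered: dict[str, list[np.ndarray]] = {}
        mean_cell = Y.sum(axis=0) / max(N, 1)  # (R, K)
        for term, _, _, n_groups, _ in self.group_terms:
            masks = []
            for r in range(R):
                if spec.parameterization == "auto":
                    if term == "artist":
                        masks.append(mean_cell[r, self.free_cols[r]] >= 5.0)
                    else:
                        masks.append(np.zeros(self.F[r], dtype=bool))
                else:
                    masks.append(np.full(
                        self.F[r], spec.parameterization == "centered"
                    ))
            self.centered[term] = masks

    def get(self, theta: np.ndarray, name: str, r: int = -1) -> np.ndarray:
        """Slice ``name`` (for row ``r``) out of a parameter vector or a
        draw array whose last axis is the flat parameter dimension."""
        sl, shape = self.slices[(name, r)]
        return theta[..., sl].reshape(theta.shape[:-1] + shape)

    @property
    def uniform(self) -> bool:
        """True when every row has a full set of free categories (no
        structural zeros), enabling row-vectorised computation on
        per-row column-permuted counts (reference pivoted last)."""
        return all(f == self.K - 1 for f in self.F)

    def get_block(self, theta: np.ndarray, name: str) -> np.ndarray:
        """All rows of a per-row parameter as one array (R, ...); valid
        only for uniform layouts (row slices are contiguous)."""
        first, shape = self.slices[(name, 0)]
        last, _ = self.slices[(name, self.R - 1)]
        block = theta[..., first.start:last.stop]
        return block.reshape(theta.shape[:-1] + (self.R,) + shape)

    def has(self, name: str) -> bool:
        return any(k[0] == name for k in self.slices)

    def sigma_of_row(self, theta: np.ndarray, pname: str, r: int) -> np.ndarray:
        """exp of the log-sigma attached to row r (handles sharing)."""
        t = self.get(theta, pname, -1)
        idx = 0 if self.spec.sigma_sharing == "matrix" else r
        return np.exp(t[..., idx])


def _make_logp_grad_uniform(
    layout: MatrixLayout, design: DesignData, priors: PriorSpec
):
    """Row-vectorised log posterior + gradient (no structural zeros)."""
    Y = design.Y[layout.key].astype(float)
    N, R, K = Y.shape
    F = K - 1
    # per-row column permutation puts the reference category last
    Yp = np.stack([Y[:, r, layout.perm[r]] for r in range(R)], axis=1)
    Yf = np.ascontiguousarray(Yp[:, :, :F])
    n_tot = Y.sum(axis=2)  # (N, R)
    z = design.z_practice
    nat = design.native
    spec = layout.spec
    s_int2 = priors.intercept_scale**2
    s_slope2 = priors.slope_scale**2
    s_sig2 = priors.sigma_scale**2
    shared = spec.sigma_sharing == "matrix"

    def row_sigma(t: np.ndarray) -> np.ndarray:
        sig = np.exp(t)
        return np.full(R, sig[0]) if shared else sig

    def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(theta)
        alpha = layout.get_block(theta, "alpha")  # (R, F)
        eta = np.broadcast_to(alpha, (N, R, F)).copy()
        if spec.has("practice"):
            bp = layout.get_block(theta, "beta_prac")
            eta += z[:, None, None] * bp
        if spec.has("nativity"):
            bn = layout.get_block(theta, "beta_nat")
            eta += nat[:, None, None] * bn
        cache = {}
        for term, pname, tname, nG, idx in layout.group_terms:
            t = layout.get(theta, tname, -1)
            sig = row_sigma(t)  # (R,)
            cen = np.asarray(layout.centered[term])  # (R, F) bool
            mult = np.where(cen, 1.0, sig[:, None])  # (R, F) eta multiplier
            B = layout.get_block(theta, pname)  # (R, nG, F)
            Bi = B[:, idx].transpose(1, 0, 2)  # (N, R, F)
            eta += mult[None, :, :] * Bi
            cache[term] = (t, sig, cen, mult, B)

        m = np.maximum(eta.max(axis=2), 0.0)  # (N, R)
        se = np.exp(eta - m[:, :, None]).sum(axis=2) + np.exp(-m)
        lse = m + np.log(se)
        logp = float((Yf * eta).sum() - (n_tot * lse).sum())
        p_free = np.exp(eta - lse[:, :, None])
        G = Yf - n_tot[:, :, None] * p_free  # (N, R, F)

        layout.get_block(grad, "alpha")[:] = G.sum(axis=0) - alpha / s_int2
        logp -= 0.5 * float((alpha * alpha).sum()) / s_int2
        if spec.has("practice"):
            layout.get_block(grad, "beta_prac")[:] = (
                (z[:, None, None] * G).sum(axis=0) - bp / s_slope2
            )
            logp -= 0.5 * float((bp * bp).sum()) / s_slope2
        if spec.has("nativity"):
            layout.get_block(grad, "beta_nat")[:] = (
                (nat[:, None, None] * G).sum(axis=0) - bn / s_slope2
            )
            logp -= 0.5 * float((bn * bn).sum()) / s_slope2

        for term, pname, tname, nG, idx in layout.group_terms:
            t, sig, cen, mult, B = cache[term]
            if term == "artist":
                M = G  # identity membership
            else:
                M = np.zeros((nG, R, F))
                np.add.at(M, idx, G)
            Mt = M.transpose(1, 0, 2)  # (R, nG, F)
            S2 = (B * B).sum(axis=1)  # (R, F)
            BM = (B * Mt).sum(axis=1)  # (R, F)
            # prior on offsets: N(0, sigma) for centered cells, N(0, 1) else
            prior_scale2 = np.where(cen, sig[:, None] ** 2, 1.0)  # (R, F)
            layout.get_block(grad, pname)[:] = (
                mult[:, None, :] * Mt - B / prior_scale2[:, None, :]
            )
            logp -= 0.5 * float((S2 / prior_scale2).sum())
            logp -= nG * float((cen.sum(axis=1) * np.log(sig)).sum())
            safe2 = np.maximum(sig, 1e-150)[:, None] ** 2
            ll_t = np.where(
                cen, S2 / safe2 - nG, sig[:, None] * BM
            ).sum(axis=1)  # (R,)
            sig_t = np.exp(t)  # (n_sig,)
            logp += float((-0.5 * sig_t**2 / s_sig2 + t).sum())
            tot = np.array([ll_t.sum()]) if shared else ll_t
            layout.get(grad, tname, -1)[:] = tot - sig_t**2 / s_sig2 + 1.0
        return logp, grad

    return logp_grad


def make_logp_grad(layout: MatrixLayout, design: DesignData, priors: PriorSpec):
    """Closure computing the log posterior and its gradient for one matrix.

    Dispatches to a row-vectorised implementation when every row shares
    the same free/reference layout; the general per-row path handles
    structural zeros.
    """
    if layout.uniform:
        return _make_logp_grad_uniform(layout, design, priors)

    Y = design.Y[layout.key].astype(float)
    N, R, K = Y.shape
    n_tot = Y.sum(axis=2)
    z = design.z_practice
    nat = design.native
    spec = layout.spec
    s_int2 = priors.intercept_scale**2
    s_slope2 = priors.slope_scale**2
    s_sig2 = priors.sigma_scale**2
    shared = spec.sigma_sharing == "matrix"
    onehot = {
        term: np.eye(nG)[:, idx]
        for term, _, _, nG, idx in layout.group_terms
        if term != "artist"
    }  # (nG, N) membership matrices for fast scatter via matmul

    def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(theta)
        logp = 0.0
        n_sig = 1 if shared else R
        sig_ll = {tname: np.zeros(n_sig)
                  for _, _, tname, _, _ in layout.group_terms}

        def gslot(name, r=-1):
            sl, shape = layout.slices[(name, r)]
            return grad[sl].reshape(shape)

        for r in range(R):
            fc = layout.free_cols[r]
            rc = layout.ref_col[r]
            F = layout.F[r]
            alpha = layout.get(theta, "alpha", r)
            eta = np.broadcast_to(alpha, (N, F)).copy()
            if spec.has("practice"):
                bp = layout.get(theta, "beta_prac", r)
                eta += z[:, None] * bp
            if spec.has("nativity"):
                bn = layout.get(theta, "beta_nat", r)
                eta += nat[:, None] * bn
            cache = {}
            for term, pname, tname, nG, idx in layout.group_terms:
                sig = layout.sigma_of_row(theta, tname, r)
                cen = layout.centered[term][r]  # (F,) bool
                mult = np.where(cen, 1.0, sig)
                B = layout.get(theta, pname, r)  # (nG, F)
                eta += mult * B[idx]
                cache[term] = (sig, cen, mult, B)

            # stable log-sum-exp over the allowed cells (reference logit 0)
            mx = np.maximum(eta.max(axis=1), 0.0)
            se = np.exp(eta - mx[:, None]).sum(axis=1) + np.exp(-mx)
            lse = mx + np.log(se)
            logp += float(
                (Y[:, r, fc] * eta).sum() - (n_tot[:, r] * lse).sum()
            )
            p_free = np.exp(eta - lse[:, None])
            G = Y[:, r, fc] - n_tot[:, r][:, None] * p_free  # (N, F)

            gslot("alpha", r)[:] = G.sum(axis=0) - alpha / s_int2
            logp -= 0.5 * float(alpha @ alpha) / s_int2
            if spec.has("practice"):
                gslot("beta_prac", r)[:] = (z[:, None] * G).sum(axis=0) - bp / s_slope2
                logp -= 0.5 * float(bp @ bp) / s_slope2
            if spec.has("nativity"):
                gslot("beta_nat", r)[:] = (nat[:, None] * G).sum(axis=0) - bn / s_slope2
                logp -= 0.5 * float(bn @ bn) / s_slope2
            for term, pname, tname, nG, idx in layout.group_terms:
                sig, cen, mult, B = cache[term]
                if term == "artist":
                    M = G
                else:
                    M = onehot[term] @ G
                slot = 0 if shared else r
                prior_scale2 = np.where(cen, sig**2, 1.0)  # (F,)
                gslot(pname, r)[:] = mult * M - B / prior_scale2
                S2 = (B * B).sum(axis=0)  # (F,)
                BM = (B * M).sum(axis=0)
                logp -= 0.5 * float((S2 / prior_scale2).sum())
                logp -= nG * int(cen.sum()) * float(np.log(sig))
                safe2 = max(sig, 1e-150) ** 2
                sig_ll[tname][slot] += float(
                    np.where(cen, S2 / safe2 - nG, sig * BM).sum()
                )

        for _, _, tname, _, _ in layout.group_terms:
            t = layout.get(theta, tname, -1)
            sig = np.exp(t)
            logp += float((-0.5 * sig**2 / s_sig2 + t).sum())
            gslot(tname)[:] = sig_ll[tname] - sig**2 / s_sig2 + 1.0
        return logp, grad

    return logp_grad


def make_interweaver(
    layout: MatrixLayout, design: DesignData, priors: PriorSpec
):
    """Interweaved exact Gibbs updates along the posterior's slow ridges.

    Two families of moves, both leaving the likelihood untouched (the
    per-artist linear predictors are invariant), so each is an exact
    draw from a 1-D conditional with no likelihood evaluation:

    * scale moves — holding the actual offsets a fixed (a = B for
      centered cells, sigma*B for non-centered ones), the conditional of
      t = log sigma is  -S2 exp(-2t)/2 - (n-1) t - exp(2t)/(2 s^2)
      with S2 the summed squared offsets and n their count; sampled by
      univariate slice sampling.  This walks the funnel's axis directly.
    * translation moves — the intercept (or covariate slope) and the
      group offsets trade off along a flat ridge: alpha -> alpha + d,
      a_g -> a_g - d x_g (x = 1, standardized practice, or the nativity
      indicator) has a Gaussian conditional for d from the priors alone.
    * joint rescaling moves — the complementary ("sufficiency") scale
      update: sigma and all its actual offsets scale together by e^d,
      holding the standardized deviates fixed.  The offset prior and
      proposal Jacobian cancel exactly, leaving the row's multinomial
      likelihood plus the sigma hyperprior as the 1-D target; slice
      sampling it lets sigma and the offsets grow or shrink jointly,
      the escape direction out of the collapsed-scale basin.

    NUTS handles every remaining direction.  Returns None when the model
    has no group terms.
    """
    from .hmc import slice_sample_1d

    if not layout.group_terms:
        return None
    s_sig2 = priors.sigma_scale**2
    s_int2 = priors.intercept_scale**2
    s_slope2 = priors.slope_scale**2
    shared = layout.spec.sigma_sharing == "matrix"
    spec = layout.spec
    R = layout.R
    slots = []
    for term, pname, tname, nG, _ in layout.group_terms:
        n_sig = 1 if shared else R
        for slot in range(n_sig):
            rows = list(range(R)) if shared else [slot]
            slots.append(
                (tname, slot,
                 [(pname, r, layout.centered[term][r]) for r in rows])
            )
    # translation directions for the artist term: intercept and the
    # per-artist covariates
    trans = [("alpha", np.ones(layout.N), s_int2)]
    if spec.has("practice"):
        trans.append(("beta_prac", design.z_practice, s_slope2))
    if spec.has("nativity"):
        trans.append(("beta_nat", design.native, s_slope2))

    Y = design.Y[layout.key].astype(float)
    n_tot = Y.sum(axis=2)
    z = design.z_practice
    nat = design.native

    def row_eta_parts(theta, r):
        """Base linear predictor (intercept + covariates) and each group
        term's actual-offset contribution, all (N, F_r)."""
        base = np.broadcast_to(
            layout.get(theta, "alpha", r), (layout.N, layout.F[r])
        ).copy()
        if spec.has("practice"):
            base += z[:, None] * layout.get(theta, "beta_prac", r)
        if spec.has("nativity"):
            base += nat[:, None] * layout.get(theta, "beta_nat", r)
        contribs = {}
        for term, pname, tname, _, idx in layout.group_terms:
            sig = float(layout.sigma_of_row(theta, tname, r))
            cen = layout.centered[term][r]
            B = layout.get(theta, pname, r)
            contribs[term] = np.where(cen, B, sig * B)[idx]
        return base, contribs

    def update(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        theta = theta.copy()
        # -- scale moves, one per sigma parameter
        for tname, slot, rows in slots:
            tsl, _ = layout.slices[(tname, -1)]
            pos = tsl.start + slot
            t0 = float(theta[pos])
            sig0 = np.exp(t0)
            S2, n = 0.0, 0
            for pname, r, cen in rows:
                B = layout.get(theta, pname, r)  # view (nG, F_r)
                a2 = np.where(cen, B * B, (sig0 * B) ** 2)
                S2 += float(a2.sum())
                n += B.size
            if S2 < 1e-300:
                continue

            def logf(t: float) -> float:
                return (
                    -0.5 * S2 * np.exp(-2.0 * t)
                    - (n - 1) * t
                    - 0.5 * np.exp(2.0 * t) / s_sig2
                )

            t1 = slice_sample_1d(logf, t0, rng)
            scale = sig0 / np.exp(t1)
            for pname, r, cen in rows:
                B = layout.get(theta, pname, r)
                B[:, ~cen] *= scale  # keep non-centered actual offsets fixed
            theta[pos] = t1

        # -- joint rescaling moves (sigma and its offsets together)
        n_sig = 1 if shared else R
        for term, pname, tname, nG, idx in layout.group_terms:
            for slot in range(n_sig):
                rows_r = list(range(R)) if shared else [slot]
                tsl, _ = layout.slices[(tname, -1)]
                pos = tsl.start + slot
                t0 = float(theta[pos])
                packs = []
                for r in rows_r:
                    base, contribs = row_eta_parts(theta, r)
                    mine = contribs.pop(term)
                    for c in contribs.values():
                        base += c
                    packs.append((r, base, mine))

                def logf2(t: float) -> float:
                    s = np.exp(t - t0)
                    ll = 0.0
                    for r, eta_rest, mine in packs:
                        etaf = eta_rest + s * mine
                        mx = np.maximum(etaf.max(axis=1), 0.0)
                        lse = mx + np.log(
                            np.exp(etaf - mx[:, None]).sum(axis=1)
                            + np.exp(-mx)
                        )
                        ll += float(
                            (Y[:, r, layout.free_cols[r]] * etaf).sum()
                            - (n_tot[:, r] * lse).sum()
                        )
                    return ll - 0.5 * np.exp(2.0 * t) / s_sig2 + t

                t1 = slice_sample_1d(logf2, t0, rng, w=0.5)
                if t1 != t0:
                    grow = np.exp(t1 - t0)
                    for r in rows_r:
                        cen = layout.centered[term][r]
                        B = layout.get(theta, pname, r)
                        B[:, cen] *= grow  # non-centered cells scale via sigma
                    theta[pos] = t1

        # -- exact per-cell intercept updates: slice-sample each alpha
        # through the row likelihood and its prior.  This is the "total
        # logit" direction, which the translation moves leave invariant
        # and which develops a long one-sided tail for zero-count cells.
        for r in range(R):
            base, contribs = row_eta_parts(theta, r)
            eta = base
            for c in contribs.values():
                eta = eta + c
            alpha = layout.get(theta, "alpha", r)  # view (F,)
            fc = layout.free_cols[r]
            Yr = Y[:, r, fc]
            n_r = n_tot[:, r]
            for f in range(len(fc)):
                mx = np.maximum(eta.max(axis=1), 0.0)
                rest = (
                    np.exp(eta - mx[:, None]).sum(axis=1)
                    + np.exp(-mx)
                    - np.exp(eta[:, f] - mx)
                )  # sum over other cells + reference, scaled by e^-mx
                ysum = float(Yr[:, f].sum())
                a0 = float(alpha[f])
                eta_f = eta[:, f]

                def logf3(a_new: float) -> float:
                    d = a_new - a0
                    lse = mx + np.log(np.exp(eta_f - mx + d) + rest)
                    return (
                        ysum * d
                        - float((n_r * lse).sum())
                        - 0.5 * a_new**2 / s_int2
                    )

                a1 = slice_sample_1d(logf3, a0, rng)
                if a1 != a0:
                    alpha[f] = a1
                    eta[:, f] = eta_f + (a1 - a0)

        # -- translation moves: intercept vs each term's offsets, and the
        # per-artist covariate slopes vs the artist offsets
        for r in range(R):
            for term, pname, tname, nG, _ in layout.group_terms:
                cen = layout.centered[term][r]
                sig = float(layout.sigma_of_row(theta, tname, r))
                B = layout.get(theta, pname, r)  # (nG, F)
                a = np.where(cen, B, sig * B)
                alpha = layout.get(theta, "alpha", r)
                tau = 1.0 / s_int2 + nG / sig**2
                mean = (-alpha / s_int2 + a.sum(axis=0) / sig**2) / tau
                d = mean + rng.standard_normal(alpha.size) / np.sqrt(tau)
                alpha += d
                a = a - d[None, :]
                B[:] = np.where(cen, a, a / sig)
            if spec.has("artist"):
                cen = layout.centered["artist"][r]
                sig = float(layout.sigma_of_row(theta, "t_artist", r))
                B = layout.get(theta, "a_tilde", r)  # (N, F)
                a = np.where(cen, B, sig * B)
                for loc_name, x, s_loc2 in trans[1:]:
                    loc = layout.get(theta, loc_name, r)  # (F,)
                    x2 = float((x * x).sum())
                    if x2 == 0.0:
                        continue
                    tau = 1.0 / s_loc2 + x2 / sig**2
                    mean = (-loc / s_loc2 + (x @ a) / sig**2) / tau
                    d = mean + rng.standard_normal(loc.size) / np.sqrt(tau)
                    loc += d
                    a = a - x[:, None] * d[None, :]
                B[:] = np.where(cen, a, a / sig)
        return theta

    return update


def make_initializer(layout: MatrixLayout, design: DesignData):
    """Data-informed chain initialization.

    Intercepts start at the pooled empirical row logits and artist
    offsets at count-shrunk per-artist deviations from them, with the
    group scale set to the spread of those deviations; remaining
    parameters start near zero.  Every quantity is jittered per chain.
    Starting in the posterior's bulk keeps chains clear of the
    metastable small-sigma region of hierarchical posteriors.
    """
    Y = design.Y[layout.key].astype(float)
    N, R, K = Y.shape
    pooled = Y.sum(axis=0) + 0.5  # (R, K)
    emp = Y + 0.5
    alpha0 = []
    off0 = []
    sig0 = []
    for r in range(R):
        fc = layout.free_cols[r]
        rc = layout.ref_col[r]
        a0 = np.log(pooled[r, fc] / pooled[r, rc])
        row_n = Y[:, r, :].sum(axis=1)
        el = np.log(emp[:, r, :][:, fc] / emp[:, r, :][:, [rc]])
        shrink = (row_n / (row_n + 10.0))[:, None]
        o0 = (el - a0) * shrink
        alpha0.append(a0)
        off0.append(o0)
        sig0.append(float(np.clip(o0.std(), 0.2, 2.0)))

    def init(rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(layout.dim)
        for r in range(R):
            layout.get(x, "alpha", r)[:] = alpha0[r] + 0.2 * rng.standard_normal(
                layout.F[r]
            )
        for name in ("beta_prac", "beta_nat"):
            if layout.has(name):
                for r in range(R):
                    layout.get(x, name, r)[:] = 0.1 * rng.standard_normal(
                        layout.F[r]
                    )
        for term, pname, tname, nG, _ in layout.group_terms:
            tsl, _ = layout.slices[(tname, -1)]
            n_sig = tsl.stop - tsl.start
            if term == "artist":
                x[tsl] = np.log(
                    [sig0[r] for r in range(R)][:n_sig]
                ) + 0.2 * rng.standard_normal(n_sig)
                for r in range(R):
                    cen = layout.centered[term][r]
                    jit = off0[r] + 0.1 * rng.standard_normal(off0[r].shape)
                    layout.get(x, pname, r)[:] = np.where(
                        cen, jit, jit / sig0[r]
                    )
            else:
                x[tsl] = np.log(0.3) + 0.2 * rng.standard_normal(n_sig)
                for r in range(R):
                    layout.get(x, pname, r)[:] = 0.1 * rng.standard_normal(
                        (nG, layout.F[r])
                    )
        return x

    return init


# ----------------------------------------------------------------------
# the Model object


class KolamTransitionModel:
    """Hierarchical multinomial-logit model of gesture transitions.

    Parameters
    ----------
    design : DesignData
        Per-artist transition counts and covariates (see ``build_design``).
    spec : ModelSpec, optional
        Which terms to include; defaults to the full model.
    priors : PriorSpec, optional
        Prior scales on the logit scale.
    """

    def __init__(
        self,
        design: DesignData,
        spec: ModelSpec | None = None,
        priors: PriorSpec | None = None,
    ) -> None:
        self.design = design
        self.spec = spec or MODEL_VARIANTS["full"]
        self.priors = priors or PriorSpec()
        self.layouts = {
            key: MatrixLayout(key, design.Y[key], self.spec, design)
            for key in self.spec.matrices
        }

    @classmethod
    def from_dataset(
        cls,
        dataset: Dataset,
        neighborhoods: NeighborhoodAssignment | None = None,
        spec: ModelSpec | None = None,
        priors: PriorSpec | None = None,
        threshold_m: float = 500.0,
        linkage: str = "complete",
        wrap: bool = True,
    ) -> "KolamTransitionModel":
        """Build the model straight from a Dataset, clustering GPS
        coordinates into neighborhoods when none are supplied."""
        if neighborhoods is None:
            artists = sorted(dataset.artists, key=lambda a: a.artist_id)
            dm = distance_matrix(
                [a.artist_id for a in artists],
                np.array([a.latitude for a in artists]),
                np.array([a.longitude for a in artists]),
            )
            neighborhoods = cluster_neighborhoods(
                dm, threshold_m=threshold_m, method=linkage
            )
        design = build_design(dataset, neighborhoods, wrap=wrap)
        return cls(design, spec=spec, priors=priors)

    def fit(
        self,
        draws: int = 1000,
        warmup: int = 1000,
        chains: int = 4,
        seed: int = 0,
        target_accept: float = 0.9,
        max_depth: int = 10,
        check: bool = True,
        rhat_threshold: float = 1.01,
        max_divergences: int = 20,
    ):
        """Sample the posterior by HMC; returns TransitionModelResults.

        With ``check`` (default) the fit fails loudly if any split R-hat
        reaches ``rhat_threshold`` or divergent transitions exceed
        ``max_divergences``.
        """
        from .results import TransitionModelResults

        raw: dict[str, np.ndarray] = {}
        stats: dict[str, dict] = {}
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(self.layouts))
        for child, (key, layout) in zip(children, self.layouts.items()):
            lg = make_logp_grad(layout, self.design, self.priors)
            init = make_initializer(layout, self.design)
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            from .hmc import sample

            raw[key], stats[key] = sample(
                lg, init, layout.dim, chains=chains, n_warmup=warmup,
                n_draws=draws, seed=sub_seed, target_accept=target_accept,
                max_depth=max_depth,
                extra_step=make_interweaver(layout, self.design, self.priors),
            )
        results = TransitionModelResults(
            model=self, draws=raw, sampler_stats=stats, seed=seed
        )
        if check:
            results.check_convergence(
                rhat_threshold=rhat_threshold, max_divergences=max_divergences
            )
        return results
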