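"""Synthetic kolam corpora from a known generative model.

The generator is the inverse of the fitted model: population row logits
for the four transition matrices plus per-artist, per-caste and
per-neighborhood offsets (drawn with known group standard deviations)
and fixed effects for practice and nativity compose per-artist
transition rows, from which grammar-valid loop sequences are emitted.
Defaults emulate the field corpus: 192 artists in 19 caste categories
and 8 neighborhood clusters, 16 drawings each, about 18% non-native,
and an effect hierarchy dominated by artist-level variation.

Loops are sampled as linear sequences: the initial geometric space from
the artist's between-space stationary law, the initial gesture from the
within-space stationary law, then iterated transitions — a same-space
step uses the within-space row of the current gesture, a space switch
lands on a gesture of the destination space drawn from that space's
stationary law.  Counting later applies cyclic (wrap-around) closure,
a mild, documented mismatch; ``wrap=False`` counting removes it for
strict recovery studies.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import ArtistRecord, Dataset, Drawing, Loop
from .geography import EARTH_RADIUS_M
from .lexicon import SPACES, Lexicon, load_lexicon, validate_state_sequence

_SPACE_IDX = {s: i for i, s in enumerate(SPACES)}


def _logits_from_probs(p: np.ndarray) -> np.ndarray:
    """Row probabilities -> logits with the last positive cell as reference."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, -np.inf)
    pos = p > 0
    ref = np.flatnonzero(pos)[-1]
    out[pos] = np.log(p[pos] / p[ref])
    return out


def _stationary(P: np.ndarray) -> np.ndarray:
    from .evaluation import NonUniqueStationaryError, stationary_distribution

    try:
        return stationary_distribution(P).pi
    except NonUniqueStationaryError:
        warnings.warn(
            "degenerate transition matrix (a space is unreachable); "
            "using uniform initial law", stacklevel=2,
        )
        return np.full(P.shape[0], 1.0 / P.shape[0])


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters: population logits, group sds, slopes."""

    logits: dict  # matrix key -> (R, K), -inf marks impossible cells
    sigma: dict  # term -> {matrix key -> (R,)}          (group terms)
    beta: dict  # term -> {matrix key -> (R, K)}         (fixed terms)
    p_native: float = 0.18

    def __post_init__(self) -> None:
        for term in ("artist", "caste", "neighborhood"):
            for key in self.logits:
                if (np.asarray(self.sigma[term][key]) < 0).any():
                    raise ValueError(f"negative sigma for {term}/{key}")
        for key, lg in self.logits.items():
            p = np.exp(lg - np.max(lg, axis=1, keepdims=True))
            if not np.all(np.isfinite(p.sum(axis=1))):
                raise ValueError(f"invalid population logits for {key}")

    def population_probs(self, key: str) -> np.ndarray:
        lg = self.logits[key]
        m = np.max(lg, axis=1, keepdims=True)
        e = np.exp(lg - m)
        return e / e.sum(axis=1, keepdims=True)


def truth_from_probs(
    probs: dict,
    sigma_artist: float = 1.0,
    sigma_caste: float = 0.2,
    sigma_neigh: float = 0.2,
    beta_practice: float = 0.5,
    beta_nativity: float = 0.25,
    p_native: float = 0.18,
) -> GroundTruth:
    """Ground truth from population probability matrices (keys space/O/D/T)
    with homogeneous group sds and slopes."""
    logits = {k: np.vstack([_logits_from_probs(row) for row in p])
              for k, p in probs.items()}
    sigma = {
        "artist": {k: np.full(p.shape[0], sigma_artist) for k, p in probs.items()},
        "caste": {k: np.full(p.shape[0], sigma_caste) for k, p in probs.items()},
        "neighborhood": {k: np.full(p.shape[0], sigma_neigh)
                         for k, p in probs.items()},
    }
    beta = {
        "practice": {k: np.where(np.isfinite(logits[k]), beta_practice, 0.0)
                     for k in probs},
        "nativity": {k: np.where(np.isfinite(logits[k]), beta_nativity, 0.0)
                     for k in probs},
    }
    # reference (last finite) cell carries no slope, matching the model
    for term in beta:
        for k in probs:
            for r in range(probs[k].shape[0]):
                ref = np.flatnonzero(np.isfinite(logits[k][r]))[-1]
                beta[term][k][r, ref] = 0.0
    return GroundTruth(logits=logits, sigma=sigma, beta=beta, p_native=p_native)


def default_truth(
    sigma_artist: float = 1.0,
    sigma_caste: float = 0.2,
    sigma_neigh: float = 0.2,
    beta_practice: float = 0.5,
    beta_nativity: float = 0.25,
    p_native: float = 0.18,
) -> GroundTruth:
    """Study-condition defaults: artist-level variance dominant, and a
    between-space matrix matching the reported population tendencies
    (orthogonal drawings stay orthogonal, diagonal/transitional mix)."""
    space = np.array(
        [[0.99, 0.01, 0.00],  # from O (order O, T, D)
         [0.51, 0.30, 0.19],  # from T
         [0.00, 0.51, 0.49]]  # from D
    )

    def within(K: int) -> np.ndarray:
        # self-transition-heavy rows with geometric decay over neighbours
        P = np.empty((K, K))
        for j in range(K):
            w = 0.6 ** np.abs(np.arange(K) - j)
            P[j] = w / w.sum()
        return P

    probs = {"space": space, "O": within(6), "D": within(4), "T": within(4)}
    return truth_from_probs(
        probs, sigma_artist=sigma_artist, sigma_caste=sigma_caste,
        sigma_neigh=sigma_neigh, beta_practice=beta_practice,
        beta_nativity=beta_nativity, p_native=p_native,
    )


@dataclass(frozen=True)
class SimConfig:
    """Corpus-shape settings; defaults emulate the field study."""

    n_artists: int = 192
    n_castes: int = 19
    n_neighborhoods: int = 8
    drawings_per_artist: int = 16
    loops_per_drawing: int = 1
    mean_loop_length: float = 8.0
    p_native: float | None = None  # None: take from GroundTruth
    decorative_rate: float = 0.2  # Poisson mean per drawing
    practice_mean: float = 15.0
    practice_sd: float = 5.0
    age_mean: float = 32.0
    age_sd: float = 10.0
    center_lat: float = 10.2381
    center_lon: float = 77.4892
    neighborhood_spacing_m: float = 1000.0
    jitter_m: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_artists, self.n_castes, self.n_neighborhoods,
               self.drawings_per_artist, self.loops_per_drawing) < 1:
            raise ValueError("all counts must be >= 1")
        if self.mean_loop_length < 1:
            raise ValueError("mean loop length must be >= 1")


@dataclass
class SimTruth:
    """Everything needed to score a recovery experiment."""

    truth: GroundTruth
    config: SimConfig
    z_practice: np.ndarray
    native: np.ndarray
    caste_index: np.ndarray  # 0-based
    neighborhood_index: np.ndarray  # 0-based
    artist_row_probs: dict  # matrix key -> (N, R, K)
    artist_offsets: dict = field(default_factory=dict)


def _artist_logits(
    truth: GroundTruth,
    rng: np.random.Generator,
    z: np.ndarray,
    native: np.ndarray,
    caste_idx: np.ndarray,
    nbhd_idx: np.ndarray,
    n_castes: int,
    n_neigh: int,
) -> tuple[dict, dict]:
    N = z.size
    probs = {}
    offsets = {}
    for key in truth.logits:
        base = truth.logits[key]
        R, K = base.shape
        finite = np.isfinite(base)
        lg = np.broadcast_to(base, (N, R, K)).copy()
        off = {}
        # group offsets (zero at each row's reference cell)
        refmask = np.zeros((R, K), dtype=bool)
        for r in range(R):
            refmask[r, np.flatnonzero(finite[r])[-1]] = True
        freemask = finite & ~refmask
        for term, n_groups, idx in (
            ("artist", N, np.arange(N)),
            ("caste", n_castes, caste_idx),
            ("neighborhood", n_neigh, nbhd_idx),
        ):
            sig = np.asarray(truth.sigma[term][key], dtype=float)  # (R,)
            raw = rng.standard_normal((n_groups, R, K)) * freemask
            off[term] = raw * sig[None, :, None]
            lg += off[term][idx]
        lg += z[:, None, None] * truth.beta["practice"][key][None]
        lg += native[:, None, None] * truth.beta["nativity"][key][None]
        off["practice"] = truth.beta["practice"][key]
        off["nativity"] = truth.beta["nativity"][key]
        m = np.max(lg, axis=2, keepdims=True)
        e = np.exp(lg - m)
        probs[key] = e / e.sum(axis=2, keepdims=True)
        offsets[key] = off
    return probs, offsets


def _sample_loop_states(
    rng: np.random.Generator,
    length: int,
    space_P: np.ndarray,
    within_P: dict,
    within_pi: dict,
    start_state: int | None = None,
) -> list[int]:
    states_in = {sp: Lexicon.states_in_space(sp) for sp in SPACES}
    if start_state is None:
        space_pi = _stationary(space_P)
        s = SPACES[rng.choice(3, p=space_pi)]
        g_local = rng.choice(len(within_pi[s]), p=within_pi[s])
    else:
        s = Lexicon.state_space(start_state)
        g_local = states_in[s].index(start_state)
    seq = [states_in[s][g_local]]
    for _ in range(length - 1):
        s_next = SPACES[rng.choice(3, p=space_P[_SPACE_IDX[s]])]
        if s_next == s:
            g_local = rng.choice(
                len(within_pi[s]), p=within_P[s][g_local]
            )
        else:
            g_local = rng.choice(len(within_pi[s_next]), p=within_pi[s_next])
            s = s_next
        seq.append(states_in[s][g_local])
    return seq


def simulate_dataset(
    truth: GroundTruth | None = None,
    config: SimConfig | None = None,
) -> tuple[Dataset, SimTruth]:
    """Generate a grammar-valid corpus; fully reproducible from the seed."""
    truth = truth or default_truth()
    config = config or SimConfig()
    if config.p_native is not None:
        truth = replace(truth, p_native=config.p_native)
    rng = np.random.default_rng(config.seed)
    lex = load_lexicon()
    N = config.n_artists
    width = max(3, len(str(N)))
    ids = [f"a{i+1:0{width}d}" for i in range(N)]

    caste_idx = np.concatenate([
        np.arange(min(N, config.n_castes)),
        rng.integers(0, config.n_castes, size=max(0, N - config.n_castes)),
    ])[:N]
    nbhd_idx = np.concatenate([
        np.arange(min(N, config.n_neighborhoods)),
        rng.integers(0, config.n_neighborhoods,
                     size=max(0, N - config.n_neighborhoods)),
    ])[:N]
    rng.shuffle(caste_idx)
    rng.shuffle(nbhd_idx)
    native = rng.binomial(1, truth.p_native, size=N)
    practice = rng.normal(config.practice_mean, config.practice_sd, size=N)
    while (practice < 0).any():
        bad = practice < 0
        practice[bad] = rng.normal(config.practice_mean, config.practice_sd,
                                   size=int(bad.sum()))
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=N), 15, 60)
    # the generative covariate is the realised standardised practice, so a
    # refit standardising the same years recovers exactly this z
    z = (practice - practice.mean()) / practice.std(ddof=1) if N > 1 else np.zeros(N)

    # neighborhood centers on a grid, artists jittered within <= jitter_m
    m_per_deg = 2 * np.pi * EARTH_RADIUS_M / 360.0
    side = int(np.ceil(np.sqrt(config.n_neighborhoods)))
    lat = np.empty(N)
    lon = np.empty(N)
    for i in range(N):
        k = nbhd_idx[i]
        gy, gx = divmod(int(k), side)
        r_j = config.jitter_m * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        dy = gy * config.neighborhood_spacing_m + r_j * np.sin(th)
        dx = gx * config.neighborhood_spacing_m + r_j * np.cos(th)
        lat[i] = config.center_lat + dy / m_per_deg
        lon[i] = config.center_lon + dx / (
            m_per_deg * np.cos(np.radians(config.center_lat))
        )

    row_probs, offsets = _artist_logits(
        truth, rng, z, native, caste_idx, nbhd_idx,
        config.n_castes, config.n_neighborhoods,
    )

    # raw codes per state (both chiral variants, chosen at random)
    codes_of_state: dict[int, list[str]] = {}
    for g in lex.entries:
        if not g.is_decorative:
            codes_of_state.setdefault(g.model_state, []).append(g.raw_code)
    deco_codes = list(lex.decorative_codes)

    artists = [
        ArtistRecord(
            artist_id=ids[i], age=float(age[i]),
            practice_years=float(practice[i]), native=int(native[i]),
            caste_id=int(caste_idx[i]) + 1,
            latitude=float(lat[i]), longitude=float(lon[i]),
        )
        for i in range(N)
    ]
    drawings = []
    p_len = min(1.0, 1.0 / config.mean_loop_length)
    for i in range(N):
        within_P = {s: row_probs[s][i] for s in SPACES}
        within_pi = {s: _stationary(within_P[s]) for s in SPACES}
        space_P = row_probs["space"][i]
        for dnum in range(config.drawings_per_artist):
            did = f"{ids[i]}_d{dnum+1:03d}"
            loops = []
            for _ in range(config.loops_per_drawing):
                L = int(rng.geometric(p_len))
                states = _sample_loop_states(
                    rng, L, space_P, within_P, within_pi
                )
                # a closed loop must be grammar-valid around the wrap pair
                # (last, first); if the sampled endpoint conflicts, extend
                # with further Markov steps until it does not.  Extension
                # steps are ordinary draws from the transition law, so the
                # conditional transition frequencies stay unbiased.
                while validate_state_sequence(states, wrap=True):
                    states = states + _sample_loop_states(
                        rng, 2, space_P, within_P, within_pi,
                        start_state=states[-1],
                    )[1:]
                loops.append(Loop(artist_id=ids[i], drawing_id=did,
                                  states=tuple(states)))
            deco = Counter()
            for _ in range(rng.poisson(config.decorative_rate)):
                deco[deco_codes[rng.integers(len(deco_codes))]] += 1
            drawings.append(Drawing(drawing_id=did, artist_id=ids[i],
                                    loops=loops, decorative_counts=deco))
    dataset = Dataset(lexicon=lex, artists=artists, drawings=drawings,
                      n_castes=config.n_castes)
    sim_truth = SimTruth(
        truth=truth, config=config, z_practice=z, native=native,
        caste_index=caste_idx.astype(int),
        neighborhood_index=nbhd_idx.astype(int),
        artist_row_probs=row_probs, artist_offsets=offsets,
    )
    return dataset, sim_truth


def recovery_experiment(
    truth: GroundTruth,
    config: SimConfig,
    spec=None,
    n_replicates: int = 10,
    seed: int = 0,
    matrices: tuple[str, ...] = ("space",),
    chains: int = 2,
    draws: int = 300,
    warmup: int = 300,
    target_accept: float = 0.8,
    max_depth: int = 7,
    rhat_threshold: float = 1.1,
    max_divergences: int = 50,
    wrap: bool = False,
) -> pd.DataFrame:
    """Simulate-fit-score replicates; reports recovery of group sds and
    the ICC term ordering.

    Each replicate simulates a corpus from ``truth``, fits the model to
    the listed matrices, and records the posterior mean and 90% interval
    of each group sd (averaged over matrix rows), interval coverage of
    the true value, and whether the estimated ICC ranks the individual
    term above caste.  Non-convergent replicates are flagged and
    excluded from fitting-based columns but still counted.  Counting is
    wrap-free by default: the generator emits linear sequences, and the
    cyclic-closure transition would otherwise attenuate the estimated
    group sds (the documented purpose of the no-cycle counting mode).
    """
    from .model import (
        MODEL_VARIANTS,
        ConvergenceError,
        KolamTransitionModel,
    )

    if spec is None:
        # the default generator truth forbids direct O<->D space moves, so
        # the nested model carries the matching structural zeros
        spec = replace(MODEL_VARIANTS["full"], structural_zeros=True)
    spec = replace(spec, matrices=tuple(matrices), name=spec.name)
    rows = []
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_replicates)]
    for rep, rseed in enumerate(rep_seeds):
        cfg = replace(config, seed=rseed)
        dataset, sim_truth = simulate_dataset(truth, cfg)
        row: dict = {"replicate": rep, "seed": rseed, "converged": True}
        try:
            model = KolamTransitionModel.from_dataset(dataset, spec=spec,
                                                      wrap=wrap)
            res = model.fit(chains=chains, draws=draws, warmup=warmup,
                            seed=rseed, check=True,
                            target_accept=target_accept, max_depth=max_depth,
                            rhat_threshold=rhat_threshold,
                            max_divergences=max_divergences)
        except ConvergenceError as exc:
            row["converged"] = False
            row["error"] = str(exc)
            rows.append(row)
            continue
        term_draws = {}
        for term in ("artist", "caste", "neighborhood"):
            if not spec.has(term):
                continue
            sig = np.concatenate(
                [res.sigma(k, term).reshape(res.draws[k].shape[0],
                                            res.draws[k].shape[1], -1)
                 for k in matrices], axis=-1,
            )
            mean_sig = sig.mean(axis=-1)  # row-average, per draw
            term_draws[term] = mean_sig
            from .results import _hdi
            lo, hi = _hdi(mean_sig, 0.9)
            true_val = float(np.mean([np.mean(truth.sigma[term][k])
                                      for k in matrices]))
            row[f"sigma_{term}_mean"] = float(mean_sig.mean())
            row[f"sigma_{term}_true"] = true_val
            row[f"sigma_{term}_bias"] = float(mean_sig.mean()) - true_val
            row[f"sigma_{term}_lo"] = float(lo)
            row[f"sigma_{term}_hi"] = float(hi)
            row[f"sigma_{term}_covered"] = bool(lo <= true_val <= hi)
        if {"artist", "caste"} <= set(term_draws):
            row["p_sigma_artist_gt_caste"] = float(
                (term_draws["artist"] > term_draws["caste"]).mean()
            )
        icc = res.icc()
        for col in icc.columns:
            row[f"icc_{col}"] = float(icc[col].mean())
        if {"individual", "caste"} <= set(icc.columns):
            row["icc_individual_gt_caste"] = bool(
                (icc["individual"] > icc["caste"]).all()
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(report: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a recovery report: per-term bias, RMSE and interval
    coverage across converged replicates."""
    rows = []
    for term in ("artist", "caste", "neighborhood"):
        col = f"sigma_{term}_mean"
        if col not in report.columns:
            continue
        ok = report.dropna(subset=[col])
        err = ok[col] - ok[f"sigma_{term}_true"]
        rows.append({
            "term": term,
            "n_converged": len(ok),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "coverage_90": float((ok[f"sigma_{term}_covered"] == True).mean()),
        })
    return pd.DataFrame(rows)
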