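"""Per-artist cyclic transition counts and their space factorisation.

Each artist's loops are reduced to an aggregated 14x14 transition count
matrix (rows = current gesture state, columns = next state).  Because a
loop is closed and its true starting gesture is unknown, the transition
from the last gesture back to the first is counted as well, so a loop of
length L contributes exactly L transitions.

The aggregate is then factored, matching the model's decomposition
P(o2|o1) = P(O|O) * P(o2|o1, O|O), into a 3x3 between-space matrix S
(space order O, T, D) and three within-space matrices: 6x6 orthogonal,
4x4 diagonal, 4x4 transitional.  Cross-space transitions contribute only
to S; the within matrices are the same-space diagonal blocks.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import Dataset, Loop
from .lexicon import N_STATES, SPACES, Lexicon

#: Matrix keys, fixed order: between-space then within-space.
MATRICES = ("space", "O", "D", "T")

#: Row/column labels per matrix.
MATRIX_LABELS = {
    "space": list(SPACES),
    "O": [f"o{i+1}" for i in range(6)],
    "D": [f"d{i+1}" for i in range(4)],
    "T": [f"t{i+1}" for i in range(4)],
}

_SPACE_INDEX = {s: i for i, s in enumerate(SPACES)}


@dataclass(frozen=True)
class AggregateCounts:
    """14x14 transition counts for one artist."""

    artist_id: str
    matrix: np.ndarray  # (14, 14) non-negative ints

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (N_STATES, N_STATES) or (m < 0).any():
            raise ValueError("aggregate counts must be a non-negative 14x14 matrix")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class FactoredCounts:
    """Between-space (3x3, order O,T,D) and within-space count matrices."""

    artist_id: str
    S: np.ndarray  # (3, 3)
    W_O: np.ndarray  # (6, 6)
    W_D: np.ndarray  # (4, 4)
    W_T: np.ndarray  # (4, 4)

    def within(self, space: str) -> np.ndarray:
        return {"O": self.W_O, "D": self.W_D, "T": self.W_T}[space]

    def matrix(self, key: str) -> np.ndarray:
        """Counts for one of the four model matrices ('space', 'O', 'D', 'T')."""
        return self.S if key == "space" else self.within(key)

    @property
    def total(self) -> int:
        return int(self.S.sum())

    def validate(self) -> None:
        for s in SPACES:
            i = _SPACE_INDEX[s]
            if self.S[i, i] != self.within(s).sum():
                raise ValueError(
                    f"artist {self.artist_id}: S[{s},{s}] != sum(W_{s})"
                )


def loop_transition_pairs(loop: Loop, wrap: bool = True) -> Counter:
    """Multiset of ordered (from_state, to_state) pairs for one loop.

    With ``wrap`` (the default) the closing (last, first) pair is
    included, so the result has exactly ``len(loop)`` pairs; without it,
    ``len(loop) - 1`` consecutive pairs (used for validation studies on
    linearly generated sequences).
    """
    states = loop.states
    pairs = Counter(zip(states, states[1:]))
    if wrap:
        pairs[(states[-1], states[0])] += 1
    return pairs


def aggregate_counts(
    dataset: Dataset, artist_id: str, wrap: bool = True
) -> AggregateCounts:
    """Sum transition pairs over all of one artist's loops."""
    if artist_id not in set(dataset.artist_ids):
        raise KeyError(f"unknown artist_id {artist_id!r}")
    m = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    loops = dataset.loops_of(artist_id)
    if not loops:
        warnings.warn(f"artist {artist_id} has no loops", stacklevel=2)
    for lp in loops:
        for (a, b), c in loop_transition_pairs(lp, wrap=wrap).items():
            m[a, b] += c
    return AggregateCounts(artist_id=artist_id, matrix=m)


def factor_counts(agg: AggregateCounts) -> FactoredCounts:
    """Factor a 14x14 aggregate into between- and within-space matrices."""
    blocks = {s: Lexicon.states_in_space(s) for s in SPACES}
    S = np.zeros((3, 3), dtype=np.int64)
    for a in SPACES:
        for b in SPACES:
            S[_SPACE_INDEX[a], _SPACE_INDEX[b]] = agg.matrix[
                np.ix_(blocks[a], blocks[b])
            ].sum()
    W = {s: agg.matrix[np.ix_(blocks[s], blocks[s])].copy() for s in SPACES}
    fc = FactoredCounts(
        artist_id=agg.artist_id, S=S, W_O=W["O"], W_D=W["D"], W_T=W["T"]
    )
    fc.validate()
    return fc


def dataset_counts(
    dataset: Dataset, wrap: bool = True
) -> dict[str, FactoredCounts]:
    """Factored counts for every artist, keyed by artist_id."""
    return {
        aid: factor_counts(aggregate_counts(dataset, aid, wrap=wrap))
        for aid in dataset.artist_ids
    }


def counts_to_frame(counts: dict[str, FactoredCounts]) -> pd.DataFrame:
    """Long-form export: artist_id, matrix, from_state, to_state, count."""
    rows = []
    for aid, fc in counts.items():
        for key in MATRICES:
            labels = MATRIX_LABELS[key]
            m = fc.matrix(key)
            for i, fr in enumerate(labels):
                for j, to in enumerate(labels):
                    rows.append((aid, key, fr, to, int(m[i, j])))
    return pd.DataFrame(
        rows, columns=["artist_id", "matrix", "from_state", "to_state", "count"]
    )


def write_counts(counts: dict[str, FactoredCounts], path: str | Path) -> None:
    counts_to_frame(counts).to_csv(path, index=False)
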