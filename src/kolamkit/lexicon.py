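"""Gesture lexicon: the state space of the kolam Markov chain.

A kolam loop is transcribed as a sequence of gestures.  Each gesture
belongs to one of three geometric spaces — orthogonal (O), diagonal (D)
or transitional (T) — or is a purely decorative single gesture (X) that
is never part of a loop.  Mirror-image (left/right) gesture variants are
distinct raw codes but collapse onto a single model state, giving the
14-state chain (6 O + 4 D + 4 T) used throughout the analysis.

The grammar of the art form constrains adjacency: orthogonal and
diagonal gestures are disjoint and can only be connected through
transitional gestures, so O and D states never neighbour each other in a
valid loop (including the wrap-around pair of a closed loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Geometric spaces of loop gestures, in the fixed display order used for
#: the between-space transition matrix.
SPACES = ("O", "T", "D")

#: Decorative (non-loop) space code.
DECORATIVE = "X"

#: Number of model states per space.
SPACE_SIZES = {"O": 6, "D": 4, "T": 4}

#: Total number of model states.
N_STATES = 14

#: Number of entries the lexicon must contain.
N_GESTURES = 29

#: Number of decorative entries.
N_DECORATIVE = 3

# Model-state layout: states 0-5 orthogonal, 6-9 diagonal, 10-13 transitional.
_STATE_SPACE = ["O"] * 6 + ["D"] * 4 + ["T"] * 4
_STATE_NAME = [f"o{i+1}" for i in range(6)] + [f"d{i+1}" for i in range(4)] + [
    f"t{i+1}" for i in range(4)
]


class LexiconError(ValueError):
    """Base class for lexicon validation failures."""


class DuplicateCodeError(LexiconError):
    """A raw gesture code appears more than once."""


class StateCountError(LexiconError):
    """The model states do not partition as 6 orthogonal + 4 diagonal +
    4 transitional (plus 3 decorative entries)."""


class MappingError(LexiconError):
    """The raw-code -> model-state mapping is not total/consistent."""


@dataclass(frozen=True)
class Gesture:
    """One lexicon entry.

    ``model_state`` is ``None`` exactly for decorative gestures; all loop
    gestures map to one of the 14 chain states.
    """

    raw_code: str
    space: str
    chirality: str
    model_state: int | None

    def __post_init__(self) -> None:
        if self.space not in SPACES + (DECORATIVE,):
            raise LexiconError(f"unknown space {self.space!r} for {self.raw_code!r}")
        if self.chirality not in ("left", "right", "none"):
            raise LexiconError(
                f"unknown chirality {self.chirality!r} for {self.raw_code!r}"
            )
        if (self.space == DECORATIVE) != (self.model_state is None):
            raise MappingError(
                f"gesture {self.raw_code!r}: decorative entries must have no "
                f"model state and loop entries must have one"
            )

    @property
    def is_decorative(self) -> bool:
        return self.space == DECORATIVE


@dataclass(frozen=True)
class Lexicon:
    """The full 29-gesture lexicon and its mapping onto 14 model states."""

    entries: tuple[Gesture, ...]
    _by_code: dict[str, Gesture] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        codes = [g.raw_code for g in self.entries]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise DuplicateCodeError(f"duplicate raw codes: {sorted(dupes)}")
        object.__setattr__(self, "_by_code", {g.raw_code: g for g in self.entries})

        if len(self.entries) != N_GESTURES:
            raise StateCountError(
                f"lexicon must contain {N_GESTURES} gestures, got {len(self.entries)}"
            )
        deco = [g for g in self.entries if g.is_decorative]
        if len(deco) != N_DECORATIVE:
            raise StateCountError(
                f"lexicon must contain {N_DECORATIVE} decorative gestures, "
                f"got {len(deco)}"
            )
        # mapping must be total and surjective onto 0..13, with consistent spaces
        states = sorted({g.model_state for g in self.entries if not g.is_decorative})
        if states != list(range(N_STATES)):
            raise MappingError(
                f"model states must cover 0..{N_STATES - 1} exactly, got {states}"
            )
        for g in self.entries:
            if g.is_decorative:
                continue
            if _STATE_SPACE[g.model_state] != g.space:
                raise StateCountError(
                    f"gesture {g.raw_code!r} declared space {g.space} but state "
                    f"{g.model_state} belongs to {_STATE_SPACE[g.model_state]}; "
                    f"states must partition as 6 O + 4 D + 4 T"
                )

    # -- lookups ------------------------------------------------------

    def __contains__(self, raw_code: str) -> bool:
        return raw_code in self._by_code

    def __getitem__(self, raw_code: str) -> Gesture:
        return self._by_code[raw_code]

    @property
    def decorative_codes(self) -> tuple[str, ...]:
        return tuple(g.raw_code for g in self.entries if g.is_decorative)

    @staticmethod
    def state_space(state: int) -> str:
        """Geometric space (O/D/T) of a model state."""
        return _STATE_SPACE[state]

    @staticmethod
    def state_name(state: int) -> str:
        """Canonical name (o1..o6, d1..d4, t1..t4) of a model state."""
        return _STATE_NAME[state]

    @staticmethod
    def states_in_space(space: str) -> list[int]:
        return [s for s in range(N_STATES) if _STATE_SPACE[s] == space]

    @property
    def state_table(self) -> dict[int, tuple[str, str]]:
        """model_state -> (space, canonical name)."""
        return {s: (_STATE_SPACE[s], _STATE_NAME[s]) for s in range(N_STATES)}


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Read a lexicon CSV (columns raw_code,space,chirality,model_state).

    With ``path=None`` the packaged default lexicon is loaded: 12 chiral
    pairs plus two achiral loop gestures (29 rows with the 3 decorative
    entries), collapsing onto canonical states o1–o6, d1–d4, t1–t4.  A
    user-supplied file with the same columns substitutes an alternative
    raw-code spelling or state mapping.
    """
    if path is None:
        with resources.as_file(
            resources.files("kolamkit.data").joinpath("lexicon.csv")
        ) as p:
            df = pd.read_csv(p, dtype={"raw_code": str})
    else:
        df = pd.read_csv(path, dtype={"raw_code": str})
    required = {"raw_code", "space", "chirality", "model_state"}
    missing = required - set(df.columns)
    if missing:
        raise LexiconError(f"lexicon file missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        state = row.model_state
        state = None if pd.isna(state) else int(state)
        entries.append(
            Gesture(
                raw_code=str(row.raw_code).strip(),
                space=str(row.space).strip(),
                chirality=str(row.chirality).strip(),
                model_state=state,
            )
        )
    return Lexicon(entries=tuple(entries))


def grammar_ok(prev_state: int, next_state: int) -> bool:
    """May ``next_state`` follow ``prev_state`` in a valid loop?

    Orthogonal and diagonal gestures never neighbour directly; every
    other adjacency is allowed.
    """
    a, b = _STATE_SPACE[prev_state], _STATE_SPACE[next_state]
    return not ({a, b} == {"O", "D"})


def validate_state_sequence(states: Iterable[int], wrap: bool = True) -> list[tuple[int, int]]:
    """Return the list of grammar-violating adjacent pairs (empty if valid).

    With ``wrap`` the closing (last, first) pair of the loop is checked too.
    """
    states = list(states)
    pairs = list(zip(states, states[1:]))
    if wrap and states:
        pairs.append((states[-1], states[0]))
    return [(a, b) for a, b in pairs if not grammar_ok(a, b)]
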