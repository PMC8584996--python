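"""Corpus data model and file I/O.

File dialects (all UTF-8 plain text):

* sequences: TSV, one loop per line —
  ``artist_id<TAB>drawing_id<TAB>loop_index<TAB>code code code ...``
  where the gesture codes are whitespace-separated raw lexicon codes
  (decorative codes may be interleaved; they are tallied per drawing and
  excluded from the loop's state sequence).
* survey: CSV with header ``artist_id,age,practice_years,native,caste_id``
  (native: 0 = native, 1 = non-native).
* gps: CSV with header ``artist_id,lat,lon`` (decimal degrees).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lexicon import Lexicon, validate_state_sequence

logger = logging.getLogger(__name__)


class EncodingError(ValueError):
    """A raw token could not be encoded against the lexicon."""


class GrammarError(ValueError):
    """A state sequence places orthogonal next to diagonal gestures."""


class DatasetError(ValueError):
    """Cross-file consistency failure while assembling a Dataset."""


@dataclass(frozen=True)
class Loop:
    """A closed gesture sequence, stored as model states."""

    artist_id: str
    drawing_id: str
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("a loop needs at least one gesture")
        bad = validate_state_sequence(self.states, wrap=True)
        if bad:
            raise GrammarError(
                f"loop {self.artist_id}/{self.drawing_id}: orthogonal-diagonal "
                f"adjacency at state pairs {bad}"
            )

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class Drawing:
    """A kolam drawing: one or more loops plus decorative-gesture tallies."""

    drawing_id: str
    artist_id: str
    loops: list[Loop] = field(default_factory=list)
    decorative_counts: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        if not self.loops and not self.decorative_counts:
            raise DatasetError(
                f"drawing {self.drawing_id}: needs at least one loop or "
                f"decorative gesture"
            )
        for lp in self.loops:
            if lp.artist_id != self.artist_id:
                raise DatasetError(
                    f"drawing {self.drawing_id}: loop artist {lp.artist_id} "
                    f"!= drawing artist {self.artist_id}"
                )


@dataclass(frozen=True)
class ArtistRecord:
    """Survey covariates and household location for one artist."""

    artist_id: str
    age: float
    practice_years: float
    native: int  # 0 = native, 1 = non-native
    caste_id: int
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if self.practice_years < 0:
            raise DatasetError(
                f"artist {self.artist_id}: negative practice_years"
            )
        if self.native not in (0, 1):
            raise DatasetError(f"artist {self.artist_id}: native must be 0/1")
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise DatasetError(f"artist {self.artist_id}: coordinates out of range")


@dataclass
class Dataset:
    """A full corpus: lexicon, artists, drawings."""

    lexicon: Lexicon
    artists: list[ArtistRecord]
    drawings: list[Drawing]
    n_castes: int | None = None  # declared category count (defaults to observed max)

    def __post_init__(self) -> None:
        ids = [a.artist_id for a in self.artists]
        if len(set(ids)) != len(ids):
            raise DatasetError("artist_ids are not unique")
        known = set(ids)
        for d in self.drawings:
            d.validate()
            if d.artist_id not in known:
                raise DatasetError(
                    f"drawing {d.drawing_id} references unknown artist "
                    f"{d.artist_id}"
                )
        if self.n_castes is None:
            self.n_castes = max((a.caste_id for a in self.artists), default=0)
        for a in self.artists:
            if not (1 <= a.caste_id <= self.n_castes):
                raise DatasetError(
                    f"artist {a.artist_id}: caste_id {a.caste_id} outside "
                    f"1..{self.n_castes}"
                )

    @property
    def artist_ids(self) -> list[str]:
        return [a.artist_id for a in self.artists]

    def loops_of(self, artist_id: str) -> list[Loop]:
        return [lp for d in self.drawings if d.artist_id == artist_id for lp in d.loops]

    @property
    def n_loops(self) -> int:
        return sum(len(d.loops) for d in self.drawings)

    def summary(self) -> str:
        return (
            f"{len(self.artists)} artists, {len(self.drawings)} drawings, "
            f"{self.n_loops} loops"
        )


def encode_loop(
    tokens: list[str],
    lexicon: Lexicon,
    artist_id: str = "",
    drawing_id: str = "",
    permissive: bool = False,
) -> tuple[Loop | None, Counter]:
    """Encode raw gesture tokens into a Loop plus decorative tallies.

    Decorative tokens are removed from the state sequence and returned as
    a Counter for Drawing bookkeeping (they are not part of any loop).
    The O/D adjacency grammar, including the wrap-around pair, is a hard
    error unless ``permissive`` is set, in which case a warning is issued
    and the loop is returned unvalidated (states stored as given).

    Returns (loop, decorative_counts); loop is None when all tokens were
    decorative.
    """
    if not tokens:
        raise EncodingError("empty token sequence")
    states: list[int] = []
    deco: Counter = Counter()
    for pos, tok in enumerate(tokens):
        if tok not in lexicon:
            raise EncodingError(f"unknown gesture code {tok!r} at position {pos}")
        g = lexicon[tok]
        if g.is_decorative:
            deco[tok] += 1
        else:
            states.append(g.model_state)
    if not states:
        return None, deco
    bad = validate_state_sequence(states, wrap=True)
    if bad and permissive:
        warnings.warn(
            f"grammar violations retained in permissive mode: {bad}",
            stacklevel=2,
        )
        loop = object.__new__(Loop)
        object.__setattr__(loop, "artist_id", artist_id)
        object.__setattr__(loop, "drawing_id", drawing_id)
        object.__setattr__(loop, "states", tuple(states))
        return loop, deco
    return Loop(artist_id=artist_id, drawing_id=drawing_id, states=tuple(states)), deco


def _read_sequences(
    path: str | Path, lexicon: Lexicon, permissive: bool
) -> list[Drawing]:
    drawings: dict[tuple[str, str], Drawing] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DatasetError(
                    f"{path}:{lineno}: expected artist_id, drawing_id, "
                    f"loop_index, gesture codes"
                )
            artist_id, drawing_id, _loop_index, codes = (
                parts[0],
                parts[1],
                parts[2],
                "\t".join(parts[3:]),
            )
            tokens = codes.split()
            loop, deco = encode_loop(
                tokens, lexicon, artist_id=artist_id, drawing_id=drawing_id,
                permissive=permissive,
            )
            key = (artist_id, drawing_id)
            if key not in drawings:
                drawings[key] = Drawing(drawing_id=drawing_id, artist_id=artist_id)
            if loop is not None:
                drawings[key].loops.append(loop)
            drawings[key].decorative_counts.update(deco)
    return list(drawings.values())


def _read_survey(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"artist_id": str})
    required = {"artist_id", "age", "practice_years", "native", "caste_id"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetError(f"survey file missing columns: {sorted(missing)}")
    for col in ("age", "practice_years", "native", "caste_id"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "artist_id"].tolist()
            raise DatasetError(f"survey: missing {col} for artists {bad}")
    return df


def read_dataset(
    sequences_path: str | Path,
    survey_path: str | Path,
    gps_path: str | Path,
    lexicon: Lexicon | None = None,
    n_castes: int | None = None,
    permissive: bool = False,
) -> Dataset:
    """Assemble a Dataset from the three standard input files."""
    from .lexicon import load_lexicon

    if lexicon is None:
        lexicon = load_lexicon()
    survey = _read_survey(survey_path)
    gps = pd.read_csv(gps_path, dtype={"artist_id": str})
    missing = {"artist_id", "lat", "lon"} - set(gps.columns)
    if missing:
        raise DatasetError(f"gps file missing columns: {sorted(missing)}")
    gps = gps.set_index("artist_id")

    artists = []
    for row in survey.itertuples(index=False):
        if row.artist_id not in gps.index:
            raise DatasetError(f"artist {row.artist_id}: no GPS coordinates")
        loc = gps.loc[row.artist_id]
        artists.append(
            ArtistRecord(
                artist_id=row.artist_id,
                age=float(row.age),
                practice_years=float(row.practice_years),
                native=int(row.native),
                caste_id=int(row.caste_id),
                latitude=float(loc["lat"]),
                longitude=float(loc["lon"]),
            )
        )
    drawings = _read_sequences(sequences_path, lexicon, permissive=permissive)
    if not drawings:
        warnings.warn(f"no drawings found in {sequences_path}", stacklevel=2)
    ds = Dataset(lexicon=lexicon, artists=artists, drawings=drawings,
                 n_castes=n_castes)
    logger.info("read dataset: %s", ds.summary())
    return ds


def write_dataset(
    dataset: Dataset,
    sequences_path: str | Path,
    survey_path: str | Path,
    gps_path: str | Path,
) -> None:
    """Write a Dataset back to the three canonical files.

    State sequences are written using the canonical (lexicographically
    first) raw code of each model state, decorative tallies as trailing
    tokens of a drawing's first loop line would be ambiguous, so each
    decorative gesture is written as its own pseudo-loop line with
    loop_index ``deco``.  ``read_dataset`` of the output reproduces the
    same loops, covariates and decorative counts.
    """
    lex = dataset.lexicon
    canonical: dict[int, str] = {}
    for g in sorted(lex.entries, key=lambda g: g.raw_code):
        if not g.is_decorative and g.model_state not in canonical:
            canonical[g.model_state] = g.raw_code

    with open(sequences_path, "w", encoding="utf-8") as fh:
        for d in dataset.drawings:
            for i, lp in enumerate(d.loops):
                codes = " ".join(canonical[s] for s in lp.states)
                fh.write(f"{d.artist_id}\t{d.drawing_id}\t{i}\t{codes}\n")
            if d.decorative_counts:
                codes = " ".join(
                    tok
                    for tok in sorted(d.decorative_counts)
                    for _ in range(d.decorative_counts[tok])
                )
                fh.write(f"{d.artist_id}\t{d.drawing_id}\tdeco\t{codes}\n")

    pd.DataFrame(
        {
            "artist_id": [a.artist_id for a in dataset.artists],
            "age": [a.age for a in dataset.artists],
            "practice_years": [a.practice_years for a in dataset.artists],
            "native": [a.native for a in dataset.artists],
            "caste_id": [a.caste_id for a in dataset.artists],
        }
    ).to_csv(survey_path, index=False)
    pd.DataFrame(
        {
            "artist_id": [a.artist_id for a in dataset.artists],
            "lat": [a.latitude for a in dataset.artists],
            "lon": [a.longitude for a in dataset.artists],
        }
    ).to_csv(gps_path, index=False)
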