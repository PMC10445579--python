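"""Rating-table data model and delimited-text I/O.

The study design is a fully crossed rating experiment: every observer
scores every cranium on three morphoscopic traits (mastoid process,
supra-orbital margin, glabella) using the standard ordinal 1-5
robusticity scale. :class:`ScoreTable` holds that grid with explicit
missing cells, so downstream statistics can choose their own
missing-data policy (listwise deletion for agreement, counting-against
for accuracy) instead of the parser deciding for them.

File formats are plain comma-delimited UTF-8:

* rating table — header ``observer,cranium,trait,score``; one row per
  cell; an empty score field marks a missing cell;
* recorded-sex table — header ``cranium,sex`` with sex ``male``/``female``.
"""

from __future__ import annotations

import csv
import enum
import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import _study_tables
from .errors import ScoreParseError, TableLookupError

__all__ = [
    "Trait",
    "Sex",
    "ScoreTable",
    "RecordedSexTable",
    "builtin_study_tables",
    "read_scores",
    "write_scores",
    "read_recorded_sex",
    "write_recorded_sex",
    "score_frequencies",
    "VALID_SCORES",
]

VALID_SCORES = frozenset({1, 2, 3, 4, 5})


class Trait(str, enum.Enum):
    """The three cranial traits scored in the study."""

    MASTOID_PROCESS = "mastoid_process"
    SUPRAORBITAL_MARGIN = "supraorbital_margin"
    GLABELLA = "glabella"

    @classmethod
    def parse(cls, text: str) -> "Trait":
        try:
            return cls(text)
        except ValueError:
            valid = ", ".join(t.value for t in cls)
            raise TableLookupError(f"unknown trait {text!r}; expected one of: {valid}")


class Sex(str, enum.Enum):
    """Recorded (ground-truth) sex of a cranium."""

    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, text: str) -> "Sex":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ScoreParseError(f"unknown sex label {text!r}; expected male or female")


def _check_score(value: int | None) -> int | None:
    if value is not None and value not in VALID_SCORES:
        raise ValueError(f"score must be in 1-5 or missing, got {value!r}")
    return value


@dataclass(frozen=True)
class ScoreTable:
    """A complete observers x crania x traits grid of ordinal scores.

    Every (observer, cranium, trait) triple has exactly one cell; a cell
    is either an int in 1-5 or ``None`` (missing). Construction fails on
    out-of-range scores or cells referencing unknown identifiers.
    """

    observers: tuple[str, ...]
    crania: tuple[int | str, ...]
    cells: Mapping[tuple[str, int | str, Trait], int | None] = field(repr=False)

    def __post_init__(self):
        if len(set(self.observers)) != len(self.observers):
            raise ValueError("duplicate observer identifiers")
        if len(set(self.crania)) != len(self.crania):
            raise ValueError("duplicate cranium identifiers")
        full = {
            (o, c, t) for o in self.observers for c in self.crania for t in Trait
        }
        cells = dict(self.cells)
        extra = set(cells) - full
        if extra:
            raise ValueError(f"cells reference unknown observer/cranium: {sorted(extra)[:3]}")
        for key in full - set(cells):
            cells[key] = None
        for value in cells.values():
            _check_score(value)
        object.__setattr__(self, "cells", cells)

    # -- accessors ---------------------------------------------------------

    def cell(self, observer: str, cranium, trait: Trait | str) -> int | None:
        trait = Trait.parse(trait) if not isinstance(trait, Trait) else trait
        if observer not in self.observers:
            raise TableLookupError(f"unknown observer {observer!r}")
        if cranium not in self.crania:
            raise TableLookupError(f"unknown cranium {cranium!r}")
        return self.cells[(observer, cranium, trait)]

    def scores_for(self, observer: str, cranium) -> dict[Trait, int | None]:
        """All three trait scores for one (observer, cranium) pair."""
        return {t: self.cell(observer, cranium, t) for t in Trait}

    def n_missing(self) -> int:
        return sum(v is None for v in self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per cell, column order of the file format."""
        rows = [
            {
                "observer": o,
                "cranium": c,
                "trait": t.value,
                "score": self.cells[(o, c, t)],
            }
            for o in self.observers
            for c in self.crania
            for t in Trait
        ]
        return pd.DataFrame(rows, columns=["observer", "cranium", "trait", "score"])


@dataclass(frozen=True)
class RecordedSexTable:
    """Ground-truth sex per cranium."""

    sexes: Mapping[int | str, Sex]

    def __post_init__(self):
        object.__setattr__(self, "sexes", dict(self.sexes))

    def __getitem__(self, cranium) -> Sex:
        try:
            return self.sexes[cranium]
        except KeyError:
            raise TableLookupError(f"cranium {cranium!r} has no recorded sex")

    def __contains__(self, cranium) -> bool:
        return cranium in self.sexes

    def crania_of(self, sex: Sex) -> list:
        return [c for c, s in self.sexes.items() if s is sex]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, s.value) for c, s in self.sexes.items()], columns=["cranium", "sex"]
        )


def builtin_study_tables() -> tuple[ScoreTable, ScoreTable, RecordedSexTable]:
    """The study's raw data: direct-observer grid, video-observer grid, recorded sexes.

    Twenty crania scored by observers O1-O4 on their own 3D models and by
    video observers V1-V4 on screen recordings of O1's models. The
    direct-observer grid contains the study's two missing cells (O3,
    cranium 4: mastoid process and supra-orbital margin unscored).
    """
    observer = _grid_to_table(_study_tables.OBSERVER_SCORES, _study_tables.OBSERVER_IDS)
    video = _grid_to_table(_study_tables.VIDEO_SCORES, _study_tables.VIDEO_OBSERVER_IDS)
    recorded = RecordedSexTable(
        {
            c: (Sex.MALE if c in _study_tables.MALE_CRANIA else Sex.FEMALE)
            for c in _study_tables.CRANIUM_IDS
        }
    )
    return observer, video, recorded


def _grid_to_table(grid, observer_ids) -> ScoreTable:
    cells = {
        (obs, cranium, Trait(trait_name)): scores[j]
        for trait_name, per_cranium in grid.items()
        for cranium, scores in per_cranium.items()
        for j, obs in enumerate(observer_ids)
    }
    return ScoreTable(tuple(observer_ids), _study_tables.CRANIUM_IDS, cells)


# -- delimited-text I/O ----------------------------------------------------


def _coerce_cranium(text: str):
    """Cranium ids are kept as integers when they look like integers."""
    text = text.strip()
    return int(text) if text.lstrip("-").isdigit() else text


def read_scores(path_or_buffer, *, delimiter: str = ",") -> ScoreTable:
    """Parse a long-format rating file into a validated :class:`ScoreTable`.

    Raises :class:`ScoreParseError` (with the offending 1-based line
    number) on a malformed row, a duplicate (observer, cranium, trait)
    triple, or a score outside 1-5. Empty score fields become missing
    cells.
    """
    if isinstance(path_or_buffer, (str, Path)):
        with open(path_or_buffer, encoding="utf-8", newline="") as handle:
            return read_scores(handle, delimiter=delimiter)

    reader = csv.reader(path_or_buffer, delimiter=delimiter)
    header = next(reader, None)
    expected = ["observer", "cranium", "trait", "score"]
    if header is None or [h.strip() for h in header] != expected:
        raise ScoreParseError(f"expected header {','.join(expected)!r}, got {header!r}", line=1)

    observers: list[str] = []
    crania: list = []
    cells: dict[tuple[str, object, Trait], int | None] = {}
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) != 4:
            raise ScoreParseError(f"expected 4 fields, got {len(row)}", line=line_no)
        observer, cranium_text, trait_text, score_text = (f.strip() for f in row)
        try:
            trait = Trait.parse(trait_text)
        except TableLookupError as exc:
            raise ScoreParseError(str(exc), line=line_no)
        cranium = _coerce_cranium(cranium_text)
        if score_text == "":
            score: int | None = None
        else:
            try:
                score = _check_score(int(score_text))
            except ValueError:
                raise ScoreParseError(
                    f"score must be an integer 1-5 or empty, got {score_text!r}",
                    line=line_no,
                )
        key = (observer, cranium, trait)
        if key in cells:
            raise ScoreParseError(
                f"duplicate cell for observer {observer!r}, cranium {cranium!r}, "
                f"trait {trait.value}",
                line=line_no,
            )
        cells[key] = score
        if observer not in observers:
            observers.append(observer)
        if cranium not in crania:
            crania.append(cranium)
    if not cells:
        raise ScoreParseError("rating file contains no data rows")
    return ScoreTable(tuple(observers), tuple(crania), cells)


def write_scores(table: ScoreTable, path_or_buffer) -> None:
    """Write a rating table in the long comma-delimited format."""
    frame = table.to_frame()
    frame["score"] = frame["score"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    frame.to_csv(path_or_buffer, index=False)


def read_recorded_sex(path_or_buffer) -> RecordedSexTable:
    """Parse a ``cranium,sex`` file."""
    if isinstance(path_or_buffer, (str, Path)):
        with open(path_or_buffer, encoding="utf-8", newline="") as handle:
            return read_recorded_sex(handle)
    reader = csv.reader(path_or_buffer)
    header = next(reader, None)
    if header is None or [h.strip() for h in header] != ["cranium", "sex"]:
        raise ScoreParseError(f"expected header 'cranium,sex', got {header!r}", line=1)
    sexes = {}
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) != 2:
            raise ScoreParseError(f"expected 2 fields, got {len(row)}", line=line_no)
        cranium = _coerce_cranium(row[0])
        if cranium in sexes:
            raise ScoreParseError(f"duplicate cranium {cranium!r}", line=line_no)
        try:
            sexes[cranium] = Sex.parse(row[1])
        except ScoreParseError as exc:
            raise ScoreParseError(str(exc), line=line_no)
    return RecordedSexTable(sexes)


def write_recorded_sex(recorded: RecordedSexTable, path_or_buffer) -> None:
    recorded.to_frame().to_csv(path_or_buffer, index=False)


def scores_to_string(table: ScoreTable) -> str:
    """The rating-file content as a string (round-trips through read_scores)."""
    buffer = io.StringIO()
    write_scores(table, buffer)
    return buffer.getvalue()


def score_frequencies(table: ScoreTable, observer: str, trait: Trait | str) -> tuple[int, ...]:
    """Counts of scores 1..5 for one observer and trait.

    Returns five non-negative integers that sum to the number of
    non-missing cells for that observer/trait. These are the counts
    behind the study's score-frequency bar charts.
    """
    trait = Trait.parse(trait) if not isinstance(trait, Trait) else trait
    if observer not in table.observers:
        raise TableLookupError(f"unknown observer {observer!r}")
    counts = [0] * 5
    for cranium in table.crania:
        value = table.cells[(observer, cranium, trait)]
        if value is not None:
            counts[value - 1] += 1
    return tuple(counts)
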