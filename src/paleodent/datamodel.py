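"""Shared domain types and tabular I/O for all proxy pipelines.

Specimens are keyed by an opaque ``specimen_id`` and optionally grouped
into individuals via ``individual_id`` (isolated teeth are their own
individual).  Localities carry a European land-mammal biozone code
(MP28–MN3, an ordered chronology); a locality straddling two zones is
represented as a :class:`BiozoneInterval`.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("paleodent")


class SchemaError(ValueError):
    """A table is missing a mandatory column or violates its schema."""


class ValidationError(ValueError):
    """A row carries a value outside the declared domain."""


# --------------------------------------------------------------------------
# Biozones
# --------------------------------------------------------------------------

@enum.unique
class Biozone(enum.IntEnum):
    """Ordered European mammal reference levels spanning the study window.

    The integer values encode chronological order (oldest first) so the
    enum sorts localities from oldest to youngest.
    """

    MP28 = 0
    MP29 = 1
    MP30 = 2
    MN1 = 3
    MN2 = 4
    MN3 = 5

    @classmethod
    def parse(cls, token: str) -> "Biozone":
        key = token.strip().upper().rstrip("AB*")
        try:
            return cls[key]
        except KeyError:
            raise ValidationError(f"unknown biozone code: {token!r}") from None


@dataclass(frozen=True)
class BiozoneInterval:
    """A (possibly degenerate) closed interval of biozones.

    Localities whose dating straddles a zone boundary (e.g. an
    'MP30 to MN1' site) are stored as a two-zone interval rather than
    forced into either zone.
    """

    start: Biozone
    end: Biozone

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"inverted biozone interval {self.start.name}-{self.end.name}")

    @property
    def is_single(self) -> bool:
        return self.start == self.end

    @classmethod
    def parse(cls, token: str) -> "BiozoneInterval":
        parts = re.split(r"\s*(?:-|–|to)\s*", str(token).strip(), maxsplit=1)
        if len(parts) == 1:
            z = Biozone.parse(parts[0])
            return cls(z, z)
        return cls(Biozone.parse(parts[0]), Biozone.parse(parts[1]))

    def __str__(self) -> str:
        if self.is_single:
            return self.start.name
        return f"{self.start.name}-{self.end.name}"


# --------------------------------------------------------------------------
# Tooth locus codes
# --------------------------------------------------------------------------

_LOCUS_RE = re.compile(r"^([icpmICPM])([1-4]?)$")

_FAMILY = {"i": "incisor", "c": "canine", "p": "premolar", "m": "molar"}


@dataclass(frozen=True)
class Locus:
    """Parsed tooth-position code: jaw (upper/lower), family, position."""

    code: str
    jaw: str        # "upper" | "lower"
    family: str     # incisor | canine | premolar | molar
    position: int | None

    @property
    def is_molar(self) -> bool:
        return self.family == "molar"

    @property
    def is_upper(self) -> bool:
        return self.jaw == "upper"


def parse_locus(code: str) -> Locus:
    """Parse a locus code such as ``m2`` (lower second molar) or ``M2``.

    Case encodes the jaw: upper-case = upper jaw, lower-case = lower jaw.
    """
    m = _LOCUS_RE.match(code.strip())
    if not m:
        raise ValidationError(f"unparseable locus code: {code!r}")
    letter, pos = m.groups()
    family = _FAMILY[letter.lower()]
    if family in ("premolar", "molar") and not pos:
        raise ValidationError(f"locus {code!r} lacks a position digit")
    position = int(pos) if pos else None
    if family == "molar" and position is not None and position > 3:
        raise ValidationError(f"molar position out of range in {code!r}")
    jaw = "upper" if letter.isupper() else "lower"
    return Locus(code=code.strip(), jaw=jaw, family=family, position=position)


# --------------------------------------------------------------------------
# Specimens
# --------------------------------------------------------------------------

UNKNOWN = "unknown"

WEAR_STAGE_MIN, WEAR_STAGE_MAX = 1, 10


@dataclass(frozen=True)
class ToothSpecimen:
    """One tooth: the join key shared by every proxy table."""

    specimen_id: str
    species: str
    locality: str
    biozone: BiozoneInterval
    locus: str | None = None
    individual_id: str | None = None
    side: str = UNKNOWN
    wear_stage: int | str = UNKNOWN

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", UNKNOWN):
            raise ValidationError(f"side must be left/right/{UNKNOWN}, got {self.side!r}")
        ws = self.wear_stage
        if ws != UNKNOWN and not (WEAR_STAGE_MIN <= int(ws) <= WEAR_STAGE_MAX):
            raise ValidationError(f"wear stage {ws!r} outside [{WEAR_STAGE_MIN}, {WEAR_STAGE_MAX}]")

    @property
    def individual(self) -> str:
        """Effective individual key: falls back to the specimen id."""
        return self.individual_id or self.specimen_id


# --------------------------------------------------------------------------
# Study tables
# --------------------------------------------------------------------------

#: mandatory columns per proxy schema
SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "measurements": (
        "specimen_id", "species", "locality", "biozone", "locus", "length_mm",
    ),
    "hypoplasia": (
        "specimen_id", "species", "locality", "biozone", "affected",
    ),
    "mesowear": (
        "specimen_id", "species", "locality", "biozone", "locus", "cusp",
        "wear_stage", "score",
    ),
    "isotopes": (
        "specimen_id", "species", "locality", "biozone", "sampling",
        "d13c_co3_pdb", "d18o_co3_pdb",
    ),
}

#: columns that, together with specimen_id, must be unique per schema
_UNIQUE_KEYS: Mapping[str, tuple[str, ...]] = {
    "measurements": ("specimen_id", "locus"),
    "hypoplasia": ("specimen_id",),
    "mesowear": ("specimen_id", "locus", "cusp"),
    "isotopes": ("specimen_id", "sampling", "serial_position_mm"),
}


@dataclass
class StudyTable:
    """A validated proxy table plus parse provenance."""

    schema: str
    frame: pd.DataFrame
    source: str = "<memory>"
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


def _detect_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_specimen_table(path: str | Path, schema: str) -> StudyTable:
    """Read and validate a CSV/TSV proxy table.

    The delimiter is auto-detected from the header line.  Mandatory
    columns missing raise :class:`SchemaError`; rows with an unknown
    biozone raise :class:`ValidationError`; duplicated key rows raise
    :class:`ValidationError` listing the offending keys.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]

    missing = [c for c in SCHEMAS[schema] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing} for schema {schema!r}")

    # biozone validation (raises on the first unknown code)
    frame["biozone"] = [str(BiozoneInterval.parse(z)) for z in frame["biozone"]]

    key_cols = [c for c in _UNIQUE_KEYS[schema] if c in frame.columns]
    dup = frame.duplicated(subset=key_cols, keep=False)
    if dup.any():
        keys = frame.loc[dup, key_cols].drop_duplicates().to_records(index=False).tolist()
        raise ValidationError(f"{path.name}: duplicate {tuple(key_cols)} rows: {keys}")

    # numeric coercion with per-row rejection reporting
    numeric_cols = [
        c for c in frame.columns
        if c.endswith("_mm") or c.startswith(("d13c", "d18o")) or c in ("score", "length_mm", "width_mm")
    ]
    rejected: list[tuple[int, str]] = []
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col].replace("", None), errors="coerce")
        bad = frame.index[coerced.isna() & (frame[col] != "")]
        for i in bad:
            rejected.append((int(i), f"non-numeric {col}={frame.at[i, col]!r}"))
        frame[col] = coerced
    if rejected:
        frame = frame.drop(index=[i for i, _ in rejected]).reset_index(drop=True)
        for i, reason in rejected:
            logger.warning("%s: rejected row %d (%s)", path.name, i, reason)

    return StudyTable(schema=schema, frame=frame, source=str(path), rejected=rejected)


#: rendering precision by column-name pattern, mirroring conventional
#: reporting granularity (isotope/climate means 1 decimal, prevalence 2,
#: body masses to the nearest 10 kg)
def _render(col: str, value: object) -> object:
    if value is None or (isinstance(value, float) and value != value):
        return ""
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        return value
    if "mass" in col and "kg" in col:
        return int(round(float(value) / 10.0) * 10)
    if "prevalence" in col or col.endswith("_pct"):
        return f"{value:.2f}"
    if any(tag in col for tag in ("d13c", "d18o", "mat_", "map_", "_permil", "_c")):
        return f"{value:.1f}"
    return value


def write_summary_table(rows: Sequence[Mapping[str, object]] | pd.DataFrame,
                        path: str | Path,
                        columns: Iterable[str] | None = None) -> None:
    """Write summary rows as CSV with stable column order and the
    package's reporting precision (see :func:`_render`)."""
    frame = pd.DataFrame(list(rows)) if not isinstance(rows, pd.DataFrame) else rows.copy()
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    out = frame.apply(lambda s: [_render(s.name, v) for v in s]) if len(frame) else frame
    out.to_csv(path, index=False)
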