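"""Specimen measurement tables: data model, CSV I/O, wingspan, completeness.

Measurements are skeletal lengths in millimetres, one row per fossil
specimen.  The fixed measurement vocabulary covers 13 dimensions: three
axial lengths (skull, neck, tail), the seven forelimb elements that make
up the wing spar (humerus, ulna/radius, metacarpal IV, wing phalanges
1-4), femur, tibia, and wingspan.  Wingspan is defined osteologically as
2.1 x the summed length of the seven forelimb elements, which accounts
for shoulder breadth and joint spacing in the outstretched wing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import pandas as pd

#: Fixed measurement vocabulary, in canonical column order.
DIMENSIONS: tuple[str, ...] = (
    "skull",
    "neck",
    "tail",
    "humerus",
    "ulna_radius",
    "mcIV",
    "wp1",
    "wp2",
    "wp3",
    "wp4",
    "femur",
    "tibia",
    "wingspan",
)

#: The seven elements of the wing spar, proximal to distal.
FORELIMB_ELEMENTS: tuple[str, ...] = (
    "humerus",
    "ulna_radius",
    "mcIV",
    "wp1",
    "wp2",
    "wp3",
    "wp4",
)

#: Multiplier converting summed forelimb length to wingspan.
WINGSPAN_FACTOR = 2.1

#: Cell values treated as "measurement not preserved".
_MISSING_TOKENS = {"", "na", "nan", "n/a", "none"}


class SpecimenTableError(ValueError):
    """Malformed specimen table (bad cell, unknown column, duplicate id)."""


class IncompleteForelimbError(ValueError):
    """Wingspan requested for a specimen missing a wing-spar element."""


@dataclass(frozen=True)
class Specimen:
    """One fossil specimen: an id plus present measurements (mm)."""

    specimen_id: str
    measurements: Mapping[str, float]

    def get(self, dim: str) -> float | None:
        return self.measurements.get(dim)

    def has(self, dims: Iterable[str]) -> bool:
        return all(d in self.measurements for d in dims)


@dataclass(frozen=True)
class SpecimenTable:
    """A taxon's specimen measurement table with missing cells allowed."""

    taxon: str
    specimens: tuple[Specimen, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sp in self.specimens:
            if sp.specimen_id in seen:
                raise SpecimenTableError(
                    f"duplicate specimen_id {sp.specimen_id!r} in {self.taxon}"
                )
            seen.add(sp.specimen_id)
            for dim, val in sp.measurements.items():
                if dim not in DIMENSIONS:
                    raise SpecimenTableError(
                        f"unknown dimension {dim!r}; vocabulary is {DIMENSIONS}"
                    )
                if not val > 0:
                    raise SpecimenTableError(
                        f"non-positive measurement {dim}={val} for specimen "
                        f"{sp.specimen_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.specimens)

    def n_absent(self) -> int:
        """Count of absent cells over the full 13-dimension vocabulary."""
        return sum(
            len(DIMENSIONS) - len(sp.measurements) for sp in self.specimens
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame (NaN = absent), columns in vocabulary order."""
        rows = {
            sp.specimen_id: {d: sp.measurements.get(d) for d in DIMENSIONS}
            for sp in self.specimens
        }
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(DIMENSIONS))
        df.index.name = "specimen_id"
        return df.astype(float)


@dataclass(frozen=True)
class DimensionConfig:
    """Which dimensions enter an analysis, and whether WP3+WP4 are merged.

    Merging the two distal phalanges (``combine_wp34``) follows the
    anurognathid convention in which the presence of a separate fourth
    phalanx in juveniles is uncertain; the merged dimension is named
    ``wp3_4`` and equals the summed length.
    """

    included_dimensions: tuple[str, ...] = field(
        default_factory=lambda: tuple(DIMENSIONS)
    )
    combine_wp34: bool = False

    def __post_init__(self) -> None:
        for d in self.included_dimensions:
            if d not in DIMENSIONS:
                raise SpecimenTableError(
                    f"unknown dimension {d!r}; vocabulary is {DIMENSIONS}"
                )
        if len(set(self.included_dimensions)) != len(self.included_dimensions):
            raise SpecimenTableError("included_dimensions contains duplicates")

    @property
    def analysis_dimensions(self) -> tuple[str, ...]:
        """Dimension names as analysed (wp3/wp4 possibly merged)."""
        if not self.combine_wp34:
            return self.included_dimensions
        out: list[str] = []
        for d in self.included_dimensions:
            if d == "wp3":
                out.append("wp3_4")
            elif d == "wp4":
                continue
            else:
                out.append(d)
        return tuple(out)


def compute_wingspan(measurements: Mapping[str, float]) -> float:
    """Wingspan in mm: 2.1 x (humerus + ulna/radius + mcIV + WP1-4).

    Raises :class:`IncompleteForelimbError` if any spar element is absent.
    """
    missing = [d for d in FORELIMB_ELEMENTS if d not in measurements]
    if missing:
        raise IncompleteForelimbError(
            f"incomplete forelimb: missing {', '.join(missing)}"
        )
    return WINGSPAN_FACTOR * sum(measurements[d] for d in FORELIMB_ELEMENTS)


def filter_complete(
    table: SpecimenTable, required: Iterable[str]
) -> SpecimenTable:
    """Keep only specimens preserving every dimension in ``required``."""
    req = tuple(required)
    for d in req:
        if d not in DIMENSIONS:
            raise SpecimenTableError(
                f"unknown dimension {d!r}; vocabulary is {DIMENSIONS}"
            )
    kept = tuple(sp for sp in table.specimens if sp.has(req))
    return replace(table, specimens=kept)


def _parse_cell(raw: object, row_id: str, col: str) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    try:
        val = float(text)
    except ValueError as exc:
        raise SpecimenTableError(
            f"non-numeric cell {text!r} at row {row_id!r}, column {col!r}"
        ) from exc
    if not val > 0:
        raise SpecimenTableError(
            f"non-positive cell {val} at row {row_id!r}, column {col!r}"
        )
    return val


def read_specimen_table(source: IO[str] | str, taxon: str) -> SpecimenTable:
    """Read a specimen CSV (UTF-8, header row, '.' decimal, mm).

    The first column must be ``specimen_id``; remaining columns must be
    drawn from the fixed vocabulary.  Empty cells and the sentinel ``NA``
    mean "not preserved" (measurements are strictly positive, so zero is
    never used as a missing marker).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if df.columns[0] != "specimen_id":
        raise SpecimenTableError("first column must be 'specimen_id'")
    for col in df.columns[1:]:
        if col not in DIMENSIONS:
            raise SpecimenTableError(
                f"unknown column {col!r}; vocabulary is {DIMENSIONS}"
            )
    specimens = []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"]).strip()
        meas = {}
        for col in df.columns[1:]:
            val = _parse_cell(row[col], sid, col)
            if val is not None:
                meas[col] = val
        specimens.append(Specimen(specimen_id=sid, measurements=meas))
    return SpecimenTable(taxon=taxon, specimens=tuple(specimens))


def write_specimen_table(table: SpecimenTable, sink: IO[str]) -> None:
    """Write a specimen table as CSV in canonical column order."""
    cols = [d for d in DIMENSIONS]
    sink.write("specimen_id," + ",".join(cols) + "\n")
    for sp in table.specimens:
        cells = []
        for d in cols:
            v = sp.measurements.get(d)
            cells.append("" if v is None else repr(v))  # shortest round-trip form
        sink.write(sp.specimen_id + "," + ",".join(cells) + "\n")
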