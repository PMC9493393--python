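"""Data model and I/O for plate-based protein binding screens.

A screen compares the binding of a library of tagged proteins to two
immobilized nucleic-acid structures (a test structure, e.g. a PNA
heterotriplex, and a reference structure, e.g. the same-sequence DNA
duplex).  Each physical plate carries wells of four kinds:

* ``factor`` wells -- lysate expressing one tagged library protein;
* ``empty_background`` wells -- no tagged protein; they define the
  per-plate luminescence background used for z-score normalization;
* ``negative_control`` / ``positive_control`` wells -- dedicated control
  lysates (e.g. GFP negative, XPA/RPA2 positive) included on every plate.

Three delimited-text inputs describe a screen: a plate map
(``plate_id, well, kind, factor_id, condition, replicate``), a long-format
readings table (``plate_id, well, luminescence``) and a library annotation
table (``factor_id, category, tag_terminus, control_role``).  All files are
UTF-8 comma-separated with a header row.

:func:`assemble_design` joins the three into a validated
:class:`ScreenDesign`, verifying that every library factor is measured in
both conditions for every replicate.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .exceptions import DesignError, LayoutError, LibraryError, ReadingError

logger = logging.getLogger("snapscreen")

#: Row letters of a 384-well plate; a 96-well plate uses the first 8.
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: Fewer empty wells than this is a hard error (background SD undefined below 2).
MIN_EMPTY_HARD = 2
#: Fewer empty wells than this triggers a warning (background SD unstable).
MIN_EMPTY_WARN = 8


class PlateFormat(enum.IntEnum):
    """Physical plate format (number of wells)."""

    WELLS_96 = 96
    WELLS_384 = 384

    @property
    def n_rows(self) -> int:
        return 8 if self is PlateFormat.WELLS_96 else 16

    @property
    def n_cols(self) -> int:
        return 12 if self is PlateFormat.WELLS_96 else 24


_WELL_RE = re.compile(r"^([A-Z])([1-9]\d*)$")


@dataclasses.dataclass(frozen=True, order=True)
class WellAddress:
    """A plate-reader well address: row letter + 1-based column ("A1".."P24").

    Canonical string form is the letter immediately followed by the unpadded
    column number; zero-padded forms ("A01") are rejected on input.
    """

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise LayoutError(f"well row {self.row!r} out of range A-{ROW_LETTERS[-1]}")
        if not 1 <= self.column <= 24:
            raise LayoutError(f"well column {self.column} out of range 1-24")

    @classmethod
    def parse(cls, text: str, plate_format: PlateFormat | int | None = None) -> "WellAddress":
        m = _WELL_RE.match(str(text).strip())
        if not m:
            raise LayoutError(f"malformed well address {text!r}")
        addr = cls(m.group(1), int(m.group(2)))
        if plate_format is not None:
            fmt = PlateFormat(int(plate_format))
            if not addr.in_format(fmt):
                raise LayoutError(
                    f"well {addr} outside {int(fmt)}-well plate bounds "
                    f"(A-{ROW_LETTERS[fmt.n_rows - 1]}, 1-{fmt.n_cols})"
                )
        return addr

    def in_format(self, plate_format: PlateFormat) -> bool:
        return (
            ROW_LETTERS.index(self.row) < plate_format.n_rows
            and self.column <= plate_format.n_cols
        )

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


class WellKind(str, enum.Enum):
    FACTOR = "factor"
    EMPTY = "empty_background"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"


CONTROL_KINDS = frozenset({WellKind.NEGATIVE_CONTROL, WellKind.POSITIVE_CONTROL})


@dataclasses.dataclass(frozen=True)
class WellContent:
    """What a well holds: kind, the factor it assays, condition, replicate.

    ``factor_id`` is absent exactly for empty background wells; control wells
    carry the id of the control lysate (e.g. "GFP").
    """

    kind: WellKind
    factor_id: str | None
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.kind is WellKind.EMPTY:
            if self.factor_id:
                raise LayoutError("empty_background wells must not carry a factor_id")
        elif not self.factor_id:
            raise LayoutError(f"{self.kind.value} wells require a factor_id")
        if not self.condition:
            raise LayoutError("well condition label must be non-empty")
        if self.replicate < 1:
            raise LayoutError(f"replicate must be >= 1, got {self.replicate}")


@dataclasses.dataclass
class PlateLayout:
    """Well-to-content assignment for one physical plate."""

    plate_id: str
    plate_format: PlateFormat
    wells: dict[WellAddress, WellContent]

    def __post_init__(self) -> None:
        self.plate_format = PlateFormat(int(self.plate_format))
        for addr in self.wells:
            if not addr.in_format(self.plate_format):
                raise LayoutError(
                    f"well {addr} outside {int(self.plate_format)}-well bounds "
                    f"on plate {self.plate_id}"
                )

    @property
    def n_empty(self) -> int:
        return sum(1 for c in self.wells.values() if c.kind is WellKind.EMPTY)

    @property
    def empty_addresses(self) -> set[WellAddress]:
        return {a for a, c in self.wells.items() if c.kind is WellKind.EMPTY}

    def validate(self, min_empty: int = MIN_EMPTY_HARD) -> None:
        """Check the layout against the configured empty-well minimum."""
        n = self.n_empty
        if n < max(min_empty, MIN_EMPTY_HARD):
            raise LayoutError(
                f"plate {self.plate_id} has {n} empty background wells; "
                f"at least {max(min_empty, MIN_EMPTY_HARD)} required"
            )
        if n < MIN_EMPTY_WARN:
            logger.warning(
                "plate %s has only %d empty background wells; background SD "
                "is unstable below %d",
                self.plate_id,
                n,
                MIN_EMPTY_WARN,
            )


@dataclasses.dataclass(frozen=True)
class RawReading:
    """One plate-reader measurement: relative luminescence units for a well."""

    plate_id: str
    well: WellAddress
    luminescence: float

    def __post_init__(self) -> None:
        lum = float(self.luminescence)
        if not lum > 0:
            raise ReadingError(
                f"luminescence must be a positive real, got {self.luminescence!r} "
                f"for {self.plate_id}/{self.well}"
            )


class Category(str, enum.Enum):
    """Library annotation category; categories are mutually exclusive."""

    DNA_REPAIR = "dna_repair"
    CHROMATIN_ASSOCIATED = "chromatin_associated"
    OTHER_CONTROL = "other_control"


class ControlRole(str, enum.Enum):
    NONE = "none"
    NEGATIVE = "negative"
    POSITIVE = "positive"


class TagTerminus(str, enum.Enum):
    N = "N"
    C = "C"


@dataclasses.dataclass(frozen=True)
class LibraryAnnotation:
    """One protein-library entry: id, functional category, tag end, control role."""

    factor_id: str
    category: Category
    tag_terminus: TagTerminus = TagTerminus.C
    control_role: ControlRole = ControlRole.NONE


def library_tallies(
    library: Sequence[LibraryAnnotation], include_controls: bool = False
) -> dict[str, int]:
    """Category counts over the library.

    Dedicated control lysates (``control_role`` != none) sit outside the
    screenable library and are excluded unless ``include_controls``.
    """
    rows = [
        a for a in library if include_controls or a.control_role is ControlRole.NONE
    ]
    tallies = {c.value: 0 for c in Category}
    for a in rows:
        tallies[a.category.value] += 1
    tallies["total"] = len(rows)
    return tallies


# ---------------------------------------------------------------------------
# File I/O (UTF-8, comma-delimited, header row, long format)
# ---------------------------------------------------------------------------

_PLATE_MAP_COLUMNS = ["plate_id", "well", "kind", "factor_id", "condition", "replicate"]
_READING_COLUMNS = ["plate_id", "well", "luminescence"]
_LIBRARY_COLUMNS = ["factor_id", "category", "tag_terminus", "control_role"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing required columns {missing}")


def read_plate_maps(
    path: Union[str, Path], plate_format: PlateFormat | int = PlateFormat.WELLS_384
) -> list[PlateLayout]:
    """Read a plate-map CSV; returns one layout per plate_id, in file order."""
    path = Path(path)
    fmt = PlateFormat(int(plate_format))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _PLATE_MAP_COLUMNS, path)
    layouts: list[PlateLayout] = []
    for plate_id, group in df.groupby("plate_id", sort=False):
        wells: dict[WellAddress, WellContent] = {}
        for row in group.itertuples(index=False):
            addr = WellAddress.parse(row.well, fmt)
            if addr in wells:
                raise LayoutError(f"duplicate well {addr} on plate {plate_id}")
            try:
                kind = WellKind(row.kind)
            except ValueError:
                raise LayoutError(
                    f"unknown well kind {row.kind!r} at {plate_id}/{addr}"
                ) from None
            try:
                replicate = int(row.replicate)
            except ValueError:
                raise LayoutError(
                    f"non-integer replicate {row.replicate!r} at {plate_id}/{addr}"
                ) from None
            wells[addr] = WellContent(
                kind=kind,
                factor_id=row.factor_id or None,
                condition=row.condition,
                replicate=replicate,
            )
        layout = PlateLayout(str(plate_id), fmt, wells)
        layout.validate()
        layouts.append(layout)
    return layouts


def read_plate_map(
    path: Union[str, Path], plate_format: PlateFormat | int = PlateFormat.WELLS_384
) -> PlateLayout:
    """Read a plate-map CSV that describes exactly one plate."""
    layouts = read_plate_maps(path, plate_format)
    if len(layouts) != 1:
        raise LayoutError(
            f"{path} describes {len(layouts)} plates; expected exactly one "
            "(use read_plate_maps for multi-plate files)"
        )
    return layouts[0]


def write_plate_map(
    layouts: PlateLayout | Sequence[PlateLayout], path: Union[str, Path]
) -> None:
    if isinstance(layouts, PlateLayout):
        layouts = [layouts]
    rows = []
    for layout in layouts:
        for addr, content in layout.wells.items():
            rows.append(
                (
                    layout.plate_id,
                    str(addr),
                    content.kind.value,
                    content.factor_id or "",
                    content.condition,
                    content.replicate,
                )
            )
    pd.DataFrame(rows, columns=_PLATE_MAP_COLUMNS).to_csv(path, index=False)


def read_readings(path: Union[str, Path]) -> list[RawReading]:
    """Read a long-format readings CSV (one positive RLU per plate/well)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    _require_columns(df, _READING_COLUMNS, path)
    try:
        lum = pd.to_numeric(df["luminescence"], errors="raise")
    except (ValueError, TypeError):
        raise ReadingError(f"{path}: non-numeric luminescence value") from None
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ReadingError(
            f"{path}: duplicate reading for {first.plate_id}/{first.well}"
        )
    readings = []
    for plate_id, well, value in zip(df["plate_id"], df["well"], lum):
        readings.append(RawReading(str(plate_id), WellAddress.parse(well), float(value)))
    return readings


def write_readings(readings: Sequence[RawReading], path: Union[str, Path]) -> None:
    rows = [(r.plate_id, str(r.well), r.luminescence) for r in readings]
    pd.DataFrame(rows, columns=_READING_COLUMNS).to_csv(path, index=False)


def read_library(path: Union[str, Path]) -> list[LibraryAnnotation]:
    """Read a library annotation CSV; factor_ids must be unique."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["factor_id", "category"], path)
    seen: set[str] = set()
    annotations: list[LibraryAnnotation] = []
    for row in df.itertuples(index=False):
        if row.factor_id in seen:
            raise LibraryError(f"{path}: duplicate factor_id {row.factor_id!r}")
        seen.add(row.factor_id)
        try:
            category = Category(row.category)
        except ValueError:
            raise LibraryError(
                f"{path}: unknown category {row.category!r} for {row.factor_id}"
            ) from None
        terminus = TagTerminus(getattr(row, "tag_terminus", "C") or "C")
        role = ControlRole(getattr(row, "control_role", "none") or "none")
        annotations.append(LibraryAnnotation(row.factor_id, category, terminus, role))
    return annotations


def write_library(
    library: Sequence[LibraryAnnotation], path: Union[str, Path]
) -> None:
    rows = [
        (a.factor_id, a.category.value, a.tag_terminus.value, a.control_role.value)
        for a in library
    ]
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ScreenDesign:
    """A validated two-condition screen: layouts joined to readings.

    ``table`` is the long-form join with one row per mapped well and columns
    ``plate_id, well, kind, factor_id, condition, replicate, rlu``.
    """

    condition_a: str
    condition_b: str
    replicates: int
    plates: list[PlateLayout]
    readings: list[RawReading]
    library: list[LibraryAnnotation]
    table: pd.DataFrame = dataclasses.field(repr=False, default=None)

    def well_table(self) -> pd.DataFrame:
        return self.table.copy()

    def summary(self) -> dict:
        tallies = library_tallies(self.library)
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "replicates": self.replicates,
            "n_plates": len(self.plates),
            "n_wells": int(len(self.table)),
            "n_factors": tallies["total"],
            "library_tallies": tallies,
            "n_controls": sum(
                1 for a in self.library if a.control_role is not ControlRole.NONE
            ),
        }


def assemble_design(
    plates: Sequence[PlateLayout],
    readings: Sequence[RawReading],
    library: Sequence[LibraryAnnotation],
    condition_a: str,
    condition_b: str,
    min_empty: int = MIN_EMPTY_HARD,
) -> ScreenDesign:
    """Join layouts, readings and annotations into a validated ScreenDesign.

    Raises :class:`DesignError` when a reading has no mapped well, a mapped
    well has no reading, a library factor is missing a (condition, replicate)
    well, or either condition is absent.  Logs a notice when a factor's two
    conditions sit on different plates (valid under per-plate normalization,
    and the layout the original assay uses: one plate set per structure).
    """
    if not list(plates):
        raise DesignError("no plates provided")
    if not list(readings):
        raise DesignError("no readings provided")
    if not list(library):
        raise DesignError("empty library annotation table")

    plate_ids = [p.plate_id for p in plates]
    if len(set(plate_ids)) != len(plate_ids):
        raise DesignError("duplicate plate_id across plate layouts")

    lib_ids = {a.factor_id for a in library}
    rows = []
    for plate in plates:
        plate.validate(min_empty)
        for addr, content in plate.wells.items():
            rows.append(
                (
                    plate.plate_id,
                    str(addr),
                    content.kind.value,
                    content.factor_id,
                    content.condition,
                    content.replicate,
                )
            )
    layout = pd.DataFrame(
        rows, columns=["plate_id", "well", "kind", "factor_id", "condition", "replicate"]
    )

    unknown = layout.loc[
        layout["factor_id"].notna() & ~layout["factor_id"].isin(lib_ids), "factor_id"
    ].unique()
    if len(unknown):
        raise DesignError(
            f"{len(unknown)} well factor_id(s) absent from library annotation "
            f"table, e.g. {sorted(unknown)[:5]}"
        )

    reads = pd.DataFrame(
        [(r.plate_id, str(r.well), r.luminescence) for r in readings],
        columns=["plate_id", "well", "rlu"],
    )
    merged = layout.merge(reads, on=["plate_id", "well"], how="outer", indicator=True)
    orphans = merged[merged["_merge"] == "right_only"]
    if len(orphans):
        examples = [
            f"{r.plate_id}/{r.well}" for r in orphans.head(5).itertuples(index=False)
        ]
        raise DesignError(
            f"{len(orphans)} reading(s) for wells absent from the plate map, "
            f"e.g. {examples}"
        )
    unread = merged[merged["_merge"] == "left_only"]
    if len(unread):
        examples = [
            f"{r.plate_id}/{r.well}" for r in unread.head(5).itertuples(index=False)
        ]
        raise DesignError(
            f"{len(unread)} mapped well(s) without a reading, e.g. {examples}"
        )
    merged = merged.drop(columns="_merge")

    conditions = set(layout.loc[layout["kind"] == WellKind.FACTOR.value, "condition"])
    for cond in (condition_a, condition_b):
        if cond not in conditions:
            raise DesignError(f"condition {cond!r} has no factor wells in the design")

    replicates = int(layout["replicate"].max())

    # Completeness: every screenable library factor must resolve to exactly
    # one factor well per (condition, replicate).
    screenable = {a.factor_id for a in library if a.control_role is ControlRole.NONE}
    fac = layout[(layout["kind"] == WellKind.FACTOR.value)]
    counts = fac.groupby(["factor_id", "condition", "replicate"]).size()
    dup_triples = counts[counts > 1]
    if len(dup_triples):
        raise DesignError(
            f"{len(dup_triples)} (factor, condition, replicate) triple(s) map to "
            f"more than one well, e.g. {list(dup_triples.index[:3])}"
        )
    missing: list[tuple[str, str, int]] = []
    index = set(counts.index)
    for fid in sorted(screenable):
        for cond in (condition_a, condition_b):
            for rep in range(1, replicates + 1):
                if (fid, cond, rep) not in index:
                    missing.append((fid, cond, rep))
    if missing:
        raise DesignError(
            f"{len(missing)} missing (factor, condition, replicate) triple(s), "
            f"e.g. {missing[:5]}"
        )

    # Dedicated controls are expected on every assay plate.
    control_ids = {a.factor_id for a in library if a.control_role is not ControlRole.NONE}
    for cid in sorted(control_ids):
        on_plates = set(layout.loc[layout["factor_id"] == cid, "plate_id"])
        absent = set(plate_ids) - on_plates
        if absent:
            logger.warning(
                "control %s absent from %d plate(s): %s",
                cid,
                len(absent),
                sorted(absent)[:5],
            )

    # Cross-plate comparison notice (one message, not per factor).
    fac_plates = fac.groupby(["factor_id", "condition"])["plate_id"].first().unstack()
    if {condition_a, condition_b} <= set(fac_plates.columns):
        n_cross = int((fac_plates[condition_a] != fac_plates[condition_b]).sum())
        if n_cross:
            logger.warning(
                "%d factor(s) are assayed on different plates for %s vs %s; "
                "z-scores are per-plate so plate effects cancel, but raw "
                "signals are not directly comparable across plates",
                n_cross,
                condition_a,
                condition_b,
            )

    return ScreenDesign(
        condition_a=condition_a,
        condition_b=condition_b,
        replicates=replicates,
        plates=list(plates),
        readings=list(readings),
        library=list(library),
        table=merged,
    )
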