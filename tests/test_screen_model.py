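"""Plate/library data model, CSV dialects and design assembly."""

import pandas as pd
import pytest

from snapscreen import (
    Category,
    ControlRole,
    LibraryAnnotation,
    PlateFormat,
    PlateLayout,
    RawReading,
    WellAddress,
    WellContent,
    WellKind,
    assemble_design,
    library_tallies,
    read_library,
    read_plate_map,
    read_plate_maps,
    read_readings,
    write_library,
    write_plate_map,
    write_readings,
)
from snapscreen.exceptions import (
    DesignError,
    LayoutError,
    LibraryError,
    ReadingError,
)
from snapscreen.screen_model import ROW_LETTERS


# ---------------------------------------------------------------------------
# Well addresses
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,row,col",
    [("A1", "A", 1), ("P24", "P", 24), ("H12", "H", 12), (" B3 ", "B", 3)],
)
def test_well_address_parses_canonical_forms(text, row, col):
    addr = WellAddress.parse(text, PlateFormat.WELLS_384)
    assert (addr.row, addr.column) == (row, col)
    assert str(addr) == f"{row}{col}"


@pytest.mark.parametrize(
    "text,fmt",
    [
        ("Q1", 384),  # row out of A-P
        ("A0", 384),  # columns are 1-based
        ("A25", 384),  # past the last column
        ("A01", 384),  # zero-padding rejected
        ("1A", 384),
        ("", 384),
        ("I1", 96),  # row out of 96-well bounds
        ("A13", 96),  # column out of 96-well bounds
    ],
)
def test_well_address_rejects_out_of_bounds_and_malformed(text, fmt):
    with pytest.raises(LayoutError):
        WellAddress.parse(text, fmt)


def test_well_content_invariants():
    with pytest.raises(LayoutError):
        WellContent(WellKind.EMPTY, "F0001", "duplex", 1)  # empties carry no factor
    with pytest.raises(LayoutError):
        WellContent(WellKind.FACTOR, None, "duplex", 1)  # factors need an id
    with pytest.raises(LayoutError):
        WellContent(WellKind.FACTOR, "F0001", "duplex", 0)  # replicates 1-based


# ---------------------------------------------------------------------------
# Plate-map I/O
# ---------------------------------------------------------------------------


def _full_384_layout(plate_id="P1", n_empty=8):
    wells = {}
    i = 0
    for r in range(16):
        for c in range(1, 25):
            addr = WellAddress(ROW_LETTERS[r], c)
            if i < 384 - n_empty:
                wells[addr] = WellContent(WellKind.FACTOR, f"F{i + 1:04d}", "duplex", 1)
            else:
                wells[addr] = WellContent(WellKind.EMPTY, None, "duplex", 1)
            i += 1
    return PlateLayout(plate_id, PlateFormat.WELLS_384, wells)


def test_plate_map_round_trip_conserves_every_well(tmp_path):
    layout = _full_384_layout()
    path = tmp_path / "map.csv"
    write_plate_map(layout, path)
    back = read_plate_map(path, 384)
    assert len(back.wells) == 384
    assert back.n_empty == 8
    assert back.wells == layout.wells
    # Round trip is idempotent up to column order: write again, bytes match.
    path2 = tmp_path / "map2.csv"
    write_plate_map(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_plate_map_rejects_duplicate_well(tmp_path):
    df = pd.DataFrame(
        {
            "plate_id": ["P1"] * 3,
            "well": ["A1", "A1", "A2"],
            "kind": ["factor", "empty_background", "empty_background"],
            "factor_id": ["F0001", "", ""],
            "condition": ["duplex"] * 3,
            "replicate": [1, 1, 1],
        }
    )
    path = tmp_path / "dup.csv"
    df.to_csv(path, index=False)
    with pytest.raises(LayoutError, match="duplicate well"):
        read_plate_maps(path, 384)


def test_plate_map_rejects_row_out_of_format(tmp_path):
    df = pd.DataFrame(
        {
            "plate_id": ["P1"],
            "well": ["Q1"],
            "kind": ["factor"],
            "factor_id": ["F0001"],
            "condition": ["duplex"],
            "replicate": [1],
        }
    )
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(LayoutError):
        read_plate_maps(path, 384)


def test_plate_map_rejects_unknown_kind_and_too_few_empties(tmp_path):
    base = {
        "plate_id": ["P1", "P1"],
        "well": ["A1", "A2"],
        "kind": ["mystery", "empty_background"],
        "factor_id": ["F0001", ""],
        "condition": ["duplex"] * 2,
        "replicate": [1, 1],
    }
    path = tmp_path / "kind.csv"
    pd.DataFrame(base).to_csv(path, index=False)
    with pytest.raises(LayoutError, match="unknown well kind"):
        read_plate_maps(path, 384)
    base["kind"] = ["factor", "empty_background"]  # only one empty well
    pd.DataFrame(base).to_csv(path, index=False)
    with pytest.raises(LayoutError, match="empty background wells"):
        read_plate_maps(path, 384)


# ---------------------------------------------------------------------------
# Readings I/O
# ---------------------------------------------------------------------------


def test_readings_identity_parse(tmp_path):
    path = tmp_path / "r.csv"
    pd.DataFrame(
        {"plate_id": ["P1"], "well": ["A1"], "luminescence": [153000.0]}
    ).to_csv(path, index=False)
    (reading,) = read_readings(path)
    assert reading == RawReading("P1", WellAddress("A", 1), 153000.0)


@pytest.mark.parametrize("value", ["0", "-5", "banana"])
def test_readings_reject_nonpositive_and_nonnumeric(tmp_path, value):
    path = tmp_path / "r.csv"
    path.write_text(f"plate_id,well,luminescence\nP1,A1,{value}\n")
    with pytest.raises(ReadingError):
        read_readings(path)


def test_readings_reject_duplicate_well(tmp_path):
    path = tmp_path / "r.csv"
    path.write_text("plate_id,well,luminescence\nP1,A1,100\nP1,A1,200\n")
    with pytest.raises(ReadingError, match="duplicate"):
        read_readings(path)


# ---------------------------------------------------------------------------
# Library I/O and tallies
# ---------------------------------------------------------------------------


def test_library_round_trip_and_category_partition(tmp_path, paper_sim):
    path = tmp_path / "lib.csv"
    write_library(paper_sim.library, path)
    lib = read_library(path)
    tallies = library_tallies(lib)
    # Screenable library: 336 DNA repair + 184 non-repair controls (64 of
    # them chromatin-associated, hence 120 others) = 520 factors.
    assert tallies["total"] == 520
    assert tallies["dna_repair"] == 336
    assert tallies["chromatin_associated"] == 64
    assert tallies["other_control"] == 120
    assert tallies["chromatin_associated"] + tallies["other_control"] == 184
    # Partition: the categories tile the library.
    assert (
        tallies["dna_repair"]
        + tallies["chromatin_associated"]
        + tallies["other_control"]
        == tallies["total"]
    )
    # Dedicated control lysates sit outside the screenable count.
    assert library_tallies(lib, include_controls=True)["total"] == 523


def test_library_rejects_duplicates_and_unknown_category(tmp_path):
    path = tmp_path / "lib.csv"
    path.write_text(
        "factor_id,category,tag_terminus,control_role\n"
        "F1,dna_repair,C,none\nF1,dna_repair,C,none\n"
    )
    with pytest.raises(LibraryError, match="duplicate"):
        read_library(path)
    path.write_text(
        "factor_id,category,tag_terminus,control_role\nF1,kinase,C,none\n"
    )
    with pytest.raises(LibraryError, match="unknown category"):
        read_library(path)


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------


def test_assemble_resolves_every_factor_condition_replicate(paper_sim):
    design = paper_sim.design()
    table = design.well_table()
    fac = table[table["kind"] == WellKind.FACTOR.value]
    # 520 factors x 2 conditions x 2 replicates
    assert len(fac) == 520 * 2 * 2
    assert design.replicates == 2
    # Well-count conservation: every mapped well got exactly one reading.
    assert len(table) == len(paper_sim.readings)
    assert table["rlu"].notna().all()


def test_assemble_reports_missing_triples(paper_sim):
    plates = [
        PlateLayout(p.plate_id, p.plate_format, dict(p.wells))
        for p in paper_sim.plates
    ]
    # Drop one factor well (and its reading) from the first plate.
    victim = next(
        addr
        for addr, c in plates[0].wells.items()
        if c.kind is WellKind.FACTOR
    )
    fid = plates[0].wells[victim].factor_id
    del plates[0].wells[victim]
    readings = [
        r
        for r in paper_sim.readings
        if not (r.plate_id == plates[0].plate_id and r.well == victim)
    ]
    with pytest.raises(DesignError, match=fid):
        assemble_design(plates, readings, paper_sim.library, "duplex", "triplex")


def test_assemble_rejects_empty_readings(paper_sim):
    with pytest.raises(DesignError, match="no readings"):
        assemble_design(paper_sim.plates, [], paper_sim.library, "duplex", "triplex")


def test_assemble_rejects_orphan_reading(paper_sim):
    # Find a plate with a free well (the trailing chunk plates are partial).
    plate = next(p for p in paper_sim.plates if len(p.wells) < 384)
    free = next(
        WellAddress(ROW_LETTERS[r], c)
        for r in range(15, -1, -1)
        for c in range(24, 0, -1)
        if WellAddress(ROW_LETTERS[r], c) not in plate.wells
    )
    extra = RawReading(plate.plate_id, free, 1000.0)
    with pytest.raises(DesignError, match="absent from the plate map"):
        assemble_design(
            paper_sim.plates,
            list(paper_sim.readings) + [extra],
            paper_sim.library,
            "duplex",
            "triplex",
        )


def test_assemble_rejects_unannotated_factor(paper_sim):
    lib = [a for a in paper_sim.library if a.factor_id != "F0001"]
    with pytest.raises(DesignError, match="absent from library"):
        assemble_design(paper_sim.plates, paper_sim.readings, lib, "duplex", "triplex")


def test_assemble_rejects_missing_condition(paper_sim):
    with pytest.raises(DesignError, match="quadruplex"):
        assemble_design(
            paper_sim.plates, paper_sim.readings, paper_sim.library,
            "duplex", "quadruplex",
        )


def test_library_annotations_are_not_hardcoded_to_one_size(tmp_path):
    # The reader must accept libraries of any size (the assay is scalable).
    lib = [
        LibraryAnnotation(f"X{i}", Category.DNA_REPAIR) for i in range(90)
    ] + [LibraryAnnotation("GFP", Category.OTHER_CONTROL, control_role=ControlRole.NEGATIVE)]
    path = tmp_path / "lib90.csv"
    write_library(lib, path)
    assert library_tallies(read_library(path))["total"] == 90
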