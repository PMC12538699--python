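"""TopoChip grid layout, design placement, and tile filename grammar.

A TopoChip is a square grid of walled TopoUnits (66x66 by default). Each of
the 2176 topography designs occupies two units ("duplicates"), and four units
carry a flat control surface that doubles as an orientation landmark in the
lower-right corner of the chip.

Tile images cropped from the stitched chip image are named with the grammar::

    [Channel]_[ChipID]_Col[Col]_Row[Row]_Seq[Seq]_[Stain].tif

``parse_tile_name`` / ``format_tile_name`` form an exact round trip: parsing a
valid name and re-formatting it reproduces the input byte for byte (observed
zero-padding widths are preserved on the parsed record).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Reserved design id for flat (pattern-less) control units.
FLAT = "FLAT"

__all__ = [
    "FLAT",
    "ChipLayout",
    "TileName",
    "TileNameError",
    "build_layout",
    "parse_tile_name",
    "format_tile_name",
    "layout_to_frame",
    "layout_from_frame",
    "make_design_table",
    "load_design_table",
    "save_design_table",
]


@dataclass(frozen=True)
class ChipLayout:
    """Design-to-position map of one TopoChip.

    Positions are 0-based ``(row, col)`` tuples with the origin at the
    top-left; the 1-based indexing of tile filenames is confined to
    :func:`parse_tile_name` / :func:`format_tile_name`.
    """

    n_rows: int
    n_cols: int
    design_at: dict = field(repr=False)
    flat_positions: frozenset = field(repr=False)

    def __post_init__(self):
        if len(self.design_at) != self.n_rows * self.n_cols:
            raise ValueError(
                f"layout covers {len(self.design_at)} positions, grid has "
                f"{self.n_rows * self.n_cols}"
            )
        for pos in self.flat_positions:
            if self.design_at.get(pos) != FLAT:
                raise ValueError(f"flat position {pos} not mapped to {FLAT}")

    @property
    def design_ids(self) -> list:
        """Sorted unique non-flat design ids."""
        return sorted({d for d in self.design_at.values() if d != FLAT})

    @property
    def n_designs(self) -> int:
        return len(self.design_ids)

    def positions_of(self, design_id: str) -> list:
        """All grid positions carrying ``design_id`` (2 for duplicates)."""
        return sorted(p for p, d in self.design_at.items() if d == design_id)


def _flat_block_positions(n_rows: int, n_cols: int, flat_count: int) -> list:
    """Flat/landmark positions, filled outward from the lower-right corner."""
    order = sorted(
        ((r, c) for r in range(n_rows) for c in range(n_cols)),
        key=lambda rc: (max(n_rows - 1 - rc[0], n_cols - 1 - rc[1]),
                        n_rows - 1 - rc[0], n_cols - 1 - rc[1]),
    )
    return order[:flat_count]


def build_layout(
    n_designs: int = 2176,
    n_rows: int = 66,
    n_cols: int = 66,
    flat_count: int = 4,
    seed: int = 0,
    flat_positions: list | None = None,
) -> ChipLayout:
    """Build a deterministic duplicate-placement layout.

    Every design receives exactly two positions, one in each half of the
    non-flat position list ordered by (col, row), so replicates land on
    opposite sides of the chip. Flat units default to the lower-right corner
    block (the orientation landmark).

    Raises
    ------
    ValueError
        If ``2 * n_designs + flat_count != n_rows * n_cols``.
    """
    n_pos = n_rows * n_cols
    if 2 * n_designs + flat_count != n_pos:
        raise ValueError(
            f"grid arity mismatch: 2*{n_designs} designs + {flat_count} flat "
            f"= {2 * n_designs + flat_count}, but grid holds {n_pos} positions"
        )
    if flat_positions is None:
        flat_positions = _flat_block_positions(n_rows, n_cols, flat_count)
    flat_positions = [tuple(p) for p in flat_positions]
    if len(flat_positions) != flat_count:
        raise ValueError(
            f"{len(flat_positions)} flat positions given, expected {flat_count}"
        )

    design_at = {p: FLAT for p in flat_positions}
    nonflat = sorted(
        ((r, c) for r in range(n_rows) for c in range(n_cols)
         if (r, c) not in design_at),
        key=lambda rc: (rc[1], rc[0]),  # column-major: left side first
    )
    rng = np.random.default_rng(seed)
    half = len(nonflat) // 2
    left = [nonflat[i] for i in rng.permutation(half)]
    right = [nonflat[half + i] for i in rng.permutation(half)]
    width = len(str(max(n_designs, 1)))
    for i in range(n_designs):
        did = f"D{i + 1:0{width}d}"
        design_at[left[i]] = did
        design_at[right[i]] = did
    return ChipLayout(n_rows=n_rows, n_cols=n_cols, design_at=design_at,
                      flat_positions=frozenset(flat_positions))


# ---------------------------------------------------------------------------
# tile filename grammar
# ---------------------------------------------------------------------------

class TileNameError(ValueError):
    """Malformed tile filename; ``token`` names the first failing token."""

    def __init__(self, name: str, token: str, reason: str):
        self.token = token
        super().__init__(f"bad tile name {name!r}: token {token!r}: {reason}")


@dataclass(frozen=True)
class TileName:
    """Parsed tile filename. ``col``/``row``/``seq`` are 1-based.

    ``*_pad`` record the zero-padded field widths so that
    ``format_tile_name(parse_tile_name(s)) == s`` for every valid ``s``.
    """

    channel: str
    chip_id: str
    col: int
    row: int
    seq: int
    stain: str
    col_pad: int = 2
    row_pad: int = 2
    seq_pad: int = 4


_TOKEN = re.compile(r"^[A-Za-z0-9][A-Za-z0-9-]*$")


def parse_tile_name(name: str) -> TileName:
    """Parse ``[Channel]_[ChipID]_Col..._Row..._Seq..._[Stain].tif``."""
    if not name.endswith(".tif"):
        raise TileNameError(name, "extension", "must end with '.tif'")
    stem = name[: -len(".tif")]
    parts = stem.split("_")
    if len(parts) != 6:
        raise TileNameError(
            name, "structure", f"expected 6 '_'-separated tokens, got {len(parts)}"
        )
    channel, chip_id, col_t, row_t, seq_t, stain = parts
    for label, tok in (("channel", channel), ("chip_id", chip_id),
                       ("stain", stain)):
        if not _TOKEN.match(tok):
            raise TileNameError(name, label, "empty or non-alphanumeric")
    fields = {}
    for label, prefix, tok in (("col", "Col", col_t), ("row", "Row", row_t),
                               ("seq", "Seq", seq_t)):
        if not tok.startswith(prefix):
            raise TileNameError(name, label, f"must start with {prefix!r}")
        digits = tok[len(prefix):]
        if not digits.isdigit():
            raise TileNameError(name, label, f"{prefix!r} must be followed by digits")
        fields[label] = (int(digits), len(digits))
    tn = TileName(
        channel=channel, chip_id=chip_id, stain=stain,
        col=fields["col"][0], row=fields["row"][0], seq=fields["seq"][0],
        col_pad=fields["col"][1], row_pad=fields["row"][1],
        seq_pad=fields["seq"][1],
    )
    if tn.col < 1:
        raise TileNameError(name, "col", "1-based, must be >= 1")
    if tn.row < 1:
        raise TileNameError(name, "row", "1-based, must be >= 1")
    if tn.seq < 1:
        raise TileNameError(name, "seq", "1-based, must be >= 1")
    return tn


def format_tile_name(t: TileName) -> str:
    """Render a :class:`TileName` in the screen's filename grammar."""
    for label, value in (("col", t.col), ("row", t.row), ("seq", t.seq)):
        if value < 1:
            raise ValueError(f"{label}={value} out of range (1-based)")
    for label, tok in (("channel", t.channel), ("chip_id", t.chip_id),
                       ("stain", t.stain)):
        if not _TOKEN.match(tok):
            raise ValueError(f"{label}={tok!r} is not a valid token")
    return (
        f"{t.channel}_{t.chip_id}"
        f"_Col{t.col:0{t.col_pad}d}_Row{t.row:0{t.row_pad}d}"
        f"_Seq{t.seq:0{t.seq_pad}d}_{t.stain}.tif"
    )


def tile_name_for(channel: str, chip_id: str, row: int, col: int, stain: str,
                  n_cols: int) -> TileName:
    """TileName at a 1-based grid position with row-major acquisition seq."""
    seq = (row - 1) * n_cols + col
    return TileName(channel=channel, chip_id=chip_id, col=col, row=row,
                    seq=seq, stain=stain)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def layout_to_frame(layout: ChipLayout) -> pd.DataFrame:
    """Layout as a (row, col, design_id) table in row-major order."""
    rows = [
        {"row": r, "col": c, "design_id": layout.design_at[(r, c)]}
        for r in range(layout.n_rows) for c in range(layout.n_cols)
    ]
    return pd.DataFrame(rows)


def layout_from_frame(frame: pd.DataFrame) -> ChipLayout:
    for col in ("row", "col", "design_id"):
        if col not in frame.columns:
            raise ValueError(f"layout table missing required column {col!r}")
    n_rows = int(frame["row"].max()) + 1
    n_cols = int(frame["col"].max()) + 1
    design_at = {
        (int(r), int(c)): str(d)
        for r, c, d in zip(frame["row"], frame["col"], frame["design_id"])
    }
    flats = frozenset(p for p, d in design_at.items() if d == FLAT)
    return ChipLayout(n_rows=n_rows, n_cols=n_cols, design_at=design_at,
                      flat_positions=flats)


# ---------------------------------------------------------------------------
# topography design descriptor (TDD) tables
# ---------------------------------------------------------------------------

DEFAULT_DESCRIPTORS = (
    "pillar_length",
    "shape_circularity",
    "internal_asymmetry",
    "surface_roughness",
    "pillar_spacing",
    "pattern_coverage",
)


def make_design_table(design_ids, descriptors=DEFAULT_DESCRIPTORS,
                      seed: int = 0) -> pd.DataFrame:
    """Synthetic TDD table: one row per design, one column per descriptor."""
    rng = np.random.default_rng(seed)
    data = {"design_id": list(design_ids)}
    for name in descriptors:
        data[name] = rng.normal(size=len(data["design_id"]))
    return pd.DataFrame(data)


def save_design_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_design_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if table.columns[0] != "design_id":
        raise ValueError("first column of a design table must be 'design_id'")
    if table["design_id"].duplicated().any():
        dupes = table.loc[table["design_id"].duplicated(), "design_id"].tolist()
        raise ValueError(f"duplicate design ids: {dupes[:5]}")
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"design table has missing values in columns {bad}")
    return table
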