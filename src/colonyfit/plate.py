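"""Plate geometry: formats, concentric layers, corners and snake-randomized layouts.

Colonies pinned in a rectangular grid experience "edge effects": positions near
the plate perimeter grow larger because they compete with fewer neighbors for
nutrients.  Positions are therefore modeled as concentric rectangular layers
(layer 0 = outermost ring).  Strain replicates are assigned to positions along
a circular snaking path that starts at a corner and spirals inward, with a
seeded random strain order, so that every strain is represented at every depth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateFormat",
    "PlateLayout",
    "FORMATS",
    "get_format",
    "layer_index",
    "max_layer",
    "is_plate_corner",
    "snake_path",
    "make_snake_layout",
    "well_label",
    "parse_well",
]


@dataclass(frozen=True)
class PlateFormat:
    """A supported pinning density: 96 (8x12), 384 (16x24) or 1536 (32x48)."""

    name: str
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if (self.n_rows, self.n_cols) not in {(8, 12), (16, 24), (32, 48)}:
            raise ValueError(
                f"unsupported plate format {self.n_rows}x{self.n_cols}; "
                "supported: 8x12 (96), 16x24 (384), 32x48 (1536)"
            )

    @property
    def n_positions(self) -> int:
        return self.n_rows * self.n_cols


FORMATS: dict[str, PlateFormat] = {
    "96": PlateFormat("96", 8, 12),
    "384": PlateFormat("384", 16, 24),
    "1536": PlateFormat("1536", 32, 48),
}


def get_format(name: "str | int | PlateFormat") -> PlateFormat:
    """Resolve ``96``/``"384"``/a PlateFormat into a PlateFormat."""
    if isinstance(name, PlateFormat):
        return name
    key = str(name)
    if key not in FORMATS:
        raise ValueError(f"unknown plate format {name!r}; choose from {sorted(FORMATS)}")
    return FORMATS[key]


def _check_position(row: int, col: int, fmt: PlateFormat) -> None:
    if not (0 <= row < fmt.n_rows and 0 <= col < fmt.n_cols):
        raise ValueError(
            f"position ({row},{col}) outside {fmt.name}-format plate "
            f"({fmt.n_rows}x{fmt.n_cols})"
        )


def layer_index(row: int, col: int, fmt: "PlateFormat | str | int") -> int:
    """Concentric-layer index of a position; layer 0 is the outermost ring."""
    fmt = get_format(fmt)
    _check_position(row, col, fmt)
    return min(row, col, fmt.n_rows - 1 - row, fmt.n_cols - 1 - col)


def max_layer(fmt: "PlateFormat | str | int") -> int:
    """Deepest layer index of a format (= n_rows/2 - 1 since n_rows < n_cols)."""
    fmt = get_format(fmt)
    return fmt.n_rows // 2 - 1


def is_plate_corner(row: int, col: int, fmt: "PlateFormat | str | int") -> bool:
    """True for the four plate-corner positions (excluded from analysis)."""
    fmt = get_format(fmt)
    _check_position(row, col, fmt)
    return row in (0, fmt.n_rows - 1) and col in (0, fmt.n_cols - 1)


def _ring_positions(fmt: PlateFormat, layer: int) -> list[tuple[int, int]]:
    """Positions of one ring, clockwise from its top-left corner."""
    top, left = layer, layer
    bottom, right = fmt.n_rows - 1 - layer, fmt.n_cols - 1 - layer
    if top > bottom or left > right:
        return []
    if top == bottom:
        return [(top, c) for c in range(left, right + 1)]
    out = [(top, c) for c in range(left, right + 1)]
    out += [(r, right) for r in range(top + 1, bottom + 1)]
    out += [(bottom, c) for c in range(right - 1, left - 1, -1)]
    out += [(r, left) for r in range(bottom - 1, top, -1)]
    return out


def snake_path(fmt: "PlateFormat | str | int") -> list[tuple[int, int]]:
    """All positions, ring by ring from the edge inward, clockwise from (0,0)."""
    fmt = get_format(fmt)
    path: list[tuple[int, int]] = []
    for layer in range(max_layer(fmt) + 1):
        path.extend(_ring_positions(fmt, layer))
    assert len(path) == fmt.n_positions
    return path


@dataclass
class PlateLayout:
    """Strain assignment of one pinned plate.

    ``assignment`` maps 0-based (row, col) to (strain_id, replicate_id);
    replicate ids count occurrences of a strain along the snake path, from 1.
    """

    format: PlateFormat
    assignment: dict[tuple[int, int], tuple[str, int]]
    trimmed: bool = False
    seed: int = 0
    plate_id: str = "plate1"

    def strains(self) -> list[str]:
        return sorted({s for s, _ in self.assignment.values()})

    def positions_of(self, strain: str) -> list[tuple[int, int]]:
        return [p for p, (s, _) in self.assignment.items() if s == strain]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: plate_id,row,col,well,strain,replicate,layer,is_corner."""
        rows = []
        for (r, c), (strain, rep) in sorted(self.assignment.items()):
            rows.append(
                {
                    "plate_id": self.plate_id,
                    "row": r,
                    "col": c,
                    "well": well_label(r, c),
                    "strain": strain,
                    "replicate": rep,
                    "layer": layer_index(r, c, self.format),
                    "is_corner": is_plate_corner(r, c, self.format),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fmt: "PlateFormat | str | int",
                   trimmed: bool = False, seed: int = 0) -> "PlateLayout":
        fmt = get_format(fmt)
        assignment = {}
        for _, rec in df.iterrows():
            r, c = int(rec["row"]), int(rec["col"])
            _check_position(r, c, fmt)
            assignment[(r, c)] = (str(rec["strain"]), int(rec.get("replicate", 1)))
        plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df else "plate1"
        return cls(fmt, assignment, trimmed=trimmed, seed=seed, plate_id=plate_id)

    @classmethod
    def from_csv(cls, path, fmt: "PlateFormat | str | int", **kw) -> "PlateLayout":
        return cls.from_frame(pd.read_csv(path), fmt, **kw)


def make_snake_layout(
    strains: "list[str]",
    fmt: "PlateFormat | str | int",
    seed: int,
    trimmed: bool = False,
    plate_id: str = "plate1",
    reshuffle_each_cycle: bool = False,
) -> PlateLayout:
    """Assign strains along the inward clockwise snake in a seeded random order.

    By default one seeded permutation of the strains is cycled along the
    path.  With ``reshuffle_each_cycle`` a fresh permutation is drawn for
    each block of ``len(strains)`` consecutive positions (a randomized-block
    layout), which breaks the periodic placement the fixed cycle produces.
    Either way every strain receives an equal number of positions (within
    one) and appears in multiple layers.
    """
    fmt = get_format(fmt)
    strains = [str(s) for s in strains]
    if not strains:
        raise ValueError("need at least one strain")
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain ids in layout request")
    if len(strains) > fmt.n_positions:
        raise ValueError(
            f"{len(strains)} strains exceed the {fmt.n_positions} positions of a "
            f"{fmt.name}-format plate"
        )
    rng = np.random.default_rng(seed)
    k = len(strains)
    order = [strains[i] for i in rng.permutation(k)]
    counts: dict[str, int] = {s: 0 for s in strains}
    assignment: dict[tuple[int, int], tuple[str, int]] = {}
    for i, pos in enumerate(snake_path(fmt)):
        if i % k == 0 and reshuffle_each_cycle:
            order = [strains[j] for j in rng.permutation(k)]
        strain = order[i % k]
        counts[strain] += 1
        assignment[pos] = (strain, counts[strain])
    return PlateLayout(fmt, assignment, trimmed=trimmed, seed=seed, plate_id=plate_id)


# -- A1-style well labels (rows beyond Z continue AA, AB, ... for 1536 plates) --

_LETTERS = string.ascii_uppercase


def well_label(row: int, col: int) -> str:
    """0-based (row, col) -> A1-style label; row 26 -> 'AA'."""
    if row < 0 or col < 0:
        raise ValueError("row/col must be non-negative")
    label = "" if row < 26 else _LETTERS[row // 26 - 1]
    return f"{label}{_LETTERS[row % 26]}{col + 1}"


def parse_well(label: str) -> tuple[int, int]:
    """A1-style label -> 0-based (row, col)."""
    label = label.strip().upper()
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    if i == 0 or i > 2 or not label[i:].isdigit():
        raise ValueError(f"malformed well label {label!r}")
    row = 0
    for ch in label[:i]:
        row = row * 26 + (_LETTERS.index(ch) + 1)
    return row - 1, int(label[i:]) - 1
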