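"""Hexagonal microwell array geometry.

The assay partitions a tissue slice over a chip of hexagonal microwells at
500 um center-to-center pitch, each well carrying a distinct 16-nt spatial
barcode in its reverse-transcription primer.  This module provides the grid
model used throughout the package: axial-coordinate wells, hexagonal graph
distance, concentric layers (the ring of wells exactly ``l`` steps away), and
TSV well-map I/O.

Internally wells live in axial coordinates ``(q, r)``; the file format speaks
"odd-row offset" ``(row, col)``, the natural indexing of a physically
row-staggered chip.  The default full-size chip is 24 rows x 32 columns = 768
wells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HexWell",
    "WellArray",
    "hex_distance",
    "layer",
    "read_well_map",
    "write_well_map",
    "axial_from_offset",
    "offset_from_axial",
    "random_barcodes",
    "default_array",
]

_VALID_BASES = frozenset("ACGT")
BARCODE_LENGTH = 16
DEFAULT_PITCH_UM = 500.0
DEFAULT_N_ROWS = 24
DEFAULT_N_COLS = 32


def axial_from_offset(row: int, col: int) -> tuple[int, int]:
    """Convert odd-row offset coordinates to axial (q, r)."""
    q = col - (row - (row & 1)) // 2
    return q, row


def offset_from_axial(q: int, r: int) -> tuple[int, int]:
    """Convert axial (q, r) back to odd-row offset (row, col)."""
    col = q + (r - (r & 1)) // 2
    return r, col


@dataclass(frozen=True)
class HexWell:
    """One microwell: identity, axial grid position, and spatial barcode."""

    well_id: str
    q: int
    r: int
    spatial_barcode: str
    pitch_um: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        if len(self.spatial_barcode) != BARCODE_LENGTH:
            raise ValueError(
                f"spatial barcode must be {BARCODE_LENGTH} nt, got "
                f"{len(self.spatial_barcode)!r} for well {self.well_id!r}"
            )
        if not _VALID_BASES.issuperset(self.spatial_barcode):
            raise ValueError(
                f"spatial barcode {self.spatial_barcode!r} contains non-ACGT bases"
            )
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    @property
    def offset(self) -> tuple[int, int]:
        """(row, col) in odd-row offset coordinates."""
        return offset_from_axial(self.q, self.r)


@dataclass
class WellArray:
    """A bounded hexagonal chip: a set of wells plus a barcode lookup."""

    wells: list[HexWell]
    n_rows: int = DEFAULT_N_ROWS
    n_cols: int = DEFAULT_N_COLS
    barcode_index: dict[str, HexWell] = field(init=False, repr=False)
    _by_axial: dict[tuple[int, int], HexWell] = field(init=False, repr=False)
    _by_id: dict[str, HexWell] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.wells) > self.n_rows * self.n_cols:
            raise ValueError("more wells than n_rows * n_cols grid positions")
        self.barcode_index = {}
        self._by_axial = {}
        self._by_id = {}
        for w in self.wells:
            if w.spatial_barcode in self.barcode_index:
                raise ValueError(f"duplicate spatial barcode {w.spatial_barcode!r}")
            if (w.q, w.r) in self._by_axial:
                raise ValueError(f"duplicate axial position {(w.q, w.r)}")
            if w.well_id in self._by_id:
                raise ValueError(f"duplicate well id {w.well_id!r}")
            self.barcode_index[w.spatial_barcode] = w
            self._by_axial[(w.q, w.r)] = w
            self._by_id[w.well_id] = w

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(self.wells)

    def __contains__(self, well: HexWell) -> bool:
        return self._by_axial.get((well.q, well.r)) is well

    def well(self, well_id: str) -> HexWell:
        return self._by_id[well_id]

    def at_axial(self, q: int, r: int) -> HexWell | None:
        return self._by_axial.get((q, r))

    def whitelist(self) -> set[str]:
        """Set of all spatial barcodes on the chip."""
        return set(self.barcode_index)

    def min_pairwise_barcode_distance(self) -> int:
        """Minimum Hamming distance between any two barcodes (brute force)."""
        best = BARCODE_LENGTH
        codes = [np.frombuffer(w.spatial_barcode.encode(), dtype=np.uint8)
                 for w in self.wells]
        arr = np.stack(codes)
        for i in range(len(arr)):
            d = (arr[i + 1:] != arr[i]).sum(axis=1)
            if d.size:
                best = min(best, int(d.min()))
        return best


def hex_distance(a: HexWell, b: HexWell, array: WellArray | None = None) -> int:
    """Hexagonal graph distance between two wells in axial coordinates.

    Equals the length of the shortest path on the hex adjacency graph of the
    unbounded grid:  (|dq| + |dr| + |dq + dr|) / 2.
    """
    if array is not None and (a not in array or b not in array):
        raise ValueError("both wells must belong to the given array")
    dq = a.q - b.q
    dr = a.r - b.r
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def layer(array: WellArray, center: HexWell, l: int) -> set[HexWell]:
    """Wells of ``array`` at hex distance exactly ``l`` from ``center``.

    Layer 0 is the center itself; layer 1 its up-to-six immediate neighbours;
    rings are truncated at the chip edge (no wrap-around).
    """
    if l < 0:
        raise ValueError("layer index must be non-negative")
    if center not in array:
        raise ValueError("center well not on array")
    if l == 0:
        return {center}
    out: set[HexWell] = set()
    # walk the ring: start l steps in direction 4, then 6 sides of l steps
    directions = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]
    q, r = center.q + directions[4][0] * l, center.r + directions[4][1] * l
    for side in range(6):
        dq, dr = directions[side]
        for _ in range(l):
            w = array.at_axial(q, r)
            if w is not None:
                out.add(w)
            q, r = q + dq, r + dr
    return out


def random_barcodes(n: int, rng: np.random.Generator,
                    length: int = BARCODE_LENGTH, min_distance: int = 3) -> list[str]:
    """Draw ``n`` distinct random barcodes with pairwise Hamming >= min_distance.

    Rejection sampling; at 16 nt and n <= 768 the acceptance rate is high.
    """
    bases = np.array(list("ACGT"))
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("barcode rejection sampling failed to converge")
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
    return ["".join(bases[c]) for c in chosen]


def default_array(n_rows: int = DEFAULT_N_ROWS, n_cols: int = DEFAULT_N_COLS,
                  seed: int = 0, pitch_um: float = DEFAULT_PITCH_UM) -> WellArray:
    """Build a fully populated chip with random well barcodes.

    Wells are id'ed ``W<row>_<col>`` in offset coordinates.
    """
    rng = np.random.default_rng(seed)
    codes = random_barcodes(n_rows * n_cols, rng)
    wells = []
    for (row, col), bc in zip(itertools.product(range(n_rows), range(n_cols)), codes):
        q, r = axial_from_offset(row, col)
        wells.append(HexWell(f"W{row}_{col}", q, r, bc, pitch_um))
    return WellArray(wells, n_rows=n_rows, n_cols=n_cols)


def write_well_map(array: WellArray, path) -> None:
    """Write a well map TSV: well_id, row, col, spatial_barcode (0-based, LF)."""
    rows = []
    for w in array.wells:
        row, col = w.offset
        rows.append((w.well_id, row, col, w.spatial_barcode))
    df = pd.DataFrame(rows, columns=["well_id", "row", "col", "spatial_barcode"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_well_map(path, n_rows: int | None = None, n_cols: int | None = None) -> WellArray:
    """Read a well map TSV back into a :class:`WellArray`.

    Raises ``ValueError`` on malformed rows, duplicate barcodes, or non-ACGT
    barcodes.  Grid dimensions default to the tightest box around the wells.
    """
    df = pd.read_csv(path, sep="\t", dtype={"well_id": str, "spatial_barcode": str})
    required = ["well_id", "row", "col", "spatial_barcode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"well map missing columns: {missing}")
    if df[required].isna().any().any():
        raise ValueError("well map contains malformed (missing) fields")
    wells = []
    for rec in df.itertuples(index=False):
        row, col = int(rec.row), int(rec.col)
        if row < 0 or col < 0:
            raise ValueError(f"negative offset coordinates for well {rec.well_id!r}")
        q, r = axial_from_offset(row, col)
        wells.append(HexWell(str(rec.well_id), q, r, str(rec.spatial_barcode)))
    if n_rows is None:
        n_rows = int(df["row"].max()) + 1 if len(df) else 0
    if n_cols is None:
        n_cols = int(df["col"].max()) + 1 if len(df) else 0
    return WellArray(wells, n_rows=n_rows, n_cols=n_cols)
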