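"""Square lattice of cell states with Moore neighborhoods.

The cell layer of the model lives on an ``n x n`` grid of spots.  Each spot
holds at most one cell: a stem cell, a transit-amplifying (TA) cell or a
terminally differentiated cell, or it is empty.  Neighborhoods are Moore
(Chebyshev distance 1, up to 8 spots) and are truncated at the hard grid
boundary, so edge spots have 5 neighbors and corner spots 3.

Coordinates are 0-based ``(row, col)`` pairs and all canonical orderings
(neighbor lists, occupied-spot lists) are row-major, so seeded simulations
are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "CellKind",
    "CellCounts",
    "Lattice",
    "moore_neighbors",
    "neighbor_counts",
    "init_center_block",
    "count_cells",
    "occupied_spots",
    "save_snapshot",
    "load_snapshot",
]


class CellKind(IntEnum):
    """State of one lattice spot (integer codes used in snapshots)."""

    EMPTY = 0
    STEM = 1
    TA = 2
    DIFF = 3


# Moore offsets in row-major canonical order.
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class CellCounts:
    stem: int
    ta: int
    diff: int

    @property
    def total(self) -> int:
        return self.stem + self.ta + self.diff


@dataclass
class Lattice:
    """An ``n x n`` grid of :class:`CellKind` codes (stored as ``int8``)."""

    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 2 or states.shape[0] != states.shape[1]:
            raise ValueError("lattice states must be a square 2-D array")
        if states.size and (states.min() < 0 or states.max() > 3):
            raise ValueError("lattice states must be codes in {0,1,2,3}")
        self.states = states

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def copy(self) -> "Lattice":
        return Lattice(self.states.copy())


def moore_neighbors(n: int, row: int, col: int) -> list[tuple[int, int]]:
    """In-grid Moore neighbors of ``(row, col)`` on an ``n x n`` grid.

    Returns 8 spots in the interior, 5 on a non-corner edge and 3 in a
    corner, in row-major order.
    """
    if not (0 <= row < n and 0 <= col < n):
        raise IndexError(f"spot ({row}, {col}) outside {n}x{n} grid")
    out = []
    for dr, dc in _OFFSETS:
        r, c = row + dr, col + dc
        if 0 <= r < n and 0 <= c < n:
            out.append((r, c))
    return out


def neighbor_counts(n: int) -> np.ndarray:
    """The per-spot neighbor count ``m`` (8 interior, 5 edge, 3 corner)."""
    if n < 1:
        raise ValueError("n must be positive")
    m = np.full((n, n), 8, dtype=np.int64)
    if n == 1:
        return np.zeros((1, 1), dtype=np.int64)
    m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = 5
    for r in (0, n - 1):
        for c in (0, n - 1):
            m[r, c] = 3
    return m


def init_center_block(n: int, side: int = 7) -> Lattice:
    """A ``side x side`` block of stem cells centered on an empty grid.

    The block origin is at ``floor((n - side) / 2)`` in each dimension; on
    grids where ``n - side`` is odd the block sits one spot off exact
    center, which is immaterial to the dynamics.
    """
    if side > n:
        raise ValueError(f"seed block side {side} exceeds grid side {n}")
    if side < 1 or n < 1:
        raise ValueError("n and side must be positive")
    states = np.zeros((n, n), dtype=np.int8)
    o = (n - side) // 2
    states[o : o + side, o : o + side] = CellKind.STEM
    return Lattice(states)


def count_cells(lattice: Lattice) -> CellCounts:
    """Exact per-kind cell counts on the lattice."""
    counts = np.bincount(lattice.states.ravel(), minlength=4)
    return CellCounts(stem=int(counts[1]), ta=int(counts[2]), diff=int(counts[3]))


def occupied_spots(lattice: Lattice) -> list[tuple[int, int]]:
    """Coordinates of all non-empty spots in row-major order."""
    rows, cols = np.nonzero(lattice.states)
    return list(zip(rows.tolist(), cols.tolist()))


def save_snapshot(lattice: Lattice, path: str | Path) -> None:
    """Write the grid as ``n`` lines of ``n`` whitespace-separated codes."""
    np.savetxt(path, lattice.states, fmt="%d")


def load_snapshot(path: str | Path) -> Lattice:
    states = np.loadtxt(path, dtype=np.int8, ndmin=2)
    return Lattice(states)
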