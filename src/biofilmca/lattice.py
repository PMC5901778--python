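"""The colonization lattice.

Sites hold one of three states: EMPTY (0), BLUE (1) or RED (2). Coordinates
are 0-based ``(x, y)`` with ``x`` increasing downstream along the flow axis
(grid columns) and ``y`` transverse to it (grid rows); the underlying numpy
array is indexed ``grid[y, x]``. Both axes are periodic.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

__all__ = ["EMPTY", "BLUE", "RED", "Lattice", "moore_offsets"]

EMPTY: int = 0
BLUE: int = 1
RED: int = 2

# Fixed Moore-neighborhood iteration order (documented so that random
# neighbor draws are reproducible given the RNG stream).
_MOORE = ((-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1))


def moore_offsets() -> tuple[tuple[int, int], ...]:
    """The 8 (dx, dy) Moore-neighborhood offsets, in fixed iteration order."""
    return _MOORE


class Lattice:
    """A 2D grid of {EMPTY, BLUE, RED} site states with periodic boundaries."""

    __slots__ = ("grid",)

    def __init__(self, grid: np.ndarray):
        grid = np.asarray(grid)
        if grid.ndim != 2:
            raise InvalidParameterError("lattice grid must be 2D")
        if not np.isin(grid, (EMPTY, BLUE, RED)).all():
            raise InvalidParameterError("lattice sites must be 0 (empty), 1 (blue) or 2 (red)")
        self.grid = grid.astype(np.int8)

    @classmethod
    def empty(cls, width: int, height: int | None = None) -> "Lattice":
        height = width if height is None else height
        return cls(np.zeros((height, width), dtype=np.int8))

    # ------------------------------------------------------------------
    @property
    def width(self) -> int:
        """Extent along the flow axis (columns)."""
        return self.grid.shape[1]

    @property
    def height(self) -> int:
        """Extent transverse to the flow (rows)."""
        return self.grid.shape[0]

    @property
    def n_sites(self) -> int:
        return self.grid.size

    @property
    def occupied_count(self) -> int:
        return int(np.count_nonzero(self.grid))

    @property
    def occupied_fraction(self) -> float:
        return self.occupied_count / self.n_sites

    def get(self, x: int, y: int) -> int:
        return int(self.grid[y % self.height, x % self.width])

    def set(self, x: int, y: int, state: int) -> None:
        self.grid[y % self.height, x % self.width] = state

    def occupied_sites(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates of occupied sites, row-major order."""
        ys, xs = np.nonzero(self.grid)
        return np.column_stack([xs, ys])

    def color_counts(self) -> tuple[int, int]:
        """(blue, red) cell counts."""
        return int(np.sum(self.grid == BLUE)), int(np.sum(self.grid == RED))

    def site_colors(self) -> dict[tuple[int, int], int]:
        """Mapping (x, y) -> color for every occupied site."""
        ys, xs = np.nonzero(self.grid)
        return {(int(x), int(y)): int(self.grid[y, x]) for x, y in zip(xs, ys)}

    def empty_moore_neighbors(self, x: int, y: int) -> list[tuple[int, int]]:
        """Empty sites among the 8 periodic Moore neighbors of (x, y)."""
        w, h = self.width, self.height
        out = []
        for dx, dy in _MOORE:
            qx, qy = (x + dx) % w, (y + dy) % h
            if self.grid[qy, qx] == EMPTY:
                out.append((qx, qy))
        return out

    def moore_neighbors(self, x: int, y: int) -> list[tuple[int, int]]:
        """All 8 periodic Moore neighbors of (x, y), in fixed order."""
        w, h = self.width, self.height
        return [((x + dx) % w, (y + dy) % h) for dx, dy in _MOORE]

    def copy(self) -> "Lattice":
        return Lattice(self.grid.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, Lattice) and np.array_equal(self.grid, other.grid)

    def __repr__(self) -> str:
        return (
            f"Lattice({self.width}x{self.height}, "
            f"occupied={self.occupied_count}/{self.n_sites})"
        )
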