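"""Raster elevation handling and D8 flow routing.

Depression filling (priority-flood with an epsilon gradient), steepest-descent
(D8) flow directions and flow accumulation on a regular grid: the standard
toolchain for deriving a channel network from a digital elevation model.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElevationGrid",
    "FlowGrid",
    "InvalidGridError",
    "TopologyError",
    "fill_depressions",
    "d8_flow_directions",
    "flow_accumulation",
    "D8_OFFSETS",
    "D8_STEP",
    "OUTLET",
    "NODATA_DIR",
]

# Neighbor scan order E, SE, S, SW, W, NW, N, NE; ties among equal steepest
# drops resolve to the first neighbor in this order.  Rows increase southward
# (ESRI ASCII convention: the first stored row is the northern edge).
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)
)
#: step length of each D8 move in units of the cell size
D8_STEP = np.array([1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0)] * 2)

OUTLET = -1      #: direction code for cells that drain off the grid
NODATA_DIR = -2  #: direction code for nodata cells


class InvalidGridError(ValueError):
    """The elevation grid cannot be processed (e.g. all cells are nodata)."""


class TopologyError(ValueError):
    """The flow-direction field contains a cycle."""


@dataclass
class ElevationGrid:
    """A regular elevation raster in ESRI ASCII convention.

    Parameters
    ----------
    elevation
        2-D array of heights in metres; ``nodata`` marks missing cells.
    cell_size
        Edge length of a (square) cell in metres.
    xllcorner, yllcorner
        Geographic coordinates of the lower-left corner of the grid.
    nodata
        Sentinel value for missing cells.
    """

    elevation: np.ndarray
    cell_size: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise InvalidGridError("elevation must be a 2-D array")
        if self.cell_size <= 0:
            raise InvalidGridError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return ~np.isclose(self.elevation, self.nodata) & np.isfinite(self.elevation)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Geographic (x, y) of a cell center; row 0 is the northern edge."""
        x = self.xllcorner + (col + 0.5) * self.cell_size
        y = self.yllcorner + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing geographic point (x, y)."""
        col = int((x - self.xllcorner) // self.cell_size)
        row = self.n_rows - 1 - int((y - self.yllcorner) // self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InvalidGridError(f"point ({x}, {y}) falls outside the grid")
        return row, col


@dataclass
class FlowGrid:
    """D8 flow directions and (optionally) flow accumulation.

    ``direction`` holds, per cell, an index into :data:`D8_OFFSETS`, or
    :data:`OUTLET` for cells draining off the grid, or :data:`NODATA_DIR`.
    ``accumulation`` counts contributing cells including the cell itself.
    """

    direction: np.ndarray
    accumulation: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        return self.direction != NODATA_DIR

    def downstream_cell(self, row: int, col: int) -> tuple[int, int] | None:
        d = self.direction[row, col]
        if d < 0:
            return None
        dr, dc = D8_OFFSETS[d]
        return row + dr, col + dc


def fill_depressions(grid: ElevationGrid, eps: float = 1e-6) -> np.ndarray:
    """Return a depression-free copy of the elevation surface.

    Priority-flood filling: cells are conquered outward from the grid
    boundary in order of elevation; any cell lower than the spill level of
    its flooding front is raised to that level plus ``eps``, which both fills
    pits to their spill elevation and imposes an epsilon gradient across
    flats toward their outlet.
    """
    z = grid.elevation.copy()
    valid = grid.valid
    if not valid.any():
        raise InvalidGridError("grid has no valid (non-nodata) cells")
    nrow, ncol = z.shape
    closed = ~valid  # nodata cells are never processed
    heap: list[tuple[float, int, int, int]] = []
    tick = 0
    for r in range(nrow):
        for c in range(ncol):
            if not valid[r, c]:
                continue
            on_edge = r in (0, nrow - 1) or c in (0, ncol - 1)
            if not on_edge:
                # interior cells adjacent to nodata also drain off the grid
                on_edge = any(
                    not valid[r + dr, c + dc] for dr, dc in D8_OFFSETS
                )
            if on_edge:
                heapq.heappush(heap, (z[r, c], tick, r, c))
                tick += 1
                closed[r, c] = True
    while heap:
        zv, _, r, c = heapq.heappop(heap)
        z[r, c] = zv
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrow and 0 <= nc < ncol and not closed[nr, nc]:
                closed[nr, nc] = True
                heapq.heappush(heap, (max(z[nr, nc], zv + eps), tick, nr, nc))
                tick += 1
    return z


def d8_flow_directions(
    grid: ElevationGrid, fill: bool = True, eps: float = 1e-6
) -> FlowGrid:
    """Assign every valid cell to its steepest-descent neighbor (D8).

    The steepest descent maximizes drop per unit distance (diagonal moves
    cover ``cell_size * sqrt(2)``).  Cells with no lower valid neighbor are
    outlets.  With ``fill`` (default) the surface is first made
    depression-free, so interior cells always drain to the boundary.
    """
    if not grid.valid.any():
        raise InvalidGridError("grid has no valid (non-nodata) cells")
    z = fill_depressions(grid, eps) if fill else grid.elevation
    valid = grid.valid
    nrow, ncol = z.shape
    direction = np.full((nrow, ncol), NODATA_DIR, dtype=np.int8)
    for r in range(nrow):
        for c in range(ncol):
            if not valid[r, c]:
                continue
            best_slope = 0.0
            best = OUTLET
            for k, (dr, dc) in enumerate(D8_OFFSETS):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrow and 0 <= nc < ncol) or not valid[nr, nc]:
                    continue
                slope = (z[r, c] - z[nr, nc]) / D8_STEP[k]
                if slope > best_slope:  # strict: first in scan order wins ties
                    best_slope = slope
                    best = k
            direction[r, c] = best
    return FlowGrid(direction=direction)


def flow_accumulation(flow: FlowGrid) -> FlowGrid:
    """Fill the accumulation field: contributing cells including self.

    Processes cells in topological order (Kahn); raises
    :class:`TopologyError` if the direction field contains a cycle.
    """
    direction = flow.direction
    nrow, ncol = direction.shape
    valid = flow.valid
    acc = np.where(valid, 1, 0).astype(np.int64)
    indeg = np.zeros((nrow, ncol), dtype=np.int32)
    for r in range(nrow):
        for c in range(ncol):
            if direction[r, c] >= 0:
                dr, dc = D8_OFFSETS[direction[r, c]]
                indeg[r + dr, c + dc] += 1
    queue = [(r, c) for r in range(nrow) for c in range(ncol)
             if valid[r, c] and indeg[r, c] == 0]
    processed = 0
    while queue:
        r, c = queue.pop()
        processed += 1
        d = direction[r, c]
        if d >= 0:
            dr, dc = D8_OFFSETS[d]
            nr, nc = r + dr, c + dc
            acc[nr, nc] += acc[r, c]
            indeg[nr, nc] -= 1
            if indeg[nr, nc] == 0:
                queue.append((nr, nc))
    if processed != int(valid.sum()):
        raise TopologyError("flow-direction field contains a cycle")
    return FlowGrid(direction=direction, accumulation=acc)
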