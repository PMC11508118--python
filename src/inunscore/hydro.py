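"""Hydrological terrain primitives.

Depression filling (priority-flood), D8 single-flow-direction routing,
upstream-cell flow accumulation and terrain convexity (curvature along
and across the slope direction).  These are the building blocks behind
the water-accumulation surface: each cell drains to its steepest-descent
neighbor and the accumulation count is the number of upstream cells
whose drainage path passes through it.

Direction conventions
---------------------
Neighbors are scanned in the fixed order N, NE, E, SE, S, SW, W, NW.
Ties in steepest descent go to the first maximum in that scan order
(deterministic and test-pinned).  Exported integer codes follow the
ESRI power-of-two convention::

    E=1, SE=2, S=4, SW=8, W=16, NW=32, N=64, NE=128, OUTLET=0
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid, RasterError

# Scan order N, NE, E, SE, S, SW, W, NW as (drow, dcol); row 0 = north.
NEIGHBOR_ORDER = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
OFFSETS = {
    "N": (-1, 0),
    "NE": (-1, 1),
    "E": (0, 1),
    "SE": (1, 1),
    "S": (1, 0),
    "SW": (1, -1),
    "W": (0, -1),
    "NW": (-1, -1),
}
OUTLET = "OUTLET"

ESRI_CODES = {"E": 1, "SE": 2, "S": 4, "SW": 8, "W": 16, "NW": 32, "N": 64, "NE": 128, OUTLET: 0}


class FlowError(RasterError):
    """Routing failure: unfilled pit or cyclic flow graph."""


@dataclass
class FlowDirectionGrid:
    """Per-cell D8 drainage direction codes.

    ``directions`` holds one of the eight compass strings, ``OUTLET``
    (boundary cell with no lower neighbor) or ``""`` for nodata.
    """

    directions: np.ndarray  # dtype object/str, shape = DEM shape
    cell_size: float
    nodata_mask: np.ndarray

    @property
    def shape(self):
        return self.directions.shape

    def as_codes(self) -> np.ndarray:
        """Integer raster using the ESRI power-of-two code table."""
        out = np.zeros(self.shape, dtype=np.int32)
        for name, code in ESRI_CODES.items():
            out[self.directions == name] = code
        out[self.nodata_mask] = -1
        return out

    def receiver(self, r: int, c: int) -> tuple[int, int] | None:
        """Downstream (row, col) of a cell, or None for outlets/nodata."""
        d = self.directions[r, c]
        if d in ("", OUTLET):
            return None
        dr, dc = OFFSETS[d]
        return r + dr, c + dc


@dataclass
class AccumulationGrid:
    """Upstream-cell counts (the cell itself excluded by default)."""

    counts: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class ConvexityGrids:
    """Longitudinal and cross-sectional convexity surfaces (1/m).

    Negative values mark concave (water-stagnating) topography,
    positive values convex topography; the magnitude is the curvature
    of the local quadratic fit.
    """

    longitudinal: np.ndarray
    cross_sectional: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray


def _neighbors(r: int, c: int, rows: int, cols: int):
    for name in NEIGHBOR_ORDER:
        dr, dc = OFFSETS[name]
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            yield name, rr, cc


def fill_depressions(dem: RasterGrid, epsilon: float = 0.0) -> RasterGrid:
    """Raise closed depressions to their spill level (priority-flood).

    Processes cells from the boundary inward in increasing elevation
    order; any cell lower than the level of the flood front when reached
    is raised to that level (plus ``epsilon`` per step when a tiny
    enforced gradient across filled flats is wanted).  Output ≥ input
    everywhere and cells that already drain are unchanged.
    """
    dem.require_nonempty()
    rows, cols = dem.shape
    valid = dem.valid_mask
    filled = np.where(valid, dem.values, np.nan)
    closed = ~valid  # nodata never enters the queue
    heap: list[tuple[float, int, int, int]] = []
    order = 0
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            # Seed with boundary cells and cells adjacent to nodata
            # (both are exits for water).
            on_edge = r in (0, rows - 1) or c in (0, cols - 1)
            if not on_edge:
                on_edge = any(not valid[rr, cc] for _, rr, cc in _neighbors(r, c, rows, cols))
            if on_edge:
                heapq.heappush(heap, (filled[r, c], order, r, c))
                order += 1
                closed[r, c] = True
    while heap:
        z, _, r, c = heapq.heappop(heap)
        for _, rr, cc in _neighbors(r, c, rows, cols):
            if closed[rr, cc]:
                continue
            closed[rr, cc] = True
            if filled[rr, cc] < z + epsilon:
                filled[rr, cc] = z + epsilon
            heapq.heappush(heap, (filled[rr, cc], order, rr, cc))
            order += 1
    return dem.with_values(np.where(valid, filled, dem.values))


def d8_directions(dem: RasterGrid, pit_policy: str = "error") -> FlowDirectionGrid:
    """Steepest-descent D8 drainage directions on a depression-filled DEM.

    Each cell drains to the neighbor with the maximum positive
    drop/distance (diagonal distance = cell_size·√2); ties go to the
    first maximum in the scan order N, NE, E, SE, S, SW, W, NW.
    Boundary cells with no lower neighbor are outlets.  Flat cells
    (no strictly lower neighbor, equal-elevation neighbors only) are
    routed across the flat toward its spill point by breadth-first
    distance.  An interior cell that is a genuine pit raises
    :class:`FlowError` instructing to fill first (``pit_policy=
    "error"``, the default) or becomes an interior sink coded OUTLET
    (``pit_policy="sink"``).
    """
    if pit_policy not in ("error", "sink"):
        raise RasterError(f"pit_policy must be 'error' or 'sink', got {pit_policy!r}")
    dem.require_nonempty()
    rows, cols = dem.shape
    valid = dem.valid_mask
    z = dem.values
    dirs = np.full((rows, cols), "", dtype=object)
    unresolved: list[tuple[int, int]] = []
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            best_name, best_grad = None, 0.0
            flat_neighbor = False
            for name, rr, cc in _neighbors(r, c, rows, cols):
                if not valid[rr, cc]:
                    continue
                drop = z[r, c] - z[rr, cc]
                if drop == 0.0:
                    flat_neighbor = True
                    continue
                dist = dem.cell_size * (np.sqrt(2.0) if (rr != r and cc != c) else 1.0)
                grad = drop / dist
                if grad > best_grad:
                    best_grad, best_name = grad, name
            if best_name is not None:
                dirs[r, c] = best_name
                continue
            on_edge = (
                r in (0, rows - 1)
                or c in (0, cols - 1)
                or any(not valid[rr, cc] for _, rr, cc in _neighbors(r, c, rows, cols))
            )
            if on_edge:
                dirs[r, c] = OUTLET
            elif flat_neighbor:
                unresolved.append((r, c))
            elif pit_policy == "sink":
                dirs[r, c] = OUTLET
            else:
                raise FlowError(
                    f"cell ({r}, {c}) is an unfilled pit; run fill_depressions first"
                )
    if unresolved:
        _route_flats(dem, dirs, set(unresolved))
    return FlowDirectionGrid(directions=dirs, cell_size=dem.cell_size, nodata_mask=~valid)


def _route_flats(dem: RasterGrid, dirs: np.ndarray, flat: set[tuple[int, int]]) -> None:
    """Assign directions inside flats toward their spill points.

    BFS seeded from equal-elevation neighbors that already drain; each
    flat cell points at the neighbor that discovered it, so paths lead
    monotonically toward the flat's exit.
    """
    rows, cols = dem.shape
    z = dem.values
    queue: deque[tuple[int, int]] = deque()
    seeded = set()
    for (r, c) in sorted(flat):
        for name, rr, cc in _neighbors(r, c, rows, cols):
            if (rr, cc) not in flat and dirs[rr, cc] not in ("",) and z[rr, cc] == z[r, c]:
                # point toward that draining neighbor
                dirs[r, c] = name
                queue.append((r, c))
                seeded.add((r, c))
                break
    flat -= seeded
    while queue:
        r, c = queue.popleft()
        for name, rr, cc in _neighbors(r, c, rows, cols):
            if (rr, cc) in flat:
                # neighbor drains into (r, c): direction is the reverse
                rev = NEIGHBOR_ORDER[(NEIGHBOR_ORDER.index(name) + 4) % 8]
                dirs[rr, cc] = rev
                flat.discard((rr, cc))
                queue.append((rr, cc))
    if flat:
        r, c = sorted(flat)[0]
        raise FlowError(
            f"cell ({r}, {c}) lies in a flat with no spill point; run fill_depressions first"
        )


def flow_accumulation(dirs: FlowDirectionGrid, include_self: bool = False) -> AccumulationGrid:
    """Count upstream cells draining through each cell.

    ``counts(c)`` is the number of distinct cells whose D8 path passes
    through ``c``, the cell itself excluded unless ``include_self``.
    Raises :class:`FlowError` with a cell coordinate if the direction
    graph contains a cycle.
    """
    rows, cols = dirs.shape
    valid = ~dirs.nodata_mask
    counts = np.zeros((rows, cols), dtype=np.int64)
    indeg = np.zeros((rows, cols), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            rec = dirs.receiver(r, c)
            if rec is not None:
                indeg[rec] += 1
    queue = deque((r, c) for r in range(rows) for c in range(cols) if valid[r, c] and indeg[r, c] == 0)
    processed = 0
    while queue:
        r, c = queue.popleft()
        processed += 1
        rec = dirs.receiver(r, c)
        if rec is not None:
            counts[rec] += counts[r, c] + 1
            indeg[rec] -= 1
            if indeg[rec] == 0:
                queue.append(rec)
    if processed != int(valid.sum()):
        stuck = np.argwhere(valid & (indeg > 0))
        r, c = (int(stuck[0][0]), int(stuck[0][1])) if len(stuck) else (-1, -1)
        raise FlowError(f"cyclic flow detected involving cell ({r}, {c})")
    if include_self:
        counts = counts + valid.astype(np.int64)
    return AccumulationGrid(counts=counts, cell_size=dirs.cell_size, nodata_mask=dirs.nodata_mask)


def convexity(dem: RasterGrid, edge: str = "nodata") -> ConvexityGrids:
    """Longitudinal and cross-sectional convexity from a 3×3 quadratic fit.

    Second derivatives come from central finite differences at spacing
    ``cell_size`` (the Zevenbergen–Thorne local quadratic, exact for
    quadratic surfaces).  Longitudinal convexity is minus the second
    directional derivative along the gradient (downslope) direction;
    cross-sectional convexity is minus the second derivative
    perpendicular to it.  The sign flip makes concave forms (valleys,
    hollows, where water stagnates) negative and convex forms (domes,
    noses) positive.

    Cells with zero gradient take the unrotated second derivatives
    (north–south for longitudinal, east–west for cross-sectional),
    signed the same way, so symmetric valley floors and dome crests are
    still scored.  Boundary cells (and cells whose 3×3 neighborhood
    touches nodata) are nodata unless ``edge="reflect"``.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise RasterError(f"convexity requires a grid of at least 3x3, got {dem.shape}")
    if edge not in ("nodata", "reflect"):
        raise RasterError(f"unknown edge policy {edge!r}")
    L = dem.cell_size
    z = np.where(dem.valid_mask, dem.values, np.nan)
    if edge == "reflect":
        pad = np.pad(z, 1, mode="reflect")
    else:
        pad = np.pad(z, 1, mode="constant", constant_values=np.nan)
    zN = pad[:-2, 1:-1]
    zS = pad[2:, 1:-1]
    zW = pad[1:-1, :-2]
    zE = pad[1:-1, 2:]
    zNW = pad[:-2, :-2]
    zNE = pad[:-2, 2:]
    zSW = pad[2:, :-2]
    zSE = pad[2:, 2:]
    zc = z
    with np.errstate(invalid="ignore", divide="ignore"):
        # x east, y north; row index increases southward
        zx = (zE - zW) / (2 * L)
        zy = (zN - zS) / (2 * L)
        zxx = (zE + zW - 2 * zc) / L**2
        zyy = (zN + zS - 2 * zc) / L**2
        zxy = (zNE + zSW - zNW - zSE) / (4 * L**2)
        g2 = zx**2 + zy**2
        dir_along = (zxx * zx**2 + 2 * zxy * zx * zy + zyy * zy**2)
        dir_across = (zxx * zy**2 - 2 * zxy * zx * zy + zyy * zx**2)
        long_c = np.where(g2 > 0, -dir_along / np.where(g2 > 0, g2, 1.0), -zyy)
        cross_c = np.where(g2 > 0, -dir_across / np.where(g2 > 0, g2, 1.0), -zxx)
    mask = dem.nodata_mask | np.isnan(long_c) | np.isnan(cross_c)
    long_c = np.where(mask, np.nan, long_c)
    cross_c = np.where(mask, np.nan, cross_c)
    return ConvexityGrids(
        longitudinal=long_c,
        cross_sectional=cross_c,
        cell_size=dem.cell_size,
        nodata_mask=mask,
    )
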