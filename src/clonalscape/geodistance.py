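"""Water-constrained least-cost distances and the max-of-Euclidean rule.

Cost distances are shortest paths on the 8-neighbour graph of water cells
(orthogonal step = cell size, diagonal = cell size * sqrt(2)); land is
impassable and unreachable pairs come back as +inf.  Because a raster walk
underestimates short straight-line separations, the working distance for
downstream analyses is the entrywise maximum of Euclidean and cost
distances.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

from .genotype_io import WaterGrid

logger = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))


def euclidean_distance(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return cdist(points, points)


def nearest_water_cell(grid: WaterGrid, x: float, y: float) -> tuple[int, int]:
    """Water cell whose center is Euclidean-nearest to (x, y).

    Deterministic tie-break: row-major order (smallest row, then column).
    """
    water = np.argwhere(grid.conductance == 1)
    if water.size == 0:
        raise ValueError("grid contains no water cells")
    centers = np.array([grid.center_of(r, c) for r, c in water])
    d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
    best = d2.min()
    ties = np.flatnonzero(np.isclose(d2, best))
    r, c = water[ties[0]]  # argwhere is already row-major sorted
    return int(r), int(c)


def snap_to_water(grid: WaterGrid, points: np.ndarray) -> list[tuple[int, int]]:
    """Map points to containing water cells, snapping land/outside points."""
    cells = []
    for x, y in np.asarray(points, dtype=float):
        try:
            r, c = grid.cell_of(x, y)
        except ValueError:
            r, c = nearest_water_cell(grid, x, y)
        if grid.conductance[r, c] == 0:
            r, c = nearest_water_cell(grid, x, y)
        cells.append((r, c))
    return cells


def site_centroids(sample_xy: np.ndarray, site_labels, grid: WaterGrid | None,
                   ) -> dict[str, tuple[float, float]]:
    """Mean sample coordinates per site, snapped to water when on land."""
    sample_xy = np.asarray(sample_xy, dtype=float)
    site_labels = np.asarray(site_labels)
    out = {}
    for site in sorted(set(site_labels)):
        pts = sample_xy[site_labels == site]
        cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
        if grid is not None:
            try:
                r, c = grid.cell_of(cx, cy)
                on_water = grid.conductance[r, c] == 1
            except ValueError:
                on_water = False
            if not on_water:
                r, c = nearest_water_cell(grid, cx, cy)
                cx, cy = grid.center_of(r, c)
                logger.info("centroid of site %s snapped to water", site)
        out[site] = (float(cx), float(cy))
    return out


def _water_graph(grid: WaterGrid):
    """Sparse 8-neighbour adjacency over water cells (cell-size weights)."""
    cond = grid.conductance
    nrows, ncols = cond.shape
    node = -np.ones((nrows, ncols), dtype=np.int64)
    water = np.argwhere(cond == 1)
    node[water[:, 0], water[:, 1]] = np.arange(len(water))
    rows, cols, data = [], [], []
    steps = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)]
    for dr, dc, cost in steps:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a, b = node[r0, c0], node[r1, c1]
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok]); cols.append(b[ok])
        data.append(np.full(int(ok.sum()), cost * grid.cell_size))
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    data = np.concatenate(data)
    n = len(water)
    graph = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return graph, node


def cost_distance(grid: WaterGrid, points: np.ndarray) -> np.ndarray:
    """All-pairs least-cost distance through water between point locations.

    Points are snapped to their containing cell (nearest water cell when on
    land); distances are between cell centers.  Unreachable pairs are +inf.
    """
    cells = snap_to_water(grid, points)
    graph, node = _water_graph(grid)
    sources = np.array([node[r, c] for r, c in cells])
    uniq, inv = np.unique(sources, return_inverse=True)
    dmat = dijkstra(graph, directed=False, indices=uniq)
    out = dmat[inv][:, sources]
    # symmetrise exactly (Dijkstra is symmetric up to float noise here)
    out = np.minimum(out, out.T)
    np.fill_diagonal(out, 0.0)
    return out


def combined_distance(euclid: np.ndarray, cost: np.ndarray) -> np.ndarray:
    """Entrywise maximum of Euclidean and cost distances."""
    euclid = np.asarray(euclid, dtype=float)
    cost = np.asarray(cost, dtype=float)
    if euclid.shape != cost.shape:
        raise ValueError("distance matrices must have matching shape")
    if np.isinf(cost).any():
        logger.warning("unreachable pairs in cost matrix propagate as +inf")
    return np.maximum(euclid, cost)
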