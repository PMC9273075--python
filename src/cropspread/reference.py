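"""Reference shortest-path distances via an explicit edge list and networkx.

Deliberately independent of the production Dijkstra kernel: the 16-neighbour
graph is enumerated edge by edge and solved with
:func:`networkx.single_source_dijkstra_path_length`.  The synthetic-data
generator uses this path so that agreement between generated arrival dates and
the production cost-accumulation is a genuine cross-check, and the test suite
uses it as the oracle for `accumulate_cost`.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .raster import NODATA, ClassRaster, validate_costs

# Same stencil definition, enumerated independently of the numba kernel.
_MOVES = (
    [(dr, dc, 1.0) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
    + [(dr, dc, math.sqrt(2.0)) for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1))]
    + [
        (dr, dc, math.sqrt(5.0))
        for dr, dc in (
            (-1, -2), (-1, 2), (1, -2), (1, 2),
            (-2, -1), (-2, 1), (2, -1), (2, 1),
        )
    ]
)


def edge_list(raster: ClassRaster, costs: np.ndarray) -> list[tuple[tuple, tuple, float]]:
    """Explicit (cell_a, cell_b, weight) list for the 16-neighbour grid graph."""
    costs = validate_costs(costs, raster.n_classes)
    n_rows, n_cols = raster.classes.shape
    cls = raster.classes
    cell = raster.cell_size
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            if cls[r, c] == NODATA:
                continue
            fa = costs[cls[r, c]]
            for dr, dc, length in _MOVES:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < n_rows and 0 <= c2 < n_cols):
                    continue
                if cls[r2, c2] == NODATA:
                    continue
                fb = costs[cls[r2, c2]]
                edges.append(((r, c), (r2, c2), length * cell * 0.5 * (fa + fb)))
    return edges


def reference_distances(
    raster: ClassRaster, costs: np.ndarray, origin_cell: tuple[int, int]
) -> np.ndarray:
    """Distance grid (km) from ``origin_cell``; inf where unreachable."""
    g = nx.Graph()
    g.add_nodes_from(
        (r, c)
        for r in range(raster.n_rows)
        for c in range(raster.n_cols)
        if raster.classes[r, c] != NODATA
    )
    g.add_weighted_edges_from(edge_list(raster, costs))
    if tuple(origin_cell) not in g:
        raise ValueError(f"origin cell {origin_cell} is nodata or outside the raster")
    lengths = nx.single_source_dijkstra_path_length(g, tuple(origin_cell))
    dist = np.full(raster.classes.shape, np.inf)
    for (r, c), d in lengths.items():
        dist[r, c] = d
    return dist
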