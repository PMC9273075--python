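"""Numba kernel for single-source shortest paths on a grid with the knight's-move stencil.

The graph is implicit: every cell connects to its 4 orthogonal, 4 diagonal and
8 knight's-move neighbours (16 directions).  The weight of the edge between
cells a and b is

    euclid(a, b) * cell_size * (f(a) + f(b)) / 2

with euclid in {1, sqrt(2), sqrt(5)} and f the per-cell friction.  Cells with
infinite friction (nodata) are disconnected.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# 16-direction stencil: (drow, dcol, geometric step length in cells)
_OFFSETS = np.array(
    [
        (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
        (-1, -1, math.sqrt(2.0)), (-1, 1, math.sqrt(2.0)),
        (1, -1, math.sqrt(2.0)), (1, 1, math.sqrt(2.0)),
        (-1, -2, math.sqrt(5.0)), (-1, 2, math.sqrt(5.0)),
        (1, -2, math.sqrt(5.0)), (1, 2, math.sqrt(5.0)),
        (-2, -1, math.sqrt(5.0)), (-2, 1, math.sqrt(5.0)),
        (2, -1, math.sqrt(5.0)), (2, 1, math.sqrt(5.0)),
    ],
    dtype=np.float64,
)

OFFSETS_RC = _OFFSETS[:, :2].astype(np.int64)
OFFSETS_LEN = np.ascontiguousarray(_OFFSETS[:, 2])


@njit(cache=True)
def _heap_push(heap_d, heap_i, size, d, i):
    heap_d[size] = d
    heap_i[size] = i
    child = size
    while child > 0:
        parent = (child - 1) >> 1
        if heap_d[child] < heap_d[parent]:
            heap_d[child], heap_d[parent] = heap_d[parent], heap_d[child]
            heap_i[child], heap_i[parent] = heap_i[parent], heap_i[child]
            child = parent
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(heap_d, heap_i, size):
    d = heap_d[0]
    i = heap_i[0]
    size -= 1
    heap_d[0] = heap_d[size]
    heap_i[0] = heap_i[size]
    parent = 0
    while True:
        left = 2 * parent + 1
        if left >= size:
            break
        right = left + 1
        small = left
        if right < size and heap_d[right] < heap_d[left]:
            small = right
        if heap_d[small] < heap_d[parent]:
            heap_d[small], heap_d[parent] = heap_d[parent], heap_d[small]
            heap_i[small], heap_i[parent] = heap_i[parent], heap_i[small]
            parent = small
        else:
            break
    return d, i, size


@njit(cache=True)
def grid_dijkstra(friction, cell_size, origin_row, origin_col, offsets_rc, offsets_len):
    """Accumulated weighted distance (km) from one origin cell to every cell.

    ``friction`` holds per-cell relative cost; ``np.inf`` marks nodata.
    Returns a float64 grid of distances, ``np.inf`` where unreachable.
    """
    n_rows, n_cols = friction.shape
    n = n_rows * n_cols
    dist = np.full(n, np.inf)
    # lazy-deletion binary heap; every edge relaxation may push once
    cap = 18 * n + 16
    heap_d = np.empty(cap)
    heap_i = np.empty(cap, dtype=np.int64)
    size = 0

    origin = origin_row * n_cols + origin_col
    dist[origin] = 0.0
    size = _heap_push(heap_d, heap_i, size, 0.0, origin)

    n_off = offsets_rc.shape[0]
    while size > 0:
        d, u, size = _heap_pop(heap_d, heap_i, size)
        if d > dist[u]:
            continue
        ur = u // n_cols
        uc = u - ur * n_cols
        fu = friction[ur, uc]
        for k in range(n_off):
            vr = ur + offsets_rc[k, 0]
            vc = uc + offsets_rc[k, 1]
            if vr < 0 or vr >= n_rows or vc < 0 or vc >= n_cols:
                continue
            fv = friction[vr, vc]
            if not np.isfinite(fv):
                continue
            nd = d + offsets_len[k] * cell_size * 0.5 * (fu + fv)
            v = vr * n_cols + vc
            if nd < dist[v]:
                dist[v] = nd
                size = _heap_push(heap_d, heap_i, size, nd, v)
    return dist.reshape(n_rows, n_cols)
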