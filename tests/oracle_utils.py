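"""Independent brute-force oracles shared by the test suite.

These implementations deliberately avoid the package's own algorithms: the
arrival-time oracle is a 26-neighbor Dijkstra shortest path on the voxel
graph (scipy.sparse.csgraph), the Hausdorff oracle is an O(n^2) all-pairs
scan, and mask generators build random geometry directly.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

#: worst-case overestimate of the 26-neighborhood chamfer metric with exact
#: Euclidean edge weights over the true geodesic (attained near direction
#: (9, 4, 3): (3*sqrt(3) + sqrt(2) + 5) / sqrt(106) = 1.1281...)
CHAMFER_26 = float((3 * np.sqrt(3) + np.sqrt(2) + 5) / np.sqrt(106))

_OFFSETS = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def dijkstra_arrival_times(F: np.ndarray, spacing: np.ndarray, src_idx) -> np.ndarray:
    """Arrival times by 26-neighbor Dijkstra; edge cost = length x mean slowness."""
    inside = F > 0
    coords = np.argwhere(inside)
    n = len(coords)
    lut = -np.ones(F.shape, dtype=int)
    lut[tuple(coords.T)] = np.arange(n)
    rows, cols, w = [], [], []
    for off in _OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < np.array(F.shape)), axis=1)
        a, b = coords[ok], nb[ok]
        okk = inside[tuple(b.T)]
        a, b = a[okk], b[okk]
        d = np.linalg.norm(np.asarray(off) * spacing)
        cost = d * 0.5 * (1.0 / F[tuple(a.T)] + 1.0 / F[tuple(b.T)])
        rows.append(lut[tuple(a.T)])
        cols.append(lut[tuple(b.T)])
        w.append(cost)
    g = sparse.coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    D = dijkstra(g, indices=lut[tuple(src_idx)])
    out = np.full(F.shape, np.inf)
    out[tuple(coords.T)] = D
    return out


def hausdorff_bruteforce(bx: np.ndarray, by: np.ndarray) -> float:
    """All-pairs Hausdorff distance between boundary voxel centers (voxels)."""
    from scipy import ndimage

    def boundary(m):
        er = ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1))
        return np.argwhere(m & ~er).astype(float)

    px, py = boundary(bx), boundary(by)
    dmat = np.linalg.norm(px[:, None, :] - py[None, :, :], axis=2)
    return float(max(dmat.min(axis=1).max(), dmat.min(axis=0).max()))


def random_blob_mask(rng: np.random.Generator, n: int = 20) -> np.ndarray:
    """Connected union of three overlapping random balls in an n^3 grid."""
    mask = np.zeros((n, n, n), dtype=bool)
    centers = [rng.integers(6, n - 6, 3)]
    for _ in range(2):
        centers.append(np.clip(centers[-1] + rng.integers(-4, 5, 3), 4, n - 5))
    idx = np.indices((n, n, n)).reshape(3, -1).T
    for c in centers:
        r = rng.uniform(4.0, 6.5)
        mask |= (np.linalg.norm(idx - c, axis=1) <= r).reshape(n, n, n)
    return mask
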