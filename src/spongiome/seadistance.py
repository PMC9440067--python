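"""Depth-constrained least-cost sea distances and distance-decay statistics.

A bathymetry raster is turned into a navigation graph over cells at
least ``depth_threshold_m`` below sea level; sites are snapped to the
nearest navigable cell and pairwise distances found by Dijkstra with
great-circle edge weights. Distance decay regresses log10 community
dissimilarity on log10 sea distance and runs a Mantel permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from spongiome.data import DistanceMatrix, InputError, ParameterError
from spongiome.stats import mantel_test
from spongiome.synthetic import BathymetryGrid, haversine_km

logger = logging.getLogger(__name__)

# 8-neighbourhood plus knight moves for the 16-neighbour graph
_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_16 = _OFFSETS_8 + [(-2, -1), (-2, 1), (-1, -2), (-1, 2),
                            (1, -2), (1, 2), (2, -1), (2, 1)]


@dataclass
class SeaGraph:
    """Sparse navigation graph over the navigable cells of a grid."""

    grid: BathymetryGrid
    depth_threshold_m: float
    node_rc: np.ndarray          # node -> (row, col)
    node_of_cell: np.ndarray     # rows x cols -> node index or -1
    adjacency: "coo_matrix"

    @property
    def n_nodes(self) -> int:
        return len(self.node_rc)


def build_sea_graph(
    grid: BathymetryGrid,
    depth_threshold_m: float = 200.0,
    neighbourhood: int = 16,
    wrap_longitude: bool = False,
) -> SeaGraph:
    """Connect all navigable cells with great-circle-weighted edges."""
    if neighbourhood not in (8, 16):
        raise ParameterError("neighbourhood must be 8 or 16")
    mask = grid.navigable_mask(depth_threshold_m)
    rows, cols = grid.shape
    node_of_cell = np.full((rows, cols), -1, dtype=np.int64)
    rc = np.argwhere(mask)
    node_of_cell[rc[:, 0], rc[:, 1]] = np.arange(len(rc))
    offsets = _OFFSETS_8 if neighbourhood == 8 else _OFFSETS_16
    src, dst, wts = [], [], []
    for dr, dc in offsets:
        r0 = rc[:, 0] + dr
        c0 = rc[:, 1] + dc
        if wrap_longitude:
            c0 = c0 % cols
            ok = (r0 >= 0) & (r0 < rows)
        else:
            ok = (r0 >= 0) & (r0 < rows) & (c0 >= 0) & (c0 < cols)
        a = np.nonzero(ok)[0]
        if not len(a):
            continue
        nb = node_of_cell[r0[a], c0[a]]
        good = nb >= 0
        a, nb = a[good], nb[good]
        if not len(a):
            continue
        lat1 = grid.lats[rc[a, 0]]
        lon1 = grid.lons[rc[a, 1]]
        lat2 = grid.lats[rc[nb, 0]]
        lon2 = grid.lons[rc[nb, 1]]
        w = _haversine_vec(lat1, lon1, lat2, lon2)
        src.append(a)
        dst.append(nb)
        wts.append(w)
    if src:
        src = np.concatenate(src)
        dst = np.concatenate(dst)
        wts = np.concatenate(wts)
    else:
        src = dst = np.array([], dtype=np.int64)
        wts = np.array([], dtype=float)
    adj = coo_matrix((wts, (src, dst)), shape=(len(rc), len(rc)))
    return SeaGraph(grid, depth_threshold_m, rc, node_of_cell, adj)


def _haversine_vec(lat1, lon1, lat2, lon2) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * 6371.0088 * np.arcsin(np.sqrt(a))


def snap_site(graph: SeaGraph, lat: float, lon: float,
              max_snap_km: float = 100.0, name: str | None = None) -> int:
    """Nearest navigable node to a site, or an error naming the site."""
    if graph.n_nodes == 0:
        raise InputError("no navigable cells at this depth threshold")
    lats = graph.grid.lats[graph.node_rc[:, 0]]
    lons = graph.grid.lons[graph.node_rc[:, 1]]
    d = _haversine_vec(np.full(len(lats), lat), np.full(len(lats), lon),
                       lats, lons)
    k = int(np.argmin(d))
    if d[k] > max_snap_km:
        raise InputError(
            f"site {name or (lat, lon)} is {d[k]:.1f} km from the nearest "
            f"navigable cell (max_snap_km={max_snap_km})"
        )
    return k


def least_cost_distances(
    grid: BathymetryGrid,
    sites: list[tuple[float, float]],
    depth_threshold_m: float = 200.0,
    neighbourhood: int = 16,
    max_snap_km: float = 100.0,
    site_ids: list[str] | None = None,
    wrap_longitude: bool = False,
) -> DistanceMatrix:
    """Pairwise shortest sea-path distances (km) between sites.

    Unreachable pairs are flagged ``+inf`` with a warning.
    """
    if len(sites) < 2:
        raise InputError("need at least 2 sites")
    ids = site_ids or [f"site_{i}" for i in range(len(sites))]
    graph = build_sea_graph(grid, depth_threshold_m, neighbourhood,
                            wrap_longitude)
    nodes = [snap_site(graph, lat, lon, max_snap_km, name)
             for (lat, lon), name in zip(sites, ids)]
    dist_from = dijkstra(graph.adjacency.tocsr(), directed=False,
                         indices=sorted(set(nodes)))
    row_of = {n: i for i, n in enumerate(sorted(set(nodes)))}
    n = len(sites)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist_from[row_of[nodes[i]], nodes[j]]
            if not np.isfinite(d):
                logger.warning("sites %s and %s are not connected by sea",
                               ids[i], ids[j])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids, out)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclass
class DecayResult:
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    mantel_r: float
    mantel_p: float
    n_pairs: int
    n_dropped_zero: int


def distance_decay(
    community_dist: DistanceMatrix,
    geo_dist: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> DecayResult:
    """Log-log distance-decay regression plus a two-sided Mantel test.

    Pairs with zero/non-finite geographic distance or non-positive
    community dissimilarity are dropped from the regression (counted in
    ``n_dropped_zero``); the Mantel test uses all finite pairs untransformed.
    """
    if set(community_dist.ids) != set(geo_dist.ids):
        raise InputError("community and geographic matrices have different ids")
    geo = geo_dist.submatrix(community_dist.ids)
    cd = community_dist.condensed()
    gd = geo.condensed()
    finite = np.isfinite(gd) & np.isfinite(cd)
    usable = finite & (gd > 0) & (cd > 0)
    n_dropped = int(finite.sum() - usable.sum())
    if usable.sum() < 3:
        raise InputError(
            f"only {int(usable.sum())} usable pair(s) for the log-log fit"
        )
    x = np.log10(gd[usable])
    y = np.log10(cd[usable])
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    r, p = mantel_test(community_dist, geo, n_permutations=n_permutations,
                       seed=seed, method=method)
    return DecayResult(
        slope=float(slope), intercept=float(intercept), r2=r2,
        adjusted_r2=float(adj), mantel_r=r, mantel_p=p,
        n_pairs=n, n_dropped_zero=n_dropped,
    )


__all__ = [
    "SeaGraph", "DecayResult", "build_sea_graph", "snap_site",
    "least_cost_distances", "distance_decay", "haversine_km",
]
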