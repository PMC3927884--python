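"""Isolation by distance: marine least-cost distances and Mantel tests.

Geographic separation between river mouths is measured along the ocean on a
rasterized land/ocean grid: mouths are snapped to the nearest passable cell
and shortest paths are found on the 8-neighbour graph of ocean cells with
great-circle step lengths (longitude steps shrink with cos(latitude)), so a
path can never cut across land.  Differentiation is linearized as
theta'/(1 - theta') before correlation with distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import linregress, pearsonr

from .genotype_io import RiverMetadata
from .pairwise import PairwiseMatrix

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in km."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


@dataclass
class OceanGrid:
    """Boolean raster, True = ocean (passable); row i, col j maps to
    latitude = lat0 + i * cell_deg, longitude = lon0 + j * cell_deg."""

    mask: np.ndarray
    lat0: float
    lon0: float
    cell_deg: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    def cell_latlon(self, i: int, j: int) -> tuple[float, float]:
        return self.lat0 + i * self.cell_deg, self.lon0 + j * self.cell_deg

    def nearest_ocean_cell(
        self, lat: float, lon: float, snap_radius: int = 3
    ) -> tuple[int, int]:
        i = int(round((lat - self.lat0) / self.cell_deg))
        j = int(round((lon - self.lon0) / self.cell_deg))
        nr, nc = self.mask.shape
        best, best_d = None, np.inf
        for di in range(-snap_radius, snap_radius + 1):
            for dj in range(-snap_radius, snap_radius + 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < nr and 0 <= jj < nc and self.mask[ii, jj]:
                    d = di * di + dj * dj
                    if d < best_d:
                        best, best_d = (ii, jj), d
        if best is None:
            raise ValueError(
                f"no passable cell within {snap_radius} cells of ({lat}, {lon})"
            )
        return best


def _ocean_graph(grid: OceanGrid):
    """Sparse 8-neighbour graph over ocean cells with great-circle weights."""
    nr, nc = grid.mask.shape
    idx = -np.ones((nr, nc), dtype=np.int64)
    cells = np.argwhere(grid.mask)
    idx[cells[:, 0], cells[:, 1]] = np.arange(cells.shape[0])
    rows, cols, wts = [], [], []
    steps = [(0, 1), (1, 0), (1, 1), (1, -1)]  # undirected graph: half-stencil
    lat_cells = grid.lat0 + cells[:, 0] * grid.cell_deg
    lon_cells = grid.lon0 + cells[:, 1] * grid.cell_deg
    for di, dj in steps:
        ii = cells[:, 0] + di
        jj = cells[:, 1] + dj
        ok = (ii >= 0) & (ii < nr) & (jj >= 0) & (jj < nc)
        ok[ok] &= grid.mask[ii[ok], jj[ok]]
        src = idx[cells[ok, 0], cells[ok, 1]]
        dst = idx[ii[ok], jj[ok]]
        la1 = lat_cells[ok]
        lo1 = lon_cells[ok]
        la2 = la1 + di * grid.cell_deg
        lo2 = lo1 + dj * grid.cell_deg
        r1, r2 = np.radians(la1), np.radians(la2)
        dlon = np.radians(lo2 - lo1)
        h = np.sin((r2 - r1) / 2) ** 2 + np.cos(r1) * np.cos(r2) * np.sin(dlon / 2) ** 2
        w = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
        rows.append(src)
        cols.append(dst)
        wts.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    wts = np.concatenate(wts)
    n = cells.shape[0]
    graph = coo_matrix(
        (np.concatenate([wts, wts]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    return graph, idx


def marine_distance_matrix(
    grid: OceanGrid, mouths: list[RiverMetadata], snap_radius: int = 3
) -> PairwiseMatrix:
    """Along-ocean shortest-path distances (km) between river mouths."""
    graph, idx = _ocean_graph(grid)
    nodes = []
    for m in mouths:
        i, j = grid.nearest_ocean_cell(m.latitude, m.longitude, snap_radius)
        nodes.append(idx[i, j])
    dmat = dijkstra(graph, indices=nodes)
    vals = dmat[:, nodes]
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    if not np.isfinite(vals).all():
        bad_i, bad_j = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"no ocean path between {mouths[bad_i].river_code} and "
            f"{mouths[bad_j].river_code}"
        )
    return PairwiseMatrix([m.river_code for m in mouths], vals, "marine_km")


def linearize(theta_prime: PairwiseMatrix) -> PairwiseMatrix:
    """Rousset linearization x -> x / (1 - x); values of exactly 1 are
    excluded (set to NaN) with a warning."""
    v = theta_prime.values.copy()
    ones = np.isclose(v, 1.0)
    if ones.any():
        warnings.warn(
            f"{int(ones.sum() // 2)} pair(s) with differentiation == 1 excluded "
            "from linearization"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ones, np.nan, v / (1.0 - v))
    np.fill_diagonal(out, 0.0)
    return PairwiseMatrix(
        theta_prime.labels, out, f"{theta_prime.statistic_name}_linearized"
    )


@dataclass
class MantelResult:
    r: float
    p: float
    slope: float
    intercept: float
    n_permutations: int
    tail: str


def mantel(
    dist: PairwiseMatrix,
    gen: PairwiseMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel correlation between two labelled matrices.

    r is the Pearson correlation of upper-triangle entries; the null is built
    by simultaneously permuting rows and columns of the second matrix.  The
    default tail tests for positive association (the IBD hypothesis); the OLS
    slope/intercept of gen on dist are reported for the IBD regression.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set(dist.labels) != set(gen.labels):
        raise ValueError("label sets differ")
    gen = gen.reorder(dist.labels)
    n = dist.n
    if n < 4:
        raise ValueError("need >= 4 populations")
    iu = np.triu_indices(n, k=1)
    x = dist.values[iu]
    y = gen.values[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    r_obs = float(pearsonr(x, y)[0])
    fit = linregress(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    g = gen.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = g[np.ix_(perm, perm)][iu][ok]
        r_perm = float(pearsonr(x, yp)[0])
        if tail == "greater":
            hits += r_perm >= r_obs - 1e-12
        elif tail == "two-sided":
            hits += abs(r_perm) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown tail {tail!r}")
    return MantelResult(
        r=r_obs,
        p=(hits + 1) / (n_perm + 1),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_permutations=n_perm,
        tail=tail,
    )
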