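"""Marine grid distances, linearization, and Mantel tests."""

import heapq

import numpy as np
import pytest

from stockpriority.genotype_io import RiverMetadata
from stockpriority.ibd import (
    OceanGrid,
    great_circle_km,
    linearize,
    mantel,
    marine_distance_matrix,
)
from stockpriority.pairwise import PairwiseMatrix
from stockpriority.synthetic_data import simulate_coastline


def _dijkstra_oracle(grid: OceanGrid, start: tuple, goal: tuple) -> float:
    """Plain heapq Dijkstra over ocean cells, 8-neighbour, great-circle steps."""
    nr, nc = grid.mask.shape
    dist = {start: 0.0}
    heap = [(0.0, start)]
    seen = set()
    while heap:
        d, cell = heapq.heappop(heap)
        if cell == goal:
            return d
        if cell in seen:
            continue
        seen.add(cell)
        i, j = cell
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if 0 <= ii < nr and 0 <= jj < nc and grid.mask[ii, jj]:
                    w = great_circle_km(
                        *grid.cell_latlon(i, j), *grid.cell_latlon(ii, jj)
                    )
                    nd = d + w
                    if nd < dist.get((ii, jj), np.inf):
                        dist[(ii, jj)] = nd
                        heapq.heappush(heap, (nd, (ii, jj)))
    return np.inf


def test_grid_paths_match_dijkstra_oracle(rng):
    """Sparse-graph shortest paths equal a hand-rolled Dijkstra exactly."""
    grid, mouths = simulate_coastline(n_rivers=4, grid_size=40, seed=5)
    dm = marine_distance_matrix(grid, mouths)
    cells = [
        grid.nearest_ocean_cell(m.latitude, m.longitude) for m in mouths
    ]
    for a in range(len(mouths)):
        for b in range(a + 1, len(mouths)):
            oracle = _dijkstra_oracle(grid, cells[a], cells[b])
            assert dm.values[a, b] == pytest.approx(oracle, rel=1e-9)


def test_straight_channel_close_to_great_circle():
    mask = np.ones((60, 5), bool)  # pure ocean strip
    grid = OceanGrid(mask, lat0=40.0, lon0=-70.0, cell_deg=0.05)
    mouths = [
        RiverMetadata("S", 40.0, -69.9),
        RiverMetadata("N", 40.0 + 59 * 0.05, -69.9),
    ]
    dm = marine_distance_matrix(grid, mouths)
    gc = great_circle_km(40.0, -69.9, 40.0 + 59 * 0.05, -69.9)
    assert dm.values[0, 1] >= gc - 1e-9
    assert dm.values[0, 1] <= gc * 1.05


def test_same_mouth_zero_and_land_barrier_error():
    mask = np.ones((20, 20), bool)
    mask[:, 10] = False  # meridional wall of land
    grid = OceanGrid(mask, 40.0, -70.0, 0.1)
    west = RiverMetadata("W", 40.5, -69.5)
    east = RiverMetadata("E", 40.5, -68.2)
    same = marine_distance_matrix(grid, [west, RiverMetadata("W2", 40.5, -69.5)])
    assert same.values[0, 1] == 0.0
    with pytest.raises(ValueError, match="no ocean path"):
        marine_distance_matrix(grid, [west, east])


def test_triangle_inequality_and_ge_great_circle():
    grid, mouths = simulate_coastline(n_rivers=5, grid_size=50, seed=8)
    dm = marine_distance_matrix(grid, mouths)
    v = dm.values
    n = len(mouths)
    for i in range(n):
        for j in range(n):
            if i != j:
                gc = great_circle_km(
                    mouths[i].latitude, mouths[i].longitude,
                    mouths[j].latitude, mouths[j].longitude,
                )
                assert v[i, j] >= gc - 1e-6
            for k in range(n):
                assert v[i, j] <= v[i, k] + v[k, j] + 1e-9


def test_linearize_values():
    m = PairwiseMatrix(list("abc"), np.array(
        [[0, 0.5, 0.233], [0.5, 0, 0.0], [0.233, 0.0, 0]]
    ))
    lin = linearize(m)
    assert lin.values[0, 1] == pytest.approx(1.0)
    assert lin.values[0, 2] == pytest.approx(0.3038, abs=2e-4)
    assert lin.values[1, 2] == 0.0
    sat = PairwiseMatrix(list("ab"), np.array([[0, 1.0], [1.0, 0]]))
    with pytest.warns(UserWarning, match="excluded"):
        lin2 = linearize(sat)
    assert np.isnan(lin2.values[0, 1])


def test_mantel_perfect_linear_and_invariance(rng):
    n = 8
    pts = rng.uniform(size=n)
    d = np.abs(pts[:, None] - pts[None])
    labels = [f"r{i}" for i in range(n)]
    dist = PairwiseMatrix(labels, d)
    gen = PairwiseMatrix(labels, 0.2 + 3.0 * d)
    res = mantel(dist, gen, n_perm=199, seed=1)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(3.0)
    assert res.p <= 0.05
    # relabeling both matrices identically leaves r unchanged
    perm = rng.permutation(n)
    rl = [labels[i] for i in perm]
    dist2 = PairwiseMatrix(rl, d[np.ix_(perm, perm)])
    gen2 = PairwiseMatrix(rl, (0.2 + 3.0 * d)[np.ix_(perm, perm)])
    res2 = mantel(dist2, gen2, n_perm=199, seed=1)
    assert res2.r == pytest.approx(res.r)


def test_mantel_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import mantel as sk_mantel

    n = 7
    a = rng.uniform(size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    b = a + rng.normal(0, 0.1, size=(n, n))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    b = np.abs(b)
    labels = [str(i) for i in range(n)]
    ours = mantel(PairwiseMatrix(labels, a), PairwiseMatrix(labels, b), n_perm=99)
    theirs_r, _, _ = sk_mantel(a, b, permutations=0)
    assert ours.r == pytest.approx(float(theirs_r), abs=1e-10)


def test_mantel_degenerate_inputs(rng):
    labels = list("abcd")
    d = np.abs(rng.normal(size=(4, 4)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    dist = PairwiseMatrix(labels, d)
    with pytest.raises(ValueError):
        mantel(dist, dist, n_perm=0)
    const = PairwiseMatrix(labels, np.ones((4, 4)) - np.eye(4))
    with pytest.raises(ValueError, match="constant"):
        mantel(const, dist, n_perm=9)
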