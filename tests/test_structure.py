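"""Admixture Gibbs sampler, K selection, hierarchical scan, PCoA."""

import numpy as np
import pytest

from stockpriority.pairwise import PairwiseMatrix
from stockpriority.structure_model import (
    admixture_gibbs,
    assignment_accuracy,
    align_to_reference,
    hierarchical_scan,
    pcoa,
    select_k,
)
from stockpriority.synthetic_data import GenotypeSimSpec, simulate_genotypes


def test_k1_forces_full_assignment(structured_dataset):
    ds, _ = structured_dataset
    res = admixture_gibbs(ds, 1, burn_in=50, reps=100, seed=1)
    assert np.allclose(res.q, 1.0)
    assert np.isfinite(res.ln_prob_k)


def test_fixed_seed_is_deterministic(structured_dataset):
    ds, _ = structured_dataset
    a = admixture_gibbs(ds, 2, burn_in=50, reps=150, seed=7)
    b = admixture_gibbs(ds, 2, burn_in=50, reps=150, seed=7)
    np.testing.assert_array_equal(a.q, b.q)
    np.testing.assert_array_equal(a.log_likelihoods, b.log_likelihoods)


def test_recovers_simulated_stocks(structured_dataset):
    ds, truth = structured_dataset
    res = admixture_gibbs(ds, 3, burn_in=300, reps=600, seed=5)
    assert assignment_accuracy(res, truth["stock"]) >= 0.9


def test_correlated_model_runs_and_recovers(structured_dataset):
    ds, truth = structured_dataset
    res = admixture_gibbs(ds, 3, burn_in=300, reps=600, model="correlated", seed=5)
    assert assignment_accuracy(res, truth["stock"]) >= 0.85


def test_label_alignment_matches_replicates(structured_dataset):
    ds, _ = structured_dataset
    a = admixture_gibbs(ds, 3, burn_in=200, reps=400, seed=1)
    b = admixture_gibbs(ds, 3, burn_in=200, reps=400, seed=2)
    aligned = align_to_reference(b, a)
    # after alignment the hard assignments mostly agree
    agree = (aligned.hard_assignment == a.hard_assignment).mean()
    assert agree >= 0.9


def test_select_k_preconditions(structured_dataset):
    ds, _ = structured_dataset
    with pytest.raises(ValueError, match="replicates"):
        select_k(ds, range(1, 5), n_replicates=2, burn_in=10, reps=20)
    with pytest.raises(ValueError, match="range"):
        select_k(ds, [1, 2], n_replicates=3, burn_in=10, reps=20)


def test_sampler_errors():
    ds, _ = simulate_genotypes(
        GenotypeSimSpec(n_stocks=1, rivers_per_stock=1, individuals_per_river=5, seed=0)
    )
    with pytest.raises(ValueError, match="exceeds"):
        admixture_gibbs(ds, 10, burn_in=5, reps=10)
    with pytest.raises(ValueError):
        admixture_gibbs(ds, 0, burn_in=5, reps=10)
    with pytest.raises(ValueError):
        admixture_gibbs(ds, 2, burn_in=5, reps=10, model="nope")


def test_hierarchical_scan_negative_control():
    """Homogeneous stocks show no sub-structure: every sub-scan picks K = 1."""
    ds, _ = simulate_genotypes(
        GenotypeSimSpec(n_stocks=2, rivers_per_stock=4, individuals_per_river=12,
                        f_stock=0.12, f_river=0.01, seed=17)
    )
    top = admixture_gibbs(ds, 2, burn_in=300, reps=600, seed=3)
    scans = hierarchical_scan(ds, top, k_max=3, burn_in=150, reps=400, seed=4)
    subks = [v["sub_k"] for v in scans.values() if v["status"] == "ok"]
    assert subks and all(k == 1 for k in subks)


def test_hierarchical_scan_positive_control():
    """Strongly diverged rivers inside a stock are found by the sub-scan."""
    ds, _ = simulate_genotypes(
        GenotypeSimSpec(n_stocks=2, rivers_per_stock=2, individuals_per_river=20,
                        f_stock=0.15, f_river=0.08, seed=19)
    )
    top = admixture_gibbs(ds, 2, burn_in=300, reps=600, seed=3)
    scans = hierarchical_scan(ds, top, k_max=3, burn_in=200, reps=500, seed=4)
    subks = [v["sub_k"] for v in scans.values() if v["status"] == "ok"]
    assert subks and any(k >= 2 for k in subks)


def test_hierarchical_scan_single_cluster_noop(structured_dataset):
    ds, _ = structured_dataset
    res = admixture_gibbs(ds, 1, burn_in=20, reps=50, seed=1)
    assert hierarchical_scan(ds, res) == {}


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_collinear_points():
    d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
    res = pcoa(PairwiseMatrix(["a", "b", "c"], d))
    assert res.percent_variation[0] == pytest.approx(100.0)


def test_pcoa_reproduces_euclidean_distances(rng):
    pts = rng.normal(size=(6, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = list("abcdef")
    res = pcoa(PairwiseMatrix(labels, d), n_axes=6)
    coords = res.coordinates.to_numpy()
    d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    np.testing.assert_allclose(d2, d, atol=1e-8)


def test_pcoa_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    pts = rng.normal(size=(8, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    ours = pcoa(PairwiseMatrix([str(i) for i in range(8)], d))
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
    np.testing.assert_allclose(
        ours.percent_variation[:2] / 100,
        theirs.proportion_explained.iloc[:2],
        atol=1e-6,
    )


def test_pcoa_latitude_gradient(rng):
    lats = np.linspace(35, 45, 8)
    vals = np.abs(lats[:, None] - lats[None, :]) * 0.01
    vals += rng.normal(0, 1e-4, vals.shape)
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0)
    res = pcoa(
        PairwiseMatrix([f"r{i}" for i in range(8)], vals),
        latitudes={f"r{i}": lats[i] for i in range(8)},
    )
    assert res.axis1_latitude_r2 >= 0.95
    assert res.axis1_latitude_p < 0.001


def test_plot_admixture_returns_axis(structured_dataset):
    import matplotlib

    matplotlib.use("Agg")
    from stockpriority.structure_model import plot_admixture

    ds, _ = structured_dataset
    res = admixture_gibbs(ds, 2, burn_in=20, reps=50, seed=1)
    ax = plot_admixture(res)
    assert len(ax.patches) > 0


def test_pcoa_degenerate_zero_matrix():
    res = pcoa(PairwiseMatrix(list("abc"), np.zeros((3, 3))))
    assert res.degenerate
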