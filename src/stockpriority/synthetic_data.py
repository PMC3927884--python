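"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three input streams:

* hierarchically structured microsatellite genotypes (a Dirichlet F-model:
  distinct stocks containing weakly differentiated rivers, global FST in the
  few-percent range typical of anadromous fish),
* demographic time series with a linear trend, AR(1) noise and missing years,
* a rasterized coastline (land half-plane with an irregular edge) with river
  mouths spaced along it, for along-ocean distance computation.

All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import Collection, GenotypeDataset, Locus, RiverMetadata
from .ibd import OceanGrid
from .trends import TimeSeries


@dataclass(frozen=True)
class GenotypeSimSpec:
    n_stocks: int = 3
    rivers_per_stock: int = 5
    individuals_per_river: int = 30
    n_loci: int = 12
    alleles_per_locus: int = 8
    f_stock: float = 0.10  # stock-vs-ancestral divergence
    f_river: float = 0.01  # river-vs-stock divergence
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_stock < 1 and 0 <= self.f_river < 1):
            raise ValueError("F parameters must lie in [0, 1)")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if self.alleles_per_locus < 2:
            raise ValueError("need >= 2 alleles per locus")


def _drift(freqs: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One level of the F-model: Dirichlet(p * (1-F)/F) around ``freqs``."""
    if f == 0:
        return freqs.copy()
    conc = np.clip(freqs, 1e-9, None) * (1.0 - f) / f
    out = rng.dirichlet(conc)
    return np.clip(out, 1e-12, None) / np.clip(out, 1e-12, None).sum()


def simulate_genotypes(spec: GenotypeSimSpec) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Hierarchical F-model genotypes under HWE within rivers.

    Ancestral allele frequencies are symmetric-Dirichlet per locus; stock
    frequencies drift from them with variance parameter ``f_stock``, river
    frequencies from their stock with ``f_river``.  Returns the dataset plus
    a truth table (individual, river, stock).
    """
    rng = np.random.default_rng(spec.seed)
    A = spec.alleles_per_locus
    allele_codes = 100 + 2 * np.arange(A)  # fragment lengths, dinucleotide ladder
    loci = [Locus(f"L{j+1:02d}") for j in range(spec.n_loci)]
    ancestral = [rng.dirichlet(np.ones(A)) for _ in range(spec.n_loci)]
    collections, truth = [], []
    for s in range(spec.n_stocks):
        stock_freqs = [_drift(ancestral[j], spec.f_stock, rng) for j in range(spec.n_loci)]
        for r in range(spec.rivers_per_stock):
            river_freqs = [
                _drift(stock_freqs[j], spec.f_river, rng) for j in range(spec.n_loci)
            ]
            code = f"S{s+1}R{r+1}"
            n = spec.individuals_per_river
            geno = np.zeros((n, spec.n_loci, 2), dtype=np.int32)
            for j in range(spec.n_loci):
                draws = rng.choice(A, size=(n, 2), p=river_freqs[j])
                geno[:, j, :] = allele_codes[draws]
            if spec.missing_rate > 0:
                miss = rng.random((n, spec.n_loci)) < spec.missing_rate
                geno[miss] = 0
            collections.append(Collection(code, 2010, geno))
            truth.extend(
                {"individual": f"{code}_{i+1}", "river": code, "stock": f"stock{s+1}"}
                for i in range(n)
            )
    ds = GenotypeDataset(loci, collections, species_label="synthetic")
    return ds, pd.DataFrame(truth)


@dataclass(frozen=True)
class SeriesSimSpec:
    n_years: int = 30
    start_year: int = 1980
    intercept: float = 0.0
    slope: float = -0.5
    ar1_coefficient: float = 0.3
    noise_sd: float = 1.0
    missing_year_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.ar1_coefficient) >= 1:
            raise ValueError("|ar1| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_years < 3:
            raise ValueError("need >= 3 years")


def simulate_series(
    spec: SeriesSimSpec,
    river_code: str = "SIM",
    variable: str = "mean_length",
    sex: str = "pooled",
) -> TimeSeries:
    """Linear trend plus AR(1) noise, with optional missing years."""
    rng = np.random.default_rng(spec.seed)
    years = spec.start_year + np.arange(spec.n_years)
    eps = np.zeros(spec.n_years)
    innov = rng.normal(0.0, spec.noise_sd, spec.n_years)
    for t in range(spec.n_years):
        eps[t] = (spec.ar1_coefficient * eps[t - 1] if t else 0.0) + innov[t]
    vals = spec.intercept + spec.slope * np.arange(spec.n_years) + eps
    if spec.missing_year_prob > 0:
        keep = rng.random(spec.n_years) >= spec.missing_year_prob
        keep[:3] = True  # keep a minimal series
        years, vals = years[keep], vals[keep]
    return TimeSeries(river_code, variable, sex, years, vals)


def simulate_coastline(
    n_rivers: int = 8, grid_size: int = 80, seed: int = 0
) -> tuple[OceanGrid, list[RiverMetadata]]:
    """Synthetic north-south coast: land to the west, ocean to the east.

    The land/ocean boundary is an irregular (random-walk) edge; river mouths
    sit on ocean cells just off the coast, spaced evenly from south to north,
    so along-coast distance ordering matches latitude ordering.
    """
    if grid_size < 20:
        raise ValueError("grid_size must be >= 20")
    rng = np.random.default_rng(seed)
    cell_deg = 0.1
    lat0, lon0 = 35.0, -76.0
    edge = np.empty(grid_size, int)
    edge[0] = grid_size // 3
    for i in range(1, grid_size):
        edge[i] = np.clip(edge[i - 1] + rng.integers(-1, 2), 3, 2 * grid_size // 3)
    mask = np.zeros((grid_size, grid_size), bool)
    for i in range(grid_size):
        mask[i, edge[i]:] = True  # ocean east of the edge
    rows = np.linspace(2, grid_size - 3, n_rivers).astype(int)
    mouths = []
    for k, i in enumerate(rows):
        j = edge[i]  # first ocean cell at that latitude
        lat = lat0 + i * cell_deg
        lon = lon0 + j * cell_deg
        mouths.append(RiverMetadata(f"RIV{k+1:02d}", lat, lon))
    return OceanGrid(mask, lat0, lon0, cell_deg), mouths
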