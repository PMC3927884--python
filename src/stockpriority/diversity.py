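"""Per-river, per-locus genetic diversity statistics.

Implements the quantities reported per river in microsatellite diversity
tables: number of alleles (Na), observed heterozygosity (Ho), Nei's unbiased
expected heterozygosity (He), the Weir–Cockerham single-population inbreeding
coefficient f (FIS), and allelic richness rarefied to a standard sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, Collection, GenotypeDataset


def _locus_alleles(col: Collection, locus_index: int) -> np.ndarray:
    """Flat array of non-missing allele copies at one locus."""
    g = col.genotypes[:, locus_index, :]
    ok = ~(g == MISSING).any(axis=1)
    return g[ok].ravel()


def allele_frequencies(col: Collection, locus_index: int) -> dict[int, float]:
    """Gene-counting allele frequencies (missing genotypes excluded)."""
    alleles = _locus_alleles(col, locus_index)
    if alleles.size == 0:
        raise ValueError(
            f"locus index {locus_index} is entirely missing in {col.river_code}"
        )
    vals, counts = np.unique(alleles, return_counts=True)
    freqs = counts / counts.sum()
    return {int(v): float(f) for v, f in zip(vals, freqs)}


def observed_heterozygosity(col: Collection, locus_index: int) -> float:
    g = col.genotypes[:, locus_index, :]
    ok = ~(g == MISSING).any(axis=1)
    if not ok.any():
        raise ValueError(
            f"locus index {locus_index} is entirely missing in {col.river_code}"
        )
    het = g[ok, 0] != g[ok, 1]
    return float(het.mean())


def unbiased_expected_heterozygosity(col: Collection, locus_index: int) -> float:
    """Nei's small-sample-corrected He = 2n/(2n-1) * (1 - sum p_a^2)."""
    g = col.genotypes[:, locus_index, :]
    ok = ~(g == MISSING).any(axis=1)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(
            f"locus index {locus_index} is entirely missing in {col.river_code}"
        )
    p = np.array(list(allele_frequencies(col, locus_index).values()))
    return float(2 * n / (2 * n - 1) * (1.0 - np.sum(p**2)))


def f_is(col: Collection, locus_index: int) -> float:
    """Weir–Cockerham single-population inbreeding coefficient f.

    Per allele A: c = h_A/2 and b = n/(n-1) [p(1-p) - (2n-1)/(4n) h_A], where
    h_A is the observed frequency of heterozygotes carrying A; then
    f = 1 - sum(c)/sum(b + c).  Monomorphic loci are undefined (NaN).
    """
    g = col.genotypes[:, locus_index, :]
    ok = ~(g == MISSING).any(axis=1)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing individuals for FIS")
    gg = g[ok]
    alleles = np.unique(gg)
    if alleles.size < 2:
        return float("nan")
    b_sum = c_sum = 0.0
    for a in alleles:
        carries = gg == a
        p = carries.mean()  # over 2n gene copies
        h = float(((gg[:, 0] == a) ^ (gg[:, 1] == a)).mean())
        c = h / 2.0
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        b_sum += b
        c_sum += c
    denom = b_sum + c_sum
    if denom == 0:
        return float("nan")
    return float(1.0 - c_sum / denom)


def allelic_richness_rarefied(col: Collection, locus_index: int, g: int) -> float:
    """Expected allele count in a subsample of 2g genes (hypergeometric rarefaction).

    R = sum_a [1 - C(N - N_a, 2g) / C(N, 2g)] with N total sampled genes and
    N_a copies of allele a; evaluated with log-binomials for stability.
    """
    alleles = _locus_alleles(col, locus_index)
    N = alleles.size
    k = 2 * g
    if k > N:
        raise ValueError(
            f"rarefaction size 2g={k} exceeds {N} sampled genes "
            f"({col.river_code}, locus index {locus_index})"
        )
    _, counts = np.unique(alleles, return_counts=True)

    def log_choose(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    r_val = 0.0
    for Na in counts:
        if N - Na < k:
            r_val += 1.0  # allele cannot be missed
        else:
            r_val += 1.0 - np.exp(log_choose(N - Na, k) - log_choose(N, k))
    return float(r_val)


def diversity_table(ds: GenotypeDataset, rarefy_g: int | None = None) -> pd.DataFrame:
    """River x locus grid of n, Na, Ho, He, FIS (and R when ``rarefy_g`` given).

    One row per (river, locus); river means over defined loci are appended
    with locus label ``"mean"``.  Loci entirely missing in a river are skipped.
    """
    rows = []
    for col in ds.collections:
        per_locus = []
        for j, loc in enumerate(ds.loci):
            g = col.genotypes[:, j, :]
            ok = ~(g == MISSING).any(axis=1)
            n = int(ok.sum())
            if n == 0:
                continue
            rec = {
                "river": col.river_code,
                "locus": loc.name,
                "n": n,
                "Na": len(allele_frequencies(col, j)),
                "Ho": observed_heterozygosity(col, j),
                "He": unbiased_expected_heterozygosity(col, j),
                "Fis": f_is(col, j),
            }
            if rarefy_g is not None:
                rec["R"] = (
                    allelic_richness_rarefied(col, j, rarefy_g)
                    if 2 * rarefy_g <= 2 * n
                    else float("nan")
                )
            per_locus.append(rec)
            rows.append(rec)
        if per_locus:
            dfl = pd.DataFrame(per_locus)
            mean_row = {"river": col.river_code, "locus": "mean", "n": dfl["n"].mean()}
            for c in ("Na", "Ho", "He", "Fis", "R"):
                if c in dfl:
                    mean_row[c] = float(dfl[c].mean(skipna=True))
            rows.append(mean_row)
    return pd.DataFrame(rows)
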