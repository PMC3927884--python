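"""Data-conformance screens.

Monte-Carlo exact tests for Hardy–Weinberg equilibrium and linkage
disequilibrium (permutation analogues of the classical Markov-chain exact
tests), sequential-Bonferroni (Holm) correction, and the lnRV / lnRH
comparative neutrality screen for microsatellite loci.

Permutation p-values use add-one smoothing, p = (b + 1) / (n_perm + 1), where
b counts permuted statistics at least as extreme as the observed one; p can
therefore never be 0 and never undercuts the Monte-Carlo resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .diversity import unbiased_expected_heterozygosity
from .genotype_io import MISSING, Collection, GenotypeDataset


@dataclass
class TestResult:
    unit: tuple
    statistic: float
    p_value: float
    n_permutations: int
    status: str = "ok"  # "ok" | "untestable"
    significant_after_holm: bool | None = None


def _nonmissing(col: Collection, j: int) -> np.ndarray:
    g = col.genotypes[:, j, :]
    return g[~(g == MISSING).any(axis=1)]


def _log_genotype_prob_term(pairs: np.ndarray) -> float:
    """Permutation-variant part of Levene's conditional probability.

    For genotype counts n_g and heterozygote count h the conditional
    probability of the genotype array given the allele counts is
    n! 2^h prod(N_a!) / ((2n)! prod(n_g!)); only 2^h / prod(n_g!) varies under
    allele permutation, so the statistic is h*ln2 - sum ln(n_g!).
    """
    a = np.sort(pairs, axis=1)
    code = a[:, 0].astype(np.int64) * 100000 + a[:, 1]
    _, counts = np.unique(code, return_counts=True)
    h = int((pairs[:, 0] != pairs[:, 1]).sum())
    return h * np.log(2.0) - float(gammaln(counts + 1).sum())


def hwe_exact_test(
    col: Collection,
    locus_index: int,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    alternative: str = "prob",
) -> TestResult:
    """Monte-Carlo exact HWE test at one locus of one collection.

    Alleles are permuted among individuals (holding allele counts fixed) and
    re-paired into genotypes.  ``alternative="prob"`` uses Levene's
    conditional probability (small probability = extreme, two-sided in
    spirit); ``alternative="deficit"`` is one-sided against heterozygote
    deficiency (fewer heterozygotes = extreme).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = _nonmissing(col, locus_index)
    n = pairs.shape[0]
    unit = (col.river_code, locus_index)
    if n < 5 or np.unique(pairs).size < 2:
        return TestResult(unit, float("nan"), float("nan"), 0, status="untestable")
    genes = pairs.ravel()
    if alternative == "deficit":
        obs = float((pairs[:, 0] != pairs[:, 1]).sum())
        perms = np.stack([rng.permutation(genes) for _ in range(n_perm)])
        perm_pairs = perms.reshape(n_perm, n, 2)
        stat = (perm_pairs[:, :, 0] != perm_pairs[:, :, 1]).sum(axis=1)
        b = int((stat <= obs).sum())
    elif alternative == "prob":
        obs = _log_genotype_prob_term(pairs)
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(genes).reshape(n, 2)
            if _log_genotype_prob_term(perm) <= obs + 1e-9:
                b += 1
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (b + 1) / (n_perm + 1)
    return TestResult(unit, obs, p, n_perm)


def ld_test(
    col: Collection,
    locus_a: int,
    locus_b: int,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Monte-Carlo exact test of genotypic linkage disequilibrium.

    Statistic: log-likelihood ratio G of the two-locus genotype contingency
    table; null distribution by permuting one locus's genotypes across
    individuals (breaking any association while preserving margins).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ga = col.genotypes[:, locus_a, :]
    gb = col.genotypes[:, locus_b, :]
    ok = ~((ga == MISSING).any(axis=1) | (gb == MISSING).any(axis=1))
    unit = (col.river_code, (locus_a, locus_b))
    if ok.sum() < 5:
        return TestResult(unit, float("nan"), float("nan"), 0, status="untestable")
    ga, gb = np.sort(ga[ok], axis=1), np.sort(gb[ok], axis=1)
    _, ca = np.unique(ga, axis=0, return_inverse=True)
    _, cb = np.unique(gb, axis=0, return_inverse=True)
    ka, kb = ca.max() + 1, cb.max() + 1
    if ka < 2 or kb < 2:
        return TestResult(unit, float("nan"), float("nan"), 0, status="untestable")

    def g_stat(cb_perm: np.ndarray) -> float:
        table = np.bincount(ca * kb + cb_perm, minlength=ka * kb).reshape(ka, kb)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows * cols / table.sum()
        nz = table > 0
        return float(2.0 * (table[nz] * np.log(table[nz] / expected[nz])).sum())

    obs = g_stat(cb)
    b = 0
    for _ in range(n_perm):
        if g_stat(rng.permutation(cb)) >= obs - 1e-9:
            b += 1
    return TestResult(unit, obs, (b + 1) / (n_perm + 1), n_perm)


def holm_correction(p_values, alpha: float = 0.05) -> np.ndarray:
    """Sequential-Bonferroni (Holm step-down) rejection flags, input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


# ---------------------------------------------------------------------------
# lnRV / lnRH neutrality screen


def _repeat_variance(col: Collection, j: int, repeat_unit: int, min_size: int) -> float:
    g = _nonmissing(col, j).ravel().astype(float)
    repeats = (g - min_size) / repeat_unit
    if repeats.size < 2:
        return float("nan")
    return float(np.var(repeats, ddof=1))


def lnrv_lnrh_screen(
    ds: GenotypeDataset, z_threshold: float = 1.96
) -> pd.DataFrame:
    """Comparative neutrality screen across population pairs.

    Per locus and population pair: lnRV = ln(V1/V2) of repeat-number variance,
    lnRH = ln(((1/(1-H1))^2 - 1) / ((1/(1-H2))^2 - 1)) with H the unbiased
    expected heterozygosity.  Pair values are averaged per locus, then
    standardized across loci; |z| > ``z_threshold`` flags a locus as an
    outlier (a locus-specific, hence possibly selected, pattern).  Pairs where
    a variance is 0 or H is 0 or 1 are excluded for that locus.
    """
    cols = ds.collections
    if len(cols) < 2:
        raise ValueError("need >= 2 populations")
    rows = []
    for j, loc in enumerate(ds.loci):
        sizes = np.concatenate([_nonmissing(c, j).ravel() for c in cols])
        if sizes.size == 0:
            continue
        min_size = int(sizes.min())
        V, H = [], []
        for c in cols:
            V.append(_repeat_variance(c, j, loc.repeat_unit_length, min_size))
            try:
                H.append(unbiased_expected_heterozygosity(c, j))
            except ValueError:
                H.append(float("nan"))
        lnrv_vals, lnrh_vals = [], []
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                if V[a] and V[b] and np.isfinite(V[a]) and np.isfinite(V[b]):
                    lnrv_vals.append(np.log(V[a] / V[b]))
                ra = (1.0 / (1.0 - H[a])) ** 2 - 1.0 if 0 < H[a] < 1 else np.nan
                rb = (1.0 / (1.0 - H[b])) ** 2 - 1.0 if 0 < H[b] < 1 else np.nan
                if np.isfinite(ra) and np.isfinite(rb) and ra > 0 and rb > 0:
                    lnrh_vals.append(np.log(ra / rb))
        rows.append(
            {
                "locus": loc.name,
                "lnRV": float(np.mean(lnrv_vals)) if lnrv_vals else float("nan"),
                "lnRH": float(np.mean(lnrh_vals)) if lnrh_vals else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    for stat in ("lnRV", "lnRH"):
        vals = out[stat].to_numpy()
        mu = np.nanmean(vals)
        sd = np.nanstd(vals, ddof=1)
        z = (vals - mu) / sd if sd > 0 else np.full_like(vals, np.nan)
        out[f"z_{stat}"] = z
        out[f"outlier_{stat}"] = np.abs(z) > z_threshold
    return out


def conformance_report(
    ds: GenotypeDataset,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """HWE tests for every (river, locus), Holm-corrected as one family."""
    rng = np.random.default_rng(seed)
    results = []
    for col in ds.collections:
        for j, loc in enumerate(ds.loci):
            res = hwe_exact_test(col, j, n_perm=n_perm, seed=rng)
            results.append(
                {
                    "river": col.river_code,
                    "locus": loc.name,
                    "p": res.p_value,
                    "status": res.status,
                }
            )
    df = pd.DataFrame(results)
    testable = df["status"] == "ok"
    flags = np.zeros(len(df), dtype=bool)
    if testable.any():
        flags[testable.to_numpy()] = holm_correction(df.loc[testable, "p"], alpha)
    df["significant_after_holm"] = flags
    return df
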