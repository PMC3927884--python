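"""Among-river genetic differentiation.

Weir–Cockerham theta (FST from nested variance components), Hedrick-style
standardized F'ST via maximal-differentiation recoding, Monte-Carlo genic
(allelic heterogeneity) tests with Fisher combination, three-level AMOVA on
allele-identity distances, Nei's DA genetic distance, and a drift-based power
simulation for contingency testing at a target FST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, Collection, GenotypeDataset, pool_all, recode_collection
from .pairwise import PairwiseMatrix

__all__ = [
    "PairwiseMatrix",
    "wc_theta",
    "pairwise_theta",
    "fst_standardized",
    "global_fst_standardized",
    "genic_test",
    "amova3",
    "AmovaResult",
    "nei_da",
    "nei_da_matrix",
    "power_simulation",
    "PowerResult",
]


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _pop_allele_stats(cols: list[Collection], j: int):
    """Per-population n, allele freqs and het freqs at locus j.

    Returns (n_i, p_ia, h_ia, alleles) with populations lacking data dropped.
    """
    alleles = np.unique(
        np.concatenate(
            [c.genotypes[:, j, :][c.genotypes[:, j, 0] != MISSING] for c in cols]
        )
    )
    alleles = alleles[alleles != MISSING]
    ns, ps, hs = [], [], []
    for c in cols:
        g = c.genotypes[:, j, :]
        ok = ~(g == MISSING).any(axis=1)
        n = int(ok.sum())
        if n == 0:
            continue
        gg = g[ok]
        p = np.array([(gg == a).mean() for a in alleles])
        h = np.array(
            [((gg[:, 0] == a) ^ (gg[:, 1] == a)).mean() for a in alleles]
        )
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns, float), np.array(ps), np.array(hs), alleles


def _wc_components_locus(cols: list[Collection], j: int):
    """Summed variance components (a, b, c) over alleles at locus j."""
    n_i, p_ia, h_ia, alleles = _pop_allele_stats(cols, j)
    r = len(n_i)
    if r < 2 or alleles.size < 2:
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for k in range(alleles.size):
        p = p_ia[:, k]
        h = h_ia[:, k]
        pbar = (n_i * p).sum() / (r * nbar)
        s2 = (n_i * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta(
    ds: GenotypeDataset, rivers: list[str] | None = None
) -> tuple[float, pd.Series]:
    """Multilocus Weir–Cockerham theta over collections (one per river).

    Components are summed over alleles and loci before the ratio is taken
    (ratio of sums, not mean of ratios); small negative estimates are
    retained.  Returns (multilocus theta, per-locus theta Series).
    """
    pooled = pool_all(ds if rivers is None else ds.subset(rivers))
    cols = pooled.collections
    if len(cols) < 2:
        raise ValueError("need >= 2 rivers for theta")
    num = den = 0.0
    per_locus = {}
    for j, loc in enumerate(pooled.loci):
        a, b, c = _wc_components_locus(cols, j)
        tot = a + b + c
        per_locus[loc.name] = a / tot if tot != 0 else float("nan")
        num += a
        den += tot
    if den == 0:
        raise ValueError("theta undefined: all loci monomorphic")
    return float(num / den), pd.Series(per_locus, name="theta")


def _theta_two_collections(colA: Collection, colB: Collection, loci) -> float:
    num = den = 0.0
    for j in range(len(loci)):
        a, b, c = _wc_components_locus([colA, colB], j)
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def pairwise_theta(
    ds: GenotypeDataset,
    n_perm: int = 0,
    seed: int = 0,
    standardized: bool = False,
) -> PairwiseMatrix:
    """Pairwise theta (or theta' when ``standardized``) between rivers.

    Optional significance by permuting individuals between the two rivers
    (``n_perm`` > 0); p-values carry add-one smoothing.
    """
    pooled = pool_all(ds)
    cols = pooled.collections
    labels = [c.river_code for c in cols]
    n = len(cols)
    vals = np.zeros((n, n))
    pmat = np.full((n, n), np.nan) if n_perm else None
    rng = np.random.default_rng(seed)
    for i in range(n):
        for k in range(i + 1, n):
            if standardized:
                _, _, val = fst_standardized(ds, (labels[i], labels[k]))
            else:
                val = _theta_two_collections(cols[i], cols[k], pooled.loci)
            vals[i, k] = vals[k, i] = val
            if n_perm:
                obs = _theta_two_collections(cols[i], cols[k], pooled.loci)
                merged = np.concatenate(
                    [cols[i].genotypes, cols[k].genotypes], axis=0
                )
                ni = cols[i].n
                b = 0
                for _ in range(n_perm):
                    idx = rng.permutation(merged.shape[0])
                    ca = Collection("A", None, merged[idx[:ni]].copy())
                    cb = Collection("B", None, merged[idx[ni:]].copy())
                    if _theta_two_collections(ca, cb, pooled.loci) >= obs - 1e-12:
                        b += 1
                pmat[i, k] = pmat[k, i] = (b + 1) / (n_perm + 1)
    return PairwiseMatrix(
        labels, vals, "theta_prime" if standardized else "theta", pmat
    )


def fst_standardized(
    ds: GenotypeDataset, pair: tuple[str, str]
) -> tuple[float, float, float]:
    """(theta, theta_max, theta') for a river pair.

    theta_max is theta recomputed after recoding so that no allele is shared
    between the two rivers (per-population offset of allele codes), which
    preserves within-population frequencies while maximising differentiation.
    """
    sub = pool_all(ds.subset(list(pair)))
    cols = sub.collections
    if len(cols) != 2:
        raise ValueError(f"pair {pair} did not resolve to two rivers")
    theta = _theta_two_collections(cols[0], cols[1], sub.loci)
    recoded = [recode_collection(c, (i + 1) * 10000) for i, c in enumerate(cols)]
    theta_max = _theta_two_collections(recoded[0], recoded[1], sub.loci)
    if not np.isfinite(theta_max) or theta_max <= 0:
        raise ValueError(f"theta_max undefined for pair {pair}")
    return float(theta), float(theta_max), float(theta / theta_max)


def global_fst_standardized(ds: GenotypeDataset) -> tuple[float, float, float]:
    """(theta, theta_max, theta') over all rivers via whole-dataset recoding."""
    pooled = pool_all(ds)
    theta, _ = wc_theta(pooled)
    recoded = GenotypeDataset(
        pooled.loci,
        [
            recode_collection(c, (i + 1) * 10000)
            for i, c in enumerate(pooled.collections)
        ],
        pooled.species_label,
    )
    theta_max, _ = wc_theta(recoded)
    if theta_max <= 0:
        raise ValueError("global theta_max undefined")
    return theta, theta_max, theta / theta_max


# ---------------------------------------------------------------------------
# Genic (allelic heterogeneity) tests


def _allele_counts_table(cols: list[Collection], j: int) -> np.ndarray:
    """alleles x populations table of gene counts at locus j."""
    alleles = np.unique(
        np.concatenate(
            [c.genotypes[:, j, :][c.genotypes[:, j, 0] != MISSING] for c in cols]
        )
    )
    alleles = alleles[alleles != MISSING]
    table = np.zeros((alleles.size, len(cols)), dtype=int)
    for p, c in enumerate(cols):
        g = c.genotypes[:, j, :]
        gg = g[~(g == MISSING).any(axis=1)].ravel()
        for k, a in enumerate(alleles):
            table[k, p] = int((gg == a).sum())
    return table


def _g_statistic(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    nz = table > 0
    return float(2.0 * (table[nz] * np.log(table[nz] / expected[nz])).sum())


def _genic_p_from_table(
    table: np.ndarray,
    method: str,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """p-value for allele-frequency homogeneity on a gene-count table."""
    if table.shape[0] < 2 or (table.sum(axis=0) > 0).sum() < 2:
        return float("nan")
    if method == "chisq":
        t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if t.shape[0] < 2 or t.shape[1] < 2:
            return float("nan")
        return float(stats.chi2_contingency(t, correction=False)[1])
    obs = _g_statistic(table)
    col_tot = table.sum(axis=0)
    genes = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    bounds = np.cumsum(col_tot)[:-1]
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(genes)
        t = np.stack(
            [
                np.bincount(chunk, minlength=table.shape[0])
                for chunk in np.split(perm, bounds)
            ],
            axis=1,
        )
        if _g_statistic(t) >= obs - 1e-9:
            b += 1
    return (b + 1) / (n_perm + 1)


def fisher_combine(p_values) -> tuple[float, float, int]:
    """Fisher's method: (-2 sum ln p, combined p, df).  NaNs are excluded."""
    p = np.asarray([x for x in p_values if np.isfinite(x)], float)
    if p.size == 0:
        return float("nan"), float("nan"), 0
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, float(stats.chi2.sf(chi2, df)), df


def genic_test(
    ds: GenotypeDataset,
    rivers: list[str] | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    method: str = "mc",
) -> dict:
    """Allelic heterogeneity among rivers, per locus and Fisher-combined.

    ``method="mc"`` permutes pooled gene copies across populations
    (Monte-Carlo exact test with add-one smoothing); ``method="chisq"`` uses
    the chi-square approximation on the alleles x populations table.  Loci
    monomorphic across the compared rivers are excluded from the combination.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = pool_all(ds if rivers is None else ds.subset(rivers))
    cols = pooled.collections
    if len(cols) < 2:
        raise ValueError("need >= 2 rivers")
    per_locus = {}
    for j, loc in enumerate(pooled.loci):
        table = _allele_counts_table(cols, j)
        per_locus[loc.name] = _genic_p_from_table(table, method, n_perm, rng)
    chi2, p_comb, df = fisher_combine(per_locus.values())
    return {
        "per_locus_p": pd.Series(per_locus),
        "chi2": chi2,
        "df": df,
        "combined_p": p_comb,
    }


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    components: dict  # sigma2_a (among groups), sigma2_b, sigma2_c
    percentages: dict
    phi: dict  # phi_CT, phi_SC, phi_ST
    p_values: dict
    df: dict


def _allele_mismatch_distances(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Squared inter-individual distances = non-shared allele counts over loci.

    Returns (D2 matrix over all individuals, pop index per individual, river
    labels).  Loci missing in either individual contribute 0.
    """
    pooled = pool_all(ds)
    genos = np.concatenate([c.genotypes for c in pooled.collections], axis=0)
    pops = np.concatenate(
        [np.full(c.n, i) for i, c in enumerate(pooled.collections)]
    )
    labels = [c.river_code for c in pooled.collections]
    N, L, _ = genos.shape
    g = np.sort(genos, axis=2)
    D2 = np.zeros((N, N))
    for j in range(L):
        a = g[:, j, :]
        ok = a[:, 0] != MISSING
        # shared alleles between ordered pairs (x1,x2),(y1,y2):
        # 2 - shared = mismatch count in {0,1,2}
        x1 = a[:, 0][:, None]
        x2 = a[:, 1][:, None]
        y1 = a[:, 0][None, :]
        y2 = a[:, 1][None, :]
        direct = (x1 != y1).astype(np.int8) + (x2 != y2).astype(np.int8)
        crossed = (x1 != y2).astype(np.int8) + (x2 != y1).astype(np.int8)
        mism = np.minimum(direct, crossed).astype(float)
        valid = ok[:, None] & ok[None, :]
        D2 += np.where(valid, mism, 0.0)
    return D2, pops, labels


def _ssd(D2: np.ndarray, members: np.ndarray) -> float:
    sub = D2[np.ix_(members, members)]
    return float(sub.sum() / (2.0 * members.size))


def _amova_from_labels(
    D2: np.ndarray, pops: np.ndarray, groups_of_pop: np.ndarray
) -> dict:
    """Nested variance components from a squared-distance matrix."""
    N = D2.shape[0]
    pop_ids = np.unique(pops)
    P = pop_ids.size
    grp_ids = np.unique(groups_of_pop)
    G = grp_ids.size
    n_p = np.array([(pops == p).sum() for p in pop_ids], float)
    grp_of_ind = groups_of_pop[np.searchsorted(pop_ids, pops)]
    ssd_t = _ssd(D2, np.arange(N))
    ssd_wp = sum(_ssd(D2, np.where(pops == p)[0]) for p in pop_ids)
    ssd_wg = sum(_ssd(D2, np.where(grp_of_ind == g)[0]) for g in grp_ids)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_t - ssd_wg
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap / df_ap if df_ap > 0 else 0.0
    ms_ag = ssd_ag / df_ag if df_ag > 0 else 0.0
    n_g = np.array(
        [n_p[groups_of_pop == g].sum() for g in grp_ids], float
    )
    sum_np2_over_ng = sum(
        (n_p[groups_of_pop == g] ** 2).sum() / n_g[i] for i, g in enumerate(grp_ids)
    )
    n1 = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else 0.0
    n2 = (sum_np2_over_ng - (n_p**2).sum() / N) / df_ag if df_ag > 0 else 0.0
    n3 = (N - (n_g**2).sum() / N) / df_ag if df_ag > 0 else 0.0
    s2_c = ms_wp
    s2_b = (ms_ap - s2_c) / n1 if n1 > 0 else 0.0
    s2_a = (ms_ag - s2_c - n2 * s2_b) / n3 if n3 > 0 else 0.0
    total = s2_a + s2_b + s2_c
    return {
        "sigma2": (s2_a, s2_b, s2_c),
        "total": total,
        "phi_CT": s2_a / total if total else float("nan"),
        "phi_SC": s2_b / (s2_b + s2_c) if (s2_b + s2_c) else float("nan"),
        "phi_ST": (s2_a + s2_b) / total if total else float("nan"),
        "df": (df_ag, df_ap, df_wp),
    }


def amova3(
    ds: GenotypeDataset,
    grouping: dict[str, str],
    n_perm: int = 99,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA: among groups / among rivers within groups / within.

    ``grouping`` maps river code to group (stock) label.  Permutation tests:
    phi_CT permutes rivers among groups, phi_SC permutes individuals among
    rivers within groups, phi_ST permutes individuals among all rivers.
    """
    D2, pops, labels = _allele_mismatch_distances(ds)
    groups_of_pop = np.array(
        [grouping[l] for l in labels]
    )
    uniq = np.unique(groups_of_pop)
    if uniq.size < 2:
        raise ValueError("grouping must define >= 2 groups")
    _, codes = np.unique(groups_of_pop, return_inverse=True)
    obs = _amova_from_labels(D2, pops, codes)
    rng = np.random.default_rng(seed)
    p = {}
    if n_perm > 0:
        hits = {"phi_CT": 0, "phi_SC": 0, "phi_ST": 0}
        N = D2.shape[0]
        grp_of_ind = codes[pops]
        for _ in range(n_perm):
            perm_ct = _amova_from_labels(D2, pops, rng.permutation(codes))
            if perm_ct["phi_CT"] >= obs["phi_CT"] - 1e-12:
                hits["phi_CT"] += 1
            # individuals among pops within groups
            perm_pops = pops.copy()
            for g in range(codes.max() + 1):
                idx = np.where(grp_of_ind == g)[0]
                perm_pops[idx] = pops[idx][rng.permutation(idx.size)]
            if _amova_from_labels(D2, perm_pops, codes)["phi_SC"] >= obs["phi_SC"] - 1e-12:
                hits["phi_SC"] += 1
            perm_all = pops[rng.permutation(N)]
            if _amova_from_labels(D2, perm_all, codes)["phi_ST"] >= obs["phi_ST"] - 1e-12:
                hits["phi_ST"] += 1
        p = {k: (v + 1) / (n_perm + 1) for k, v in hits.items()}
    s2_a, s2_b, s2_c = obs["sigma2"]
    total = obs["total"]
    return AmovaResult(
        components={"among_groups": s2_a, "among_pops_within": s2_b, "within_pops": s2_c},
        percentages={
            "among_groups": 100 * s2_a / total,
            "among_pops_within": 100 * s2_b / total,
            "within_pops": 100 * s2_c / total,
        },
        phi={k: obs[k] for k in ("phi_CT", "phi_SC", "phi_ST")},
        p_values=p,
        df=dict(zip(("among_groups", "among_pops_within", "within_pops"), obs["df"])),
    )


# ---------------------------------------------------------------------------
# Nei's DA distance


def nei_da(ds: GenotypeDataset, pair: tuple[str, str]) -> float:
    """Nei et al. DA = 1 - (1/L) sum_l sum_a sqrt(x_la * y_la)."""
    sub = pool_all(ds.subset(list(pair)))
    colx, coly = sub.collections
    terms = []
    for j in range(sub.n_loci):
        try:
            from .diversity import allele_frequencies

            fx = allele_frequencies(colx, j)
            fy = allele_frequencies(coly, j)
        except ValueError:
            continue
        shared = set(fx) & set(fy)
        terms.append(sum(np.sqrt(fx[a] * fy[a]) for a in shared))
    if not terms:
        raise ValueError(f"no shared genotyped loci for pair {pair}")
    return float(1.0 - np.mean(terms))


def nei_da_matrix(ds: GenotypeDataset) -> PairwiseMatrix:
    pooled = pool_all(ds)
    labels = pooled.river_codes
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            vals[i, k] = vals[k, i] = nei_da(pooled, (labels[i], labels[k]))
    return PairwiseMatrix(labels, vals, "DA")


# ---------------------------------------------------------------------------
# Power simulation (drift to a target FST, then contingency testing)


@dataclass
class PowerResult:
    target_fst: float
    realized_fst: float
    n_generations: int
    ne: int
    rejection_rate: float
    n_reps: int


def power_simulation(
    base_freqs: list[np.ndarray],
    target_fst: float,
    ne: int = 1000,
    n_pops: int = 10,
    sample_n: int = 50,
    n_reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "chisq",
) -> PowerResult:
    """Power of the combined genic test at a drift-generated target FST.

    Each replicate drifts ``n_pops`` populations independently from the base
    allele frequencies for t generations chosen so that the expected
    FST = 1 - (1 - 1/(2Ne))^t matches ``target_fst``; ``sample_n`` diploids
    are then drawn per population and allele-frequency homogeneity is tested
    per locus (chi-square by default, as in drift-based power assessment) and
    combined with Fisher's method.  At ``target_fst = 0`` the rejection rate
    is the realized alpha.
    """
    if target_fst < 0:
        raise ValueError("target_fst must be >= 0")
    base = [np.asarray(f, float) for f in base_freqs]
    if all((f > 0).sum() < 2 for f in base):
        raise ValueError("base frequencies are monomorphic at every locus")
    per_gen = 1.0 - 1.0 / (2 * ne)
    t = 0 if target_fst == 0 else int(round(np.log(1.0 - target_fst) / np.log(per_gen)))
    realized = 1.0 - per_gen**t
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        p_locus = []
        for f in base:
            k = f.size
            pops = np.tile(f, (n_pops, 1))
            for _g in range(t):
                counts = np.stack(
                    [rng.multinomial(2 * ne, pops[i]) for i in range(n_pops)]
                )
                pops = counts / (2.0 * ne)
            samples = np.stack(
                [rng.multinomial(2 * sample_n, pops[i]) for i in range(n_pops)]
            ).T  # alleles x pops
            pv = _genic_p_from_table(samples, method, 0, rng)
            if np.isfinite(pv):
                p_locus.append(pv)
        _, p_comb, _ = fisher_combine(p_locus)
        if np.isfinite(p_comb) and p_comb < alpha:
            rejections += 1
    return PowerResult(
        target_fst=target_fst,
        realized_fst=realized,
        n_generations=t,
        ne=ne,
        rejection_rate=rejections / n_reps,
        n_reps=n_reps,
    )
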