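"""Model-based clustering for stock delineation, plus PCoA ordination.

The clustering engine is a Gibbs sampler for the admixture model: each allele
copy has a latent cluster of origin z, each individual an admixture vector q
(Dirichlet(alpha) prior, alpha updated by Metropolis), and each cluster
per-locus allele frequencies P (Dirichlet prior).  Two frequency priors are
available: "independent" (symmetric Dirichlet per cluster) and "correlated"
(F-model: cluster frequencies drift away from shared ancestral frequencies by
a per-cluster drift parameter, both updated by Metropolis).  The model
evidence lnPr(X|K) is estimated from the post-burn-in log-likelihood trace as
mean(lnL) - var(lnL)/2, and the number of clusters K is chosen by the
second-order rate of change of lnPr(X|K) across K (the Evanno Delta-K) with a
likelihood-plateau diagnostic reported alongside; when the two criteria
disagree the result carries an explicit disagreement flag rather than a
silent choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from scipy.stats import linregress

from .genotype_io import MISSING, GenotypeDataset, pool_all
from .pairwise import PairwiseMatrix


@dataclass
class ClusterResult:
    K: int
    q: np.ndarray  # (N, K) posterior-mean admixture fractions
    cluster_freqs: list[np.ndarray]  # per locus (K, n_alleles)
    log_likelihoods: np.ndarray  # post-burn-in trace
    ln_prob_k: float  # mean(lnL) - var(lnL)/2
    individual_rivers: list[str]
    seed: int
    replicate_id: int = 0

    @property
    def hard_assignment(self) -> np.ndarray:
        return self.q.argmax(axis=1)


@dataclass
class KSelection:
    table: pd.DataFrame  # per K: mean_lnP, sd_lnP, delta_k
    chosen_k: int
    rule: str  # "delta_k" | "plateau"
    plateau_k: int
    disagreement: bool
    results: dict = field(default_factory=dict)  # K -> list[ClusterResult]


# ---------------------------------------------------------------------------
# data preparation


def _flatten(ds: GenotypeDataset):
    pooled = pool_all(ds)
    genos = np.concatenate([c.genotypes for c in pooled.collections], axis=0)
    rivers = [c.river_code for c in pooled.collections for _ in range(c.n)]
    N, L, _ = genos.shape
    allele_maps = []
    ind_idx, loc_idx, all_idx = [], [], []
    for j in range(L):
        col = genos[:, j, :]
        alleles = np.unique(col[col != MISSING])
        amap = {int(a): i for i, a in enumerate(alleles)}
        allele_maps.append(alleles)
        for copy in range(2):
            ok = col[:, copy] != MISSING
            ind_idx.append(np.where(ok)[0])
            loc_idx.append(np.full(ok.sum(), j))
            all_idx.append(np.array([amap[int(a)] for a in col[ok, copy]]))
    return (
        np.concatenate(ind_idx),
        np.concatenate(loc_idx),
        np.concatenate(all_idx),
        allele_maps,
        N,
        L,
        rivers,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler


def admixture_gibbs(
    ds: GenotypeDataset,
    K: int,
    burn_in: int = 5000,
    reps: int = 25000,
    model: str = "independent",
    seed: int = 0,
    thin: int = 10,
    lambda_prior: float = 1.0,
    replicate_id: int = 0,
) -> ClusterResult:
    """Admixture-model Gibbs sampler; returns posterior means and lnPr(X|K).

    ``reps`` counts post-burn-in sweeps; the likelihood trace is recorded
    every ``thin`` sweeps.  Fixed seed gives identical output.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if burn_in < 0 or reps <= 0:
        raise ValueError("need reps > burn_in >= 0")
    if model not in ("independent", "correlated"):
        raise ValueError(f"unknown model {model!r}")
    ind, loc, alle, allele_maps, N, L, rivers = _flatten(ds)
    if K > N:
        raise ValueError(f"K={K} exceeds {N} individuals")
    rng = np.random.default_rng(seed)
    Amax = max(a.size for a in allele_maps)
    n_alleles = np.array([a.size for a in allele_maps])
    valid = np.zeros((L, Amax), bool)
    for j in range(L):
        valid[j, : n_alleles[j]] = True
    M = ind.size
    flat_la = loc * Amax + alle

    # init
    q = rng.dirichlet(np.ones(K), size=N)
    P = np.where(valid, 1.0 / n_alleles[:, None], 0.0)[None].repeat(K, axis=0)
    alpha = 1.0
    # correlated model state
    p_anc = P[0].copy()
    F = np.full(K, 0.05)

    q_accum = np.zeros((N, K))
    P_accum = np.zeros((K, L, Amax))
    lnls = []
    n_kept = 0

    total_sweeps = burn_in + reps
    for sweep in range(total_sweeps):
        # --- z | q, P
        w = q[ind] * P[:, loc, alle].T  # (M, K)
        tot = w.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        cum = np.cumsum(w, axis=1)
        u = rng.random((M, 1)) * tot
        z = (cum < u).sum(axis=1).clip(0, K - 1)

        # --- P | z
        counts = np.zeros((K, L * Amax))
        np.add.at(counts, (z, flat_la), 1.0)
        counts = counts.reshape(K, L, Amax)
        if model == "independent":
            prior = lambda_prior
            shape = np.where(valid[None], counts + prior, 0.0)
        else:
            c_k = (1.0 - F) / F  # per-cluster concentration
            shape = np.where(
                valid[None], counts + p_anc[None] * c_k[:, None, None], 0.0
            )
        gam = np.where(shape > 0, rng.gamma(np.maximum(shape, 1e-12)), 0.0)
        denom = gam.sum(axis=2, keepdims=True)
        denom[denom == 0] = 1.0
        P = gam / denom
        P = np.clip(P, 1e-300, None) * valid[None]

        # --- q | z
        qc = np.zeros((N, K))
        np.add.at(qc, (ind, z), 1.0)
        gam = rng.gamma(qc + alpha)
        q = gam / gam.sum(axis=1, keepdims=True)

        # --- alpha Metropolis (log-normal proposal, uniform(0,10) prior)
        if K > 1:
            prop = alpha * np.exp(rng.normal(0.0, 0.2))
            if 0 < prop < 10:
                logq = np.log(np.clip(q, 1e-300, None)).sum()

                def alpha_ll(a):
                    return N * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * logq

                log_r = alpha_ll(prop) - alpha_ll(alpha) + np.log(prop / alpha)
                if np.log(rng.random()) < log_r:
                    alpha = prop

        # --- correlated-model hyperparameters
        if model == "correlated" and K >= 1:
            _update_f_model(rng, P, p_anc, F, valid, n_alleles)

        if sweep >= burn_in:
            q_accum += q
            P_accum += P
            n_kept += 1
            if (sweep - burn_in) % thin == 0:
                lik = (q[ind] * P[:, loc, alle].T).sum(axis=1)
                lnls.append(float(np.log(np.clip(lik, 1e-300, None)).sum()))

    lnls = np.asarray(lnls)
    ln_prob = float(lnls.mean() - lnls.var(ddof=1) / 2.0) if lnls.size > 1 else float(
        lnls.mean()
    )
    q_mean = q_accum / n_kept
    P_mean = P_accum / n_kept
    cluster_freqs = [P_mean[:, j, : n_alleles[j]] for j in range(L)]
    return ClusterResult(
        K=K,
        q=q_mean,
        cluster_freqs=cluster_freqs,
        log_likelihoods=lnls,
        ln_prob_k=ln_prob,
        individual_rivers=rivers,
        seed=seed,
        replicate_id=replicate_id,
    )


def _log_dirichlet(x: np.ndarray, conc: np.ndarray) -> float:
    x = np.clip(x, 1e-12, None)
    conc = np.clip(conc, 1e-12, None)
    return float(
        gammaln(conc.sum()) - gammaln(conc).sum() + ((conc - 1) * np.log(x)).sum()
    )


def _update_f_model(rng, P, p_anc, F, valid, n_alleles):
    """Metropolis updates of per-cluster drift F_k and ancestral freqs."""
    K, L, _ = P.shape
    for k in range(K):
        prop = 1.0 / (1.0 + (1.0 / F[k] - 1.0) * np.exp(rng.normal(0, 0.3)))
        if not 1e-4 < prop < 0.5:
            continue
        ll_cur = ll_prop = 0.0
        for j in range(L):
            a = n_alleles[j]
            ll_cur += _log_dirichlet(P[k, j, :a], p_anc[j, :a] * (1 - F[k]) / F[k])
            ll_prop += _log_dirichlet(P[k, j, :a], p_anc[j, :a] * (1 - prop) / prop)
        if np.log(rng.random()) < ll_prop - ll_cur:
            F[k] = prop
    conc_prop = 200.0
    for j in range(L):
        a = n_alleles[j]
        cur = p_anc[j, :a]
        prop = rng.dirichlet(conc_prop * np.clip(cur, 1e-6, None))
        prop = np.clip(prop, 1e-9, None)
        prop /= prop.sum()
        ll = 0.0
        for k in range(K):
            ll += _log_dirichlet(P[k, j, :a], prop * (1 - F[k]) / F[k])
            ll -= _log_dirichlet(P[k, j, :a], cur * (1 - F[k]) / F[k])
        # proposal asymmetry + uniform Dirichlet(1) prior
        ll += _log_dirichlet(cur, conc_prop * prop) - _log_dirichlet(
            prop, conc_prop * cur
        )
        if np.log(rng.random()) < ll:
            p_anc[j, :a] = prop


# ---------------------------------------------------------------------------
# label alignment and accuracy


def align_to_reference(result: ClusterResult, reference: ClusterResult) -> ClusterResult:
    """Permute cluster labels to best match a reference run (Hungarian on
    cluster allele-frequency profiles)."""
    if result.K != reference.K:
        raise ValueError("K mismatch")
    K = result.K
    cost = np.zeros((K, K))
    for fa, fb in zip(result.cluster_freqs, reference.cluster_freqs):
        for a in range(K):
            for b in range(K):
                cost[a, b] += np.abs(fa[a] - fb[b]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, int)
    perm[cols] = rows
    return ClusterResult(
        K=K,
        q=result.q[:, perm],
        cluster_freqs=[f[perm] for f in result.cluster_freqs],
        log_likelihoods=result.log_likelihoods,
        ln_prob_k=result.ln_prob_k,
        individual_rivers=result.individual_rivers,
        seed=result.seed,
        replicate_id=result.replicate_id,
    )


def assignment_accuracy(result: ClusterResult, true_labels) -> float:
    """Fraction of individuals whose max-q cluster matches their true group,
    after optimal (Hungarian) matching of clusters to groups."""
    truth = pd.Categorical(true_labels).codes
    hard = result.hard_assignment
    n_true = truth.max() + 1
    conf = np.zeros((result.K, n_true))
    np.add.at(conf, (hard, truth), 1)
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(truth))


# ---------------------------------------------------------------------------
# K selection


def select_k(
    ds: GenotypeDataset,
    k_range,
    n_replicates: int = 3,
    burn_in: int = 5000,
    reps: int = 25000,
    model: str = "independent",
    seed: int = 0,
    keep_results: bool = False,
) -> KSelection:
    """Run replicate samplers over a K range and choose K.

    Delta-K (second-order rate of change of lnPr(X|K), scaled by the SD over
    replicates) is the primary rule; a likelihood-plateau rule (stop when the
    next K no longer improves mean lnPr by more than the replicate SD) is
    reported alongside, and ``disagreement`` is set when they differ.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("K range must contain >= 3 values")
    if n_replicates < 3:
        raise ValueError("Delta-K needs >= 3 replicates per K for an SD")
    rng = np.random.default_rng(seed)
    lnp = {}
    results: dict[int, list[ClusterResult]] = {}
    for K in ks:
        runs = []
        for r in range(n_replicates):
            sub_seed = int(rng.integers(2**31 - 1))
            runs.append(
                admixture_gibbs(
                    ds, K, burn_in=burn_in, reps=reps, model=model,
                    seed=sub_seed, replicate_id=r,
                )
            )
        lnp[K] = np.array([res.ln_prob_k for res in runs])
        results[K] = runs
    rows = []
    for i, K in enumerate(ks):
        mean_l = lnp[K].mean()
        sd_l = lnp[K].std(ddof=1)
        delta = np.nan
        if 0 < i < len(ks) - 1:
            second = np.abs(lnp[ks[i + 1]] - 2 * lnp[K] + lnp[ks[i - 1]])
            delta = float(second.mean() / sd_l) if sd_l > 0 else float("inf")
        rows.append({"K": K, "mean_lnP": mean_l, "sd_lnP": sd_l, "delta_k": delta})
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    chosen_delta = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    plateau_k = _plateau_k(table)
    return KSelection(
        table=table,
        chosen_k=chosen_delta,
        rule="delta_k",
        plateau_k=plateau_k,
        disagreement=chosen_delta != plateau_k,
        results=results if keep_results else {},
    )


def _plateau_k(table: pd.DataFrame) -> int:
    """Smallest K after which mean lnPr stops improving beyond replicate SD."""
    ks = table["K"].tolist()
    means = table["mean_lnP"].to_numpy()
    sds = table["sd_lnP"].to_numpy()
    for i in range(len(ks) - 1):
        gain = means[i + 1] - means[i]
        noise = max(sds[i], sds[i + 1])
        if gain <= noise:
            return int(ks[i])
    return int(ks[-1])


def hierarchical_scan(
    ds: GenotypeDataset,
    top: ClusterResult,
    k_max: int = 3,
    n_replicates: int = 3,
    burn_in: int = 1000,
    reps: int = 4000,
    seed: int = 0,
) -> dict[int, dict]:
    """Re-scan each top-level cluster's member rivers for sub-structure.

    Rivers are assigned to the cluster with the highest mean admixture
    fraction among their individuals; clusters with < 2 rivers are skipped.
    Sub-K is chosen by the likelihood-plateau rule (Delta-K cannot select
    K = 1, the expected answer when a stock is homogeneous).
    """
    if top.K < 2:
        return {}
    rivers = np.asarray(top.individual_rivers)
    river_cluster = {}
    for r in np.unique(rivers):
        river_cluster[r] = int(top.q[rivers == r].mean(axis=0).argmax())
    out = {}
    rng = np.random.default_rng(seed)
    for k in range(top.K):
        members = [r for r, c in river_cluster.items() if c == k]
        if len(members) < 2:
            out[k] = {"rivers": members, "sub_k": None, "status": "skipped"}
            continue
        sel = select_k(
            ds.subset(members),
            range(1, k_max + 1),
            n_replicates=n_replicates,
            burn_in=burn_in,
            reps=reps,
            seed=int(rng.integers(2**31 - 1)),
        )
        out[k] = {
            "rivers": members,
            "sub_k": sel.plateau_k,
            "status": "ok",
            "selection": sel,
        }
    return out


def plot_admixture(result: ClusterResult, ax=None):
    """Stacked-bar plot of per-individual admixture fractions, grouped by
    river (one thin bar per individual)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    order = np.argsort(result.individual_rivers, kind="stable")
    q = result.q[order]
    bottom = np.zeros(q.shape[0])
    x = np.arange(q.shape[0])
    for k in range(result.K):
        ax.bar(x, q[:, k], bottom=bottom, width=1.0)
        bottom += q[:, k]
    rivers = np.asarray(result.individual_rivers)[order]
    ticks = [int(np.mean(np.where(rivers == r)[0])) for r in np.unique(rivers)]
    ax.set_xticks(ticks)
    ax.set_xticklabels(np.unique(rivers), rotation=90, fontsize=6)
    ax.set_ylim(0, 1)
    ax.set_ylabel("q")
    return ax


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # rivers x axes
    percent_variation: np.ndarray
    eigenvalues: np.ndarray
    axis1_latitude_r2: float | None = None
    axis1_latitude_p: float | None = None
    degenerate: bool = False


def pcoa(
    dist: PairwiseMatrix, latitudes: dict[str, float] | None = None, n_axes: int = 3
) -> PcoaResult:
    """Principal coordinates analysis of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and reports percent variation
    from the positive eigenvalues.  When latitudes are supplied, Axis-1
    scores are regressed on latitude (OLS r^2 and p).
    """
    D = dist.values
    if dist.n < 3:
        raise ValueError("need >= 3 points")
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-8 * abs(evals).max(initial=0.0))
    if not pos.any():
        return PcoaResult(
            coordinates=pd.DataFrame(index=dist.labels),
            percent_variation=np.array([]),
            eigenvalues=evals,
            degenerate=True,
        )
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    k = min(n_axes, lam.size)
    percent = 100.0 * lam / lam.sum()
    frame = pd.DataFrame(
        coords[:, :k], index=dist.labels, columns=[f"Axis{i+1}" for i in range(k)]
    )
    r2 = p = None
    if latitudes is not None:
        lat = np.array([latitudes[l] for l in dist.labels])
        fit = linregress(lat, coords[:, 0])
        r2, p = float(fit.rvalue**2), float(fit.pvalue)
    return PcoaResult(
        coordinates=frame,
        percent_variation=percent[:k],
        eigenvalues=evals,
        axis1_latitude_r2=r2,
        axis1_latitude_p=p,
    )
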