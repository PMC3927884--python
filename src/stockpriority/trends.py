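"""Demographic time-series analysis.

Theil-Sen slopes and Mann-Kendall trend tests per river/variable/sex series,
z-score normalization of run-size series, the five-way trend categories
(significant/nonsignificant decline, no change, nonsignificant/significant
increase), and fixed-effects comparisons of slopes between species and among
stocks with Tukey-Kramer post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

VARIABLES = ("mean_length", "run_count", "run_cpue")
CATEGORIES = (
    "significant decline",
    "nonsignificant decline",
    "no change",
    "nonsignificant increase",
    "significant increase",
)


@dataclass
class TimeSeries:
    river_code: str
    variable: str
    sex: str  # "F" | "M" | "pooled"
    years: np.ndarray
    values: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.values = np.asarray(self.values, float)
        if self.years.size != self.values.size:
            raise ValueError("years/values length mismatch")
        if self.years.size and not np.all(np.diff(self.years) > 0):
            raise ValueError(
                f"years must be strictly increasing ({self.river_code} {self.variable})"
            )
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")

    @property
    def n(self) -> int:
        return self.years.size


@dataclass
class TrendResult:
    river_code: str
    variable: str
    sex: str
    slope: float
    mk_s: int
    tau: float
    p_value: float
    n: int
    category: str
    species: str = ""


def read_series_csv(path) -> list[TimeSeries]:
    """Read a long-format CSV (river,variable,sex,year,value[,species])."""
    df = pd.read_csv(path)
    out = []
    keys = ["river", "variable", "sex"] + (["species"] if "species" in df else [])
    for key, grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("year")
        out.append(
            TimeSeries(
                river_code=key[0],
                variable=key[1],
                sex=key[2],
                years=grp["year"].to_numpy(),
                values=grp["value"].to_numpy(),
                species=key[3] if len(key) > 3 else "",
            )
        )
    return out


def normalize_series(ts: TimeSeries) -> TimeSeries:
    """z-score over observed years, sample (n-1) SD convention."""
    if ts.n < 2:
        raise ValueError("need >= 2 records to normalize")
    sd = np.std(ts.values, ddof=1)
    if sd == 0:
        raise ValueError(f"constant series {ts.river_code}/{ts.variable}")
    return replace(ts, values=(ts.values - ts.values.mean()) / sd)


def theil_sen(ts: TimeSeries) -> float:
    """Median of all pairwise slopes (units per year)."""
    if np.unique(ts.years).size < 2:
        raise ValueError("need >= 2 distinct years")
    return float(stats.theilslopes(ts.values, ts.years).slope)


def _mk_s_and_var(values: np.ndarray) -> tuple[int, float]:
    n = values.size
    diff = np.sign(values[None, :] - values[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, tie_counts = np.unique(values, return_counts=True)
    t = tie_counts[tie_counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - (t * (t - 1) * (2 * t + 5)).sum()) / 18.0
    return s, var


def _exact_s_pvalue(s_obs: int, n: int) -> float:
    """Two-sided exact p for Mann-Kendall S, no ties.

    S = n(n-1)/2 - 2*inversions; the inversion-count distribution over
    permutations has generating function prod_i (1 + x + ... + x^(i-1)).
    """
    dist = np.array([1.0])
    for i in range(2, n + 1):
        dist = np.convolve(dist, np.ones(i))
    dist /= dist.sum()
    n0 = n * (n - 1) // 2
    s_of_inv = n0 - 2 * np.arange(dist.size)
    return float(dist[np.abs(s_of_inv) >= abs(s_obs)].sum())


def mann_kendall(ts: TimeSeries, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall trend test with tie-corrected variance.

    Uses the exact null distribution of S for n <= 10 without ties, otherwise
    the normal approximation with continuity correction.  The trend category
    combines the Theil-Sen slope sign with two-sided p vs ``alpha``.
    """
    if ts.n < 3:
        raise ValueError("need >= 3 records for Mann-Kendall")
    s, var = _mk_s_and_var(ts.values)
    n = ts.n
    n0 = n * (n - 1) / 2
    _, tie_counts = np.unique(ts.values, return_counts=True)
    n2 = (tie_counts * (tie_counts - 1) / 2).sum()
    denom = np.sqrt((n0 - n2) * n0)
    tau = s / denom if denom > 0 else 0.0
    has_ties = (tie_counts > 1).any()
    if s == 0 or var == 0:
        p = 1.0
    elif n <= 10 and not has_ties:
        p = _exact_s_pvalue(s, n)
    else:
        z = (s - np.sign(s)) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    slope = theil_sen(ts)
    category = _category(slope, p, alpha)
    return TrendResult(
        river_code=ts.river_code,
        variable=ts.variable,
        sex=ts.sex,
        slope=slope,
        mk_s=s,
        tau=float(tau),
        p_value=p,
        n=n,
        category=category,
        species=ts.species,
    )


def _category(slope: float, p: float, alpha: float) -> str:
    if abs(slope) < 1e-12:
        return "no change"
    if slope < 0:
        return "significant decline" if p < alpha else "nonsignificant decline"
    return "significant increase" if p < alpha else "nonsignificant increase"


def trend_table(
    series: list[TimeSeries], alpha: float = 0.05, normalize_run_size: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-series trend results plus category counts.

    Run-size series (counts and CPUE) are z-score normalized before slope
    estimation so their slopes are dimensionless and comparable across rivers;
    mean-length slopes stay in cm/yr.
    """
    rows = []
    for ts in series:
        work = (
            normalize_series(ts)
            if normalize_run_size and ts.variable in ("run_count", "run_cpue")
            else ts
        )
        rows.append(vars(mann_kendall(work, alpha)))
    df = pd.DataFrame(rows)
    if df.empty:
        return df, pd.Series({c: 0 for c in CATEGORIES})
    counts = df["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    return df, counts


def slope_comparison(
    slopes: pd.DataFrame, factors: list[str], tukey_factor: str | None = None
) -> dict:
    """Fixed-effects linear model of trend slopes on grouping factors.

    ``slopes`` needs a ``slope`` column plus the factor columns.  Returns the
    ANOVA table (type II F tests) and, for ``tukey_factor``, Tukey-Kramer
    family-wise pairwise comparisons (valid with unequal group sizes).
    """
    for f in factors:
        levels = slopes[f].value_counts()
        if (levels < 2).any() or len(levels) < 2:
            bad = levels[levels < 2].index.tolist() or ["<2 levels>"]
            raise ValueError(f"factor {f!r} has degenerate level(s): {bad}")
    formula = "slope ~ " + " + ".join(f"C({f})" for f in factors)
    model = ols(formula, data=slopes).fit()
    table = anova_lm(model, typ=2)
    out = {"anova": table, "model": model}
    if tukey_factor is not None:
        tk = pairwise_tukeyhsd(slopes["slope"], slopes[tukey_factor])
        out["tukey"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return out
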