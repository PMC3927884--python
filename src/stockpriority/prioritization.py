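"""Conservation prioritization rules.

Populations are classified from demographic trend slopes: increasing
(slope > 0) populations are low priority, stable or slightly declining ones
medium, steeply declining ones high, with the medium/high cut at -0.75 cm/yr
for mean length and -0.05 normalized units/yr for run size.  When a river has
designations from several variables (or sexes) the more protective one wins
(precautionary principle).  Stock-level designations are computed from the
average member slopes per variable and extended to rivers without demographic
monitoring; rivers without genetic sampling are first attached to the stock
of the nearest sampled river.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ibd import great_circle_km
from .pairwise import PairwiseMatrix

DESIGNATIONS = ("low", "medium", "high")
_ORDER = {d: i for i, d in enumerate(DESIGNATIONS)}


@dataclass(frozen=True)
class Thresholds:
    length_cut: float = -0.75  # units/yr of mean length
    runsize_cut: float = -0.05  # normalized units/yr
    low_cut: float = 0.0

    def __post_init__(self) -> None:
        if not (self.length_cut < self.low_cut and self.runsize_cut < self.low_cut):
            raise ValueError("medium/high cuts must lie below the low cut")


def classify_variable(
    slope: float, variable: str, thresholds: Thresholds = Thresholds()
) -> str:
    """slope > 0 -> low; cut < slope <= 0 -> medium; slope <= cut -> high."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if variable == "mean_length":
        cut = thresholds.length_cut
    elif variable in ("run_count", "run_cpue", "run_size"):
        cut = thresholds.runsize_cut
    else:
        raise ValueError(f"unknown variable {variable!r}")
    if slope > thresholds.low_cut:
        return "low"
    if slope <= cut:
        return "high"
    return "medium"


def merge_designations(*designations: str | None) -> str:
    """Precautionary join: the most protective present designation wins."""
    present = [d for d in designations if d is not None]
    if not present:
        raise ValueError("no designation present; use stock extension")
    for d in present:
        if d not in _ORDER:
            raise ValueError(f"unknown designation {d!r}")
    return max(present, key=_ORDER.__getitem__)


def stock_designation(
    member_slopes: dict[str, list[float]], thresholds: Thresholds = Thresholds()
) -> str:
    """Designation from per-variable mean slopes over all member series."""
    per_var = []
    for variable, slopes in member_slopes.items():
        if slopes:
            per_var.append(
                classify_variable(float(np.mean(slopes)), variable, thresholds)
            )
    if not per_var:
        raise ValueError("no member slopes")
    return merge_designations(*per_var)


def quantile_thresholds(slopes: pd.DataFrame) -> Thresholds:
    """Data-driven cuts putting about equal numbers of non-increasing series
    in medium and high (median of the negative slopes per variable)."""
    cuts = {}
    for variable, col in (("mean_length", "length_cut"), ("run", "runsize_cut")):
        mask = (
            slopes["variable"].str.startswith(variable)
            if variable == "run"
            else slopes["variable"] == variable
        )
        neg = slopes.loc[mask & (slopes["slope"] <= 0), "slope"]
        if len(neg):
            cuts[col] = float(neg.median())
    return Thresholds(**cuts)


@dataclass
class PriorityRecord:
    river_code: str
    stock: str | None
    has_demographic_data: bool
    designation: str | None = None
    provenance: str | None = None  # own_data | stock_extended | override
    length_slopes: list[float] = field(default_factory=list)
    runsize_slopes: list[float] = field(default_factory=list)


def river_designation(
    trend_rows: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> str:
    """Own-data designation of one river from its trend results.

    Per variable, each sex's slope is classified separately and the more
    protective class kept; variables are then merged precautionarily.
    """
    per_var: dict[str, list[str]] = {}
    for _, row in trend_rows.iterrows():
        per_var.setdefault(row["variable"], []).append(
            classify_variable(row["slope"], row["variable"], thresholds)
        )
    return merge_designations(*(merge_designations(*v) for v in per_var.values()))


def assign_stock_by_proximity(
    river: str,
    coords: dict[str, tuple[float, float]],
    sampled_stocks: dict[str, str],
    distances: PairwiseMatrix | None = None,
) -> str:
    """Stock of the nearest genetically sampled river.

    Uses along-coast distances when a matrix is supplied, else great-circle.
    Exact ties go to the more northern neighbour, with a warning.
    """
    if river not in coords:
        raise ValueError(f"river {river!r} has no stock and no coordinates")
    lat, lon = coords[river]
    best: list[tuple[float, float, str]] = []
    for other, stock in sampled_stocks.items():
        if other == river or other not in coords:
            continue
        if distances is not None and river in distances.labels and other in distances.labels:
            d = float(
                distances.values[
                    distances.labels.index(river), distances.labels.index(other)
                ]
            )
        else:
            d = great_circle_km(lat, lon, *coords[other])
        best.append((d, coords[other][0], other))
    if not best:
        raise ValueError(f"no sampled rivers available to place {river!r}")
    best.sort(key=lambda t: t[0])
    ties = [b for b in best if np.isclose(b[0], best[0][0])]
    if len(ties) > 1:
        stocks = {sampled_stocks[b[2]] for b in ties}
        if len(stocks) > 1:
            warnings.warn(
                f"{river}: equidistant neighbours in different stocks; "
                "taking the northern one"
            )
        ties.sort(key=lambda t: -t[1])
    return sampled_stocks[ties[0][2]]


def extend_to_unmonitored(
    records: list[PriorityRecord],
    stock_designations: dict[str, str],
    coords: dict[str, tuple[float, float]] | None = None,
    distances: PairwiseMatrix | None = None,
    overrides: dict[str, tuple[str, str]] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Complete the priority table.

    Monitored rivers keep their own-data designation; unmonitored rivers
    inherit their stock's designation; rivers without a stock are first
    attached by proximity to sampled rivers.  ``overrides`` maps river to
    (designation, reason) for explicit case-specific upgrades.
    """
    sampled = {
        r.river_code: r.stock for r in records if r.stock is not None
    }
    rows = []
    for rec in records:
        stock = rec.stock
        if stock is None:
            if coords is None:
                raise ValueError(f"river {rec.river_code} has no stock and no coordinates")
            stock = assign_stock_by_proximity(
                rec.river_code, coords, sampled, distances
            )
        if rec.has_demographic_data and rec.designation is not None:
            designation, provenance = rec.designation, "own_data"
        elif rec.has_demographic_data and (rec.length_slopes or rec.runsize_slopes):
            per_var = {}
            if rec.length_slopes:
                per_var["mean_length"] = rec.length_slopes
            if rec.runsize_slopes:
                per_var["run_size"] = rec.runsize_slopes
            designation, provenance = stock_designation(per_var, thresholds), "own_data"
        else:
            if stock not in stock_designations:
                raise ValueError(f"no stock designation for {stock!r}")
            designation, provenance = stock_designations[stock], "stock_extended"
        reason = ""
        if overrides and rec.river_code in overrides:
            designation, reason = overrides[rec.river_code]
            provenance = "override"
        rows.append(
            {
                "river": rec.river_code,
                "stock": stock,
                "demographic_data": "Y" if rec.has_demographic_data else "N",
                "designation": designation,
                "provenance": provenance,
                "override_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def load_rules(path) -> tuple[Thresholds, dict[str, tuple[str, str]]]:
    """Read a YAML/JSON rules file: optional ``thresholds`` mapping and an
    ``overrides`` list of {river, designation, reason} entries."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    thr = Thresholds(**cfg.get("thresholds", {}))
    overrides = {
        o["river"]: (o["designation"], o.get("reason", ""))
        for o in cfg.get("overrides", [])
    }
    return thr, overrides


def tally_report(priority_table: pd.DataFrame) -> dict:
    """Counts per designation, total, and per-stock breakdown."""
    if priority_table.empty:
        return {"counts": {d: 0 for d in DESIGNATIONS}, "total": 0, "by_stock": {}}
    counts = (
        priority_table["designation"].value_counts().reindex(DESIGNATIONS, fill_value=0)
    )
    by_stock = {
        stock: grp["designation"]
        .value_counts()
        .reindex(DESIGNATIONS, fill_value=0)
        .to_dict()
        for stock, grp in priority_table.groupby("stock")
    }
    return {
        "counts": counts.to_dict(),
        "total": int(len(priority_table)),
        "by_stock": by_stock,
    }
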