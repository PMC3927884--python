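"""Demographic trends: Theil-Sen slopes, Mann-Kendall tests, stock GLM."""

from pathlib import Path

import pandas as pd

from stockpriority.genotype_io import read_river_metadata
from stockpriority.trends import read_series_csv, slope_comparison, trend_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    series = read_series_csv(BASE / "synthetic" / "series.csv")
    results, counts = trend_table(series)
    results.to_csv(BASE / "trend_results.csv", index=False)
    counts.to_csv(BASE / "trend_category_counts.csv")
    print(f"{len(results)} series analyzed; categories: "
          + ", ".join(f"{k}={v}" for k, v in counts.items() if v))

    meta = read_river_metadata(BASE / "synthetic" / "river_metadata.csv")
    stock_of = {m.river_code: m.stock_label for m in meta}
    lengths = results[results["variable"] == "mean_length"].copy()
    lengths["stock"] = lengths["river_code"].map(stock_of)
    cmp_res = slope_comparison(lengths, ["stock"], tukey_factor="stock")
    cmp_res["anova"].to_csv(BASE / "slope_anova.csv")
    cmp_res["tukey"].to_csv(BASE / "slope_tukey.csv", index=False)
    f = cmp_res["anova"].loc["C(stock)", "F"]
    p = cmp_res["anova"].loc["C(stock)", "PR(>F)"]
    print(f"mean-length slopes differ among stocks: F = {f:.2f}, p = {p:.4f}")


if __name__ == "__main__":
    main()
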