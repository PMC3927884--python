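"""Theil-Sen slopes, Mann-Kendall tests, normalization, slope comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stockpriority.trends import (
    TimeSeries,
    mann_kendall,
    normalize_series,
    read_series_csv,
    slope_comparison,
    theil_sen,
    trend_table,
)


def ts(years, values, **kw):
    defaults = dict(river_code="X", variable="mean_length", sex="F")
    defaults.update(kw)
    return TimeSeries(years=np.asarray(years), values=np.asarray(values, float), **defaults)


def brute_force_theil_sen(years, values):
    slopes = [
        (values[j] - values[i]) / (years[j] - years[i])
        for i, j in itertools.combinations(range(len(years)), 2)
        if years[j] != years[i]
    ]
    return float(np.median(slopes))


def test_normalize_hand_example_and_idempotence():
    s = normalize_series(ts([1, 2, 3], [1, 2, 3]))
    np.testing.assert_allclose(s.values, [-1, 0, 1])  # sample-SD convention
    again = normalize_series(s)
    np.testing.assert_allclose(again.values, s.values, atol=1e-12)
    with pytest.raises(ValueError):
        normalize_series(ts([1], [5]))
    with pytest.raises(ValueError, match="constant"):
        normalize_series(ts([1, 2, 3], [2, 2, 2]))


def test_theil_sen_exact_line_and_outlier():
    years = np.arange(1990, 2000)
    line = ts(years, 3 - 0.75 * years)
    assert theil_sen(line) == pytest.approx(-0.75)
    out = ts([1, 2, 3], [1, 2, 100])
    assert theil_sen(out) == pytest.approx(49.5)  # median of {1, 49.5, 98}
    assert theil_sen(ts([1, 2, 3], [4, 4, 4])) == 0.0


def test_theil_sen_matches_brute_force_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(4, 15))
        years = np.sort(rng.choice(np.arange(1970, 2015), size=n, replace=False))
        values = rng.normal(size=n)
        assert theil_sen(ts(years, values)) == pytest.approx(
            brute_force_theil_sen(years, values)
        )


def test_mann_kendall_monotone_series():
    up = mann_kendall(ts(np.arange(2000, 2005), np.arange(5.0)))
    assert up.mk_s == 10 and up.tau == pytest.approx(1.0)
    assert up.category == "significant increase"
    down = mann_kendall(ts(np.arange(2000, 2004), [4.0, 3.0, 2.0, 1.0]))
    assert down.mk_s == -6 and down.tau == pytest.approx(-1.0)


def test_mann_kendall_reversal_flips_s(rng):
    years = np.arange(1990, 2010)
    vals = rng.normal(size=20)
    fwd = mann_kendall(ts(years, vals))
    rev = mann_kendall(ts(years, vals[::-1]))
    assert fwd.mk_s == -rev.mk_s
    assert fwd.p_value == pytest.approx(rev.p_value)


def test_mann_kendall_ties_and_exact_p():
    tied = mann_kendall(ts([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0]))
    assert tied.mk_s == 0 and tied.p_value == 1.0 and tied.category == "no change"
    # exact p for n=5 strictly increasing: 2/120
    up = mann_kendall(ts(np.arange(5), np.arange(5.0)))
    assert up.p_value == pytest.approx(2 / 120)
    # exact route agrees with scipy's exact kendall tau p (no ties, n<=10)
    years = np.arange(8)
    vals = np.array([0.3, -1.2, 0.8, 0.1, 2.0, -0.5, 1.1, 0.4])
    ours = mann_kendall(ts(years, vals))
    sk = stats.kendalltau(years, vals, method="exact")
    assert ours.p_value == pytest.approx(sk.pvalue)
    assert ours.tau == pytest.approx(sk.statistic)


def test_mann_kendall_null_calibration(rng):
    """Type-I error of the two-sided test is near nominal on white noise."""
    hits = sum(
        mann_kendall(ts(np.arange(1990, 2010), rng.normal(size=20))).p_value < 0.05
        for _ in range(1000)
    )
    assert 0.03 <= hits / 1000 <= 0.07


def test_trend_table_counts_and_closure(rng):
    series = []
    for i in range(3):  # strong declines
        series.append(ts(np.arange(2000, 2015), 100 - 2.0 * np.arange(15)
                         + rng.normal(0, 0.5, 15), river_code=f"D{i}"))
    for i in range(2):  # flat
        series.append(ts(np.arange(2000, 2015), np.full(15, 7.0), river_code=f"F{i}"))
    df, counts = trend_table(series, normalize_run_size=False)
    assert counts.sum() == len(series)
    assert counts["significant decline"] == 3
    assert counts["no change"] == 2
    empty_df, empty_counts = trend_table([])
    assert empty_df.empty and empty_counts.sum() == 0


def test_trend_table_normalizes_run_size(rng):
    s = ts(np.arange(2000, 2020), 1000.0 - 30 * np.arange(20) + rng.normal(0, 40, 20),
           variable="run_count")
    df, _ = trend_table([s])
    assert abs(df.loc[0, "slope"]) < 1.0  # normalized units/yr, not fish/yr


def test_read_series_csv_round_trip(tmp_path):
    p = tmp_path / "series.csv"
    p.write_text(
        "river,variable,sex,year,value\n"
        "HUD,mean_length,F,2000,250\nHUD,mean_length,F,2001,249\n"
        "HUD,mean_length,F,2003,247\nCHO,run_count,pooled,1990,5000\n"
        "CHO,run_count,pooled,1991,4000\nCHO,run_count,pooled,1992,3000\n"
    )
    series = read_series_csv(p)
    assert len(series) == 2
    hud = next(s for s in series if s.river_code == "HUD")
    assert hud.n == 3 and hud.years[-1] == 2003  # gapped years allowed


def test_slope_comparison_identical_groups():
    df = pd.DataFrame(
        {
            "slope": [-1.0, -0.5, 0.0, -1.0, -0.5, 0.0],
            "stock": ["A"] * 3 + ["B"] * 3,
        }
    )
    res = slope_comparison(df, ["stock"], tukey_factor="stock")
    assert res["anova"].loc["C(stock)", "F"] == pytest.approx(0.0, abs=1e-10)
    assert (res["tukey"]["p-adj"].astype(float) > 0.9).all()


def test_slope_comparison_detects_offset_group(rng):
    base = rng.normal(0, 0.05, 6)
    df = pd.DataFrame(
        {
            "slope": np.concatenate([base, base - 3.0, base + rng.normal(0, 0.05, 6)]),
            "stock": ["A"] * 6 + ["B"] * 6 + ["C"] * 6,
        }
    )
    res = slope_comparison(df, ["stock"], tukey_factor="stock")
    assert res["anova"].loc["C(stock)", "PR(>F)"] < 0.01
    tk = res["tukey"]
    ab = tk[(tk["group1"] == "A") & (tk["group2"] == "B")]
    assert bool(ab["reject"].iloc[0])


def test_slope_comparison_matches_hand_anova():
    """One-way ANOVA F on a 3-group toy table, computed by hand."""
    groups = {"A": [1.0, 2.0, 3.0], "B": [2.0, 3.0, 4.0], "C": [6.0, 7.0, 8.0]}
    df = pd.DataFrame(
        {
            "slope": sum(groups.values(), []),
            "stock": sum(([k] * 3 for k in groups), []),
        }
    )
    grand = np.mean(df["slope"])
    ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
    ss_within = sum(
        sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values()
    )
    f_hand = (ss_between / 2) / (ss_within / 6)
    res = slope_comparison(df, ["stock"])
    assert res["anova"].loc["C(stock)", "F"] == pytest.approx(f_hand)


def test_slope_comparison_degenerate_level():
    df = pd.DataFrame({"slope": [1.0, 2.0, 3.0], "stock": ["A", "A", "B"]})
    with pytest.raises(ValueError, match="degenerate"):
        slope_comparison(df, ["stock"])


def test_timeseries_validation():
    with pytest.raises(ValueError, match="increasing"):
        ts([2000, 2000, 2001], [1, 2, 3])
    with pytest.raises(ValueError, match="variable"):
        ts([1, 2, 3], [1, 2, 3], variable="weight")
    with pytest.raises(ValueError):
        mann_kendall(ts([1, 2], [1.0, 2.0]))
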