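"""Conservation prioritization rules and the published priority tallies."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stockpriority import datasets
from stockpriority.prioritization import (
    PriorityRecord,
    Thresholds,
    classify_variable,
    extend_to_unmonitored,
    merge_designations,
    quantile_thresholds,
    river_designation,
    stock_designation,
    tally_report,
)


def test_classify_variable_published_thresholds():
    assert classify_variable(-0.80, "mean_length") == "high"
    assert classify_variable(-0.04, "run_count") == "medium"
    assert classify_variable(0.2, "mean_length") == "low"
    assert classify_variable(-0.75, "mean_length") == "high"  # boundary inclusive
    assert classify_variable(0.0, "run_count") == "medium"
    with pytest.raises(ValueError, match="variable"):
        classify_variable(-1.0, "age")
    with pytest.raises(ValueError):
        classify_variable(float("nan"), "mean_length")


def test_classify_is_monotone_step_function():
    slopes = np.linspace(-2, 1, 61)
    order = {"low": 0, "medium": 1, "high": 2}
    prio = [order[classify_variable(s, "mean_length")] for s in slopes]
    assert all(a >= b for a, b in zip(prio, prio[1:]))


def test_merge_designations_lattice_properties():
    assert merge_designations("medium", "high") == "high"
    assert merge_designations("low", "low") == "low"
    assert merge_designations("medium", None) == "medium"
    for a, b, c in itertools.product(("low", "medium", "high"), repeat=3):
        assert merge_designations(a, b) == merge_designations(b, a)
        assert merge_designations(a, merge_designations(b, c)) == merge_designations(
            merge_designations(a, b), c
        )
        assert merge_designations(a, a) == a
    with pytest.raises(ValueError):
        merge_designations(None, None)


def test_stock_designation_from_mean_slopes():
    assert stock_designation({"mean_length": [-1.0, -0.9]}) == "high"
    assert stock_designation({"run_size": [0.1, 0.3]}) == "low"
    # mixed variables merged precautionarily: length medium + run high -> high
    assert (
        stock_designation({"mean_length": [-0.5], "run_size": [-0.2, -0.1]}) == "high"
    )
    with pytest.raises(ValueError):
        stock_designation({"mean_length": []})


def test_river_designation_uses_conservative_sex():
    rows = pd.DataFrame(
        {"variable": ["mean_length", "mean_length"], "sex": ["F", "M"],
         "slope": [-0.2, -0.9]}
    )
    assert river_designation(rows) == "high"


def test_extend_to_unmonitored_rules():
    records = [
        PriorityRecord("MON", "SNE", True, length_slopes=[-0.9]),
        PriorityRecord("GIL", "SNE", True, length_slopes=[0.3]),
        PriorityRecord("MER", "SNE", False),  # unmonitored -> stock-extended
        PriorityRecord("UNK", None, False),  # no genetics -> proximity stock
    ]
    coords = {"MON": (41.7, -70.6), "GIL": (41.5, -71.4), "MER": (42.8, -70.8),
              "UNK": (41.71, -70.61)}
    table = extend_to_unmonitored(
        records, {"SNE": "high"}, coords=coords
    )
    t = table.set_index("river")
    assert t.loc["MON", "designation"] == "high"
    assert t.loc["GIL", "designation"] == "low"  # own data wins inside a high stock
    assert t.loc["MER", "designation"] == "high"
    assert t.loc["MER", "provenance"] == "stock_extended"
    assert t.loc["UNK", "stock"] == "SNE"  # nearest sampled river is MON


def test_proximity_tie_break_warns_and_picks_north():
    records = [
        PriorityRecord("N", "A", True, designation="medium"),
        PriorityRecord("S", "B", True, designation="medium"),
        PriorityRecord("MID", None, False),
    ]
    coords = {"N": (43.0, -70.0), "S": (41.0, -70.0), "MID": (42.0, -70.0)}
    with pytest.warns(UserWarning, match="northern"):
        table = extend_to_unmonitored(
            records, {"A": "high", "B": "medium"}, coords=coords
        )
    assert table.set_index("river").loc["MID", "stock"] == "A"


def test_extend_requires_stock_or_coordinates():
    with pytest.raises(ValueError, match="coordinates"):
        extend_to_unmonitored([PriorityRecord("X", None, False)], {})


def test_overrides_are_explicit_and_logged():
    records = [PriorityRecord("STJ", "SAT", True, designation="medium")]
    table = extend_to_unmonitored(
        records, {}, overrides={"STJ": ("high", "genetic uniqueness")}
    )
    assert table.loc[0, "designation"] == "high"
    assert table.loc[0, "provenance"] == "override"
    assert table.loc[0, "override_reason"] == "genetic uniqueness"


def test_tally_published_priority_tables():
    """Direct tallies of the published per-river prioritizations."""
    ale = datasets.load_priority_table("alewife")
    res = tally_report(ale.assign(river=ale["river"]))
    assert res["total"] == 45
    assert res["counts"]["low"] == 6
    assert res["counts"]["medium"] == 23
    assert res["counts"]["high"] == 16  # the narrative total prints 15
    bb = datasets.load_priority_table("blueback")
    res = tally_report(bb)
    assert res["total"] == 55
    assert res["counts"] == {"low": 0, "medium": 26, "high": 29}
    empty = tally_report(pd.DataFrame())
    assert empty["total"] == 0 and sum(empty["counts"].values()) == 0


def test_round_trip_designed_stock_designations():
    """Rules reproduce intended designations on synthetic stocks exactly."""
    member_slopes = {
        "HIGHSTOCK": {"mean_length": [-1.2, -0.8], "run_size": [-0.2]},
        "MEDSTOCK": {"mean_length": [-0.3, -0.1]},
        "LOWSTOCK": {"run_size": [0.2, 0.4]},
    }
    designs = {s: stock_designation(v) for s, v in member_slopes.items()}
    assert designs == {"HIGHSTOCK": "high", "MEDSTOCK": "medium", "LOWSTOCK": "low"}


def test_load_rules_yaml(tmp_path):
    p = tmp_path / "rules.yaml"
    p.write_text(
        "thresholds:\n  length_cut: -0.5\n"
        "overrides:\n  - river: STJ\n    designation: high\n    reason: uniqueness\n"
    )
    from stockpriority.prioritization import load_rules

    thr, overrides = load_rules(p)
    assert thr.length_cut == -0.5 and thr.runsize_cut == -0.05
    assert overrides == {"STJ": ("high", "uniqueness")}


def test_thresholds_validation_and_quantile_finder():
    with pytest.raises(ValueError):
        Thresholds(length_cut=0.5)
    slopes = pd.DataFrame(
        {
            "variable": ["mean_length"] * 4 + ["run_count"] * 4,
            "slope": [-2.0, -1.0, -0.5, 0.3, -0.2, -0.1, -0.04, 0.1],
        }
    )
    thr = quantile_thresholds(slopes)
    assert thr.length_cut == pytest.approx(-1.0)
    assert thr.runsize_cut == pytest.approx(-0.1)
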