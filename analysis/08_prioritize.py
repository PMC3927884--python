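"""Conservation prioritization: classify monitored rivers from their slopes,
derive stock-level designations, extend to unmonitored rivers, and compare
with the published per-river tallies for the real species."""

from pathlib import Path

import pandas as pd

from stockpriority import datasets
from stockpriority.genotype_io import read_river_metadata
from stockpriority.prioritization import (
    PriorityRecord,
    extend_to_unmonitored,
    stock_designation,
    tally_report,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    results = pd.read_csv(BASE / "trend_results.csv")
    meta = read_river_metadata(BASE / "synthetic" / "river_metadata.csv")
    stock_of = {m.river_code: m.stock_label for m in meta}
    coords = {m.river_code: (m.latitude, m.longitude) for m in meta}

    stock_slopes: dict[str, dict[str, list[float]]] = {}
    for _, row in results.iterrows():
        var = "mean_length" if row["variable"] == "mean_length" else "run_size"
        stock_slopes.setdefault(stock_of[row["river_code"]], {}).setdefault(
            var, []
        ).append(row["slope"])
    stock_designs = {s: stock_designation(v) for s, v in stock_slopes.items()}
    print("stock designations:", stock_designs)

    monitored = set(results["river_code"])
    records = []
    for river, stock in stock_of.items():
        if river in monitored:
            rows = results[results["river_code"] == river]
            records.append(PriorityRecord(
                river, stock, True,
                length_slopes=rows.loc[rows["variable"] == "mean_length", "slope"].tolist(),
                runsize_slopes=rows.loc[rows["variable"] != "mean_length", "slope"].tolist(),
            ))
        else:
            records.append(PriorityRecord(river, stock, False))
    table = extend_to_unmonitored(records, stock_designs, coords=coords)
    table.to_csv(BASE / "priority_table.csv", index=False)
    tally = tally_report(table)
    print(f"synthetic study: {tally['counts']} over {tally['total']} rivers "
          f"({(table['provenance'] == 'stock_extended').sum()} stock-extended)")

    for species in ("alewife", "blueback"):
        pub = tally_report(datasets.load_priority_table(species))
        print(f"published {species} tally: {pub['counts']} over {pub['total']} rivers")


if __name__ == "__main__":
    main()
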