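"""Generate the synthetic study inputs.

Writes a GENEPOP genotype file (3 stocks x 5 rivers x 30 individuals,
stock-level FST ~ 0.10, river-level ~ 0.01), river metadata with coordinates
along a synthetic coast, a demographic series table (declining / stable /
increasing stocks), and the ocean raster used for marine distances.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stockpriority.genotype_io import write_genepop
from stockpriority.synthetic_data import (
    GenotypeSimSpec,
    SeriesSimSpec,
    simulate_coastline,
    simulate_genotypes,
    simulate_series,
)
from stockpriority.workflow import STOCK_DESIGNS

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    spec = GenotypeSimSpec(individuals_per_river=30, seed=int(rng.integers(2**31 - 1)))
    ds, truth = simulate_genotypes(spec)
    write_genepop(ds, OUT / "genotypes.gen")
    truth.to_csv(OUT / "truth.csv", index=False)

    grid, mouths = simulate_coastline(
        n_rivers=spec.n_stocks * spec.rivers_per_stock,
        grid_size=80,
        seed=int(rng.integers(2**31 - 1)),
    )
    codes = ds.river_codes  # stocks laid out south -> north along the coast
    meta = pd.DataFrame(
        {
            "code": codes,
            "lat": [m.latitude for m in mouths],
            "lon": [m.longitude for m in mouths],
            "state": "",
            "stock": truth.drop_duplicates("river").set_index("river")["stock"].loc[codes].values,
        }
    )
    meta.to_csv(OUT / "river_metadata.csv", index=False)
    np.savetxt(OUT / "ocean_mask.txt", grid.mask.astype(int), fmt="%d")
    (OUT / "ocean_grid.json").write_text(
        json.dumps({"lat0": grid.lat0, "lon0": grid.lon0, "cell_deg": grid.cell_deg})
    )

    rows = []
    designs = list(STOCK_DESIGNS.values())
    for s in range(spec.n_stocks):
        design = designs[s % len(designs)]
        for r in range(3):  # 3 of 5 rivers per stock are monitored
            code = f"S{s+1}R{r+1}"
            ts = simulate_series(
                SeriesSimSpec(n_years=25, intercept=270.0,
                              slope=design["length_slope"], ar1_coefficient=0.2,
                              noise_sd=0.8, seed=int(rng.integers(2**31 - 1))),
                river_code=code, variable="mean_length", sex="F",
            )
            rows += [
                {"river": code, "variable": "mean_length", "sex": "F", "year": y, "value": v}
                for y, v in zip(ts.years, ts.values)
            ]
            if design["run_slope"] is not None:
                ts = simulate_series(
                    SeriesSimSpec(n_years=25, intercept=5000.0,
                                  slope=design["run_slope"], ar1_coefficient=0.2,
                                  noise_sd=60.0, seed=int(rng.integers(2**31 - 1))),
                    river_code=code, variable="run_count", sex="pooled",
                )
                rows += [
                    {"river": code, "variable": "run_count", "sex": "pooled",
                     "year": y, "value": v}
                    for y, v in zip(ts.years, ts.values)
                ]
    pd.DataFrame(rows).to_csv(OUT / "series.csv", index=False)
    print(f"wrote genotypes ({sum(c.n for c in ds.collections)} individuals, "
          f"{ds.n_loci} loci), metadata, series and ocean grid to {OUT}")


if __name__ == "__main__":
    main()
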