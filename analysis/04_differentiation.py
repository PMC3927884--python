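"""Among-river differentiation: theta, theta', genic tests, AMOVA, DA."""

from pathlib import Path

import pandas as pd

from stockpriority import differentiation as diff
from stockpriority.genotype_io import read_genepop, read_river_metadata

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_genepop(BASE / "synthetic" / "genotypes.gen")
    meta = read_river_metadata(BASE / "synthetic" / "river_metadata.csv")
    grouping = {m.river_code: m.stock_label for m in meta}

    theta, per_locus = diff.wc_theta(ds)
    g_theta, g_max, g_prime = diff.global_fst_standardized(ds)
    print(f"global theta = {theta:.4f}, theta_max = {g_max:.4f}, "
          f"theta' = {g_prime:.4f}")

    pm = diff.pairwise_theta(ds)
    pm.to_frame().to_csv(BASE / "pairwise_theta.csv")
    pmp = diff.pairwise_theta(ds, standardized=True)
    pmp.to_frame().to_csv(BASE / "pairwise_theta_prime.csv")
    da = diff.nei_da_matrix(ds)
    da.to_frame().to_csv(BASE / "pairwise_da.csv")

    genic = diff.genic_test(ds, n_perm=499, seed=7)
    print(f"genic heterogeneity across all rivers: combined p = "
          f"{genic['combined_p']:.2e} (chi2 = {genic['chi2']:.1f}, df {genic['df']})")

    am = diff.amova3(ds, grouping, n_perm=199, seed=7)
    pd.DataFrame(
        {"percent": am.percentages, "p": am.p_values | {"within_pops": None}}
    ).to_csv(BASE / "amova.csv")
    print(f"AMOVA: among stocks {am.percentages['among_groups']:.2f}% "
          f"(p={am.p_values['phi_CT']:.3f}), among rivers within stocks "
          f"{am.percentages['among_pops_within']:.2f}% "
          f"(p={am.p_values['phi_SC']:.3f})")


if __name__ == "__main__":
    main()
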