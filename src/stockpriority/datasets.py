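"""Bundled reference tables for US river herring populations.

Two small published summary tables ship with the package:

* ``genetic_collections.csv`` — the coastal sampling design for the
  microsatellite survey: one row per (river, year) collection with the number
  of specimens genotyped (2008–2012, Maine to Florida).
* ``priority_table.csv`` — the published per-river conservation
  prioritizations for both species, with stock membership (NNE/SNE/MAT/SAT)
  and whether the river has demographic monitoring.

The raw genotypes behind the survey are not publicly deposited, so analyses
that need genotypes run on synthetic data (see :mod:`.synthetic_data`); the
bookkeeping quantities (specimen totals, river counts, priority tallies) are
computed from these tables.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genotype_io import Collection, GenotypeDataset, Locus


def _read(name: str) -> pd.DataFrame:
    with resources.files("stockpriority.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_genetic_collections(species: str | None = None) -> pd.DataFrame:
    """Sampling design rows (species, river, code, state, year, n)."""
    df = _read("genetic_collections.csv")
    if species is not None:
        df = df[df["species"] == species].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"unknown species {species!r}")
    return df


def load_priority_table(species: str) -> pd.DataFrame:
    """Published priority table for one species.

    Returns columns (state, river, demographic_data, stock, designation) with
    rivers outside the species' assessed range dropped.
    """
    df = _read("priority_table.csv")
    prefix = {"alewife": "ale", "blueback": "bb"}.get(species)
    if prefix is None:
        raise ValueError(f"unknown species {species!r}")
    out = df[["state", "river"]].copy()
    out["demographic_data"] = df[f"{prefix}_demographic"]
    out["stock"] = df[f"{prefix}_stock"]
    out["designation"] = df[f"{prefix}_priority"].str.lower()
    return out.dropna(subset=["stock"]).reset_index(drop=True)


def sampling_dataset(species: str, seed: int = 0) -> GenotypeDataset:
    """GenotypeDataset with the published collection structure.

    Genotypes themselves are synthetic placeholders (one locus, random
    alleles) since the survey genotypes are not deposited; collection sizes,
    river codes and years follow the published design, so dataset-level
    bookkeeping (per-river and total specimen counts) is faithful.
    """
    rng = np.random.default_rng(seed)
    rows = load_genetic_collections(species)
    loci = [Locus("placeholder")]
    collections = []
    for _, row in rows.iterrows():
        n = int(row["n"])
        geno = rng.choice([100, 102, 104], size=(n, 1, 2)).astype(np.int32)
        collections.append(Collection(str(row["code"]), int(row["year"]), geno))
    return GenotypeDataset(loci, collections, species_label=species)
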