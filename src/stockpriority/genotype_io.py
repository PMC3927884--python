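"""Genotype containers and GENEPOP text I/O.

The analysis unit throughout the package is the *collection*: all individuals
genotyped from one river in one year.  Rivers sampled in several years carry
one collection per year; after temporal homogeneity has been established the
years are pooled with :func:`pool_temporal_replicates` and rivers become the
unit of reporting.

Genotypes are stored as integer allele codes (microsatellite fragment lengths);
``0`` is the missing code.  An individual missing one allele at a locus is
treated as wholly missing at that locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = 0


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    ``repeat_unit_length`` (in base pairs) converts fragment lengths to repeat
    numbers for the lnRV neutrality screen; it defaults to a dinucleotide
    repeat, the most common motif in these marker panels.
    """

    name: str
    repeat_unit_length: int = 2

    def __post_init__(self) -> None:
        if self.repeat_unit_length < 1:
            raise ValueError(f"repeat_unit_length must be >= 1 for locus {self.name}")


@dataclass
class Collection:
    """Diploid genotypes for one (river, year) sample.

    ``genotypes`` has shape (n_individuals, n_loci, 2) with integer allele
    codes, 0 = missing.  A half-missing call (one allele 0) is normalised to
    fully missing on construction.
    """

    river_code: str
    year: int | None
    genotypes: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.river_code:
            raise ValueError("river_code must be nonempty")
        g = np.asarray(self.genotypes, dtype=np.int32)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        half = (g == MISSING).any(axis=2)
        g[half] = MISSING
        self.genotypes = g
        if not self.individual_ids:
            self.individual_ids = [
                f"{self.river_code}_{i + 1}" for i in range(g.shape[0])
            ]
        elif len(self.individual_ids) != g.shape[0]:
            raise ValueError("individual_ids length mismatch")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci): genotype wholly missing."""
        return (self.genotypes == MISSING).all(axis=2)


@dataclass
class GenotypeDataset:
    loci: list[Locus]
    collections: list[Collection]
    species_label: str = ""

    def __post_init__(self) -> None:
        if not self.collections:
            raise ValueError("dataset needs at least one collection")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        L = len(self.loci)
        for col in self.collections:
            if col.genotypes.shape[1] != L:
                raise ValueError(
                    f"collection {col.river_code} has {col.genotypes.shape[1]} loci, expected {L}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def river_codes(self) -> list[str]:
        seen: list[str] = []
        for c in self.collections:
            if c.river_code not in seen:
                seen.append(c.river_code)
        return seen

    def subset(self, river_codes: list[str]) -> "GenotypeDataset":
        cols = [c for c in self.collections if c.river_code in set(river_codes)]
        if not cols:
            raise ValueError(f"no collections match {river_codes}")
        return GenotypeDataset(self.loci, cols, self.species_label)


@dataclass(frozen=True)
class RiverMetadata:
    river_code: str
    latitude: float
    longitude: float
    state: str = ""
    stock_label: str | None = None

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")


# ---------------------------------------------------------------------------
# GENEPOP text format


def _detect_width(token: str) -> int:
    if len(token) == 4:
        return 2
    if len(token) == 6:
        return 3
    raise ValueError(f"unknown allele-code width in genotype token {token!r}")


def read_genepop(path, species_label: str = "") -> GenotypeDataset:
    """Read a GENEPOP file: title line, locus names, POP blocks.

    Allele-code width (2 or 3 digits) is auto-detected from the first genotype
    token; mixed widths are rejected.  ``00``/``000`` is the missing code.
    Population names are taken from the individual id before the comma of the
    first individual in each POP block (GENEPOP convention).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise ValueError("file too short to be GENEPOP")
    it = iter(enumerate(lines[1:], start=2))
    locus_names: list[str] = []
    pop_starts: list[int] = []
    body: list[tuple[int, str]] = []
    in_header = True
    for lineno, ln in it:
        stripped = ln.strip()
        if in_header:
            if stripped.upper() == "POP":
                in_header = False
                pop_starts.append(len(body))
                continue
            if "," in stripped and not stripped.upper() == "POP":
                locus_names.extend(t.strip() for t in stripped.split(",") if t.strip())
            elif stripped:
                locus_names.append(stripped)
        else:
            if stripped.upper() == "POP":
                pop_starts.append(len(body))
            elif stripped:
                body.append((lineno, stripped))
    if not locus_names:
        raise ValueError("no locus names found")
    if not pop_starts:
        raise ValueError("no POP blocks found")
    pop_starts.append(len(body))

    width: int | None = None
    loci = [Locus(nm) for nm in locus_names]
    L = len(loci)
    collections: list[Collection] = []
    for b, (start, stop) in enumerate(zip(pop_starts[:-1], pop_starts[1:])):
        if start == stop:
            raise ValueError(f"empty POP block #{b + 1}")
        rows = []
        ids = []
        for lineno, ln in body[start:stop]:
            if "," not in ln:
                raise ValueError(f"line {lineno}: missing ',' separator")
            ident, geno = ln.split(",", 1)
            tokens = geno.split()
            if len(tokens) != L:
                raise ValueError(
                    f"line {lineno}: expected {L} genotypes, got {len(tokens)}"
                )
            if width is None:
                width = _detect_width(tokens[0])
            row = np.empty((L, 2), dtype=np.int32)
            for j, tok in enumerate(tokens):
                if len(tok) != 2 * width:
                    raise ValueError(
                        f"line {lineno}: genotype token {tok!r} does not match "
                        f"{width}-digit allele codes"
                    )
                row[j, 0] = int(tok[:width])
                row[j, 1] = int(tok[width:])
            rows.append(row)
            ids.append(ident.strip())
        river_code = ids[0].split("_")[0] if ids else f"POP{b + 1}"
        collections.append(
            Collection(river_code, None, np.stack(rows), individual_ids=ids)
        )
    return GenotypeDataset(loci, collections, species_label)


def write_genepop(ds: GenotypeDataset, path, title: str | None = None) -> None:
    """Write ``ds`` in 3-digit GENEPOP format (re-parses to an equal dataset)."""
    if int(max((ds_max := _max_allele(ds)), 0)) > 999:
        raise ValueError(f"allele code {ds_max} exceeds 3 digits")
    with open(path, "w") as fh:
        fh.write((title or ds.species_label or "stockpriority export") + "\n")
        for loc in ds.loci:
            fh.write(loc.name + "\n")
        for col in ds.collections:
            if col.n == 0:
                raise ValueError(f"collection {col.river_code} is empty")
            fh.write("POP\n")
            for i in range(col.n):
                toks = [
                    f"{col.genotypes[i, j, 0]:03d}{col.genotypes[i, j, 1]:03d}"
                    for j in range(ds.n_loci)
                ]
                fh.write(f"{col.individual_ids[i]} , " + " ".join(toks) + "\n")


def _max_allele(ds: GenotypeDataset) -> int:
    return max(int(c.genotypes.max(initial=0)) for c in ds.collections)


# ---------------------------------------------------------------------------


def pool_temporal_replicates(ds: GenotypeDataset, river_code: str) -> Collection:
    """Merge all yearly collections of one river into a single collection.

    Used after temporal homogeneity among replicate years has been established
    (nonsignificant among-collection variation), so rivers become the analysis
    unit.
    """
    parts = [c for c in ds.collections if c.river_code == river_code]
    if not parts:
        raise ValueError(f"unknown river code {river_code!r}")
    if len(parts) == 1:
        return parts[0]
    genos = np.concatenate([c.genotypes for c in parts], axis=0)
    ids = [i for c in parts for i in c.individual_ids]
    return Collection(river_code, None, genos, individual_ids=ids)


def pool_all(ds: GenotypeDataset) -> GenotypeDataset:
    """Dataset with one pooled collection per river."""
    cols = [pool_temporal_replicates(ds, r) for r in ds.river_codes]
    return GenotypeDataset(ds.loci, cols, ds.species_label)


def summarize_dataset(ds: GenotypeDataset | None) -> pd.DataFrame:
    """Per-river sample sizes: columns (river, years, n), plus a TOTAL row."""
    if ds is None or not getattr(ds, "collections", None):
        return pd.DataFrame(columns=["river", "years", "n"])
    rows = []
    for river in ds.river_codes:
        parts = [c for c in ds.collections if c.river_code == river]
        years = ", ".join(str(c.year) for c in parts if c.year is not None)
        rows.append({"river": river, "years": years, "n": sum(c.n for c in parts)})
    out = pd.DataFrame(rows)
    total = pd.DataFrame([{"river": "TOTAL", "years": "", "n": int(out["n"].sum())}])
    return pd.concat([out, total], ignore_index=True)


def read_river_metadata(path) -> list[RiverMetadata]:
    """Read river metadata CSV with columns code,lat,lon[,state][,stock]."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        out.append(
            RiverMetadata(
                river_code=str(row[cols["code"]]),
                latitude=float(row[cols["lat"]]),
                longitude=float(row[cols["lon"]]),
                state=str(row[cols["state"]]) if "state" in cols else "",
                stock_label=(
                    str(row[cols["stock"]])
                    if "stock" in cols and pd.notna(row[cols["stock"]])
                    else None
                ),
            )
        )
    return out


def recode_collection(col: Collection, offset: int) -> Collection:
    """Shift all non-missing allele codes by ``offset`` (used for FST(max))."""
    g = col.genotypes.copy()
    g[g != MISSING] += offset
    return replace(col, genotypes=g)
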