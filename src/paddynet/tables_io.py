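"""Readers, writers and validated containers for the tabular inputs.

Three kinds of tables flow through the pipeline:

* soil physicochemical profiles (organic matter, pH, CEC, EC, texture,
  N/P/K fractions), one row per sampled field;
* heavy-metal concentrations, total and DTPA-extractable, in mg/kg;
* OTU count tables (samples x taxa) with optional taxonomy lineages.

All containers validate on construction, so downstream stages can assume
well-formed data.  TSV is the canonical on-disk dialect; CSV is accepted
via the ``sep`` argument.  An explicit ``NA`` token is permitted in general
input (excluded, with a logged count, from stages needing that column);
the packaged fixtures contain no missing values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METALS = ("Cd", "Cu", "Pb", "Zn")

#: accepted (case-insensitive) header aliases -> canonical soil column names
SOIL_ALIASES = {
    "som": "som", "som(g/kg)": "som", "organic_matter": "som",
    "ph": "ph",
    "cec": "cec", "cec(cmol/kg)": "cec",
    "ec": "ec", "ec(ms/m)": "ec",
    "clay": "clay", "clay(%)": "clay",
    "silt": "silt", "silt(%)": "silt",
    "sand": "sand", "sand(%)": "sand",
    "tn": "tn", "tn(g/kg)": "tn",
    "an": "an", "an(mg/kg)": "an",
    "ap": "ap", "ap(mg/kg)": "ap",
    "ak": "ak", "ak(mg/kg)": "ak",
    "sample_id": "sample_id", "samples": "sample_id", "sample": "sample_id",
}

SOIL_COLUMNS = ("som", "ph", "cec", "ec", "clay", "silt", "sand",
                "tn", "an", "ap", "ak")

TEXTURE_TOLERANCE = 0.5  # printed percentages are rounded to 2 decimals


class SchemaError(ValueError):
    """A required column is missing or a header cannot be interpreted."""


class TableParseError(ValueError):
    """A cell could not be parsed; message carries row/column context."""


class TableValidationError(ValueError):
    """Values parsed but violate a table invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate {what}: {dupes}")


@dataclass
class SoilProfileTable:
    """Per-sample soil physicochemical properties.

    Units: som, tn in g/kg; cec in cmol/kg; ec in ms/m; clay/silt/sand in
    percent (must sum to 100 +- 0.5); an, ap, ak in mg/kg; ph unitless.
    """

    data: pd.DataFrame  # index sample_id, columns SOIL_COLUMNS

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SOIL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"soil table missing column(s): {missing}")
        _check_unique(df.index, "sample_id")
        vals = df[list(SOIL_COLUMNS)]
        present = vals.notna()
        if ((vals < 0) & present).any().any():
            bad = vals.columns[((vals < 0) & present).any()].tolist()
            raise TableValidationError(f"negative values in column(s): {bad}")
        ph = df["ph"].dropna()
        if ((ph <= 0) | (ph >= 14)).any():
            raise TableValidationError("pH outside (0, 14)")
        texture = df[["clay", "silt", "sand"]].dropna()
        sums = texture.sum(axis=1)
        off = sums[(sums - 100.0).abs() > TEXTURE_TOLERANCE]
        if len(off):
            raise TableValidationError(
                "clay+silt+sand outside 100 +- "
                f"{TEXTURE_TOLERANCE} for sample(s) {off.index.tolist()} "
                f"(sums {off.round(3).tolist()})"
            )
        n_na = int(vals.isna().sum().sum())
        if n_na:
            logger.info("soil table carries %d NA cell(s); affected samples "
                        "are excluded from stages needing those columns", n_na)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        out = self.data.reset_index(names="sample_id")
        out.to_csv(path, sep=sep, index=False, float_format="%.12g")


@dataclass
class MetalTable:
    """Total and DTPA-extractable metal concentrations (mg/kg) per sample."""

    total: pd.DataFrame  # index sample_id, columns metals
    dtpa: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.total.index, "sample_id")
        if not self.total.index.equals(self.dtpa.index):
            raise TableValidationError("total/dtpa sample sets differ")
        for df, what in ((self.total, "total"), (self.dtpa, "dtpa")):
            if (df.fillna(0) < 0).any().any():
                raise TableValidationError(f"negative {what} concentration")
        common = [m for m in self.dtpa.columns if m in self.total.columns]
        exceed = (self.dtpa[common] > self.total[common]).any(axis=1)
        if exceed.any():
            warnings.warn(
                "DTPA-extractable exceeds total for sample(s) "
                f"{self.total.index[exceed].tolist()}", stacklevel=2)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.total.index)

    @property
    def metals(self) -> list[str]:
        return list(self.total.columns)

    def row(self, sample_id: str) -> dict[str, float]:
        """Total concentrations for one sample as metal -> mg/kg."""
        return self.total.loc[sample_id].to_dict()

    def write(self, path: str | Path, sep: str = "\t") -> None:
        out = pd.DataFrame(index=self.total.index)
        for m in self.total.columns:
            out[f"T-{m}"] = self.total[m]
        for m in self.dtpa.columns:
            out[f"A-{m}"] = self.dtpa[m]
        out.reset_index(names="sample_id").to_csv(
            path, sep=sep, index=False, float_format="%.12g")


@dataclass
class BackgroundTable:
    """Regional background concentrations (mg/kg) used as CF denominators."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        self.values = dict(self.values)
        for metal, v in self.values.items():
            if not v > 0:
                raise TableValidationError(
                    f"background for {metal} must be strictly positive, got {v}")

    def __getitem__(self, metal: str) -> float:
        return self.values[metal]

    def covers(self, metals: Sequence[str]) -> bool:
        return all(m in self.values for m in metals)


@dataclass
class OTUTable:
    """Integer count matrix (samples x taxa) with optional taxonomy lineages."""

    counts: pd.DataFrame  # index sample_id, columns otu_id; integer dtype
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "sample_id")
        _check_unique(df.columns, "otu_id")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = np.abs(arr - np.round(arr))
            if np.nanmax(frac) > 1e-6:
                i, j = np.unravel_index(np.nanargmax(frac), frac.shape)
                raise TableParseError(
                    f"non-integer count {arr[i, j]} at sample "
                    f"{df.index[i]!r}, OTU {df.columns[j]!r}")
            self.counts = df.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise TableValidationError("negative counts")
        zero = self.counts.sum(axis=1) == 0
        if zero.any():
            raise TableValidationError(
                f"all-zero sample(s): {df.index[zero].tolist()}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OTUTable":
        tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OTUTable(self.counts[list(otu_ids)].copy(), tax)

    def write(self, path: str | Path, sep: str = "\t",
              orientation: str = "taxa_rows") -> None:
        if orientation == "taxa_rows":
            out = self.counts.T
            out.index.name = "otu_id"
            out = out.reset_index()
            if self.taxonomy:
                out["taxonomy"] = [self.taxonomy.get(o, "Unclassified")
                                   for o in out["otu_id"]]
        else:
            out = self.counts.reset_index(names="sample_id")
        out.to_csv(path, sep=sep, index=False)


def _read_numeric(df: pd.DataFrame, context: str) -> pd.DataFrame:
    """Coerce a frame to float, raising TableParseError with cell context."""
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col].replace("NA", np.nan), errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str) != "NA")
        blank = df[col].isna()
        if bad.any() or blank.any():
            row = int(np.argmax((bad | blank).to_numpy())) + 1
            raise TableParseError(
                f"{context}: non-numeric or blank value in column "
                f"{col!r}, row {row}")
        out[col] = coerced
    return pd.DataFrame(out, index=df.index)


def read_soil_table(path: str | Path, sep: str = "\t") -> SoilProfileTable:
    """Read a soil-property table; header aliases are case-insensitive."""
    raw = pd.read_csv(path, sep=sep, dtype=str)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower().replace(" ", "")
        if key in SOIL_ALIASES:
            rename[col] = SOIL_ALIASES[key]
            if col != SOIL_ALIASES[key]:
                logger.debug("soil header alias %r -> %r", col, rename[col])
    raw = raw.rename(columns=rename)
    if "sample_id" not in raw.columns:
        raise SchemaError("soil table missing column(s): ['sample_id']")
    missing = [c for c in SOIL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"soil table missing column(s): {missing}")
    body = _read_numeric(raw.set_index("sample_id")[list(SOIL_COLUMNS)],
                         str(path))
    return SoilProfileTable(body)


def read_metal_table(path: str | Path, sep: str = "\t") -> MetalTable:
    """Read a metal table with ``T-<metal>`` / ``A-<metal>`` columns.

    Extra metal columns beyond Cd/Cu/Pb/Zn are accepted and carried
    through; non-metal extras (e.g. a printed PLI column) are ignored.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    id_col = next((c for c in raw.columns
                   if c.strip().lower() in ("sample_id", "samples", "sample")),
                  None)
    if id_col is None:
        raise SchemaError("metal table missing a sample_id column")
    raw = raw.set_index(id_col)
    totals, dtpas = {}, {}
    for col in raw.columns:
        name = col.strip()
        if name.upper().startswith("T-"):
            totals[name[2:]] = col
        elif name.upper().startswith("A-"):
            dtpas[name[2:]] = col
    missing = [m for m in METALS if m not in totals]
    if missing:
        raise SchemaError(f"metal table missing total column(s) for {missing}")
    total = _read_numeric(raw[[totals[m] for m in totals]], str(path))
    total.columns = list(totals)
    dtpa = _read_numeric(raw[[dtpas[m] for m in dtpas]], str(path))
    dtpa.columns = list(dtpas)
    return MetalTable(total=total, dtpa=dtpa)


def read_background_table(path: str | Path, sep: str = "\t") -> BackgroundTable:
    raw = pd.read_csv(path, sep=sep)
    cols = {c.strip().lower(): c for c in raw.columns}
    if "metal" not in cols:
        raise SchemaError("background table missing 'metal' column")
    value_col = next((cols[k] for k in cols
                      if k.startswith("background")), None)
    if value_col is None:
        raise SchemaError("background table missing 'background' value column")
    return BackgroundTable(dict(zip(raw[cols["metal"]], raw[value_col])))


def read_otu_table(path: str | Path, sep: str = "\t",
                   orientation: str = "taxa_rows") -> OTUTable:
    """Read an OTU count table, normalising orientation to samples x taxa.

    ``taxa_rows`` (the common ``#OTU ID`` layout, first column otu_id,
    optional trailing ``taxonomy`` column) or ``samples_rows``.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=sep, comment=None)
    first = raw.columns[0]
    raw = raw.set_index(first)
    taxonomy: dict[str, str] = {}
    if orientation == "taxa_rows":
        tax_col = next((c for c in raw.columns
                        if c.strip().lower() == "taxonomy"), None)
        if tax_col is not None:
            taxonomy = raw[tax_col].astype(str).to_dict()
            raw = raw.drop(columns=[tax_col])
        counts = raw.T
        counts.index.name = "sample_id"
        counts.columns.name = "otu_id"
    else:
        counts = raw
        counts.index.name = "sample_id"
        counts.columns.name = "otu_id"
    counts = counts.apply(pd.to_numeric)
    return OTUTable(counts=counts, taxonomy=taxonomy)


def aggregate_phylum(table: OTUTable) -> pd.DataFrame:
    """Relative abundance per sample aggregated at phylum level.

    The phylum is the second ';'-separated field of each lineage;
    OTUs without one fall into ``Unclassified``.
    """
    rel = table.relative_abundance()
    phylum = {}
    for o in table.otu_ids:
        lineage = table.taxonomy.get(o, "")
        parts = [p.strip() for p in lineage.split(";")]
        phylum[o] = parts[1] if len(parts) > 1 and parts[1] else "Unclassified"
    return rel.T.groupby(pd.Series(phylum)).sum().T


def read_biom_otu_table(path: str | Path) -> OTUTable:
    """Read a BIOM 2.1 (HDF5) OTU table via the ``biom-format`` layout."""
    import h5py

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() for x in f["observation/ids"][:]]
        sample_ids = [x.decode() for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr),
                     shape=(len(otu_ids), len(sample_ids)))
    counts = pd.DataFrame(mat.toarray().T, index=sample_ids, columns=otu_ids)
    counts.index.name = "sample_id"
    return OTUTable(counts=counts)
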