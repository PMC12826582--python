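"""Readers and writers for the pipeline's tabular formats.

Morphology incidence tables, gene-by-sample count matrices with sample
metadata, and GMT gene-set annotations. All readers validate their input and
raise ``ValueError`` with an actionable message on malformed files; every
writer produces a file its paired reader accepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Declared vocabulary of morphological endpoints.
ENDPOINTS = (
    "mortality",
    "cranial",
    "axis",
    "edema",
    "muscular/cardiovascular",
    "lower trunk",
    "brain",
    "skin/pigmentation",
    "notochord",
    "x-fin",
)

MORPHOLOGY_COLUMNS = [
    "line",
    "chemical",
    "concentration_uM",
    "timepoint_hpf",
    "endpoint",
    "n_affected",
    "n_total",
]


@dataclass
class MorphologyTable:
    """Dichotomous incidence per (line, chemical, concentration, timepoint, endpoint)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(MORPHOLOGY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"morphology table missing columns: {sorted(missing)}")
        bad = set(df["endpoint"]) - set(ENDPOINTS)
        if bad:
            raise ValueError(
                f"unknown endpoints {sorted(bad)}; allowed vocabulary: {list(ENDPOINTS)}"
            )
        if (df["n_affected"] > df["n_total"]).any() or (df["n_affected"] < 0).any():
            raise ValueError("n_affected must satisfy 0 <= n_affected <= n_total")
        if (df["concentration_uM"] < 0).any():
            raise ValueError("concentrations must be >= 0")

    def subset(self, **selectors) -> "MorphologyTable":
        df = self.data
        for key, value in selectors.items():
            df = df[df[key] == value]
        return MorphologyTable(df.reset_index(drop=True))

    def incidence(self, endpoint: str, **selectors) -> pd.DataFrame:
        """(concentration_uM, n_affected, n_total) rows for one endpoint, summed."""
        df = self.subset(endpoint=endpoint, **selectors).data
        agg = (
            df.groupby("concentration_uM", as_index=False)[["n_affected", "n_total"]]
            .sum()
            .sort_values("concentration_uM")
        )
        return agg.reset_index(drop=True)


@dataclass
class CountMatrix:
    """Raw integer gene-by-sample counts plus per-sample metadata.

    ``counts`` is genes x samples; ``metadata`` is indexed by sample id with
    columns chemical, concentration_uM, timepoint_hpf, replicate.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()][:5]
            raise ValueError(f"duplicate gene ids: {list(dups)}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.metadata.index[mask.loc[self.metadata.index]]
        return CountMatrix(self.counts[list(keep)].copy(), self.metadata.loc[keep].copy())

    def select(self, **conditions) -> "CountMatrix":
        """Subset samples by metadata equality, e.g. ``select(timepoint_hpf=48)``."""
        mask = pd.Series(True, index=self.metadata.index)
        for key, value in conditions.items():
            mask &= self.metadata[key] == value
        return self.subset_samples(mask)


@dataclass
class GroundTruthManifest:
    """Simulation ground truth: per-gene true model/BMC, per-endpoint true curve."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    endpoints: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# morphology CSV


def read_morphology(path: str | Path) -> MorphologyTable:
    """Read a morphology CSV, either aggregated or per-well.

    Per-well files carry columns (line, chemical, concentration_uM,
    timepoint_hpf, well, endpoint, affected) and are aggregated to
    (n_affected, n_total) per concentration group.
    """
    df = pd.read_csv(path)
    if "affected" in df.columns:
        if not df["affected"].isin((0, 1)).all():
            raise ValueError("per-well 'affected' must be 0 or 1")
        group_cols = ["line", "chemical", "concentration_uM", "timepoint_hpf", "endpoint"]
        agg = df.groupby(group_cols, as_index=False).agg(
            n_affected=("affected", "sum"), n_total=("affected", "size")
        )
        return MorphologyTable(agg)
    return MorphologyTable(df[MORPHOLOGY_COLUMNS].copy())


def write_morphology(table: MorphologyTable, path: str | Path) -> None:
    table.data[MORPHOLOGY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# counts TSV + metadata TSV


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_counts(matrix: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")
    matrix.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a tab-delimited GMT file into term -> gene set.

    Standard layout is ``term<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate genes within a term are deduplicated; an empty gene list is
    retained with a warning.
    """
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs term and description")
            term = parts[0]
            genes = {g for g in parts[2:] if g}
            if not genes:
                warnings.warn(f"GMT term {term!r} has an empty gene list")
            terms[term] = genes
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in terms:
            genes = sorted(terms[term])
            fh.write("\t".join([term, "na", *genes]) + "\n")
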