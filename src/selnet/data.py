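"""Core tabular containers and TSV/GMT input-output.

All tabular formats are tab-delimited UTF-8 with ``#`` comment lines.
Counts files carry gene ids in the first column and one column per sample;
metadata files carry ``sample_id``, ``line`` (HIGH/LOW, matched
case-insensitively) and ``region``. Exon count files prepend a ``gene_id``
and ``exon_id`` column pair to the sample columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINES = ("HIGH", "LOW")

__all__ = [
    "LINES",
    "CountMatrix",
    "NormalizedExpression",
    "ExonCountTable",
    "read_counts",
    "read_exon_counts",
    "read_gmt",
]


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with per-sample line/region metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = gene ids, columns = sample ids.
    meta : pandas.DataFrame
        Indexed by sample id with columns ``line`` and ``region``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicated gene ids: {list(dupes)[:5]}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicated sample ids in counts")
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise ValueError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.meta = self.meta.loc[self.counts.columns]
        self.meta.index.name = "sample_id"
        line = self.meta["line"].astype(str).str.upper()
        bad = sorted(set(line) - set(LINES))
        if bad:
            raise ValueError(f"unknown line labels {bad}; expected HIGH/LOW")
        self.meta = self.meta.assign(line=line)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, line: str) -> list[str]:
        line = line.upper()
        return list(self.meta.index[self.meta["line"] == line])

    def write(self, counts_path, meta_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        if meta_path is not None:
            m = self.meta.copy()
            m.index.name = "sample_id"
            m.to_csv(meta_path, sep="\t")


@dataclass
class NormalizedExpression:
    """Upper-quartile CPM and log2 CPM with the per-sample scale factors."""

    cpm: pd.DataFrame
    log2cpm: pd.DataFrame
    scale_factors: pd.Series
    meta: pd.DataFrame = field(default=None)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)

    def samples_of(self, line: str) -> list[str]:
        line = line.upper()
        return list(self.meta.index[self.meta["line"] == line])

    def write(self, cpm_path, factors_path=None) -> None:
        out = self.log2cpm.copy()
        out.index.name = "gene_id"
        out.to_csv(cpm_path, sep="\t", float_format="%.10g")
        if factors_path is not None:
            sf = self.scale_factors.rename("scale_factor")
            sf.index.name = "sample_id"
            sf.to_csv(factors_path, sep="\t", float_format="%.10g")


@dataclass
class ExonCountTable:
    """Long-form exon counts: one row per (gene, exon), one column per sample."""

    table: pd.DataFrame  # columns: gene_id, exon_id, <samples...>
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["gene_id", "exon_id"]:
            raise ValueError("first two columns must be gene_id, exon_id")
        if t.duplicated(["gene_id", "exon_id"]).any():
            raise ValueError("duplicated (gene_id, exon_id) pairs")
        vals = t.iloc[:, 2:].to_numpy()
        if (vals < 0).any():
            raise ValueError("negative exon counts")
        line = self.meta["line"].astype(str).str.upper()
        self.meta = self.meta.assign(line=line)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.columns[2:])

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def samples_of(self, line: str) -> list[str]:
        line = line.upper()
        return list(self.meta.index[self.meta["line"] == line])

    def counts_for(self, gene_id: str) -> pd.DataFrame:
        sub = self.table[self.table["gene_id"] == gene_id]
        return sub.set_index("exon_id").iloc[:, 1:]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _read_meta(meta_path) -> pd.DataFrame:
    meta = _read_tsv(meta_path, dtype=str)
    required = {"sample_id", "line", "region"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta.set_index("sample_id")


def read_counts(path, meta_path) -> CountMatrix:
    """Read a gene-level counts TSV plus its sample metadata TSV.

    The counts header row names the samples; the first column holds gene ids.
    Samples missing from the metadata are rejected by name.
    """
    df = _read_tsv(path, index_col=0)
    meta = _read_meta(meta_path)
    return CountMatrix(df, meta)


def read_exon_counts(path, meta_path) -> ExonCountTable:
    """Read an exon-level counts TSV (gene_id, exon_id, samples...)."""
    df = _read_tsv(path)
    meta = _read_meta(meta_path)
    return ExonCountTable(df, meta)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {raw[:60]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
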