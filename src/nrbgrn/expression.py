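"""Expression matrix container and TSV I/O.

The pipeline moves a single in-memory object between stages: a genes × samples
matrix (counts, coverage, or TPM) together with per-sample metadata
(developmental stage = phytomer index, tissue class, replicate) and optional
per-gene transcript lengths.  Everything is backed by pandas so downstream
stages can use ordinary DataFrame operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

VALID_UNITS = ("counts", "TPM", "coverage")

#: tissue class labels used throughout: nodal-root-bud pulvinus vs internode rind
NRB = "NRB"
INTERNODE = "internode"

META_COLUMNS = ["sample_id", "stage", "tissue_class", "replicate"]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene ID, columns by sample ID.  Non-negative.
    unit : str
        One of ``counts``, ``TPM``, ``coverage``.
    meta : DataFrame
        One row per sample: columns ``sample_id``, ``stage`` (nullable int),
        ``tissue_class`` (``NRB`` | ``internode``), ``replicate``.
    lengths : Series or None
        Gene → transcript length in bp (longest transcript per gene).
        Required for count/TPM conversions.
    """

    values: pd.DataFrame
    unit: str
    meta: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not self.values.index.is_unique:
            raise ValueError("gene IDs must be unique")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.meta = self.meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if list(self.values.columns) != list(self.meta["sample_id"]):
            raise ValueError("metadata sample order must match matrix columns")
        if self.lengths is not None:
            self.lengths = self.lengths.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, tissue_class: str | None = None, stage: int | None = None) -> list[str]:
        """Sample IDs matching a tissue class and/or stage."""
        mask = pd.Series(True, index=self.meta.index)
        if tissue_class is not None:
            mask &= self.meta["tissue_class"] == tissue_class
        if stage is not None:
            mask &= self.meta["stage"] == stage
        return list(self.meta.loc[mask, "sample_id"])

    def stages(self, tissue_class: str = NRB) -> list[int]:
        """Sorted distinct stages present for a tissue class."""
        sub = self.meta[self.meta["tissue_class"] == tissue_class]
        return sorted(int(s) for s in sub["stage"].dropna().unique())

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        absent = [g for g in genes if g not in self.values.index]
        if absent:
            raise KeyError(f"genes absent from matrix: {absent[:5]}")
        lengths = self.lengths.loc[genes] if self.lengths is not None else None
        return ExpressionMatrix(self.values.loc[genes], self.unit, self.meta.copy(), lengths)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        meta = self.meta[self.meta["sample_id"].isin(sample_ids)].copy()
        meta["sample_id"] = pd.Categorical(meta["sample_id"], categories=sample_ids, ordered=True)
        meta = meta.sort_values("sample_id").reset_index(drop=True)
        meta["sample_id"] = meta["sample_id"].astype(str)
        return ExpressionMatrix(self.values[sample_ids], self.unit, meta, self.lengths)


# -- TSV I/O -------------------------------------------------------------------
# All tables are plain TSV with an optional block of '# key=value' header
# comments recording the parameters that produced them.


def _write_with_comments(df: pd.DataFrame, path: str | Path, comments: dict | None, index: bool) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def write_matrix(expr: ExpressionMatrix, path: str | Path, comments: dict | None = None) -> None:
    header = {"unit": expr.unit}
    header.update(comments or {})
    df = expr.values.copy()
    df.index.name = "gene_id"
    _write_with_comments(df, path, header, index=True)


def write_meta(expr: ExpressionMatrix, path: str | Path) -> None:
    _write_with_comments(expr.meta[META_COLUMNS], path, None, index=False)


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    df = lengths.rename("length").to_frame()
    df.index.name = "gene_id"
    _write_with_comments(df, path, None, index=True)


def read_matrix(path: str | Path, meta_path: str | Path, unit: str,
                lengths_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes × samples TSV plus its sample-metadata TSV."""
    values = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values.index = values.index.astype(str)
    meta = read_meta(meta_path)
    lengths = read_lengths(lengths_path) if lengths_path is not None else None
    return ExpressionMatrix(values, unit, meta, lengths)


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    meta["stage"] = meta["stage"].astype("Int64")
    return meta


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    ser = df.iloc[:, 0].astype(float)
    ser.index = ser.index.astype(str)
    return ser
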