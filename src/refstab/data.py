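"""Core data containers and file readers.

Two matrices drive everything in this package:

* :class:`ExpressionMatrix` — a genes × samples table of bulk RNA-seq
  expression values (FPKM), the substrate of candidate screening.
* :class:`CtMatrix` — a genes × samples table of qRT-PCR cycle-threshold
  (Ct) values plus per-sample metadata (group label, material), the
  substrate of all stability estimation and validation.

Both are thin, validated wrappers around :class:`pandas.DataFrame`; the
underlying frame is always available as ``.values_frame`` and every
analysis entry point also accepts a bare DataFrame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CtMatrix",
    "NoGenesSurviveError",
    "read_expression_matrix",
    "read_sample_metadata",
    "read_ct_table",
]

CT_PLAUSIBLE_RANGE = (5.0, 40.0)


class NoGenesSurviveError(ValueError):
    """Raised when a filtering step removes every gene."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what} identifiers: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of non-negative expression values (FPKM).

    Parameters
    ----------
    values_frame : pandas.DataFrame
        Rows indexed by gene identifier, columns by sample identifier.
        All values must be finite and ≥ 0; at least 2 samples.
    """

    values_frame: pd.DataFrame

    def __post_init__(self) -> None:
        vf = pd.DataFrame(self.values_frame).astype(float)
        _check_unique(vf.index, "gene")
        _check_unique(vf.columns, "sample")
        if vf.shape[1] < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        arr = vf.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative (FPKM)")
        self.values_frame = vf

    @property
    def gene_ids(self) -> list:
        return list(self.values_frame.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values_frame.columns)

    @property
    def n_genes(self) -> int:
        return self.values_frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values_frame.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values_frame.loc[list(genes)])


@dataclass
class CtMatrix:
    """Genes × samples matrix of (collapsed) Ct values with sample metadata.

    Parameters
    ----------
    values_frame : pandas.DataFrame
        Rows indexed by gene, columns by sample; finite Ct values in cycles.
    meta : pandas.DataFrame, optional
        Indexed by sample identifier; recognised columns are
        ``class_label`` (tissue group / cell line level) and ``material``
        (``"tissue"`` or ``"cell_line"``).  Samples present in the matrix
        must be present in the metadata when metadata is given.
    provenance : str
        ``"raw_replicate_mean"`` or ``"simulated"``.
    """

    values_frame: pd.DataFrame
    meta: pd.DataFrame | None = None
    provenance: str = "raw_replicate_mean"

    def __post_init__(self) -> None:
        vf = pd.DataFrame(self.values_frame).astype(float)
        _check_unique(vf.index, "gene")
        _check_unique(vf.columns, "sample")
        arr = vf.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("Ct values must be finite")
        lo, hi = CT_PLAUSIBLE_RANGE
        if arr.size and ((arr < lo) | (arr > hi)).any():
            warnings.warn(
                f"Ct values outside the plausible range ({lo}, {hi}) cycles",
                stacklevel=2,
            )
        if self.meta is not None:
            meta = pd.DataFrame(self.meta)
            missing = [s for s in vf.columns if s not in meta.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing[:5]}")
            self.meta = meta
        self.values_frame = vf

    @property
    def gene_ids(self) -> list:
        return list(self.values_frame.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values_frame.columns)

    @property
    def n_genes(self) -> int:
        return self.values_frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values_frame.shape[1]

    def groups(self) -> pd.Series | None:
        """Per-sample class labels aligned to the matrix columns, if known."""
        if self.meta is None or "class_label" not in self.meta.columns:
            return None
        return self.meta.loc[self.sample_ids, "class_label"]

    def subset_samples(self, samples) -> "CtMatrix":
        samples = list(samples)
        meta = None if self.meta is None else self.meta.loc[samples]
        return CtMatrix(self.values_frame[samples], meta, self.provenance)

    def select(self, **meta_filters) -> "CtMatrix":
        """Restrict to samples whose metadata matches every filter.

        ``ct.select(material="tissue")`` keeps tissue samples only; values
        may be scalars or collections of accepted levels.
        """
        if self.meta is None:
            raise ValueError("no metadata attached; cannot filter samples")
        keep = pd.Series(True, index=self.meta.index)
        for col, val in meta_filters.items():
            if col not in self.meta.columns:
                raise KeyError(f"metadata has no column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                keep &= self.meta[col].isin(list(val))
            else:
                keep &= self.meta[col] == val
        samples = [s for s in self.sample_ids if keep.get(s, False)]
        if not samples:
            raise ValueError(f"no samples match {meta_filters!r}")
        return self.subset_samples(samples)


def _read_table(path, **kw) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, **kw)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV (first column gene IDs, header samples)."""
    df = _read_table(path, index_col=0)
    return ExpressionMatrix(df)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV/TSV with columns sample,class_label[,material]."""
    df = _read_table(path)
    if "sample" not in df.columns:
        raise ValueError("metadata file must have a 'sample' column")
    df = df.set_index("sample")
    if df.index.has_duplicates:
        raise ValueError("duplicated sample identifiers in metadata")
    if "class_label" not in df.columns:
        raise ValueError("metadata file must have a 'class_label' column")
    return df


def read_ct_table(path, meta_path=None, *, form: str = "auto") -> pd.DataFrame:
    """Read a replicate-level Ct table into a long DataFrame.

    Accepts either the long form (columns ``sample,gene,replicate,ct``) or
    the wide form (gene rows × sample columns, implicitly one replicate).
    Returns a long DataFrame with exactly those four columns; pass the
    result to :func:`refstab.qpcr.collapse_technical_replicates` to obtain
    a :class:`CtMatrix`.

    Parameters
    ----------
    path : path-like
        Ct table file.
    meta_path : path-like, optional
        Sample metadata; when given, every sample in the Ct table must be
        present in it (unknown samples raise).
    form : {"auto", "long", "wide"}
    """
    df = _read_table(path)
    long_cols = {"sample", "gene", "replicate", "ct"}
    if form == "auto":
        form = "long" if long_cols.issubset(df.columns) else "wide"

    if form == "long":
        missing = long_cols - set(df.columns)
        if missing:
            raise ValueError(f"long-form Ct table missing columns: {sorted(missing)}")
        long = df.loc[:, ["sample", "gene", "replicate", "ct"]].copy()
    else:
        wide = _read_table(path, index_col=0)
        long = (
            wide.reset_index(names="gene")
            .melt(id_vars="gene", var_name="sample", value_name="ct")
            .assign(replicate=1)
        )

    bad = pd.to_numeric(long["ct"], errors="coerce")
    if bad.isna().any():
        row = long.index[bad.isna()][0]
        raise ValueError(
            f"non-numeric Ct value {long.loc[row, 'ct']!r} at row {row} "
            f"(sample={long.loc[row, 'sample']!r}, gene={long.loc[row, 'gene']!r})"
        )
    long["ct"] = bad

    dup = long.duplicated(subset=["sample", "gene", "replicate"])
    if dup.any():
        first = long.loc[dup.idxmax()]
        raise ValueError(
            "duplicate (sample, gene, replicate) rows, e.g. "
            f"({first['sample']!r}, {first['gene']!r}, {first['replicate']!r})"
        )

    if meta_path is not None:
        meta = read_sample_metadata(meta_path)
        unknown = sorted(set(long["sample"]) - set(meta.index))
        if unknown:
            raise ValueError(f"Ct table samples absent from metadata: {unknown[:5]}")
        long.attrs["meta"] = meta
    return long
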