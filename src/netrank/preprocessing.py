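"""Loading, cleaning, normalization and splitting of expression data.

The in-memory substrate throughout the package is a plain
:class:`pandas.DataFrame` with genes in rows and samples in columns
(numeric values), and phenotype labels as a :class:`pandas.Series`
indexed by sample ID with values in {0, 1} (1 = case, 0 = control).

The canonical order of operations mirrors a typical expression pipeline:
load -> clean (drop duplicated / incomplete samples) -> per-gene min-max
normalization -> stratified development/test split.  Normalization is
applied to the full matrix before splitting by default; this leaks the
test extremes into the scaler and callers wanting the stricter variant
should normalize dev and test separately after :func:`split_dev_test`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CleanReport",
    "load_expression",
    "load_labels",
    "clean",
    "minmax_normalize",
    "split_dev_test",
    "write_expression",
]


@dataclass
class CleanReport:
    """Record of samples removed by :func:`clean` and why.

    ``removed`` maps sample ID to a reason string, either ``"duplicate"``
    (a later column repeating an already-seen sample ID) or ``"missing"``
    (the sample column contained at least one missing value).
    """

    removed: dict[str, str] = field(default_factory=dict)

    def __bool__(self) -> bool:  # truthy iff anything was removed
        return bool(self.removed)


def load_expression(path, orientation: str = "genes") -> pd.DataFrame:
    """Read a delimited expression table into a genes x samples frame.

    Parameters
    ----------
    path
        TSV/CSV file with one header row and one leading ID column.
        The delimiter is sniffed (tab or comma).
    orientation
        ``"genes"`` if rows are genes (default), ``"samples"`` if rows
        are samples; the latter is transposed so the returned frame is
        always genes x samples.

    IDs are preserved verbatim, including duplicates — duplicate and
    missing-value handling is :func:`clean`'s job, not the loader's.
    """
    if orientation not in ("genes", "samples"):
        raise ValueError(f"orientation must be 'genes' or 'samples', got {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"no data rows in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate the first non-numeric cell, if any, for a useful message
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    if orientation == "samples":
        df = df.T
    df = df.astype(float)
    df.index.name = "gene_id"
    df.columns.name = None
    return df


def load_labels(path) -> pd.Series:
    """Read a two-column ``sample_id<TAB>label`` table.

    Labels may be 0/1 integers or the strings ``case``/``control``
    (case-insensitive).  Returns an int Series (1 = case) indexed by
    sample ID.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 columns in label file {path}, got {df.shape[1]}")
    sample_ids = df.iloc[:, 0].astype(str)
    raw = df.iloc[:, 1]
    mapping = {"case": 1, "control": 0, "1": 1, "0": 0}
    labels = raw.astype(str).str.strip().str.lower().map(mapping)
    if labels.isna().any():
        bad = raw[labels.isna()].iloc[0]
        raise ValueError(f"unrecognized label {bad!r}; expected 0/1 or case/control")
    if sample_ids.duplicated().any():
        dup = sample_ids[sample_ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample ID in label file: {dup!r}")
    return pd.Series(labels.to_numpy(dtype=int), index=pd.Index(sample_ids, name="sample_id"))


def clean(expr: pd.DataFrame) -> tuple[pd.DataFrame, CleanReport]:
    """Drop duplicated and incomplete sample columns.

    Duplicated sample IDs keep the first occurrence; samples with any
    missing value are removed.  Returns the cleaned matrix together with
    a :class:`CleanReport` listing every removed sample and the reason.

    Raises
    ------
    ValueError
        If no samples survive cleaning.
    """
    report = CleanReport()
    dup_mask = expr.columns.duplicated(keep="first")
    for sid in expr.columns[dup_mask]:
        report.removed[str(sid)] = "duplicate"
    out = expr.loc[:, ~dup_mask]
    missing = out.columns[out.isna().any(axis=0)]
    for sid in missing:
        report.removed[str(sid)] = "missing"
    out = out.drop(columns=missing)
    if out.shape[1] == 0:
        raise ValueError("empty matrix after cleaning")
    return out, report


def minmax_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Map each gene linearly onto [0, 1] across all samples.

    Per gene g: ``x -> (x - min_g) / (max_g - min_g)``.  Constant genes
    (min == max) are mapped to all-zeros with a warning — the scaler is
    undefined for them and zeros leave them inert in the correlation and
    network stages downstream.
    """
    values = expr.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0.0).ravel()
    if constant.any():
        names = list(expr.index[constant][:5])
        warnings.warn(
            f"{constant.sum()} constant gene(s) mapped to all-zeros "
            f"(e.g. {names})",
            stacklevel=2,
        )
    span[span == 0.0] = 1.0  # avoid 0/0; numerator is 0 for constant genes
    scaled = (values - lo) / span
    return pd.DataFrame(scaled, index=expr.index, columns=expr.columns)


def split_dev_test(
    expr: pd.DataFrame,
    labels: pd.Series,
    dev_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Random stratified split into development and test sets.

    Each label class is permuted independently with a generator seeded
    from ``seed`` and the first ``round(dev_fraction * n_class)`` samples
    go to the development set, so per-class dev counts are within one
    sample of the requested fraction and the same seed reproduces the
    partition bit-for-bit.

    Returns ``(dev_expr, dev_labels, test_expr, test_labels)``.
    """
    if not 0.0 < dev_fraction < 1.0:
        raise ValueError(f"dev_fraction must be in (0, 1), got {dev_fraction}")
    labels = labels.loc[expr.columns]
    rng = np.random.default_rng(seed)
    dev_ids: list[str] = []
    test_ids: list[str] = []
    for cls in (0, 1):
        cls_ids = labels.index[labels == cls].to_numpy()
        if len(cls_ids) < 2:
            raise ValueError(
                f"class {cls} has {len(cls_ids)} sample(s); need >= 2 to stratify"
            )
        perm = rng.permutation(len(cls_ids))
        n_dev = int(round(dev_fraction * len(cls_ids)))
        n_dev = min(max(n_dev, 1), len(cls_ids) - 1)  # both splits non-empty
        dev_ids.extend(cls_ids[perm[:n_dev]])
        test_ids.extend(cls_ids[perm[n_dev:]])
    # keep original column order within each split for readability
    dev_ids = [s for s in expr.columns if s in set(dev_ids)]
    test_ids = [s for s in expr.columns if s in set(test_ids)]
    return (
        expr.loc[:, dev_ids],
        labels.loc[dev_ids],
        expr.loc[:, test_ids],
        labels.loc[test_ids],
    )


def write_expression(expr: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a genes x samples frame back out with gene IDs as the first column."""
    expr.to_csv(path, sep=sep, index_label="gene_id")
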