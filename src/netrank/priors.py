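"""Per-gene phenotype-association priors.

The prior fed into the network ranking is the Pearson correlation of
each gene's expression vector with the binary 0/1 phenotype vector
(i.e. the point-biserial correlation).  By default the ranking uses the
absolute value, on the view that down-regulation is as informative as
up-regulation and that the random-surfer score must stay nonnegative;
``signed=True`` keeps the sign for exploratory use.

Significance is the classical two-sided t-test of a Pearson coefficient:
t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_prior", "write_prior", "load_prior"]


def pearson_prior(
    expr: pd.DataFrame, labels: pd.Series, signed: bool = False
) -> pd.DataFrame:
    """Correlate every gene with the binary phenotype.

    Parameters
    ----------
    expr
        Genes x samples expression frame.
    labels
        0/1 phenotype Series covering ``expr``'s columns.
    signed
        If True, the prior column ``s`` keeps the sign of the
        correlation; by default ``s = |raw_r|``.

    Returns
    -------
    DataFrame indexed by gene ID with columns ``raw_r`` (signed Pearson
    coefficient), ``s`` (the prior used by the ranking) and ``p_value``
    (two-sided).  Genes with zero variance have undefined correlation
    and carry ``raw_r = s = 0``, ``p_value = 1`` (with a warning); a
    zero-variance label vector is a hard error.
    """
    y = labels.loc[expr.columns].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {n}")
    if y.std() == 0.0:
        raise ValueError("label vector has zero variance (single class)")

    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = np.einsum("ij,ij->i", xc, xc)
    y_ss = float(yc @ yc)
    denom = np.sqrt(x_ss * y_ss)
    degenerate = denom == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s): correlation "
            "undefined, prior set to 0 with p-value 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / np.where(degenerate, 1.0, denom)
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))

    # two-sided p from the t statistic; |r| = 1 gives p = 0 in the limit
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, np.clip(p, 0.0, 1.0))

    s = r if signed else np.abs(r)
    return pd.DataFrame(
        {"raw_r": r, "s": s, "p_value": p},
        index=pd.Index(expr.index, name="gene_id"),
    )


def write_prior(prior: pd.DataFrame, path) -> None:
    prior.to_csv(path, sep="\t", index_label="gene_id")


def load_prior(path) -> pd.DataFrame:
    prior = pd.read_csv(path, sep="\t", index_col="gene_id")
    prior.index = prior.index.astype(str)
    missing = {"raw_r", "s", "p_value"} - set(prior.columns)
    if missing:
        raise ValueError(f"prior table {path} missing columns {sorted(missing)}")
    return prior
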