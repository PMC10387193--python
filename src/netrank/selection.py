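"""Signature selection and held-out evaluation.

A signature is the top-K genes by propagation score among those whose
phenotype-association p-value clears a cutoff (defaults K = 100,
p < 0.05, no multiple-testing correction — an optional Benjamini-
Hochberg step is available but off by default).  Signatures are
evaluated on the held-out split two ways: the AUC of the first
principal component of the signature-restricted test matrix
(orientation-corrected, so always >= 0.5), and a support-vector
machine trained on the development split and scored on test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import NetRankResult

__all__ = [
    "Signature",
    "EvalReport",
    "select_signature",
    "evaluate_pca",
    "evaluate_svm",
    "compare_rankings",
]


@dataclass
class Signature:
    """Ordered biomarker gene set (descending propagation score)."""

    gene_ids: pd.Index
    k_requested: int
    p_cutoff: float

    def __len__(self) -> int:
        return len(self.gene_ids)

    def write(self, path) -> None:
        pd.Series(self.gene_ids).to_csv(path, index=False, header=["gene_id"])


@dataclass
class EvalReport:
    """Held-out classifier metrics (case = positive class)."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float | None
    tn: int
    fp: int
    fn: int
    tp: int
    note: str = ""
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "Precision": self.precision,
            "Recall": self.recall,
            "F1_score": self.f1,
            "Accuracy": self.accuracy,
            "AUC": self.auc,
            "confusion": {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp},
            "note": self.note,
            "config": self.config,
        }

    def table(self) -> str:
        auc = "NA" if self.auc is None else f"{self.auc:.3f}"
        return (
            "Precision\tRecall\tF1_score\tAccuracy\tAUC\n"
            f"{self.precision:.3f}\t{self.recall:.3f}\t{self.f1:.3f}\t"
            f"{self.accuracy:.3f}\t{auc}"
        )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def select_signature(
    result: NetRankResult,
    prior: pd.DataFrame,
    k: int = 100,
    p_cutoff: float = 0.05,
    bh_correct: bool = False,
) -> Signature:
    """Filter to significant genes, then take the K highest scores.

    Genes with association p-value < ``p_cutoff`` (raw by default;
    ``bh_correct`` switches to Benjamini-Hochberg adjusted values) are
    ranked by descending propagation score with ties broken by gene ID
    ascending, and the top ``k`` returned.  Fewer than ``k`` survivors
    yields all of them with a warning; zero survivors is an error.
    """
    genes = pd.Index(result.gene_ids)
    shared = genes.intersection(prior.index)
    if len(shared) != len(genes):
        raise ValueError("prior does not cover all scored genes")
    p = prior["p_value"].reindex(genes).to_numpy(dtype=float)
    if bh_correct:
        p = _bh_adjust(p)
    frame = pd.DataFrame({"gene_id": genes, "r": result.r, "p": p})
    survivors = frame[frame["p"] < p_cutoff]
    if survivors.empty:
        raise ValueError(f"no significant genes at cutoff {p_cutoff}")
    if len(survivors) < k:
        warnings.warn(
            f"only {len(survivors)} genes pass p < {p_cutoff}; "
            f"signature shorter than requested k = {k}",
            stacklevel=2,
        )
    picked = survivors.sort_values(["r", "gene_id"], ascending=[False, True]).head(k)
    return Signature(pd.Index(picked["gene_id"]), k_requested=k, p_cutoff=p_cutoff)


def evaluate_pca(
    test_expr: pd.DataFrame,
    signature: Signature,
    labels: pd.Series,
    n_components: int = 2,
    fit_expr: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Project samples onto signature principal components; AUC of PC1.

    The PCA is fitted on the mean-centered samples x signature-genes
    matrix of ``test_expr`` itself (pass ``fit_expr`` for the stricter
    fit-on-dev/project-on-test variant).  Because a component's sign is
    arbitrary, the reported AUC is orientation-corrected to
    max(AUC, 1 - AUC) >= 0.5.

    Returns ``(component_scores, component_auc)`` where the scores frame
    is samples x components (columns ``PC1..``) for plotting.
    """
    missing = signature.gene_ids.difference(test_expr.index)
    if len(missing):
        raise ValueError(f"signature genes absent from test matrix: {list(missing[:5])}")
    x_test = test_expr.loc[signature.gene_ids].T.to_numpy(dtype=float)
    x_fit = (
        x_test
        if fit_expr is None
        else fit_expr.loc[signature.gene_ids].T.to_numpy(dtype=float)
    )
    n_components = min(n_components, min(x_fit.shape), len(signature))
    if len(signature) == 1:
        # PCA degenerates to the gene itself
        comp = x_test - x_fit.mean(axis=0)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(x_fit)
        comp = pca.transform(x_test)
    y = labels.loc[test_expr.columns].to_numpy(dtype=int)
    auc = roc_auc_score(y, comp[:, 0])
    auc = max(auc, 1.0 - auc)
    scores = pd.DataFrame(
        comp,
        index=pd.Index(test_expr.columns, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(comp.shape[1])],
    )
    return scores, float(auc)


def evaluate_svm(
    dev: tuple[pd.DataFrame, pd.Series],
    test: tuple[pd.DataFrame, pd.Series],
    signature: Signature,
    kernel: str = "rbf",
    C: float = 1.0,
    seed: int = 0,
) -> EvalReport:
    """Train an SVM on dev, report held-out metrics on test.

    Features are the signature genes (standardized on dev); the positive
    class is the case label.  AUC comes from decision-function scores.
    A single-class test split leaves AUC as None with a note.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    dev_expr, dev_labels = dev
    test_expr, test_labels = test
    if dev_labels.nunique() < 2:
        raise ValueError("development split must contain both classes")
    x_dev = dev_expr.loc[signature.gene_ids].T.to_numpy(dtype=float)
    x_test = test_expr.loc[signature.gene_ids].T.to_numpy(dtype=float)
    y_dev = dev_labels.loc[dev_expr.columns].to_numpy(dtype=int)
    y_test = test_labels.loc[test_expr.columns].to_numpy(dtype=int)

    clf = make_pipeline(
        StandardScaler(), SVC(kernel=kernel, C=C, random_state=seed)
    )
    clf.fit(x_dev, y_dev)
    y_pred = clf.predict(x_test)
    scores = clf.decision_function(x_test)

    note = ""
    if len(np.unique(y_test)) < 2:
        auc = None
        note = "AUC undefined: test split contains a single class"
    else:
        auc = float(roc_auc_score(y_test, scores))
    tn, fp, fn, tp = confusion_matrix(y_test, y_pred, labels=[0, 1]).ravel()
    return EvalReport(
        precision=float(precision_score(y_test, y_pred, zero_division=0)),
        recall=float(recall_score(y_test, y_pred, zero_division=0)),
        f1=float(f1_score(y_test, y_pred, zero_division=0)),
        accuracy=float(accuracy_score(y_test, y_pred)),
        auc=auc,
        tn=int(tn),
        fp=int(fp),
        fn=int(fn),
        tp=int(tp),
        note=note,
        config={"kernel": kernel, "C": C, "seed": seed, "n_features": len(signature)},
    )


def compare_rankings(
    r_a: NetRankResult, r_b: NetRankResult
) -> tuple[float, int, pd.DataFrame]:
    """Pearson correlation of two score vectors over their shared genes.

    Returns ``(pearson_r, n_shared, pairs)`` where ``pairs`` holds the
    aligned score columns ``score_a, score_b`` for scatter plotting.
    """
    shared = pd.Index(r_a.gene_ids).intersection(r_b.gene_ids)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    a = r_a.scores().loc[shared].to_numpy()
    b = r_b.scores().loc[shared].to_numpy()
    r = float(np.corrcoef(a, b)[0, 1])
    pairs = pd.DataFrame(
        {"score_a": a, "score_b": b}, index=pd.Index(shared, name="gene_id")
    )
    return r, len(shared), pairs
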