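"""End-to-end convenience wrapper chaining the pipeline stages.

clean -> min-max normalize -> stratified split -> correlation prior on
the development set -> network (supplied, or co-expression built from
the development set) restricted to the scored genes -> damped
propagation -> top-K signature -> held-out PCA and SVM evaluation.

This is the composition the CLI's ``run-all`` subcommand and the
acceptance script execute; each stage remains individually callable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import NetRankParams, NetRankResult, run_netrank
from .network import GeneNetwork, build_coexpression_network, restrict_to
from .preprocessing import CleanReport, clean, minmax_normalize, split_dev_test
from .priors import pearson_prior
from .selection import EvalReport, Signature, evaluate_pca, evaluate_svm, select_signature

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one full run, in stage order."""

    clean_report: CleanReport
    dev_expr: pd.DataFrame
    dev_labels: pd.Series
    test_expr: pd.DataFrame
    test_labels: pd.Series
    prior: pd.DataFrame
    network: GeneNetwork
    netrank: NetRankResult
    signature: Signature
    component_scores: pd.DataFrame
    component_auc: float
    svm_report: EvalReport


def run_pipeline(
    expr: pd.DataFrame,
    labels: pd.Series,
    network: GeneNetwork | None = None,
    params: NetRankParams = NetRankParams(),
    dev_fraction: float = 0.7,
    split_seed: int = 0,
    k: int = 100,
    p_cutoff: float = 0.05,
    beta: int = 6,
    edge_floor: float = 0.01,
    svm_kernel: str = "rbf",
    scale_after_split: bool = False,
) -> PipelineResult:
    """Run the whole pipeline on a raw expression matrix.

    ``network=None`` builds an unsigned soft-thresholded co-expression
    network from the development split; otherwise the supplied network
    is restricted/extended to the scored gene set.  With
    ``scale_after_split`` the min-max scaler is fitted per split
    (stricter, no leakage of test extremes) instead of on the full
    matrix first.
    """
    cleaned, report = clean(expr)
    if not scale_after_split:
        cleaned = minmax_normalize(cleaned)
    dev_expr, dev_labels, test_expr, test_labels = split_dev_test(
        cleaned, labels, dev_fraction=dev_fraction, seed=split_seed
    )
    if scale_after_split:
        dev_expr = minmax_normalize(dev_expr)
        test_expr = minmax_normalize(test_expr)

    prior = pearson_prior(dev_expr, dev_labels)
    if network is None:
        net = build_coexpression_network(dev_expr, beta=beta, edge_floor=edge_floor)
    else:
        net = network
    net = restrict_to(net, dev_expr.index)

    result = run_netrank(net, prior, params)
    signature = select_signature(result, prior, k=k, p_cutoff=p_cutoff)
    component_scores, component_auc = evaluate_pca(test_expr, signature, test_labels)
    svm_report = evaluate_svm(
        (dev_expr, dev_labels), (test_expr, test_labels), signature, kernel=svm_kernel
    )
    return PipelineResult(
        clean_report=report,
        dev_expr=dev_expr,
        dev_labels=dev_labels,
        test_expr=test_expr,
        test_labels=test_labels,
        prior=prior,
        network=net,
        netrank=result,
        signature=signature,
        component_scores=component_scores,
        component_auc=component_auc,
        svm_report=svm_report,
    )
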