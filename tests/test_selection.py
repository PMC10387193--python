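import numpy as np
import pandas as pd
import pytest

from netrank import (
    NetRankResult,
    Signature,
    compare_rankings,
    evaluate_pca,
    evaluate_svm,
    select_signature,
)


def _result(gene_ids, scores):
    return NetRankResult(
        gene_ids=pd.Index(gene_ids),
        r=np.asarray(scores, dtype=float),
        iterations=1,
        converged=True,
        residual=0.0,
    )


def _prior(gene_ids, p):
    return pd.DataFrame(
        {"raw_r": 0.5, "s": 0.5, "p_value": np.asarray(p, dtype=float)},
        index=pd.Index(gene_ids, name="gene_id"),
    )


class TestSelectSignature:
    def test_filter_then_truncate(self):
        genes = [f"G{i}" for i in range(10)]
        res = _result(genes, np.linspace(1.0, 0.1, 10))
        p = [0.01, 0.5, 0.02, 0.5, 0.5, 0.03, 0.5, 0.5, 0.5, 0.5]
        with pytest.warns(UserWarning, match="signature shorter"):
            sig = select_signature(res, _prior(genes, p), k=100, p_cutoff=0.05)
        assert list(sig.gene_ids) == ["G0", "G2", "G5"]  # score order among survivors

    def test_truncates_to_k(self):
        genes = [f"G{i}" for i in range(10)]
        sig = select_signature(
            _result(genes, np.linspace(1.0, 0.1, 10)), _prior(genes, [0.01] * 10), k=4
        )
        assert list(sig.gene_ids) == ["G0", "G1", "G2", "G3"]

    def test_score_ties_break_by_gene_id(self):
        genes = ["B", "A", "C"]
        sig = select_signature(
            _result(genes, [0.5, 0.5, 0.1]), _prior(genes, [0.01] * 3), k=2
        )
        assert list(sig.gene_ids) == ["A", "B"]

    def test_invariant_to_input_gene_order(self):
        genes = [f"G{i}" for i in range(8)]
        scores = np.linspace(0.9, 0.2, 8)
        p = [0.01] * 8
        order = np.argsort([3, 1, 4, 0, 7, 5, 2, 6])
        a = select_signature(_result(genes, scores), _prior(genes, p), k=5)
        b = select_signature(
            _result(list(np.array(genes)[order]), scores[order]),
            _prior(genes, p),
            k=5,
        )
        assert list(a.gene_ids) == list(b.gene_ids)

    def test_zero_survivors_errors(self):
        genes = ["G1", "G2"]
        with pytest.raises(ValueError, match="no significant genes"):
            select_signature(_result(genes, [1.0, 0.5]), _prior(genes, [0.5, 0.9]))

    def test_bh_correction_is_stricter(self):
        # 3 marginal hits among 17 nulls: raw keeps the 3, BH (0.04*20/3 > 0.05) none
        genes = [f"G{i}" for i in range(20)]
        p = [0.04] * 3 + [0.9] * 17
        res = _result(genes, np.linspace(1, 0.05, 20))
        raw = select_signature(res, _prior(genes, p), k=100)
        assert len(raw) == 3
        with pytest.raises(ValueError, match="no significant genes"):
            select_signature(res, _prior(genes, p), k=100, bh_correct=True)


def _two_cluster_data(n=60, sep=6.0, seed=0, n_genes=5):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    x = rng.standard_normal((n_genes, n)) + sep * y
    expr = pd.DataFrame(
        x, index=[f"G{i}" for i in range(n_genes)], columns=[f"S{i}" for i in range(n)]
    )
    labels = pd.Series(y, index=expr.columns)
    return expr, labels


class TestEvaluatePCA:
    def test_perfect_separation_gives_auc_one(self):
        expr, labels = _two_cluster_data(sep=8.0)
        sig = Signature(pd.Index(expr.index), k_requested=5, p_cutoff=0.05)
        _, auc = evaluate_pca(expr, sig, labels)
        assert auc == pytest.approx(1.0)

    def test_orientation_correction_sign_invariant(self):
        expr, labels = _two_cluster_data(sep=2.0, seed=3)
        sig = Signature(pd.Index(expr.index), k_requested=5, p_cutoff=0.05)
        _, auc_pos = evaluate_pca(expr, sig, labels)
        _, auc_neg = evaluate_pca(-expr, sig, labels)
        assert auc_pos == pytest.approx(auc_neg)
        assert auc_pos >= 0.5

    def test_shuffled_labels_near_half(self):
        # permutation null: expected AUC 0.5 within Monte Carlo error
        rng = np.random.default_rng(17)
        expr, labels = _two_cluster_data(n=400, sep=0.0, seed=17, n_genes=10)
        aucs = []
        sig = Signature(pd.Index(expr.index), k_requested=10, p_cutoff=0.05)
        for _ in range(10):
            shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            _, auc = evaluate_pca(expr, sig, shuffled)
            aucs.append(auc)
        # orientation correction biases upward from 0.5 by the folded sampling noise
        assert 0.5 <= float(np.mean(aucs)) < 0.58

    def test_single_gene_signature_degenerates_to_gene(self):
        expr, labels = _two_cluster_data(sep=5.0, n_genes=1)
        sig = Signature(pd.Index(["G0"]), k_requested=1, p_cutoff=0.05)
        scores, auc = evaluate_pca(expr, sig, labels)
        assert scores.shape[1] == 1
        assert auc > 0.95

    def test_missing_signature_gene_errors(self):
        expr, labels = _two_cluster_data()
        sig = Signature(pd.Index(["NOPE"]), k_requested=1, p_cutoff=0.05)
        with pytest.raises(ValueError, match="absent from test matrix"):
            evaluate_pca(expr, sig, labels)


class TestEvaluateSVM:
    def test_separable_data_perfect_metrics(self):
        dev = _two_cluster_data(n=80, sep=8.0, seed=1)
        test = _two_cluster_data(n=40, sep=8.0, seed=2)
        sig = Signature(pd.Index(dev[0].index), k_requested=5, p_cutoff=0.05)
        report = evaluate_svm(dev, test, sig)
        assert report.accuracy == 1.0
        assert report.auc == 1.0
        assert report.f1 == 1.0

    def test_metric_identities_from_confusion_counts(self):
        dev = _two_cluster_data(n=100, sep=1.0, seed=4)
        test = _two_cluster_data(n=60, sep=1.0, seed=5)
        sig = Signature(pd.Index(dev[0].index), k_requested=5, p_cutoff=0.05)
        rep = evaluate_svm(dev, test, sig)
        tp, fp, fn, tn = rep.tp, rep.fp, rep.fn, rep.tn
        assert tp + fp + fn + tn == 60
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        assert rep.precision == pytest.approx(precision)
        assert rep.recall == pytest.approx(recall)
        assert rep.f1 == pytest.approx(f1)
        assert rep.accuracy == pytest.approx((tp + tn) / 60)

    def test_deterministic(self):
        dev = _two_cluster_data(n=60, sep=1.5, seed=6)
        test = _two_cluster_data(n=30, sep=1.5, seed=7)
        sig = Signature(pd.Index(dev[0].index), k_requested=5, p_cutoff=0.05)
        a = evaluate_svm(dev, test, sig)
        b = evaluate_svm(dev, test, sig)
        assert a == b

    def test_single_class_test_split_auc_missing(self):
        dev = _two_cluster_data(n=60, sep=3.0, seed=8)
        expr, labels = _two_cluster_data(n=20, sep=3.0, seed=9)
        labels[:] = 1
        sig = Signature(pd.Index(dev[0].index), k_requested=5, p_cutoff=0.05)
        rep = evaluate_svm(dev, (expr, labels), sig)
        assert rep.auc is None
        assert "single class" in rep.note

    def test_empty_signature_errors(self):
        dev = _two_cluster_data(seed=10)
        sig = Signature(pd.Index([]), k_requested=0, p_cutoff=0.05)
        with pytest.raises(ValueError, match="empty signature"):
            evaluate_svm(dev, dev, sig)


class TestCompareRankings:
    def test_self_correlation_is_one(self):
        res = _result(["A", "B", "C", "D"], [0.4, 0.3, 0.2, 0.1])
        r, n, _ = compare_rankings(res, res)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_negation_is_minus_one(self):
        a = _result(["A", "B", "C"], [0.4, 0.3, 0.2])
        b = _result(["A", "B", "C"], [-0.4, -0.3, -0.2])
        r, _, _ = compare_rankings(a, b)
        assert r == pytest.approx(-1.0)

    def test_correlation_recomputable_from_pair_table(self):
        rng = np.random.default_rng(19)
        genes = [f"G{i}" for i in range(50)]
        a = _result(genes, rng.random(50))
        b = _result(genes, rng.random(50))
        r, n, pairs = compare_rankings(a, b)
        assert n == 50
        recomputed = float(np.corrcoef(pairs["score_a"], pairs["score_b"])[0, 1])
        assert r == pytest.approx(recomputed, abs=1e-12)

    def test_tiny_intersection_errors(self):
        a = _result(["A", "B"], [0.1, 0.2])
        b = _result(["B", "C"], [0.1, 0.2])
        with pytest.raises(ValueError, match="shared genes"):
            compare_rankings(a, b)
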