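"""Prediction, degree-preserving permutation, connectivity scores."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oligonet.inference import GeneModel, NetworkEnsemble, RegulatoryNetwork
from oligonet.validation import (
    category_score_test,
    compare_to_random_prediction,
    connectivity_scores,
    permute_degree_preserving,
    predict_expression,
    prediction_quality,
)


def _net(edge_spec, genes, cn_coefs=None, intercepts=None):
    """Build a network from {target: {regulator: beta}}."""
    models = {}
    for g in genes:
        models[g] = GeneModel(
            target=g,
            intercept=(intercepts or {}).get(g, 0.0),
            cn_coef=(cn_coefs or {}).get(g, 0.0),
        )
    for t, regs in edge_spec.items():
        for r, b in regs.items():
            models[t].regulators[r] = b
            models[t].regulator_q[r] = 0.005
    return RegulatoryNetwork(models=models)


class TestPrediction:
    def test_hand_arithmetic(self):
        genes = ["t", "r"]
        net = _net({"t": {"r": 0.5}}, genes, cn_coefs={"t": 2.0})
        expr = pd.DataFrame({"s1": [9.0, 1.0], "s2": [9.0, 2.0], "s3": [9.0, 0.0]}, index=genes)
        cn = pd.DataFrame({"s1": [-0.5, 0.0], "s2": [0.0, 0.0], "s3": [1.0, 0.0]}, index=genes)
        pred = predict_expression(net, expr, cn)
        assert pred.loc["t", "s1"] == pytest.approx(2 * -0.5 + 0.5 * 1)
        assert pred.loc["t", "s2"] == pytest.approx(0.5 * 2)
        assert pred.loc["t", "s3"] == pytest.approx(2 * 1 + 0.0)

    def test_empty_model_predicts_intercept(self):
        genes = ["a"]
        net = _net({}, genes, intercepts={"a": 1.5})
        expr = pd.DataFrame({"s1": [0.0], "s2": [3.0], "s3": [1.0]}, index=genes)
        pred = predict_expression(net, expr, expr * 0)
        assert (pred.loc["a"] == 1.5).all()

    def test_true_network_exact_on_noise_free_data(self, small_cohort):
        ann, truth, cn, _, meta = small_cohort
        from oligonet.simulate import GroundTruthNetwork, simulate_expression

        noiseless = GroundTruthNetwork(
            edges=truth.edges, cn_effect=truth.cn_effect, noise_sd=0.0,
            dag_order=truth.dag_order,
        )
        expr = simulate_expression(noiseless, cn, seed=0)
        genes = list(cn.index)
        edge_spec: dict[str, dict[str, float]] = {}
        for r, t, b in zip(truth.edges["regulator"], truth.edges["target"], truth.edges["beta"]):
            edge_spec.setdefault(t, {})[r] = b
        net = _net(edge_spec, genes, cn_coefs={g: truth.cn_effect[g] for g in genes})
        pred = predict_expression(net, expr, cn)
        assert np.abs(pred.to_numpy() - expr.to_numpy()).max() < 1e-10


class TestPredictionQuality:
    def test_perfect_and_anti_prediction(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.standard_normal((4, 6)))
        q = prediction_quality(m, m)
        assert np.allclose(q.correlations, 1.0)
        q = prediction_quality(-m, m)
        assert np.allclose(q.correlations, -1.0)

    def test_textbook_formula_spot_check(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        pred = pd.DataFrame([x], index=["g"])
        meas = pd.DataFrame([y], index=["g"])
        xc, yc = x - x.mean(), y - y.mean()
        expect = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert prediction_quality(pred, meas).correlations["g"] == pytest.approx(expect)

    def test_constant_prediction_undefined_and_excluded(self):
        pred = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        meas = pd.DataFrame([[0.0, 1.0, 2.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        q = prediction_quality(pred, meas)
        assert np.isnan(q.correlations["a"])
        assert q.median == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["g"])
        with pytest.raises(ValueError):
            prediction_quality(m, m)


class TestDegreePreservingPermutation:
    def _degrees(self, net):
        e = net.edges()
        out = e.groupby("regulator").size().to_dict()
        into = e.groupby("target").size().to_dict()
        return out, into

    def test_degrees_preserved_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for rep in range(50):
            genes = [f"g{i}" for i in range(12)]
            edge_spec: dict[str, dict[str, float]] = {}
            for _ in range(25):
                r, t = rng.choice(genes, 2, replace=False)
                edge_spec.setdefault(t, {})[r] = float(rng.normal())
            net = _net(edge_spec, genes)
            rn, _ = permute_degree_preserving(net, seed=rep)
            assert self._degrees(rn) == self._degrees(net)
            # beta multiset is preserved globally
            assert sorted(rn.edges()["beta"]) == pytest.approx(sorted(net.edges()["beta"]))

    def test_two_edges_reach_only_the_one_alternative(self):
        genes = ["a", "b", "c", "d"]
        net = _net({"b": {"a": 1.0}, "d": {"c": 2.0}}, genes)
        seen = set()
        for seed in range(20):
            rn, _ = permute_degree_preserving(net, seed=seed)
            seen.add(frozenset(zip(rn.edges()["regulator"], rn.edges()["target"])))
        allowed = {
            frozenset({("a", "b"), ("c", "d")}),
            frozenset({("a", "d"), ("c", "b")}),
        }
        assert seen <= allowed and len(seen) == 2

    def test_attributes_travel_with_source(self):
        genes = ["a", "b", "c", "d"]
        net = _net({"b": {"a": 1.0}, "d": {"c": 2.0}}, genes)
        rn, swapped = permute_degree_preserving(net, seed=0)
        e = rn.edges().set_index("regulator")
        assert e.loc["a", "beta"] == 1.0 and e.loc["c", "beta"] == 2.0
        if swapped:
            assert e.loc["a", "target"] == "d"

    def test_single_edge_returned_unchanged_with_flag(self):
        genes = ["a", "b"]
        net = _net({"b": {"a": 1.0}}, genes)
        rn, swapped = permute_degree_preserving(net, seed=0)
        assert not swapped
        pd.testing.assert_frame_equal(rn.edges(), net.edges())

    def test_intercept_and_cn_stay_with_target(self):
        genes = ["a", "b", "c", "d"]
        net = _net({"b": {"a": 1.0}, "d": {"c": 2.0}}, genes,
                   cn_coefs={"b": 5.0}, intercepts={"d": -1.0})
        rn, _ = permute_degree_preserving(net, seed=0)
        assert rn.models["b"].cn_coef == 5.0
        assert rn.models["d"].intercept == -1.0


class TestRandomComparison:
    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal(300)
        from oligonet.validation import PredictionQuality

        rand = PredictionQuality(correlations=pd.Series(vals))
        _, p = compare_to_random_prediction(pd.Series(vals), [rand])
        assert 0.45 < p < 0.55

    def test_shift_detected(self):
        # correlation-scale dispersion (sd 0.2) with a +0.5 shift
        rng = np.random.default_rng(3)
        base = 0.2 * rng.standard_normal(200)
        from oligonet.validation import PredictionQuality

        rand = PredictionQuality(correlations=pd.Series(base))
        _, p = compare_to_random_prediction(pd.Series(base + 0.5), [rand])
        assert p < 1e-10

    def test_degenerate_inputs_rejected(self):
        from oligonet.validation import PredictionQuality

        with pytest.raises(ValueError):
            compare_to_random_prediction(pd.Series([1.0]), [])
        tied = PredictionQuality(correlations=pd.Series([0.5, 0.5]))
        with pytest.raises(ValueError, match="tied"):
            compare_to_random_prediction(pd.Series([0.5, 0.5]), [tied])


class TestConnectivityScores:
    def _ensemble(self, nets):
        return NetworkEnsemble(networks=nets)

    def test_worked_example(self):
        genes = ["A", "B", "x", "y", "z"]
        # A: two links present in all 10 networks; B: one link in exactly 1
        nets = []
        for j in range(10):
            spec = {"x": {"A": 1.0}, "y": {"A": 1.0}}
            if j == 0:
                spec["z"] = {"B": 1.0}
            nets.append(_net(spec, genes))
        scores = connectivity_scores(self._ensemble(nets))
        assert scores.loc["A", "c_10"] == 2 and scores.loc["B", "c_1"] == 1
        assert scores.loc["A", "score"] == pytest.approx(1.0)
        assert scores.loc["B", "score"] == pytest.approx(1.0)
        # adding gene C with one link in one network halves B's share
        genes2 = genes + ["C"]
        nets2 = []
        for j in range(10):
            spec = {"x": {"A": 1.0}, "y": {"A": 1.0}}
            if j == 0:
                spec["z"] = {"B": 1.0, "C": 1.0}
            nets2.append(_net(spec, genes2))
        scores2 = connectivity_scores(self._ensemble(nets2))
        assert scores2.loc["B", "score"] == pytest.approx(0.5)
        assert scores2.loc["C", "score"] == pytest.approx(0.5)
        assert scores2.loc["A", "score"] == pytest.approx(1.0)

    def test_gene_without_links_scores_zero(self):
        genes = ["A", "x", "lonely"]
        nets = [_net({"x": {"A": 1.0}}, genes) for _ in range(3)]
        scores = connectivity_scores(self._ensemble(nets))
        assert scores.loc["lonely", "score"] == 0.0

    def test_nonzero_columns_sum_to_one(self, small_cohort):
        ann, truth, cn, expr, meta = small_cohort
        from oligonet.inference import infer_network_ensemble

        tumors = list(meta.index[meta["is_tumor"]])
        ens = infer_network_ensemble(
            expr[tumors], cn[tumors], ann, n_networks=2, local_window=5,
            max_steps=8, seed=5,
        )
        scores = connectivity_scores(ens)
        C = scores[[c for c in scores.columns if c.startswith("c_")]].to_numpy()
        colsum = C.sum(axis=0)
        std = np.divide(C, colsum, out=np.zeros_like(C), where=colsum > 0)
        assert np.allclose(std.sum(axis=0)[colsum > 0], 1.0)
        assert (scores["score"] >= 0).all()

    def test_single_network_rejected(self):
        with pytest.raises(ValueError):
            connectivity_scores(self._ensemble([_net({}, ["a"])]))


class TestCategoryScoreTest:
    def _annotation(self, n, members):
        import pandas as pd

        rows = []
        for i in range(n):
            rows.append(
                {"gene_id": f"g{i}", "chrom": "1", "arm": "1p", "start": 0,
                 "end": 1, "genome_index": i,
                 "categories": "oncogene" if f"g{i}" in members else ""}
            )
        return pd.DataFrame(rows).set_index("gene_id")

    def test_extreme_ranks_give_exact_minimal_p(self):
        n, k = 8, 2
        members = {"g0", "g1"}
        ann = self._annotation(n, members)
        scores = pd.Series(np.arange(n, 0, -1, dtype=float), index=[f"g{i}" for i in range(n)])
        _, p = category_score_test(scores, ann, "oncogene")
        # category genes hold the top k ranks: p = 1 / C(n, k)
        from math import comb

        assert p == pytest.approx(1 / comb(n, k))

    def test_calibration_under_random_labels(self):
        rng = np.random.default_rng(6)
        n, k, reps = 40, 10, 400
        hits = 0
        for _ in range(reps):
            members = {f"g{i}" for i in rng.choice(n, k, replace=False)}
            ann = self._annotation(n, members)
            scores = pd.Series(rng.standard_normal(n), index=[f"g{i}" for i in range(n)])
            _, p = category_score_test(scores, ann, "oncogene")
            hits += p <= 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_full_or_empty_category_rejected(self):
        ann = self._annotation(4, {"g0", "g1", "g2", "g3"})
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"g{i}" for i in range(4)])
        with pytest.raises(ValueError):
            category_score_test(scores, ann, "oncogene")
        with pytest.raises(ValueError):
            category_score_test(scores, ann, "kinase")
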