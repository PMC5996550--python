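"""All-paths propagation and the paired permutation-null impact test."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oligonet.impact import (
    PropagationConfig,
    paired_signed_rank,
    pathway_impact,
    per_pathway_profile,
    propagate_impact,
    propagation_matrix,
    spectral_radius,
)
from oligonet.inference import GeneModel, NetworkEnsemble, RegulatoryNetwork
from oligonet.validation import PredictionQuality


def _net(edge_spec, genes):
    models = {g: GeneModel(target=g) for g in genes}
    for t, regs in edge_spec.items():
        for r, b in regs.items():
            models[t].regulators[r] = b
    return RegulatoryNetwork(models=models)


def _quality(values, genes):
    return PredictionQuality(correlations=pd.Series(values, index=genes))


class TestPropagationMatrix:
    def test_weighting_off_equals_coefficient_matrix(self):
        genes = ["a", "b", "c"]
        net = _net({"b": {"a": 0.5}, "c": {"b": -0.4}}, genes)
        cfg = PropagationConfig(quality_weighting=False)
        M = propagation_matrix(net, genes, None, cfg)
        expect = np.zeros((3, 3))
        expect[1, 0] = 0.5
        expect[2, 1] = -0.4
        assert np.array_equal(M, expect)

    def test_zero_quality_zeroes_row(self):
        genes = ["a", "b", "c"]
        net = _net({"b": {"a": 0.5}, "c": {"b": 0.4}}, genes)
        q = _quality([1.0, 0.0, 1.0], genes)
        M = propagation_matrix(net, genes, q, PropagationConfig())
        assert (M[1] == 0.0).all() and M[2, 1] == 0.4

    def test_hand_built_weighted_matrix(self):
        genes = ["a", "b", "c"]
        net = _net({"b": {"a": 2.0}, "c": {"a": -1.0, "b": 0.5}}, genes)
        q = _quality([0.9, 0.5, -0.3], genes)  # negative weight clips to 0
        M = propagation_matrix(net, genes, q, PropagationConfig(max_spectral_radius=np.inf))
        assert M[1, 0] == pytest.approx(0.5 * 2.0)
        assert M[2, 0] == 0.0 and M[2, 1] == 0.0

    def test_supercritical_matrix_rescaled(self):
        genes = ["a", "b"]
        net = _net({"b": {"a": 2.0}, "a": {"b": 2.0}}, genes)  # radius 2
        cfg = PropagationConfig(quality_weighting=False, max_spectral_radius=0.9)
        M = propagation_matrix(net, genes, None, cfg)
        assert spectral_radius(np.abs(M)) == pytest.approx(0.9)


class TestPropagateImpact:
    def test_chain_products(self):
        genes = ["a", "b", "c"]
        net = _net({"b": {"a": 0.5}, "c": {"b": 0.4}}, genes)
        M = propagation_matrix(net, genes, None, PropagationConfig(quality_weighting=False))
        v = propagate_impact(M, 0, PropagationConfig(max_path_length=5))
        assert v[1] == pytest.approx(0.5)
        assert v[2] == pytest.approx(0.2)

    def test_two_cycle_closed_form_geometric_series(self):
        genes = ["a", "b"]
        net = _net({"b": {"a": 0.5}, "a": {"b": 0.5}}, genes)
        M = propagation_matrix(net, genes, None, PropagationConfig(quality_weighting=False))
        v = propagate_impact(M, 0, PropagationConfig(closed_form=True))
        assert v[1] == pytest.approx(0.5 / (1 - 0.25))

    def test_truncated_series_matches_path_enumeration_on_dags(self):
        rng = np.random.default_rng(0)
        cfg = PropagationConfig(max_path_length=5)
        for _ in range(100):
            n = int(rng.integers(3, 11))
            M = np.zeros((n, n))
            for t in range(n):
                for r in range(t):
                    if rng.random() < 0.4:
                        M[t, r] = rng.normal()
            src = int(rng.integers(n))
            v = propagate_impact(M, src, cfg)
            oracle = _path_enumeration_oracle(M, src, cfg.max_path_length)
            assert np.abs(v - oracle).max() < 1e-10

    def test_closed_form_is_limit_of_truncation(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(8, 8)) * 0.1
        M *= 0.8 / spectral_radius(np.abs(M))
        closed = propagate_impact(M, 0, PropagationConfig(closed_form=True))
        deep = propagate_impact(M, 0, PropagationConfig(max_path_length=50))
        assert np.abs(closed - deep).max() < 1e-8

    def test_closed_form_rejected_when_supercritical(self):
        M = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="spectral"):
            propagate_impact(M, 0, PropagationConfig(closed_form=True,
                                                     max_spectral_radius=np.inf))


def _path_enumeration_oracle(M, src, K):
    """Sum signed weight products over all directed walks of length <= K."""
    n = M.shape[0]
    total = np.zeros(n)

    def walk(node, length, weight):
        if length == K:
            return
        for nxt in range(n):
            w = M[nxt, node]
            if w != 0.0:
                total[nxt] += weight * w
                walk(nxt, length + 1, weight * w)

    walk(src, 0, 1.0)
    return total


class TestPairedSignedRank:
    def test_all_real_above_random_gives_exact_floor(self):
        real = np.arange(1.0, 11.0)
        rand = np.zeros(10)
        assert paired_signed_rank(real, rand) == pytest.approx(1 / 1024)

    def test_all_ties_give_one(self):
        x = np.ones(10)
        assert paired_signed_rank(x, x) == 1.0

    def test_mixed_signs_match_scipy_exact(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        real = rng.normal(size=10)
        rand = rng.normal(size=10)
        expect = sps.wilcoxon(real - rand, alternative="greater", method="exact").pvalue
        assert paired_signed_rank(real, rand) == pytest.approx(expect)


class TestPathwayImpact:
    def _setup(self):
        genes = ["s", "iso", "p1", "p2", "q1"]
        real = _net({"p1": {"s": 1.0}, "p2": {"s": 1.0}, "q1": {"p1": 0.5}}, genes)
        rand = _net({"q1": {"s": 1.0}, "p1": {"p2": 1.0}, "p2": {"q1": 0.5}}, genes)
        ens = NetworkEnsemble(networks=[real] * 10)
        randoms = [[rand] for _ in range(10)]
        return genes, ens, randoms

    def test_wired_source_flagged_isolated_not(self):
        genes, ens, randoms = self._setup()
        cfg = PropagationConfig(quality_weighting=False)
        table = pathway_impact(
            ens, randoms, ["s", "iso"], {"signaling": ["p1", "p2"]}, None, cfg,
            q_cutoff=0.05,
        )
        t = table.set_index("source")
        assert t.loc["s", "p"] == pytest.approx(1 / 1024)
        assert bool(t.loc["s", "high_impact"])
        assert t.loc["iso", "p"] == 1.0 and not t.loc["iso", "high_impact"]

    def test_self_impact_excluded(self):
        genes = ["s", "t"]
        net = _net({"t": {"s": 1.0}, "s": {"t": 1.0}}, genes)
        ens = NetworkEnsemble(networks=[net, net])
        cfg = PropagationConfig(quality_weighting=False)
        table = pathway_impact(ens, [[net], [net]], ["s"], {"c": ["s", "t"]}, None, cfg)
        # impact counts |v_t| only; the source's own feedback is dropped
        genes_order = sorted(net.models)
        M = propagation_matrix(net, genes_order, None, cfg)
        v = propagate_impact(M, genes_order.index("s"), cfg)
        assert table["median_impact"].iloc[0] == pytest.approx(abs(v[genes_order.index("t")]))

    def test_set_order_and_nonmember_relabeling_invariance(self):
        genes, ens, randoms = self._setup()
        cfg = PropagationConfig(quality_weighting=False)
        a = pathway_impact(ens, randoms, ["s"], {"x": ["p1", "p2"], "y": ["q1"]}, None, cfg)
        b = pathway_impact(ens, randoms, ["s"], {"y": ["q1"], "x": ["p2", "p1"]}, None, cfg)
        ax = a.set_index("pathway_class").loc[["x", "y"], "median_impact"]
        bx = b.set_index("pathway_class").loc[["x", "y"], "median_impact"]
        assert np.allclose(ax, bx)

    def test_pairwise_is_singleton_pathway(self):
        from oligonet.impact import pairwise_impact_test

        genes, ens, randoms = self._setup()
        cfg = PropagationConfig(quality_weighting=False)
        p, table = pairwise_impact_test("s", "p1", ens, randoms, None, cfg)
        ref = pathway_impact(ens, randoms, ["s"], {"only": ["p1"]}, None, cfg)
        assert p == pytest.approx(ref["p"].iloc[0])
        assert table["median_impact"].iloc[0] == pytest.approx(ref["median_impact"].iloc[0])


class TestPerPathwayProfile:
    def test_profiles_and_additivity(self):
        genes = ["s", "a", "b", "c"]
        net = _net({"a": {"s": 0.5}, "b": {"s": -0.25}, "c": {"a": 0.4}}, genes)
        ens = NetworkEnsemble(networks=[net, net])
        cfg = PropagationConfig(quality_weighting=False)
        sets = {"empty": [], "single": ["a"], "rest": ["b", "c"]}
        prof = per_pathway_profile("s", ens, sets, None, cfg)
        assert prof.loc["empty", "median_abs_impact"] == 0.0
        assert prof.loc["single", "median_signed_impact"] == pytest.approx(0.5)
        # disjoint unsigned sums add up to the class total
        total = pathway_impact(
            ens, [[net], [net]], ["s"], {"all": ["a", "b", "c"]}, None, cfg
        )["median_impact"].iloc[0]
        assert prof["median_abs_impact"].sum() == pytest.approx(total)
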