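"""Network validation against held-out data and degree-preserving nulls.

A learned network predicts each gene from its fitted model using the
measured regulator expression of a held-out sample (one-step prediction).
Prediction quality is the per-gene Pearson correlation between predicted
and measured expression across test samples; it is compared with the same
quantity under degree-preserving random rewirings of the network, which
keep every gene's in- and out-degree but destroy the specific wiring.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import GeneModel, NetworkEnsemble, RegulatoryNetwork

log = logging.getLogger(__name__)


@dataclass
class PredictionQuality:
    """Per-gene correlations between predicted and measured expression.

    Genes with a constant prediction (e.g. empty models) have undefined
    correlation, stored as NaN and excluded from medians and rank tests.
    """

    correlations: pd.Series
    label: str = ""

    @property
    def median(self) -> float:
        return float(self.correlations.median())

    def defined(self) -> pd.Series:
        return self.correlations.dropna()


def predict_expression(
    network: RegulatoryNetwork, expr_test: pd.DataFrame, cn_test: pd.DataFrame
) -> pd.DataFrame:
    """One-step expression prediction on held-out samples.

    Per gene: intercept + cn_coef * cn_g + sum_r beta_r * x_r with the
    regulators' *measured* expression in each test sample.
    """
    missing = [
        r
        for m in network.models.values()
        for r in m.regulators
        if r not in expr_test.index
    ]
    if missing:
        raise KeyError(f"regulators missing from test matrix: {sorted(set(missing))[:5]}")
    pred = pd.DataFrame(0.0, index=expr_test.index, columns=expr_test.columns)
    for g in expr_test.index:
        m = network.models.get(g)
        if m is None:
            pred.loc[g] = np.nan
            continue
        yhat = np.full(expr_test.shape[1], m.intercept)
        if m.cn_coef != 0.0:
            yhat = yhat + m.cn_coef * cn_test.loc[g].to_numpy(float)
        for r, b in m.regulators.items():
            yhat = yhat + b * expr_test.loc[r].to_numpy(float)
        pred.loc[g] = yhat
    return pred


def prediction_quality(
    predicted: pd.DataFrame, measured: pd.DataFrame, label: str = ""
) -> PredictionQuality:
    """Per-gene Pearson correlation across test samples (NaN if constant)."""
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured matrices differ in shape")
    if predicted.shape[1] < 3:
        raise ValueError("need at least 3 test samples for correlations")
    # fixed memory layout so pairwise-summation order (hence the last ulp)
    # does not depend on how the frames were materialized
    P = np.ascontiguousarray(predicted.to_numpy(float))
    M = np.ascontiguousarray(measured.loc[predicted.index, predicted.columns].to_numpy(float))
    Pc = P - P.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    sp = np.sqrt((Pc**2).sum(axis=1))
    sm = np.sqrt((Mc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Pc * Mc).sum(axis=1) / (sp * sm)
    # constancy by exact range: mean subtraction alone can leave ~1e-17
    # residue on a constant row, which would fake a defined correlation
    constant = (np.ptp(P, axis=1) == 0) | (np.ptp(M, axis=1) == 0)
    rho[constant | (sp == 0) | (sm == 0)] = np.nan
    n_undef = int(np.isnan(rho).sum())
    if n_undef:
        log.info("%d genes with undefined correlation excluded", n_undef)
    return PredictionQuality(
        correlations=pd.Series(rho, index=predicted.index, name="rho"), label=label
    )


def permute_degree_preserving(
    network: RegulatoryNetwork,
    n_swaps_factor: int = 100,
    seed: int = 0,
) -> tuple[RegulatoryNetwork, bool]:
    """Rewire a network by repeated directed double-edge swaps.

    Each attempted swap picks two edges (a->b, c->d) and replaces them by
    (a->d, c->b), rejecting self-loops and duplicate edges, so every
    gene's in- and out-degree is preserved exactly. Edge attributes (beta,
    q) travel with the edge's source endpoint. Target-level intercepts and
    copy-number coefficients stay in place. Attempts
    ``n_swaps_factor * n_edges`` swaps.

    Returns ``(random_network, swapped)``; ``swapped`` is False when no
    swap was applied (e.g. a single-edge network, where no valid swap
    exists), in which case a copy is returned.
    """
    edge_list: list[tuple[str, str, float, float]] = []
    for t, m in network.models.items():
        for r, b in m.regulators.items():
            edge_list.append((r, t, b, m.regulator_q.get(r, np.nan)))
    n_edges = len(edge_list)
    rng = np.random.default_rng(seed)
    swapped = False
    if n_edges >= 2:
        present = {(r, t) for r, t, _, _ in edge_list}
        attempts = n_swaps_factor * n_edges
        pairs = rng.integers(0, n_edges, size=(attempts, 2))
        for i, j in pairs:
            if i == j:
                continue
            a, b, w1, q1 = edge_list[i]
            c, d, w2, q2 = edge_list[j]
            if a == d or c == b:
                continue
            if (a, d) in present or (c, b) in present:
                continue
            present.discard((a, b))
            present.discard((c, d))
            present.add((a, d))
            present.add((c, b))
            edge_list[i] = (a, d, w1, q1)
            edge_list[j] = (c, b, w2, q2)
            swapped = True
    if not swapped and n_edges >= 2:
        log.warning("no valid degree-preserving swap found; returning a copy")

    models: dict[str, GeneModel] = {}
    for t, m in network.models.items():
        models[t] = GeneModel(
            target=t, intercept=m.intercept, cn_coef=m.cn_coef, cn_q=m.cn_q
        )
    for r, t, b, q in edge_list:
        models[t].regulators[r] = b
        models[t].regulator_q[r] = q
    return (
        RegulatoryNetwork(
            models=models,
            train_ids=list(network.train_ids),
            test_ids=list(network.test_ids),
            seed=network.seed,
        ),
        swapped,
    )


def compare_to_random_prediction(
    real: pd.Series | np.ndarray, randoms: list[PredictionQuality]
) -> tuple[float, float]:
    """One-sided rank-sum test: real correlations shifted above random?

    ``real`` holds per-gene (median) correlations under the learned
    networks; the random replicates are pooled. Returns ``(statistic, p)``
    for the one-sided alternative real > random.
    """
    if not randoms:
        raise ValueError("need at least one random replicate")
    x = pd.Series(real).dropna().to_numpy(float)
    y = np.concatenate([r.defined().to_numpy(float) for r in randoms])
    if x.size == 0 or y.size == 0:
        raise ValueError("no defined correlations to compare")
    if np.unique(np.concatenate([x, y])).size == 1:
        raise ValueError("all correlation values tied")
    stat, p = stats.mannwhitneyu(x, y, alternative="greater")
    return float(stat), float(p)


def connectivity_scores(ensemble: NetworkEnsemble) -> pd.DataFrame:
    """Ensemble connectivity score of each gene's outgoing links.

    Counts for every gene the number of distinct outgoing links observed
    in exactly i of the n networks (count matrix C, genes x n), divides
    each nonzero column of C by its sum, and scores each gene by its row
    sum. Genes whose links recur across networks score higher.

    Returns a DataFrame with columns ``c_1..c_n`` (raw counts) and
    ``score``.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 networks")
    genes: set[str] = set()
    link_counts: dict[tuple[str, str], int] = {}
    for net in ensemble:
        genes.update(net.models)
        for t, m in net.models.items():
            for r in m.regulators:
                link_counts[(r, t)] = link_counts.get((r, t), 0) + 1
    gene_list = sorted(genes)
    pos = {g: i for i, g in enumerate(gene_list)}
    C = np.zeros((len(gene_list), n))
    for (r, _t), c in link_counts.items():
        C[pos[r], c - 1] += 1
    colsum = C.sum(axis=0)
    std = np.divide(C, colsum, out=np.zeros_like(C), where=colsum > 0)
    out = pd.DataFrame(C, index=gene_list, columns=[f"c_{i}" for i in range(1, n + 1)])
    out["score"] = std.sum(axis=1)
    return out


def category_score_test(
    scores: pd.Series, annotation: pd.DataFrame, category: str
) -> tuple[float, float]:
    """One-sided rank-sum test: do category genes have greater scores?

    Returns ``(statistic, p)`` comparing genes carrying the category flag
    against all other scored genes (alternative: category > complement).
    """
    from .annotation import genes_in_category

    members = set(genes_in_category(annotation, category)) & set(scores.index)
    complement = [g for g in scores.index if g not in members]
    if not members or not complement:
        raise ValueError(f"category {category!r} is empty or covers all genes")
    stat, p = stats.mannwhitneyu(
        scores.loc[sorted(members)], scores.loc[complement], alternative="greater"
    )
    return float(stat), float(p)
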