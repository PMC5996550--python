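"""Per-gene sparse regression models and ensemble network inference.

Each gene's expression is modeled as a linear combination of its own copy
number and the expression of all genes outside a +/-50-position window in
genome order (local predictors would mostly re-encode the shared copy
number state of neighboring genes, not regulation). Predictors are
selected along the lasso path by the covariance significance test at a
per-target q-value cutoff, then the coefficients are re-estimated by an
unpenalized least-squares refit on the selected support so downstream
propagation works with unshrunken effect sizes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lasso import covariance_test, fit_lasso_path
from .stats import compute_qvalues

log = logging.getLogger(__name__)

CN_PREDICTOR = "__cn__"


@dataclass
class GeneModel:
    """Selected predictors of one target gene, refit without penalty."""

    target: str
    intercept: float = 0.0
    cn_coef: float = 0.0
    cn_q: float = float("nan")
    regulators: dict[str, float] = field(default_factory=dict)
    regulator_q: dict[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.regulators and self.cn_coef == 0.0


@dataclass
class RegulatoryNetwork:
    """A directed signed network: one fitted :class:`GeneModel` per target."""

    models: dict[str, GeneModel]
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": r,
                "target": t,
                "beta": b,
                "q_value": m.regulator_q.get(r, np.nan),
                "sign": "activator" if b > 0 else "inhibitor",
            }
            for t, m in self.models.items()
            for r, b in m.regulators.items()
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "beta", "q_value", "sign"])

    def n_edges(self) -> int:
        return sum(len(m.regulators) for m in self.models.values())

    def activator_fraction(self) -> float:
        betas = [b for m in self.models.values() for b in m.regulators.values()]
        if not betas:
            return float("nan")
        return float(np.mean([b > 0 for b in betas]))

    def coefficient_matrix(self, genes: list[str]) -> np.ndarray:
        """Signed coefficient matrix B with B[t, r] = beta of edge r -> t."""
        pos = {g: i for i, g in enumerate(genes)}
        B = np.zeros((len(genes), len(genes)))
        for t, m in self.models.items():
            for r, b in m.regulators.items():
                B[pos[t], pos[r]] = b
        return B


@dataclass
class NetworkEnsemble:
    """Networks learned on repeated train/test splits of one cohort."""

    networks: list[RegulatoryNetwork]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)


def build_design_matrix(
    target: str,
    expr: pd.DataFrame,
    cn: pd.DataFrame,
    annotation: pd.DataFrame,
    local_window: int = 50,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray, float]:
    """Assemble the standardized predictor matrix for one target gene.

    Columns: the target's own copy number, then the expression of every
    gene farther than ``local_window`` positions away in genome order
    (the window always contains the target itself, so no self-expression
    predictor exists). Constant columns are dropped. Returns
    ``(X_std, y_centered, names, X_raw, y_mean)`` with names using
    :data:`CN_PREDICTOR` for the copy-number column.
    """
    if target not in annotation.index:
        raise KeyError(f"target {target!r} not in annotation")
    gi = annotation["genome_index"]
    ti = gi[target]
    candidates = [g for g in expr.index if abs(int(gi[g]) - int(ti)) > local_window]

    cols = [cn.loc[target].to_numpy(float)] + [expr.loc[g].to_numpy(float) for g in candidates]
    names = [CN_PREDICTOR] + candidates
    X_raw = np.column_stack(cols)
    sd = X_raw.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError(f"all candidate predictors of {target!r} are constant")
    X_raw = X_raw[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    X_std = (X_raw - X_raw.mean(axis=0)) / X_raw.std(axis=0)
    y = expr.loc[target].to_numpy(float)
    y_mean = float(y.mean())
    return X_std, y - y_mean, names, X_raw, y_mean


def fit_gene_model(
    target: str,
    expr: pd.DataFrame,
    cn: pd.DataFrame,
    annotation: pd.DataFrame,
    q_cutoff: float = 0.01,
    local_window: int = 50,
    max_steps: int | None = None,
) -> GeneModel:
    """Fit one target's sparse model: lasso path, covariance test, refit.

    Covariance-test p-values of the predictors that entered the path are
    converted to q-values within the target (Benjamini-Hochberg, the
    conservative pi0 = 1 variant); predictors at q <= ``q_cutoff`` are kept
    and their coefficients re-estimated by ordinary least squares on the
    unstandardized columns, so the model is directly usable for
    prediction on held-out samples. ``q_cutoff = 0`` yields an empty model.
    """
    X_std, y, names, X_raw, y_mean = build_design_matrix(
        target, expr, cn, annotation, local_window=local_window
    )
    model = GeneModel(target=target, intercept=y_mean)
    if q_cutoff <= 0:
        return model
    path = covariance_test(y, X_std, max_steps=max_steps)
    if not path.pvalues:
        return model
    idx = sorted(path.pvalues)
    pvals = np.array([path.pvalues[j] for j in idx])
    qres = compute_qvalues(pvals, method="bh")
    selected = [j for j, q in zip(idx, qres.qvalues) if q <= q_cutoff]
    if not selected:
        return model
    qmap = {j: q for j, q in zip(idx, qres.qvalues)}

    Xs = np.column_stack([np.ones(X_raw.shape[0]), X_raw[:, selected]])
    beta, *_ = np.linalg.lstsq(Xs, y + y_mean, rcond=None)
    model.intercept = float(beta[0])
    for k, j in enumerate(selected):
        coef = float(beta[k + 1])
        if names[j] == CN_PREDICTOR:
            model.cn_coef = coef
            model.cn_q = float(qmap[j])
        else:
            model.regulators[names[j]] = coef
            model.regulator_q[names[j]] = float(qmap[j])
    return model


def infer_network(
    expr: pd.DataFrame,
    cn: pd.DataFrame,
    annotation: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str] | None = None,
    q_cutoff: float = 0.01,
    local_window: int = 50,
    max_steps: int | None = None,
    seed: int | None = None,
) -> RegulatoryNetwork:
    """Fit all per-gene models on the training samples of one split."""
    expr_tr = expr[train_ids]
    cn_tr = cn[train_ids]
    models: dict[str, GeneModel] = {}
    for target in expr.index:
        models[target] = fit_gene_model(
            target,
            expr_tr,
            cn_tr,
            annotation,
            q_cutoff=q_cutoff,
            local_window=local_window,
            max_steps=max_steps,
        )
    return RegulatoryNetwork(
        models=models, train_ids=list(train_ids), test_ids=list(test_ids or []), seed=seed
    )


def train_test_split_ids(
    sample_ids: list[str], train_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Random split with ``|train| = round(train_fraction * n)``."""
    n = len(sample_ids)
    n_train = int(np.floor(train_fraction * n + 0.5))
    perm = rng.permutation(n)
    train = [sample_ids[i] for i in sorted(perm[:n_train])]
    test = [sample_ids[i] for i in sorted(perm[n_train:])]
    return train, test


def infer_network_ensemble(
    expr: pd.DataFrame,
    cn: pd.DataFrame,
    annotation: pd.DataFrame,
    n_networks: int = 10,
    train_fraction: float = 2.0 / 3.0,
    q_cutoff: float = 0.01,
    local_window: int = 50,
    max_steps: int | None = None,
    seed: int = 0,
) -> NetworkEnsemble:
    """Learn ``n_networks`` networks on fresh random train/test splits.

    Two-thirds of the cohort (rounded) trains each network; the held-out
    third is kept on the network for validation.
    """
    samples = list(expr.columns)
    if len(samples) < 6:
        raise ValueError("cohort too small for train/test splitting")
    rng = np.random.default_rng(seed)
    networks = []
    for k in range(n_networks):
        train, test = train_test_split_ids(samples, train_fraction, rng)
        log.info("network %d: %d train / %d test samples", k, len(train), len(test))
        net = infer_network(
            expr,
            cn,
            annotation,
            train_ids=train,
            test_ids=test,
            q_cutoff=q_cutoff,
            local_window=local_window,
            max_steps=max_steps,
            seed=k,
        )
        networks.append(net)
    return NetworkEnsemble(networks=networks, seed=seed)
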