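"""Synthetic tumor-cohort generator: copy number, expression, pathways.

Emulates the statistical structure of an oligodendroglioma-like cohort: a
recurrent two-arm co-deletion carried by ~75% of tumors, rarer whole-arm
deletions/duplications, and expression generated from a sparse signed
regulatory network plus a per-gene copy-number dose effect. The generator
mirrors the linear model the inference stage assumes, so ground-truth
recovery is well defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import genes_in_category

#: whole-arm event frequencies for rarely mutated arms (fraction of tumors);
#: the co-deletion itself is configured separately on CohortSpec
DEFAULT_ARM_EVENTS: tuple[tuple[str, str, float], ...] = (
    ("4q", "del", 0.098),
    ("9q", "del", 0.045),
    ("13q", "del", 0.105),
    ("15q", "del", 0.090),
    ("18q", "del", 0.150),
    ("7p", "dup", 0.060),
    ("7q", "dup", 0.090),
    ("11q", "dup", 0.045),
)


@dataclass
class GroundTruthNetwork:
    """A known sparse signed regulatory network used to simulate expression.

    Attributes
    ----------
    edges
        DataFrame with columns ``regulator, target, beta`` (directed,
        acyclic with respect to ``dag_order``).
    cn_effect
        Per-gene copy-number dose coefficient ``u_g`` (Series over genes).
    noise_sd
        Standard deviation of the per-gene biological noise term.
    dag_order
        Topological order of the genes; every edge points forward in it.
    """

    edges: pd.DataFrame
    cn_effect: pd.Series
    noise_sd: float
    dag_order: list[str]

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def signed_edge_map(self) -> dict[tuple[str, str], float]:
        return {
            (r, t): b
            for r, t, b in zip(
                self.edges["regulator"], self.edges["target"], self.edges["beta"]
            )
        }


@dataclass
class CohortSpec:
    """Configuration of a simulated tumor cohort.

    ``codeletion_fraction`` tumors (exact count, rounded) carry a concurrent
    hemizygous loss of both ``codeletion_arms``; log-ratio depth is drawn
    per tumor from ``codeletion_depth_range``. ``arm_events`` are applied
    independently per tumor at the stated frequencies.
    """

    n_tumors: int = 120
    n_normals: int = 3
    codeletion_arms: tuple[str, str] = ("1p", "19q")
    codeletion_fraction: float = 0.75
    codeletion_depth_range: tuple[float, float] = (-1.0, -0.6)
    arm_events: tuple[tuple[str, str, float], ...] = DEFAULT_ARM_EVENTS
    measurement_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 1 or self.n_normals < 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.codeletion_fraction <= 1.0:
            raise ValueError("codeletion_fraction must be in [0, 1]")
        lo, hi = self.codeletion_depth_range
        if not (lo <= hi < 0.0):
            raise ValueError("codeletion_depth_range must be strictly negative")
        for arm, kind, freq in self.arm_events:
            if kind not in ("del", "dup"):
                raise ValueError(f"arm event type {kind!r} must be 'del' or 'dup'")
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"arm event frequency {freq} out of [0, 1]")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")


def generate_ground_truth_network(
    annotation: pd.DataFrame,
    n_regulators: int,
    mean_out_degree: float = 5.5,
    activator_fraction: float = 0.78,
    coeff_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 0.2,
    cn_effect: float = 1.0,
    local_exclusion: int = 50,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Sample a sparse signed DAG over the annotated genes.

    Edges run from a designated regulator set to downstream genes in a
    random topological order. Each admissible (regulator, target) pair is
    included independently with a probability chosen so the expected edge
    count is ``mean_out_degree * n_regulators`` (i.e. ``mean_out_degree``
    is the expected number of outgoing links per regulator); admissible
    means the regulator precedes the target in the DAG order and the pair
    is farther apart than ``local_exclusion`` positions in genome order
    (the inference stage never considers local predictors, so the truth
    carries no local edges either).

    ``activator_fraction`` of edges get a positive coefficient; magnitudes
    are uniform on ``coeff_range``.
    """
    genes = list(annotation.index)
    n_genes = len(genes)
    if n_regulators > n_genes:
        raise ValueError("n_regulators exceeds number of genes")
    if mean_out_degree < 0:
        raise ValueError("mean_out_degree must be >= 0")
    if not 0.0 <= activator_fraction <= 1.0:
        raise ValueError("activator_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    dag_order = [genes[i] for i in rng.permutation(n_genes)]
    order_pos = {g: i for i, g in enumerate(dag_order)}
    gidx = annotation["genome_index"].to_dict()
    regulators = [genes[i] for i in rng.choice(n_genes, size=n_regulators, replace=False)]

    admissible: list[tuple[str, str]] = []
    for r in regulators:
        pr, xr = order_pos[r], gidx[r]
        for t in genes:
            if t == r or order_pos[t] <= pr:
                continue
            if abs(gidx[t] - xr) <= local_exclusion:
                continue
            admissible.append((r, t))
    target_edges = mean_out_degree * n_regulators
    p_edge = min(1.0, target_edges / len(admissible)) if admissible else 0.0
    keep = rng.random(len(admissible)) < p_edge
    chosen = [admissible[i] for i in np.flatnonzero(keep)]

    mags = rng.uniform(coeff_range[0], coeff_range[1], size=len(chosen))
    signs = np.where(rng.random(len(chosen)) < activator_fraction, 1.0, -1.0)
    edges = pd.DataFrame(
        {
            "regulator": [r for r, _ in chosen],
            "target": [t for _, t in chosen],
            "beta": mags * signs,
        }
    )
    u = pd.Series(cn_effect, index=genes, name="cn_effect", dtype=float)
    return GroundTruthNetwork(edges=edges, cn_effect=u, noise_sd=noise_sd, dag_order=dag_order)


def simulate_copy_number(
    annotation: pd.DataFrame, spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples copy-number log-ratio matrix.

    Returns ``(cn, meta)`` where ``cn`` holds log2 tumor/normal DNA ratios
    (normal samples sit at ~0) and ``meta`` is a per-sample table with the
    tumor flag, co-deletion flag and one boolean column per configured arm
    event. Exactly ``round(codeletion_fraction * n_tumors)`` tumors carry
    the co-deletion; both co-deleted arms share one per-tumor depth drawn
    from ``codeletion_depth_range``. Gene-level Gaussian measurement noise
    is added everywhere.
    """
    spec.validate()
    arms_present = set(annotation["arm"])
    for arm in spec.codeletion_arms:
        if arm not in arms_present:
            raise ValueError(f"co-deletion arm {arm!r} absent from annotation")
    for arm, _, _ in spec.arm_events:
        if arm not in arms_present:
            raise ValueError(f"arm event arm {arm!r} absent from annotation")

    rng = np.random.default_rng(spec.seed)
    genes = list(annotation.index)
    tumors = [f"T{i:03d}" for i in range(spec.n_tumors)]
    normals = [f"N{i:02d}" for i in range(spec.n_normals)]
    arm_of = annotation["arm"]

    n_codel = int(np.floor(spec.codeletion_fraction * spec.n_tumors + 0.5))
    codel_idx = set(rng.permutation(spec.n_tumors)[:n_codel])

    cn = np.zeros((len(genes), spec.n_tumors + spec.n_normals))
    meta_rows = []
    lo, hi = spec.codeletion_depth_range
    for j, t in enumerate(tumors):
        row = {"sample_id": t, "is_tumor": True, "codeleted": j in codel_idx}
        if j in codel_idx:
            depth = rng.uniform(lo, hi)
            for arm in spec.codeletion_arms:
                cn[(arm_of == arm).to_numpy(), j] = depth
        for arm, kind, freq in spec.arm_events:
            hit = rng.random() < freq
            row[f"evt_{arm}_{kind}"] = hit
            if hit:
                depth = rng.uniform(lo, hi)
                value = depth if kind == "del" else -depth
                cn[(arm_of == arm).to_numpy(), j] = value
        meta_rows.append(row)
    for k, nsample in enumerate(normals):
        row = {"sample_id": nsample, "is_tumor": False, "codeleted": False}
        for arm, kind, _ in spec.arm_events:
            row[f"evt_{arm}_{kind}"] = False
        meta_rows.append(row)

    if spec.measurement_noise_sd > 0:
        cn = cn + rng.normal(0.0, spec.measurement_noise_sd, size=cn.shape)

    cn_df = pd.DataFrame(cn, index=genes, columns=tumors + normals)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return cn_df, meta


def simulate_expression(
    truth: GroundTruthNetwork,
    cn: pd.DataFrame,
    seed: int = 0,
    emit: str = "log_ratio",
    baseline_range: tuple[float, float] = (50.0, 5000.0),
) -> pd.DataFrame:
    """Generate expression from the ground-truth network and copy number.

    Per sample, genes are evaluated in DAG order::

        x_g = u_g * cn_g + sum_{r -> g} beta_rg * x_r + eps_g,
        eps_g ~ Normal(0, noise_sd^2)

    ``emit="log_ratio"`` returns ``x`` directly (log2 tumor/normal scale);
    ``emit="counts"`` maps x to Poisson read counts around a per-gene
    baseline, ``counts ~ Poisson(baseline_g * 2^x)``, to exercise the
    count-filtering path.
    """
    if emit not in ("log_ratio", "counts"):
        raise ValueError("emit must be 'log_ratio' or 'counts'")
    genes = list(cn.index)
    if set(truth.dag_order) != set(genes):
        raise ValueError("truth network genes do not match copy-number matrix")
    order_pos = {g: i for i, g in enumerate(truth.dag_order)}
    for r, t in zip(truth.edges["regulator"], truth.edges["target"]):
        if order_pos[r] >= order_pos[t]:
            raise ValueError("truth network is cyclic w.r.t. dag_order")

    rng = np.random.default_rng(seed)
    n_samples = cn.shape[1]
    x = pd.DataFrame(0.0, index=genes, columns=cn.columns)
    parents: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    for r, t, b in zip(truth.edges["regulator"], truth.edges["target"], truth.edges["beta"]):
        parents[t].append((r, b))

    cn_vals = cn.to_numpy()
    gene_row = {g: i for i, g in enumerate(genes)}
    xv = np.zeros_like(cn_vals)
    for g in truth.dag_order:
        i = gene_row[g]
        acc = truth.cn_effect[g] * cn_vals[i]
        for r, b in parents[g]:
            acc = acc + b * xv[gene_row[r]]
        if truth.noise_sd > 0:
            acc = acc + rng.normal(0.0, truth.noise_sd, size=n_samples)
        xv[i] = acc
    x.iloc[:, :] = xv

    if emit == "log_ratio":
        return x
    baseline = np.exp(
        rng.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]), size=len(genes))
    )
    lam = baseline[:, None] * np.exp2(xv)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=cn.columns)


def generate_pathway_sets(
    annotation: pd.DataFrame,
    n_sets: int,
    size_range: tuple[int, int],
    seed: int = 0,
    category: str = "signaling",
    prefix: str | None = None,
) -> dict[str, list[str]]:
    """Draw GMT-shaped gene sets from genes carrying a category flag."""
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    pool = genes_in_category(annotation, category)
    if hi > len(pool):
        raise ValueError(
            f"size_range upper bound {hi} exceeds {category} pool of {len(pool)} genes"
        )
    rng = np.random.default_rng(seed)
    prefix = prefix or category
    sets: dict[str, list[str]] = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
        sets[f"{prefix}_{k:02d}"] = sorted(members)
    return sets
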