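"""Expression filtering, log-ratio construction, and copy-number mutation calls.

Mutation calling uses a tumor-adaptive threshold: for each tumor the mean
copy-number log-ratio r_i over the recurrently co-deleted region is
computed (r_i < 0 for carriers), and a gene counts as deleted when its
log-ratio falls below 0.5*r_i, duplicated when it exceeds -0.5*r_i. The
0.5 scaling absorbs per-sample noise and tumor-content differences. Arm
status is then called from gene status with an 80%-of-genes rule.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DELETED, NEUTRAL, DUPLICATED = -1, 0, 1


@dataclass
class MutationCalls:
    """Per-tumor, per-gene copy-number status and the thresholds behind it.

    ``gene_status`` and ``arm_status`` use -1 (deleted), 0 (neutral),
    +1 (duplicated). Tumors whose region mean ``r_i`` is non-negative are
    uncallable (the threshold pair degenerates); they are listed in
    ``uncallable`` and left all-neutral.
    """

    region_mean: pd.Series
    scaling: float
    gene_status: pd.DataFrame  # genes x tumors
    uncallable: list[str] = field(default_factory=list)
    arm_status: pd.DataFrame | None = None  # arms x tumors


def filter_low_expression(
    counts: pd.DataFrame, cpm_threshold: float = 1.0, sample_fraction: float = 0.5
) -> pd.DataFrame:
    """Drop genes with low counts-per-million in too many samples.

    A gene is removed when its CPM falls below ``cpm_threshold`` in at
    least ``sample_fraction`` of the samples (inclusive boundary: a gene
    failing in exactly half the samples is dropped).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    cpm = counts.div(libsize, axis=1) * 1e6
    fail_fraction = (cpm < cpm_threshold).mean(axis=1)
    kept = counts.loc[fail_fraction < sample_fraction]
    log.info("CPM filter kept %d of %d genes", len(kept), len(counts))
    return kept


def log_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a small prior count, median-centered per sample."""
    libsize = counts.sum(axis=0)
    lcpm = np.log2(counts.div(libsize, axis=1) * 1e6 + prior)
    return lcpm.sub(lcpm.median(axis=0), axis=1)


def to_log_ratios(expr: pd.DataFrame, normal_ids: list[str]) -> pd.DataFrame:
    """Convert log-scale expression to log-ratios against the normal mean.

    Per gene, subtracts the mean over the normal samples; the inputs must
    already be on a log2 scale (log-CPM or log intensities).
    """
    missing = [s for s in normal_ids if s not in expr.columns]
    if missing:
        raise ValueError(f"normal samples missing from matrix: {missing}")
    if len(normal_ids) == 0:
        raise ValueError("need at least one normal sample")
    ref = expr[normal_ids].mean(axis=1)
    return expr.sub(ref, axis=0)


def call_gene_copy_number(
    cn: pd.DataFrame,
    region_genes: list[str],
    tumor_ids: list[str] | None = None,
    scaling: float = 0.5,
    region_mean: pd.Series | None = None,
) -> MutationCalls:
    """Call deleted/neutral/duplicated per gene with tumor-adaptive thresholds.

    ``region_genes`` define the recurrently lost region whose mean
    log-ratio r_i anchors the thresholds; the call is intended for tumors
    carrying that loss (r_i < 0). Tumors with r_i >= 0 are flagged
    uncallable and left neutral. ``region_mean`` overrides the computed
    per-tumor r_i (e.g. when thresholds were calibrated on another
    matrix).
    """
    if not region_genes:
        raise ValueError("region_genes must be non-empty")
    missing = [g for g in region_genes if g not in cn.index]
    if missing:
        raise ValueError(f"region genes missing from matrix: {missing[:5]}")
    tumors = list(cn.columns) if tumor_ids is None else list(tumor_ids)

    sub = cn.loc[region_genes, tumors]
    r = sub.mean(axis=0) if region_mean is None else region_mean.loc[tumors]
    status = pd.DataFrame(NEUTRAL, index=cn.index, columns=tumors, dtype=np.int8)
    uncallable: list[str] = []
    vals = cn[tumors].to_numpy()
    for j, t in enumerate(tumors):
        ri = r[t]
        if ri >= 0:
            uncallable.append(t)
            continue
        col = vals[:, j]
        status.iloc[col < scaling * ri, j] = DELETED
        status.iloc[col > -scaling * ri, j] = DUPLICATED
    if uncallable:
        warnings.warn(
            f"{len(uncallable)} tumor(s) with non-negative region mean are uncallable",
            stacklevel=2,
        )
    return MutationCalls(
        region_mean=r, scaling=scaling, gene_status=status, uncallable=uncallable
    )


def call_arm_mutations(
    calls: MutationCalls,
    annotation: pd.DataFrame,
    arm_fraction: float = 0.8,
    min_tumors: int = 6,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[str]]]:
    """Call whole-arm events and emit qualifying subcohorts.

    An arm counts as deleted (duplicated) in a tumor when at least
    ``arm_fraction`` of its genes carry that call (inclusive boundary).
    For every (arm, event type) observed in at least ``min_tumors`` tumors
    a subcohort of affected tumor ids is emitted.

    Fills ``calls.arm_status`` and returns ``(arm_status, subcohorts)``.
    """
    arms = list(dict.fromkeys(annotation["arm"]))
    tumors = list(calls.gene_status.columns)
    arm_status = pd.DataFrame(NEUTRAL, index=arms, columns=tumors, dtype=np.int8)
    for arm in arms:
        genes = annotation.index[annotation["arm"] == arm]
        genes = [g for g in genes if g in calls.gene_status.index]
        if not genes:
            raise ValueError(f"arm {arm!r} has no genes in the call matrix")
        sub = calls.gene_status.loc[genes]
        frac_del = (sub == DELETED).mean(axis=0)
        frac_dup = (sub == DUPLICATED).mean(axis=0)
        arm_status.loc[arm, (frac_del >= arm_fraction).to_numpy()] = DELETED
        arm_status.loc[arm, (frac_dup >= arm_fraction).to_numpy()] = DUPLICATED

    subcohorts: dict[tuple[str, str], list[str]] = {}
    for arm in arms:
        for kind, code in (("del", DELETED), ("dup", DUPLICATED)):
            affected = [t for t in tumors if arm_status.loc[arm, t] == code]
            if len(affected) >= min_tumors:
                subcohorts[(arm, kind)] = affected
    calls.arm_status = arm_status
    return arm_status, subcohorts
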