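"""Synthetic genome annotation: genome-ordered genes grouped into chromosome arms.

The annotation table is the ordering authority for the whole pipeline: the
local-predictor exclusion window and the arm-level mutation rules both
operate on ``genome_index``, a 0-based permutation of the genes in which
every chromosome arm occupies a contiguous block.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: functional category labels a gene may carry (a gene may carry several)
CATEGORIES = (
    "TF",
    "kinase",
    "phosphatase",
    "oncogene",
    "tumor_suppressor",
    "essential",
    "signaling",
    "metabolic",
)

#: default per-gene probability of carrying each category flag
DEFAULT_CATEGORY_RATES: dict[str, float] = {
    "TF": 0.08,
    "kinase": 0.04,
    "phosphatase": 0.02,
    "oncogene": 0.03,
    "tumor_suppressor": 0.03,
    "essential": 0.10,
    "signaling": 0.15,
    "metabolic": 0.15,
}

ANNOTATION_COLUMNS = ("gene_id", "chrom", "arm", "start", "end", "genome_index", "categories")

_GENE_SPACING = 20_000
_GENE_LENGTH = 10_000


def generate_genome_annotation(
    n_genes: int,
    arm_sizes: Mapping[str, int],
    seed: int,
    category_rates: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Build a synthetic, genome-ordered gene annotation table.

    Parameters
    ----------
    n_genes
        Total number of genes; must equal the sum of ``arm_sizes``.
    arm_sizes
        Mapping arm label (e.g. ``"1p"``, ``"19q"``) -> number of genes on
        that arm. Arms are laid out in insertion order, so genes of one arm
        are contiguous in ``genome_index``.
    seed
        Seed for the category-flag assignment.
    category_rates
        Per-category probability that a gene carries the flag; defaults to
        :data:`DEFAULT_CATEGORY_RATES`.

    Returns
    -------
    pandas.DataFrame
        Indexed by ``gene_id`` with columns ``chrom, arm, start, end,
        genome_index, categories`` (categories as a ``;``-joined string,
        possibly empty).
    """
    if len(arm_sizes) < 2:
        raise ValueError("need at least 2 arms")
    if any(s <= 0 for s in arm_sizes.values()):
        raise ValueError("arm sizes must be positive")
    if sum(arm_sizes.values()) != n_genes:
        raise ValueError(
            f"arm sizes sum to {sum(arm_sizes.values())}, expected n_genes={n_genes}"
        )
    rates = dict(DEFAULT_CATEGORY_RATES if category_rates is None else category_rates)
    unknown = set(rates) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    rows = []
    gi = 0
    chrom_cursor: dict[str, int] = {}
    for arm, size in arm_sizes.items():
        chrom = arm[:-1] if len(arm) > 1 and arm[-1] in "pq" else arm
        for _ in range(size):
            pos = chrom_cursor.get(chrom, 0)
            start = pos * _GENE_SPACING
            rows.append(
                {
                    "gene_id": f"g{gi:04d}",
                    "chrom": chrom,
                    "arm": arm,
                    "start": start,
                    "end": start + _GENE_LENGTH,
                    "genome_index": gi,
                }
            )
            chrom_cursor[chrom] = pos + 1
            gi += 1

    table = pd.DataFrame(rows).set_index("gene_id")
    flags = {
        cat: rng.random(n_genes) < rates.get(cat, 0.0) for cat in CATEGORIES
    }
    table["categories"] = [
        ";".join(cat for cat in CATEGORIES if flags[cat][i]) for i in range(n_genes)
    ]
    return table


def genes_in_category(annotation: pd.DataFrame, category: str) -> list[str]:
    """Gene ids carrying ``category`` among their flags."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    mask = annotation["categories"].str.split(";").apply(lambda c: category in c)
    return list(annotation.index[mask])


def genes_on_arm(annotation: pd.DataFrame, arm: str) -> list[str]:
    """Gene ids on a chromosome arm, in genome order."""
    sub = annotation[annotation["arm"] == arm]
    if sub.empty:
        raise ValueError(f"arm {arm!r} not present in annotation")
    return list(sub.sort_values("genome_index").index)


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Check the structural invariants of an annotation table.

    ``genome_index`` must be a permutation of ``0..G-1``, arms must be
    contiguous in genome order, and ``start <= end`` per gene.
    """
    gi = np.sort(annotation["genome_index"].to_numpy())
    if not np.array_equal(gi, np.arange(len(annotation))):
        raise ValueError("genome_index is not a permutation of 0..G-1")
    ordered = annotation.sort_values("genome_index")
    arm_blocks = ordered["arm"].to_numpy()
    # an arm is contiguous iff it never re-appears after a different arm
    seen: set[str] = set()
    prev = None
    for arm in arm_blocks:
        if arm != prev:
            if arm in seen:
                raise ValueError(f"arm {arm!r} is not contiguous in genome order")
            seen.add(arm)
            prev = arm
    if (annotation["start"] > annotation["end"]).any():
        raise ValueError("gene with start > end")
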