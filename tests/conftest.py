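"""Shared fixtures: small synthetic genomes and cohorts."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oligonet.annotation import generate_genome_annotation
from oligonet.pipeline import DEFAULT_ARM_SIZES
from oligonet.simulate import (
    CohortSpec,
    GroundTruthNetwork,
    generate_ground_truth_network,
    simulate_copy_number,
    simulate_expression,
)


@pytest.fixture(scope="session")
def annotation300() -> pd.DataFrame:
    """Default-sized genome: 300 genes over the standard arm layout."""
    return generate_genome_annotation(300, DEFAULT_ARM_SIZES, seed=7)


@pytest.fixture(scope="session")
def tiny_annotation() -> pd.DataFrame:
    return generate_genome_annotation(30, {"1p": 10, "19q": 8, "rest": 12}, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with known truth (60 genes, 40 tumors).

    The local window is kept small relative to the genome so per-gene
    models have predictors; inference tests pass local_window=5.
    """
    ann = generate_genome_annotation(60, {"1p": 15, "19q": 10, "rest": 35}, seed=11)
    truth = generate_ground_truth_network(
        ann, n_regulators=12, mean_out_degree=3.0, noise_sd=0.2,
        local_exclusion=5, seed=12,
    )
    spec = CohortSpec(n_tumors=40, n_normals=3, arm_events=(), seed=13)
    cn, meta = simulate_copy_number(ann, spec)
    expr = simulate_expression(truth, cn, seed=14)
    return ann, truth, cn, expr, meta


def make_chain_truth(genes: list[str], chain: list[tuple[str, str, float]],
                     noise_sd: float = 0.0, cn_effect: float = 0.0) -> GroundTruthNetwork:
    """Hand-built truth network for targeted simulation tests."""
    edges = pd.DataFrame(chain, columns=["regulator", "target", "beta"])
    order = list(genes)
    u = pd.Series(cn_effect, index=genes, dtype=float)
    return GroundTruthNetwork(edges=edges, cn_effect=u, noise_sd=noise_sd, dag_order=order)
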