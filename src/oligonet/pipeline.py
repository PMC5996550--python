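"""End-to-end pipeline: simulate -> preprocess -> infer -> validate -> score -> impact -> report.

Each stage reads the previous stage's on-disk outputs (or reuses the
in-memory state when run in one process), writes TSV/GMT/JSON results
into the run directory, and records a manifest with its resolved
parameters, derived seed and a hash of the full configuration, so a run
is resumable and reproducible file-by-file.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .annotation import generate_genome_annotation, genes_on_arm
from .impact import PropagationConfig, pathway_impact
from .inference import (
    GeneModel,
    NetworkEnsemble,
    RegulatoryNetwork,
    infer_network_ensemble,
)
from .preprocess import (
    DELETED,
    DUPLICATED,
    call_arm_mutations,
    call_gene_copy_number,
    filter_low_expression,
    log_cpm,
    to_log_ratios,
)
from .simulate import (
    CohortSpec,
    DEFAULT_ARM_EVENTS,
    generate_ground_truth_network,
    generate_pathway_sets,
    simulate_copy_number,
    simulate_expression,
)
from .stats import moderated_t_test, pathway_enrichment
from .validation import (
    compare_to_random_prediction,
    connectivity_scores,
    permute_degree_preserving,
    predict_expression,
    prediction_quality,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "infer", "validate", "score", "impact", "report")

DEFAULT_ARM_SIZES = {
    "1p": 45,
    "19q": 30,
    "4q": 18,
    "9q": 18,
    "13q": 18,
    "15q": 18,
    "18q": 18,
    "7p": 18,
    "7q": 18,
    "11q": 18,
    "rest": 81,
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results/run",
    "simulate": {
        "n_genes": 300,
        "arm_sizes": dict(DEFAULT_ARM_SIZES),
        "n_regulators": 60,
        "mean_out_degree": 5.5,
        "activator_fraction": 0.78,
        "coeff_range": [0.5, 1.5],
        "noise_sd": 0.2,
        "cn_effect": 1.0,
        "n_tumors": 120,
        "n_normals": 3,
        "codeletion_arms": ["1p", "19q"],
        "codeletion_fraction": 0.75,
        "codeletion_depth_range": [-1.0, -0.6],
        "measurement_noise_sd": 0.05,
        "emit": "log_ratio",
        "n_signaling_sets": 8,
        "n_metabolic_sets": 8,
        "set_size_range": [5, 15],
    },
    "preprocess": {
        "cpm_threshold": 1.0,
        "sample_fraction": 0.5,
        "scaling": 0.5,
        "arm_fraction": 0.8,
        "min_tumors": 6,
        "de_q_cutoff": 0.05,
    },
    "inference": {
        "n_networks": 10,
        "train_fraction": 2.0 / 3.0,
        "q_cutoff": 0.01,
        "local_window": 50,
        "max_steps": 25,
    },
    "validation": {
        "n_random": 25,
        "n_swaps_factor": 100,
    },
    "impact": {
        "max_path_length": 5,
        "quality_weighting": True,
        "q_cutoff_main": 0.05,
        "q_cutoff_arms": 0.1,
    },
}


class ConfigError(ValueError):
    """A pipeline configuration key is missing or invalid."""


def _merge(base: dict, override: dict, depth: int = 0) -> dict:
    # merge section/key levels; leaf dicts (e.g. arm_sizes) are replaced whole
    out = dict(base)
    for k, v in override.items():
        if depth < 1 and isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v, depth + 1)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults merged with overrides)."""

    data: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONFIG)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(override)

    @classmethod
    def from_dict(cls, override: dict) -> "PipelineConfig":
        cfg = cls(data=_merge(json.loads(json.dumps(DEFAULT_CONFIG)), override))
        cfg.validate()
        return cfg

    def __getitem__(self, key: str):
        return self.data[key]

    def validate(self) -> None:
        unknown = set(self.data) - set(DEFAULT_CONFIG)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        for section, defaults in DEFAULT_CONFIG.items():
            if not isinstance(defaults, dict):
                continue
            extra = set(self.data.get(section, {})) - set(defaults)
            if extra:
                raise ConfigError(f"unknown key(s) in '{section}': {sorted(extra)}")
        sim = self.data["simulate"]
        if sum(sim["arm_sizes"].values()) != sim["n_genes"]:
            raise ConfigError("simulate.arm_sizes must sum to simulate.n_genes")
        if not isinstance(self.data["seed"], int):
            raise ConfigError("seed must be an integer")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.data["seed"], spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineState:
    """In-memory carrier of stage products (mirrors the on-disk layout)."""

    annotation: pd.DataFrame | None = None
    truth_edges: pd.DataFrame | None = None
    cn: pd.DataFrame | None = None
    expr: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None
    signaling_sets: dict | None = None
    metabolic_sets: dict | None = None
    log_ratios: pd.DataFrame | None = None
    codeleted: list[str] | None = None
    subcohorts: dict | None = None
    de_tables: dict | None = None
    sources: dict | None = None
    ensemble: NetworkEnsemble | None = None
    qualities: list | None = None
    scores: pd.DataFrame | None = None
    impact_tables: dict | None = None


def _manifest(outdir: Path, stage: str, cfg: PipelineConfig, outputs: list[str]) -> None:
    io.write_json(
        {
            "stage": stage,
            "seed": cfg.stage_seed(stage),
            "master_seed": cfg.data["seed"],
            "config_hash": cfg.hash(),
            "params": cfg.data.get(
                {"infer": "inference", "validate": "validation", "score": "validation"}.get(
                    stage, stage
                ),
                {},
            ),
            "outputs": outputs,
        },
        outdir / f"manifest_{stage}.json",
    )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    sim = cfg["simulate"]
    seed = cfg.stage_seed("simulate")
    annotation = generate_genome_annotation(
        sim["n_genes"], sim["arm_sizes"], seed=seed
    )
    truth = generate_ground_truth_network(
        annotation,
        n_regulators=sim["n_regulators"],
        mean_out_degree=sim["mean_out_degree"],
        activator_fraction=sim["activator_fraction"],
        coeff_range=tuple(sim["coeff_range"]),
        noise_sd=sim["noise_sd"],
        cn_effect=sim["cn_effect"],
        local_exclusion=cfg["inference"]["local_window"],
        seed=seed + 1,
    )
    spec = CohortSpec(
        n_tumors=sim["n_tumors"],
        n_normals=sim["n_normals"],
        codeletion_arms=tuple(sim["codeletion_arms"]),
        codeletion_fraction=sim["codeletion_fraction"],
        codeletion_depth_range=tuple(sim["codeletion_depth_range"]),
        arm_events=tuple(
            (a, k, f) for a, k, f in DEFAULT_ARM_EVENTS if a in set(annotation["arm"])
        ),
        measurement_noise_sd=sim["measurement_noise_sd"],
        seed=seed + 2,
    )
    cn, meta = simulate_copy_number(annotation, spec)
    expr = simulate_expression(truth, cn, seed=seed + 3, emit=sim["emit"])
    signaling = generate_pathway_sets(
        annotation, sim["n_signaling_sets"], tuple(sim["set_size_range"]),
        seed=seed + 4, category="signaling",
    )
    metabolic = generate_pathway_sets(
        annotation, sim["n_metabolic_sets"], tuple(sim["set_size_range"]),
        seed=seed + 5, category="metabolic",
    )
    state.annotation, state.truth_edges = annotation, truth.edges
    state.cn, state.expr, state.meta = cn, expr, meta
    state.signaling_sets, state.metabolic_sets = signaling, metabolic

    io.write_annotation(annotation, outdir / "annotation.tsv")
    io.write_table(truth.edges, outdir / "truth_edges.tsv")
    io.write_matrix(cn, outdir / "copy_number.tsv")
    io.write_matrix(expr, outdir / "expression.tsv")
    io.write_sample_metadata(meta, outdir / "sample_metadata.tsv")
    io.write_gmt(signaling, outdir / "signaling.gmt")
    io.write_gmt(metabolic, outdir / "metabolic.gmt")
    _manifest(outdir, "simulate", cfg, [
        "annotation.tsv", "truth_edges.tsv", "copy_number.tsv", "expression.tsv",
        "sample_metadata.tsv", "signaling.gmt", "metabolic.gmt",
    ])


def stage_preprocess(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    pp = cfg["preprocess"]
    annotation, meta = state.annotation, state.meta
    tumors = list(meta.index[meta["is_tumor"]])
    normals = list(meta.index[~meta["is_tumor"]])

    expr = state.expr
    if cfg["simulate"]["emit"] == "counts":
        expr = filter_low_expression(expr, pp["cpm_threshold"], pp["sample_fraction"])
        expr = to_log_ratios(log_cpm(expr), normals)
        io.write_matrix(expr, outdir / "log_ratios.tsv")
    state.log_ratios = expr

    codel_arms = list(cfg["simulate"]["codeletion_arms"])
    region = [g for arm in codel_arms for g in genes_on_arm(annotation, arm)]
    calls = call_gene_copy_number(
        state.cn.loc[expr.index], region_genes=[g for g in region if g in expr.index],
        tumor_ids=tumors, scaling=pp["scaling"],
    )
    arm_status, _ = call_arm_mutations(
        calls, annotation.loc[expr.index], arm_fraction=pp["arm_fraction"],
        min_tumors=pp["min_tumors"],
    )
    codeleted = [
        t for t in tumors
        if t not in calls.uncallable
        and all(arm_status.loc[arm, t] == DELETED for arm in codel_arms)
    ]
    state.codeleted = codeleted
    if not codeleted:
        raise RuntimeError("no callable co-deleted tumors found")

    # rare-arm subcohorts among co-deleted tumors only
    codel_status = arm_status[codeleted]
    subcohorts: dict[str, list[str]] = {}
    for arm in arm_status.index:
        if arm in codel_arms:
            continue
        for kind, code in (("del", DELETED), ("dup", DUPLICATED)):
            affected = [t for t in codeleted if codel_status.loc[arm, t] == code]
            if len(affected) >= pp["min_tumors"]:
                subcohorts[f"{arm}_{kind}"] = affected
    state.subcohorts = subcohorts

    de_tables: dict[str, pd.DataFrame] = {}
    sources: dict[str, list[str]] = {}
    de_main = moderated_t_test(expr[codeleted], expr[normals], q_cutoff=pp["de_q_cutoff"])
    de_tables["codeletion"] = de_main.table
    region_set = set(region)
    sources["codeletion"] = [
        g for g in de_main.table.index
        if g in region_set and de_main.table.loc[g, "direction"] != "ns"
    ]
    for name, members in subcohorts.items():
        arm = name.rsplit("_", 1)[0]
        de_sub = moderated_t_test(expr[members], expr[normals], q_cutoff=pp["de_q_cutoff"])
        de_tables[name] = de_sub.table
        arm_genes = set(genes_on_arm(annotation, arm)) & set(expr.index)
        sources[name] = [
            g for g in de_sub.table.index
            if g in arm_genes and de_sub.table.loc[g, "direction"] != "ns"
        ]
    state.de_tables, state.sources = de_tables, sources

    enrichment = {}
    for cls, sets in (("signaling", state.signaling_sets), ("metabolic", state.metabolic_sets)):
        for direction in ("up", "down"):
            enrichment[f"{cls}_{direction}"] = pathway_enrichment(de_main, sets, direction)

    io.write_table(
        calls.gene_status.rename_axis("gene_id").reset_index(), outdir / "gene_status.tsv"
    )
    io.write_table(
        arm_status.rename_axis("arm").reset_index(), outdir / "arm_status.tsv"
    )
    io.write_json(
        {"codeleted": codeleted, "uncallable": calls.uncallable, "subcohorts": subcohorts},
        outdir / "cohorts.json",
    )
    for name, table in de_tables.items():
        io.write_table(table.rename_axis("gene_id").reset_index(), outdir / f"de_{name}.tsv")
    for name, table in enrichment.items():
        io.write_table(table.reset_index(), outdir / f"enrichment_{name}.tsv")
    io.write_json(sources, outdir / "sources.json")
    _manifest(outdir, "preprocess", cfg, ["gene_status.tsv", "arm_status.tsv",
                                          "cohorts.json", "sources.json"])


def stage_infer(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    inf = cfg["inference"]
    tumors = list(state.meta.index[state.meta["is_tumor"]])
    ensemble = infer_network_ensemble(
        state.log_ratios[tumors],
        state.cn.loc[state.log_ratios.index, tumors],
        state.annotation.loc[state.log_ratios.index],
        n_networks=inf["n_networks"],
        train_fraction=inf["train_fraction"],
        q_cutoff=inf["q_cutoff"],
        local_window=inf["local_window"],
        max_steps=inf["max_steps"],
        seed=cfg.stage_seed("infer"),
    )
    state.ensemble = ensemble
    splits = []
    for j, net in enumerate(ensemble):
        io.write_table(net.edges(), outdir / f"network_{j}_edges.tsv")
        targets = pd.DataFrame(
            [
                {"target": t, "intercept": m.intercept, "cn_coef": m.cn_coef,
                 "cn_q": m.cn_q, "n_regulators": len(m.regulators)}
                for t, m in net.models.items()
            ]
        )
        io.write_table(targets, outdir / f"network_{j}_targets.tsv")
        splits.append({"network": j, "train": net.train_ids, "test": net.test_ids})
    io.write_json(
        {"seed": cfg.stage_seed("infer"), "splits": splits}, outdir / "ensemble.json"
    )
    _manifest(outdir, "infer", cfg, ["ensemble.json"])


def _random_networks_for(
    net: RegulatoryNetwork, j: int, n_random: int, n_swaps_factor: int, seed: int
) -> list[RegulatoryNetwork]:
    """The j-th network's permutation replicates (deterministic in seed)."""
    out = []
    for k in range(n_random):
        rn, _ = permute_degree_preserving(
            net, n_swaps_factor=n_swaps_factor, seed=seed + 1000 * j + k
        )
        out.append(rn)
    return out


def stage_validate(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    val = cfg["validation"]
    seed = cfg.stage_seed("validate")
    expr, cn = state.log_ratios, state.cn.loc[state.log_ratios.index]
    qualities, rand_qualities = [], []
    table = pd.DataFrame(index=expr.index)
    for j, net in enumerate(state.ensemble):
        test = net.test_ids
        pred = predict_expression(net, expr[test], cn[test])
        q = prediction_quality(pred, expr[test], label=f"network_{j}")
        qualities.append(q)
        table[f"rho_{j}"] = q.correlations
        for rn in _random_networks_for(net, j, val["n_random"], val["n_swaps_factor"], seed):
            rpred = predict_expression(rn, expr[test], cn[test])
            rand_qualities.append(prediction_quality(rpred, expr[test]))
    table["median_rho"] = table.median(axis=1)
    state.qualities = qualities
    stat, p = compare_to_random_prediction(table["median_rho"], rand_qualities)
    summary = {
        "median_correlation": float(table["median_rho"].median()),
        "per_network_medians": [q.median for q in qualities],
        "random_median": float(
            np.median(np.concatenate([r.defined().to_numpy() for r in rand_qualities]))
        ),
        "wilcoxon_statistic": stat,
        "wilcoxon_p_one_sided": p,
        "n_random_per_network": val["n_random"],
    }
    io.write_table(table.rename_axis("gene_id").reset_index(), outdir / "validation.tsv")
    io.write_json(summary, outdir / "validation_summary.json")
    _manifest(outdir, "validate", cfg, ["validation.tsv", "validation_summary.json"])


def stage_score(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    scores = connectivity_scores(state.ensemble)
    state.scores = scores
    io.write_table(scores.rename_axis("gene_id").reset_index(),
                   outdir / "connectivity_scores.tsv")
    from .validation import category_score_test

    tests = {}
    for cat in ("tumor_suppressor", "oncogene", "essential", "signaling"):
        try:
            stat, p = category_score_test(scores["score"], state.annotation, cat)
            tests[cat] = {"statistic": stat, "p_one_sided": p}
        except ValueError as exc:
            tests[cat] = {"error": str(exc)}
    io.write_json(tests, outdir / "connectivity_tests.json")
    _manifest(outdir, "score", cfg, ["connectivity_scores.tsv", "connectivity_tests.json"])


def stage_impact(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    imp = cfg["impact"]
    val = cfg["validation"]
    seed = cfg.stage_seed("validate")  # same permutation replicates as validation
    config = PropagationConfig(
        quality_weighting=imp["quality_weighting"], max_path_length=imp["max_path_length"]
    )
    random_ensembles = [
        _random_networks_for(net, j, val["n_random"], val["n_swaps_factor"], seed)
        for j, net in enumerate(state.ensemble)
    ]
    class_sets = {
        "signaling": sorted({g for s in state.signaling_sets.values() for g in s}),
        "metabolic": sorted({g for s in state.metabolic_sets.values() for g in s}),
    }
    tables = {}
    for name, sources in state.sources.items():
        if not sources:
            log.warning("no differentially expressed sources for %s", name)
            tables[name] = pd.DataFrame()
            continue
        cutoff = imp["q_cutoff_main"] if name == "codeletion" else imp["q_cutoff_arms"]
        tables[name] = pathway_impact(
            state.ensemble, random_ensembles, sources, class_sets,
            state.qualities, config, q_cutoff=cutoff,
        )
        io.write_table(tables[name], outdir / f"impact_{name}.tsv")
    state.impact_tables = tables
    _manifest(outdir, "impact", cfg, [f"impact_{n}.tsv" for n in tables])


def stage_report(cfg: PipelineConfig, state: PipelineState, outdir: Path) -> dict:
    ensemble = state.ensemble
    report = {
        "cohort": {
            "n_tumors": int(state.meta["is_tumor"].sum()),
            "n_normals": int((~state.meta["is_tumor"]).sum()),
            "n_codeleted_called": len(state.codeleted),
            "subcohorts": {k: len(v) for k, v in (state.subcohorts or {}).items()},
        },
        "differential_expression": {
            name: {
                "n_up": int((t["direction"] == "up").sum()),
                "n_down": int((t["direction"] == "down").sum()),
            }
            for name, t in (state.de_tables or {}).items()
        },
        "n_sources": {k: len(v) for k, v in (state.sources or {}).items()},
        "networks": {
            "n_networks": len(ensemble),
            "edges_per_network": [net.n_edges() for net in ensemble],
            "activator_fraction": [net.activator_fraction() for net in ensemble],
        },
        "high_impact": {
            name: {
                cls: sorted(
                    t.loc[(t["pathway_class"] == cls) & t["high_impact"], "source"]
                )
                for cls in ("signaling", "metabolic")
            }
            for name, t in (state.impact_tables or {}).items()
            if len(t)
        },
    }
    io.write_json(report, outdir / "report.json")
    lines = [
        f"cohort: {report['cohort']['n_tumors']} tumors "
        f"({report['cohort']['n_codeleted_called']} called co-deleted), "
        f"{report['cohort']['n_normals']} normals",
        f"networks: {report['networks']['n_networks']}, "
        f"edges {report['networks']['edges_per_network']}",
    ]
    for name, classes in report["high_impact"].items():
        for cls, genes in classes.items():
            lines.append(f"high-impact [{name}/{cls}]: {len(genes)} gene(s) {genes}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    _manifest(outdir, "report", cfg, ["report.json", "report.txt"])
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "infer": stage_infer,
    "validate": stage_validate,
    "score": stage_score,
    "impact": stage_impact,
    "report": stage_report,
}

# stages whose on-disk outputs can be reloaded instead of recomputed
_LOADERS_ORDER = ("simulate", "preprocess", "infer")


def _load_simulate(state: PipelineState, outdir: Path) -> None:
    state.annotation = io.read_annotation(outdir / "annotation.tsv")
    state.truth_edges = io.read_table(outdir / "truth_edges.tsv")
    state.cn = io.read_matrix(outdir / "copy_number.tsv")
    state.expr = io.read_matrix(outdir / "expression.tsv")
    state.meta = io.read_sample_metadata(outdir / "sample_metadata.tsv")
    state.signaling_sets = io.read_gmt(outdir / "signaling.gmt")
    state.metabolic_sets = io.read_gmt(outdir / "metabolic.gmt")


def _load_preprocess(state: PipelineState, outdir: Path) -> None:
    lr = outdir / "log_ratios.tsv"
    state.log_ratios = io.read_matrix(lr) if lr.exists() else state.expr
    cohorts = io.read_json(outdir / "cohorts.json")
    state.codeleted = cohorts["codeleted"]
    state.subcohorts = cohorts["subcohorts"]
    state.sources = io.read_json(outdir / "sources.json")
    state.de_tables = {
        name: io.read_table(outdir / f"de_{name}.tsv").set_index("gene_id")
        for name in ["codeletion"] + list(state.subcohorts)
    }


def _load_infer(state: PipelineState, outdir: Path) -> None:
    manifest = io.read_json(outdir / "ensemble.json")
    networks = []
    for split in manifest["splits"]:
        j = split["network"]
        targets = io.read_table(outdir / f"network_{j}_targets.tsv")
        edges = io.read_table(outdir / f"network_{j}_edges.tsv")
        models = {
            row["target"]: GeneModel(
                target=row["target"], intercept=row["intercept"],
                cn_coef=row["cn_coef"], cn_q=row["cn_q"],
            )
            for _, row in targets.iterrows()
        }
        for _, row in edges.iterrows():
            models[row["target"]].regulators[row["regulator"]] = row["beta"]
            models[row["target"]].regulator_q[row["regulator"]] = row["q_value"]
        networks.append(
            RegulatoryNetwork(
                models=models, train_ids=split["train"], test_ids=split["test"], seed=j
            )
        )
    state.ensemble = NetworkEnsemble(networks=networks, seed=manifest["seed"])


_STAGE_LOADERS = {
    "simulate": _load_simulate,
    "preprocess": _load_preprocess,
    "infer": _load_infer,
}


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    outdir: str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
    resume: bool = False,
) -> tuple[PipelineState, Path]:
    """Run the pipeline stages in order, writing all outputs to ``outdir``.

    With ``resume=True``, stages whose manifest already exists in the run
    directory are reloaded from their on-disk outputs instead of being
    recomputed (supported for simulate/preprocess/infer; the cheap
    downstream stages always recompute).
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(outdir if outdir is not None else config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(
        {"config": config.data, "config_hash": config.hash()}, out / "resolved_config.json"
    )
    state = PipelineState()
    for stage in STAGES:
        if stage not in stages:
            continue
        if (
            resume
            and stage in _STAGE_LOADERS
            and (out / f"manifest_{stage}.json").exists()
        ):
            log.info("stage %s: reloading from %s", stage, out)
            _STAGE_LOADERS[stage](state, out)
            continue
        log.info("stage %s", stage)
        _STAGE_FUNCS[stage](config, state, out)
    return state, out
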