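"""Pipeline orchestration: config, seed fan-out, artifact export.

`run_pipeline` drives cohort → preprocess → dimensions → clustering →
network over either a CSV cohort or a synthetic cohort generated in-memory,
writing plain-text artifacts (CSV/JSON/GraphML) to an output directory.
All stage seeds are derived from one master seed by hashing the stage name,
so adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd

from . import cohort as cohort_mod
from . import clustering as clustering_mod
from . import dimensions as dimensions_mod
from . import network as network_mod
from . import preprocess as preprocess_mod
from . import synthetic as synthetic_mod
from .cohort import CohortTable

logger = logging.getLogger("cohortnet")

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "export_network",
           "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with the
    master seed, kept below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31)


@dataclass
class PipelineConfig:
    input_csv: str | None = None  # mutually exclusive with synthetic_n
    synthetic_n: int | None = 519
    cell_missing_rate: float = 0.0145
    max_missing_fraction: float = 0.20
    knn_k: int = 9
    pa_iterations: int = 1000
    pa_percentile: float = 95.0
    k_min: int = 2
    k_max: int = 10
    silhouette_threshold: float = 0.5
    silhouette_variant: str = "classical"
    kmeans_restarts: int = 10
    mds_restarts: int = 4
    bootstrap_B: int = 3000
    cv_folds: int = 5
    lambda_mode: str = "fixed"
    alpha: float = 0.05
    master_seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return f"{zlib.crc32(blob.encode()):08x}"


@dataclass
class ResultBundle:
    config: PipelineConfig
    table: CohortTable
    excluded_ids: list[str]
    descriptives: cohort_mod.Descriptives
    zmatrix: preprocess_mod.ZMatrix
    factor: dimensions_mod.FactorSolution
    sweep: clustering_mod.ClusterSweepResult
    estimate: network_mod.NetworkEstimate
    bootstrap: network_mod.BootstrapSummary
    timings: dict[str, float] = field(default_factory=dict)


def _load_or_generate(config: PipelineConfig) -> CohortTable:
    if config.input_csv is not None:
        return cohort_mod.read_cohort_csv(
            config.input_csv, synthetic_mod.ANALYSIS_MEASURES
        )
    spec = synthetic_mod.spec_from_table2(
        n_children=config.synthetic_n,
        cell_missing_rate=config.cell_missing_rate,
        seed=stage_seed(config.master_seed, "synthetic"),
    )
    table, _ = synthetic_mod.generate_factor_cohort(spec)
    return table


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full analysis; identical config+seed gives an identical
    bundle. Artifacts are written when ``config.outdir`` is set."""
    timings: dict[str, float] = {}

    def timed(stage, fn):
        t0 = time.perf_counter()
        out = fn()
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", stage, timings[stage])
        return out

    table = timed("cohort", lambda: _load_or_generate(config))
    desc = timed("descriptives", lambda: cohort_mod.descriptives(table))
    kept, excluded = timed(
        "exclude",
        lambda: preprocess_mod.exclude_high_missingness(
            table, config.max_missing_fraction
        ),
    )
    z = timed("standardize", lambda: preprocess_mod.standardize(kept))
    z = timed("impute", lambda: preprocess_mod.impute_knn(z, k=config.knn_k))
    factor = timed(
        "dimensions",
        lambda: dimensions_mod.factor_solution(
            z,
            pa_iterations=config.pa_iterations,
            pa_percentile=config.pa_percentile,
            seed=stage_seed(config.master_seed, "parallel"),
        ),
    )
    sweep = timed(
        "clustering",
        lambda: clustering_mod.cluster_sweep(
            z,
            k_min=config.k_min,
            k_max=config.k_max,
            threshold=config.silhouette_threshold,
            seed=stage_seed(config.master_seed, "clustering"),
            n_restarts=config.kmeans_restarts,
            mds_restarts=config.mds_restarts,
            variant=config.silhouette_variant,
        ),
    )
    estimate = timed(
        "network",
        lambda: network_mod.estimate_network(
            z,
            node_names=z.columns,
            node_categories=[m.category for m in kept.measures],
            n_folds=config.cv_folds,
            seed=stage_seed(config.master_seed, "lambda_cv"),
            layout_seed=stage_seed(config.master_seed, "layout"),
        ),
    )
    bootstrap = timed(
        "bootstrap",
        lambda: network_mod.bootstrap_network(
            z,
            B=config.bootstrap_B,
            seed=stage_seed(config.master_seed, "bootstrap"),
            lambda_mode=config.lambda_mode,
            lam=estimate.regularization if config.lambda_mode == "fixed" else None,
            n_folds=config.cv_folds,
        ),
    )
    bundle = ResultBundle(
        config=config,
        table=table,
        excluded_ids=excluded,
        descriptives=desc,
        zmatrix=z,
        factor=factor,
        sweep=sweep,
        estimate=estimate,
        bootstrap=bootstrap,
        timings=timings,
    )
    if config.outdir is not None:
        write_bundle(bundle, Path(config.outdir))
    return bundle


def write_bundle(bundle: ResultBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    stamp = {"config_hash": cfg.config_hash(), "master_seed": cfg.master_seed}

    (outdir / "run.json").write_text(
        json.dumps(
            {
                **stamp,
                "config": dataclasses.asdict(cfg),
                "excluded_ids": bundle.excluded_ids,
                "retained_parallel": bundle.factor.retained_parallel,
                "retained_kaiser": bundle.factor.retained_kaiser,
                "clusters_present": bool(bundle.sweep.clusters_present),
                "best_k": bundle.sweep.best_k,
                "max_mean_silhouette": max(bundle.sweep.mean_silhouettes.values()),
                "selected_lambda": bundle.estimate.regularization,
                "chance_fraction_uncorrected":
                    bundle.bootstrap.chance_fraction_uncorrected,
                "chance_fraction_bonferroni":
                    bundle.bootstrap.chance_fraction_bonferroni,
                "timings_s": bundle.timings,
            },
            indent=2,
        )
    )
    bundle.descriptives.to_frame().to_csv(outdir / "descriptives.csv")
    dimensions_mod.factor_table(bundle.factor).to_csv(outdir / "factor_report.csv")
    pd.DataFrame(
        {
            "k": bundle.sweep.ks,
            "mean_silhouette": [
                bundle.sweep.mean_silhouettes[k] for k in bundle.sweep.ks
            ],
        }
    ).to_csv(outdir / "cluster_sweep.csv", index=False)
    pd.DataFrame(
        bundle.sweep.embedding.coordinates, columns=["x", "y"],
        index=bundle.zmatrix.child_ids,
    ).to_csv(outdir / "embedding.csv")
    export_network(bundle.estimate, bundle.bootstrap, outdir / "network.csv", "csv")
    export_network(
        bundle.estimate, bundle.bootstrap, outdir / "network.graphml", "graphml"
    )


def _edge_records(
    estimate: network_mod.NetworkEstimate, summary: network_mod.BootstrapSummary
) -> pd.DataFrame:
    p = len(estimate.node_names)
    iu = np.triu_indices(p, k=1)
    rows = []
    for i, j in zip(*iu):
        rows.append(
            {
                "node_i": estimate.node_names[i],
                "node_j": estimate.node_names[j],
                "weight": estimate.weights[i, j],
                "probability": summary.edge_probability[i, j],
                "ci_low": summary.ci_low[i, j],
                "ci_high": summary.ci_high[i, j],
                "significant_uncorrected": bool(
                    summary.significant_uncorrected[i, j]
                ),
                "significant_bonferroni": bool(summary.significant_bonferroni[i, j]),
                "significant_ci": bool(summary.significant_ci[i, j]),
            }
        )
    return pd.DataFrame(rows)


def export_network(
    estimate: network_mod.NetworkEstimate,
    summary: network_mod.BootstrapSummary,
    path,
    format: str = "csv",
) -> None:
    """Write the edge list (CSV) or annotated graph (GraphML)."""
    if format == "csv":
        df = _edge_records(estimate, summary)
        df.to_csv(path, index=False, float_format="%.10g")
        return
    if format != "graphml":
        raise ValueError(f"unknown export format {format!r}")
    g = nx.Graph()
    for idx, (name, cat) in enumerate(
        zip(estimate.node_names, estimate.node_categories)
    ):
        attrs = {"category": cat}
        if estimate.layout is not None:
            attrs["x"] = float(estimate.layout[idx, 0])
            attrs["y"] = float(estimate.layout[idx, 1])
        g.add_node(name, **attrs)
    df = _edge_records(estimate, summary)
    for rec in df.itertuples(index=False):
        if rec.weight != 0:
            g.add_edge(
                rec.node_i,
                rec.node_j,
                weight=float(rec.weight),
                probability=float(rec.probability),
                ci_low=float(rec.ci_low),
                ci_high=float(rec.ci_high),
                significant_uncorrected=rec.significant_uncorrected,
                significant_bonferroni=rec.significant_bonferroni,
                significant_ci=rec.significant_ci,
            )
    nx.write_graphml(g, path)
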