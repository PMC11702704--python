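"""End-to-end pipeline: simulate/load -> filter -> fit -> test -> networks -> report.

Every stage writes its documented CSV/JSON artifact so stages can also be run
independently from the CLI; a manifest records the seed, the configuration,
per-stage counts and a content hash of every output file. Two runs with the
same configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DEFAULT_LIFE_STAGE_TABLE,
    Cohort,
    LifeStageTable,
    apply_inclusion_criteria,
    cohort_summary,
    read_cohort,
    write_cohort,
)
from .directed import pairwise_directed
from .network import (
    build_network,
    degree_fit_comparison,
    topology_summary,
    write_edgelist_tsv,
    write_graphml,
)
from .pbc import pairwise_comorbidity
from .risk import DEFAULT_REFERENCE_SEX, export_coefficients, fit_all_models
from .stratified import compare_to_unstratified, stratify_and_analyze
from .synthetic import (
    GeneratorConfig,
    default_coefficients,
    generate_cohort,
    write_truth,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "fit", "undirected", "directed", "stratify", "topology")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "comorbnet_run"
    seed: int = 0
    # either generator settings ...
    simulate: bool = True
    n_dogs: int = 20000
    n_conditions: int = 20
    planted_pairs: list = field(default_factory=list)       # [[y, z, delta], ...]
    planted_directions: list = field(default_factory=list)  # [[y, z, max_lag], ...]
    # ... or input files
    dogs_csv: str | None = None
    conditions_csv: str | None = None
    # analysis settings
    min_cases: int = 60
    alpha_undirected: float = 0.001
    alpha_directed: float = 0.01
    alpha_stratified: float = 0.01
    window_months: float = 12.0
    reference_sex: str = DEFAULT_REFERENCE_SEX
    life_stage_table: LifeStageTable = field(default_factory=lambda: DEFAULT_LIFE_STAGE_TABLE)
    stages: tuple = ALL_STAGES

    def __post_init__(self):
        for name in ("alpha_undirected", "alpha_directed", "alpha_stratified"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {a}")
        if self.window_months <= 0:
            raise ValueError("window_months must be positive")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if not self.simulate and not (self.dogs_csv and self.conditions_csv):
            raise ValueError("either simulate=True or dogs_csv+conditions_csv required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "life_stage_table" in raw:
            t = raw["life_stage_table"]
            raw["life_stage_table"] = LifeStageTable(
                weight_breaks=tuple(t["weight_breaks"]),
                age_cutoffs=tuple(tuple(r) for r in t["age_cutoffs"]),
            )
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        # output_dir excluded so identical runs in different folders produce
        # byte-identical manifests
        "config": {
            k: v for k, v in config.__dict__.items()
            if k not in ("life_stage_table", "output_dir")
        },
        "stages": {},
        "files": {},
    }
    # timings are kept out of the manifest so identical runs hash identically
    timings = {}
    t_prev = time.time()

    def record(stage, **counts):
        nonlocal t_prev
        manifest["stages"][stage] = counts
        timings[stage] = round(time.time() - t_prev, 3)
        t_prev = time.time()

    # --- simulate or load -------------------------------------------------
    if config.simulate and "simulate" in config.stages:
        gen = GeneratorConfig(
            n_dogs=config.n_dogs,
            n_conditions=config.n_conditions,
            coefficients=default_coefficients(config.n_conditions, seed=config.seed),
            planted_pairs=tuple(tuple(p) for p in config.planted_pairs),
            planted_directions=tuple(tuple(p) for p in config.planted_directions),
            seed=config.seed,
        )
        cohort, truth = generate_cohort(gen)
        write_cohort(cohort, out / "dogs.csv", out / "conditions.csv")
        write_truth(truth, out / "truth.json")
        record("simulate", n_dogs=cohort.n_dogs, n_conditions=config.n_conditions)
    else:
        cohort = read_cohort(config.dogs_csv, config.conditions_csv)
        truth = None
        record("load", n_dogs=cohort.n_dogs,
               n_conditions=int(cohort.conditions["condition_id"].nunique()))

    # --- inclusion filter -------------------------------------------------
    included = apply_inclusion_criteria(cohort, min_cases=config.min_cases)
    summary = cohort_summary(included) if included.n_dogs else None
    record("filter", dogs_in=cohort.n_dogs, dogs_out=included.n_dogs,
           conditions_out=len(included.catalog))
    logger.info("inclusion filter: %d -> %d dogs, %d conditions retained",
                cohort.n_dogs, included.n_dogs, len(included.catalog))

    # --- risk models ------------------------------------------------------
    models = fit_all_models(included, reference_sex=config.reference_sex)
    coef = export_coefficients(models)
    _write_csv(coef, out / "coefficients.csv")
    n_conv = sum(m.converged for m in models.values())
    record("fit", models=len(models), converged=n_conv)

    results = {"cohort": included, "models": models, "truth": truth,
               "summary": summary}

    # --- undirected scan --------------------------------------------------
    if "undirected" in config.stages:
        edges = pairwise_comorbidity(included, models, alpha=config.alpha_undirected)
        _write_csv(edges, out / "edges_undirected.csv")
        net = build_network(edges, included.catalog, n_dogs=included.n_dogs)
        write_graphml(net, out / "network_undirected.graphml")
        write_edgelist_tsv(net, out / "network_undirected.tsv")
        results["edges_undirected"] = edges
        results["network_undirected"] = net
        record("undirected", pairs_tested=int(edges.attrs["n_tests"]),
               pairs_included=int(edges["included"].sum()))

    # --- directed scan ----------------------------------------------------
    if "directed" in config.stages:
        d_edges = pairwise_directed(included, models, w=config.window_months,
                                    alpha=config.alpha_directed)
        _write_csv(d_edges, out / "edges_directed.csv")
        d_net = build_network(d_edges, included.catalog, n_dogs=included.n_dogs,
                              directed=True)
        write_graphml(d_net, out / "network_directed.graphml")
        results["edges_directed"] = d_edges
        results["network_directed"] = d_net
        record("directed", tests=int(d_edges.attrs["n_tests"]),
               edges_included=int(d_edges["included"].sum()))

    # --- stratified analysis ----------------------------------------------
    if "stratify" in config.stages:
        strat = stratify_and_analyze(
            included, table=config.life_stage_table, min_cases=config.min_cases,
            alpha=config.alpha_stratified, reference_sex=config.reference_sex,
        )
        for stage, res in strat.strata.items():
            if res.edges is not None:
                _write_csv(res.edges, out / f"edges_{stage.replace(' ', '_')}.csv")
        strat.overlap.to_csv(out / "edge_overlap.csv")
        results["stratified"] = strat
        if "network_undirected" in results:
            comparison = compare_to_unstratified(strat, results["network_undirected"])
            with open(out / "stratified_comparison.json", "w") as fh:
                json.dump(comparison, fh, indent=1, default=str)
            results["stratified_comparison"] = comparison
        record("stratify", **{
            f"{s.replace(' ', '_')}_edges": int(r.network.number_of_edges())
            for s, r in strat.strata.items()
        })

    # --- topology ---------------------------------------------------------
    if "topology" in config.stages:
        metrics = {}
        if "network_undirected" in results:
            net = results["network_undirected"]
            if net.number_of_nodes() >= 2:
                metrics["unstratified"] = topology_summary(net).as_dict()
                degs = np.array([d for _, d in net.degree()])
                if (degs > 0).sum() >= 20 and len(np.unique(degs[degs > 0])) > 1:
                    cmp_ = degree_fit_comparison(net)
                    metrics["degree_fit"] = {
                        "preferred": cmp_.preferred,
                        "lr_statistic": cmp_.lr_statistic,
                        "p_value": cmp_.p_value,
                        "power_law_alpha": cmp_.power_law.alpha,
                        "xmin": cmp_.power_law.xmin,
                        "exponential_rate": cmp_.exponential.rate,
                    }
        if "stratified" in results:
            for s, r in results["stratified"].strata.items():
                if r.metrics is not None:
                    metrics[s] = r.metrics.as_dict()
        with open(out / "topology.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
        results["topology"] = metrics
        record("topology", networks=len(metrics))

    # --- recovery report vs planted truth ---------------------------------
    if truth is not None and "edges_undirected" in results:
        edges = results["edges_undirected"]
        planted = {tuple(sorted(p)) for p in truth.dependent_pairs}
        edge_pairs = {
            tuple(sorted((r.condition_y, r.condition_z)))
            for r in edges[edges["included"]].itertuples()
        }
        recovered = planted & edge_pairs
        manifest["recovery"] = {
            "planted_pairs": len(planted),
            "recovered_pairs": len(recovered),
            "false_included_pairs": len(edge_pairs - planted),
        }

    manifest["filter_log"] = included.filter_log
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=1)
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in ("manifest.json", "timings.json"):
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
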