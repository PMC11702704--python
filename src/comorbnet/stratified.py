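"""Life-stage-stratified comorbidity analysis.

The undirected pipeline is re-run inside each life-stage stratum: within each
stratum the minimum-case inclusion filter is re-applied, the logistic risk
models are refit (stratum-specific covariate effects), and the
Poisson-binomial pairwise scan is run with a per-stratum Bonferroni
multiplier. Strata with no retainable conditions yield empty networks rather
than errors. Age stays in the within-stratum models by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import (
    DEFAULT_LIFE_STAGE_TABLE,
    LIFE_STAGES,
    Cohort,
    LifeStageTable,
    apply_inclusion_criteria,
    assign_life_stages,
)
from .network import build_network, edge_overlap, topology_summary
from .pbc import pairwise_comorbidity
from .risk import DEFAULT_REFERENCE_SEX, fit_all_models


@dataclass
class StratumResult:
    stage: str
    n_dogs: int
    n_dogs_retained: int
    n_conditions: int
    edges: pd.DataFrame | None
    network: object
    metrics: object | None


@dataclass
class StratifiedResult:
    strata: dict = field(default_factory=dict)        # stage -> StratumResult
    stage_assignment: pd.Series | None = None
    overlap: pd.DataFrame | None = None
    pairs_unique_to: dict = field(default_factory=dict)
    pairs_in_all: set = field(default_factory=set)

    def edge_sets(self) -> dict:
        return {
            s: {frozenset(e) for e in r.network.edges()} if r.network is not None else set()
            for s, r in self.strata.items()
        }


def stratify_and_analyze(
    cohort: Cohort,
    table: LifeStageTable = DEFAULT_LIFE_STAGE_TABLE,
    min_cases: int = 60,
    alpha: float = 0.01,
    reference_sex: str = DEFAULT_REFERENCE_SEX,
) -> StratifiedResult:
    """Partition the (already included) cohort by life stage and run the
    undirected analysis within each stratum."""
    stages = assign_life_stages(cohort, table)
    out = StratifiedResult(stage_assignment=stages)
    for stage in LIFE_STAGES:
        ids = stages.index[stages == stage]
        sub = cohort.subset_dogs(ids)
        if sub.n_dogs == 0:
            out.strata[stage] = StratumResult(stage, 0, 0, 0, None, build_network(
                pd.DataFrame(columns=["condition_y", "condition_z", "included",
                                      "p_adjusted", "observed", "expected"]),
                cohort.catalog), None)
            continue
        filtered = apply_inclusion_criteria(sub, min_cases=min_cases)
        n_cond = len(filtered.catalog)
        if n_cond < 2:
            net = build_network(
                pd.DataFrame(columns=["condition_y", "condition_z", "included",
                                      "p_adjusted", "observed", "expected"]),
                cohort.catalog,
            )
            out.strata[stage] = StratumResult(stage, sub.n_dogs, filtered.n_dogs,
                                              n_cond, None, net, None)
            continue
        models = fit_all_models(filtered, reference_sex=reference_sex)
        edges = pairwise_comorbidity(filtered, models, alpha=alpha)
        net = build_network(edges, filtered.catalog, n_dogs=filtered.n_dogs)
        metrics = topology_summary(net) if net.number_of_nodes() >= 2 else None
        out.strata[stage] = StratumResult(stage, sub.n_dogs, filtered.n_dogs,
                                          n_cond, edges, net, metrics)

    nets = {s: r.network for s, r in out.strata.items() if r.network is not None}
    out.overlap = edge_overlap(nets)
    sets = out.edge_sets()
    for s in out.strata:
        others = set().union(*(sets[o] for o in out.strata if o != s)) if len(sets) > 1 else set()
        out.pairs_unique_to[s] = sets[s] - others
    nonempty = [v for v in sets.values() if v]
    out.pairs_in_all = set.intersection(*nonempty) if nonempty else set()
    return out


def compare_to_unstratified(stratified: StratifiedResult, unstratified) -> dict:
    """Set algebra between stratified edge sets and the unstratified network.

    Returns explicit pair lists: found only by some stratum, found only by the
    unstratified network, and found in every (non-empty) stratified network.
    Raises if the condition universes are disjoint (different cohorts).
    """
    un = {frozenset(e) for e in unstratified.edges()}
    sets = stratified.edge_sets()
    strat_nodes = set().union(
        *(set(r.network.nodes) for r in stratified.strata.values() if r.network is not None)
    )
    if un and strat_nodes and not (set(unstratified.nodes) & strat_nodes):
        raise ValueError(
            "condition universes of stratified and unstratified networks do not overlap"
        )
    any_stratum = set().union(*sets.values()) if sets else set()
    return {
        "stratified_only": sorted(tuple(sorted(p, key=str)) for p in any_stratum - un),
        "unstratified_only": sorted(tuple(sorted(p, key=str)) for p in un - any_stratum),
        "in_all_strata": sorted(tuple(sorted(p, key=str)) for p in stratified.pairs_in_all),
        "per_stratum_unique": {
            s: sorted(tuple(sorted(p, key=str)) for p in pairs)
            for s, pairs in stratified.pairs_unique_to.items()
        },
    }
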