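"""Comorbidity-network construction and topology characterization.

Networks are ``networkx`` graphs whose nodes are health conditions (with
name, body-system category and prevalence attributes) and whose edges are the
pairs passing the significance screen. Topology measures follow the usual
conventions: edge density, global transitivity, and Freeman graph-level
centralization of degree and betweenness (normalized by the star-graph
maximum, so a star scores 1 and any regular graph 0).

The degree-distribution model comparison pits a discrete power law (Hurwitz
zeta normalization, Clauset-style xmin selection by KS distance) against a
discrete exponential (geometric) law fitted on the same x >= xmin support,
compared with a Vuong-style normalized log-likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_network(
    edges: pd.DataFrame,
    catalog: pd.DataFrame,
    n_dogs: int | None = None,
    directed: bool | None = None,
    include_all_nodes: bool = False,
):
    """Build a graph from an edge-result table, keeping only included rows.

    ``edges`` is the output of the undirected or directed pairwise scan
    (directedness is inferred from its columns unless given). Nodes default to
    conditions incident to at least one included edge; with
    ``include_all_nodes`` every catalog condition becomes a node. Node
    attributes: name, category, n_cases and (if ``n_dogs``) prevalence.
    """
    if directed is None:
        directed = "source" in edges.columns
    G = nx.DiGraph() if directed else nx.Graph()
    cat = catalog.set_index("condition_id")

    def add_node(c):
        info = cat.loc[c]
        attrs = {
            "name": info["condition_name"],
            "category": info["category"],
            "n_cases": int(info.get("n_cases", 0)),
        }
        if n_dogs:
            attrs["prevalence"] = attrs["n_cases"] / n_dogs
        G.add_node(c, **attrs)

    if include_all_nodes:
        for c in cat.index:
            add_node(c)
    inc = edges[edges["included"]] if "included" in edges.columns else edges
    a_col, b_col = ("source", "target") if directed else ("condition_y", "condition_z")
    for row in inc.itertuples():
        a, b = getattr(row, a_col), getattr(row, b_col)
        if a == b:
            continue
        for c in (a, b):
            if c not in G:
                add_node(c)
        G.add_edge(a, b, p_adjusted=float(getattr(row, "p_adjusted")),
                   observed=int(getattr(row, "observed")),
                   expected=float(getattr(row, "expected")))
    return G


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyMetrics:
    edge_density: float
    clustering_coefficient: float        # global transitivity
    degree_centralization: float
    betweenness_centralization: float
    clustering_average_local: float      # reported alongside; see methods note

    def as_dict(self) -> dict:
        return {
            "edge_density": self.edge_density,
            "clustering_coefficient": self.clustering_coefficient,
            "degree_centralization": self.degree_centralization,
            "betweenness_centralization": self.betweenness_centralization,
            "clustering_average_local": self.clustering_average_local,
        }


def degree_centralization(G: nx.Graph) -> float:
    """Freeman degree centralization: sum(dmax - d_i) / ((n-1)(n-2))."""
    n = G.number_of_nodes()
    if n < 3:
        return 0.0
    deg = np.array([d for _, d in G.degree()], dtype=float)
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def betweenness_centralization(G: nx.Graph) -> float:
    """Freeman betweenness centralization on normalized node betweenness:
    sum(bmax - b_i) / (n-1), which is 1 for a star and 0 for regular graphs."""
    n = G.number_of_nodes()
    if n < 3:
        return 0.0
    b = np.array(list(nx.betweenness_centrality(G, normalized=True).values()))
    return float((b.max() - b).sum() / (n - 1))


def topology_summary(G: nx.Graph) -> TopologyMetrics:
    """Edge density, transitivity, and degree/betweenness centralization."""
    if G.is_directed():
        G = G.to_undirected(as_view=False)
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("topology summary needs at least 2 nodes")
    return TopologyMetrics(
        edge_density=float(nx.density(G)),
        clustering_coefficient=float(nx.transitivity(G)),
        degree_centralization=degree_centralization(G),
        betweenness_centralization=betweenness_centralization(G),
        clustering_average_local=float(nx.average_clustering(G)),
    )


# ---------------------------------------------------------------------------
# Degree-distribution model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    xmin: int
    loglik: float
    n_tail: int
    ks: float


@dataclass(frozen=True)
class ExponentialFit:
    rate: float            # lambda of P(x) ~ exp(-lambda x), x >= xmin
    xmin: int
    loglik: float
    n_tail: int


@dataclass(frozen=True)
class DegreeFitComparison:
    power_law: PowerLawFit
    exponential: ExponentialFit
    lr_statistic: float     # Vuong normalized; > 0 favors the power law
    p_value: float          # two-sided
    preferred: str | None   # assigned only when p_value < significance
    n_tail: int


def _powerlaw_loglik(alpha: float, x: np.ndarray, xmin: int) -> float:
    return float(-len(x) * np.log(special.zeta(alpha, xmin)) - alpha * np.log(x).sum())


def fit_discrete_powerlaw(data, xmin: int | None = None, max_xmin_candidates: int = 50) -> PowerLawFit:
    """Discrete power-law MLE P(x) = x^-alpha / zeta(alpha, xmin) for x >= xmin.

    When ``xmin`` is not given it is chosen by scanning candidate values and
    minimizing the KS distance between the empirical and fitted tails.
    """
    x_all = np.asarray(data, dtype=int)
    if (x_all < 1).any():
        raise ValueError("power-law fit requires values >= 1")

    def fit_at(xm: int):
        x = x_all[x_all >= xm]
        if len(x) < 2 or np.all(x == x[0]):
            return None
        res = optimize.minimize_scalar(
            lambda a: -_powerlaw_loglik(a, x, xm), bounds=(1.0001, 8.0), method="bounded"
        )
        alpha = float(res.x)
        # KS distance on the common support
        xs = np.arange(xm, x.max() + 1)
        pmf = xs.astype(float) ** -alpha / special.zeta(alpha, xm)
        cdf = np.cumsum(pmf)
        ecdf = np.searchsorted(np.sort(x), xs, side="right") / len(x)
        ks = float(np.max(np.abs(cdf - ecdf)))
        return PowerLawFit(alpha=alpha, xmin=int(xm), loglik=_powerlaw_loglik(alpha, x, xm),
                           n_tail=len(x), ks=ks)

    if xmin is not None:
        fit = fit_at(int(xmin))
        if fit is None:
            raise ValueError("degenerate tail at requested xmin")
        return fit
    candidates = np.unique(x_all)
    candidates = candidates[candidates < x_all.max()]
    if len(candidates) > max_xmin_candidates:
        idx = np.linspace(0, len(candidates) - 1, max_xmin_candidates).astype(int)
        candidates = candidates[idx]
    fits = [f for f in (fit_at(int(c)) for c in candidates) if f is not None]
    if not fits:
        raise ValueError("no valid xmin candidate (constant degree sequence?)")
    return min(fits, key=lambda f: f.ks)


def fit_discrete_exponential(data, xmin: int = 1) -> ExponentialFit:
    """Discrete exponential (geometric) MLE on x >= xmin:
    P(x) = (1 - e^-lam) e^{-lam (x - xmin)}; closed form via the tail mean."""
    x = np.asarray(data, dtype=int)
    x = x[x >= xmin]
    if len(x) < 2:
        raise ValueError("need >= 2 tail observations")
    m = float((x - xmin).mean())
    if m == 0:
        raise ValueError("constant tail: exponential fit undefined")
    q = m / (1.0 + m)                     # e^-lambda
    lam = -np.log(q)
    loglik = float(len(x) * np.log(1 - q) + np.log(q) * (x - xmin).sum())
    return ExponentialFit(rate=float(lam), xmin=int(xmin), loglik=loglik, n_tail=len(x))


def degree_fit_comparison(
    net_or_degrees,
    min_nodes: int = 20,
    significance: float = 0.1,
    xmin: int | None = None,
) -> DegreeFitComparison:
    """Compare power-law vs exponential fits of the degree sequence.

    Zero-degree nodes are excluded (unsupported by the power law). The two
    families are fitted on the common x >= xmin support (xmin from the
    power-law scan unless given) and compared with the Vuong normalized
    log-likelihood ratio; ``preferred`` is set only when the two-sided p-value
    is below ``significance``.
    """
    if isinstance(net_or_degrees, (nx.Graph, nx.DiGraph)):
        degrees = np.array([d for _, d in net_or_degrees.degree()])
    else:
        degrees = np.asarray(net_or_degrees, dtype=int)
    degrees = degrees[degrees > 0]
    if len(degrees) < min_nodes:
        raise ValueError(f"need >= {min_nodes} nonzero-degree nodes, got {len(degrees)}")
    if np.all(degrees == degrees[0]):
        raise ValueError("constant degree sequence: comparison undefined")

    pl = fit_discrete_powerlaw(degrees, xmin=xmin)
    ex = fit_discrete_exponential(degrees, xmin=pl.xmin)
    x = degrees[degrees >= pl.xmin].astype(float)
    ll_pl = -pl.alpha * np.log(x) - np.log(special.zeta(pl.alpha, pl.xmin))
    q = np.exp(-ex.rate)
    ll_ex = np.log(1 - q) - ex.rate * (x - ex.xmin)
    diff = ll_pl - ll_ex
    n = len(diff)
    sd = float(diff.std(ddof=0))
    if sd == 0:
        lr, p = 0.0, 1.0
    else:
        lr = float(diff.sum() / (sd * np.sqrt(n)))
        p = float(2 * stats.norm.sf(abs(lr)))
    preferred = None
    if p < significance and lr != 0:
        preferred = "power_law" if lr > 0 else "exponential"
    return DegreeFitComparison(power_law=pl, exponential=ex, lr_statistic=lr,
                               p_value=p, preferred=preferred, n_tail=n)


# ---------------------------------------------------------------------------
# Cross-network comparison and aggregation
# ---------------------------------------------------------------------------

def _edge_set(G) -> set:
    return {frozenset((a, b)) for a, b in G.edges() if a != b}


def edge_overlap(networks: dict) -> pd.DataFrame:
    """Symmetric matrix of shared edges (as unordered condition pairs);
    diagonal = per-network edge counts."""
    if not networks:
        raise ValueError("need at least one network")
    names = list(networks)
    sets = {n: _edge_set(networks[n]) for n in names}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i:]:
            shared = len(sets[a] & sets[b])
            mat.loc[a, b] = shared
            mat.loc[b, a] = shared
    return mat


def aggregate_category_nodes(G, categories) -> nx.Graph:
    """Collapse every node of each listed category into one super-node.

    Parallel edges collapse to a single edge; within-category edges become
    self-loops, which are removed but counted in
    ``H.graph["within_category_edges"]``.
    """
    known = {d.get("category") for _, d in G.nodes(data=True)}
    unknown = set(categories) - known
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    collapse = set(categories)
    mapping = {
        n: f"category::{d['category']}" if d.get("category") in collapse else n
        for n, d in G.nodes(data=True)
    }
    H = nx.Graph()
    for n, d in G.nodes(data=True):
        m = mapping[n]
        if m not in H:
            if m.__class__ is str and str(m).startswith("category::"):
                H.add_node(m, name=str(m).split("::", 1)[1],
                           category=str(m).split("::", 1)[1], aggregate=True)
            else:
                H.add_node(m, **d)
    within = 0
    for a, b in G.edges():
        ma, mb = mapping[a], mapping[b]
        if ma == mb:
            within += 1
            continue
        H.add_edge(ma, mb)
    H.graph["within_category_edges"] = within
    return H


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_graphml(G, path) -> None:
    """GraphML export with deterministic node/edge ordering."""
    H = nx.DiGraph() if G.is_directed() else nx.Graph()
    for n in sorted(G.nodes, key=str):
        H.add_node(n, **{k: v for k, v in G.nodes[n].items() if v is not None})
    for a, b in sorted(G.edges, key=lambda e: (str(e[0]), str(e[1]))):
        H.add_edge(a, b, **G.edges[a, b])
    nx.write_graphml(H, path)


def write_edgelist_tsv(G, path) -> None:
    rows = [
        {"source": a, "target": b, **G.edges[a, b]}
        for a, b in sorted(G.edges, key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["source", "target", "p_adjusted", "observed", "expected"]).to_csv(
        path, sep="\t", index=False
    )
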