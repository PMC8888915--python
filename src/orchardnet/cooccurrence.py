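"""Co-occurrence networks from rarefied counts, topology metrics, keystones.

One undirected simple graph is built per stratum: nodes are taxa, edges are
strong, significant, *positive* Spearman rank correlations of abundance
across that stratum's samples (default rho > 0.6 and p < 0.05, strict
inequalities). Topology metrics use the unweighted graph. Closeness is the
unnormalized 1 / (sum of shortest-path distances within the node's
component) and betweenness is the unnormalized Brandes count with each
unordered pair counted once: the published keystone cutoffs (closeness
0.005 / 0.03, betweenness 40 / 50) only make sense on these scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CorrelationMatrix,
    CountMatrix,
    KeystoneCriteria,
    SampleMetadata,
    TopologySummary,
    warn,
)

def spearman_matrix(matrix: CountMatrix, min_prevalence: int = 0) -> CorrelationMatrix:
    """All-pairs Spearman correlations among taxa across samples.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    the two-sided p comes from the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom
    (standard at the study's per-stratum n of ~90), with p = 0 at rho = +/-1.

    Zero-variance taxa cannot be rank-correlated and are excluded with a
    warning. ``min_prevalence`` optionally drops taxa present (count > 0)
    in fewer than that many samples; the default 0 applies no filter.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation, got {n}")
    keep = np.ones(matrix.n_taxa, dtype=bool)
    if min_prevalence > 0:
        prev = (matrix.counts > 0).sum(axis=1)
        keep &= prev >= min_prevalence
        warn(
            f"prevalence filter >= {min_prevalence} active: "
            f"{int(keep.sum())}/{matrix.n_taxa} taxa retained"
        )
    variable = matrix.counts.std(axis=1) > 0
    if (~variable & keep).any():
        dropped = [t for t, k, v in zip(matrix.taxon_ids, keep, variable) if k and not v]
        warn(
            f"excluding {len(dropped)} zero-variance taxa from correlation "
            f"(first few: {dropped[:5]})"
        )
    keep &= variable
    ids = [t for t, k in zip(matrix.taxon_ids, keep) if k]
    X = matrix.counts[keep, :]
    if len(ids) < 2:
        raise ValueError("fewer than 2 variable taxa; correlation matrix undefined")
    rho, p = stats.spearmanr(X.T)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if rho.shape == (1, 1):  # spearmanr collapses the 2-taxon case to scalars
        r = float(stats.spearmanr(X[0], X[1]).statistic)
        pv = float(stats.spearmanr(X[0], X[1]).pvalue)
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(ids, rho, p, n)


@dataclass
class CooccurrenceNetwork:
    """Undirected simple graph on taxa; edges carry (rho, p)."""

    stratum: str
    graph: nx.Graph
    rho_min: float
    alpha: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    corr: CorrelationMatrix,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    positive_only: bool = True,
    stratum: str = "",
) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    Edge (i, j) is included iff rho_ij > rho_min AND p_ij < alpha AND
    (when ``positive_only``) rho_ij > 0 — all strict, as published. Taxa
    with no qualifying edge remain as isolated nodes.
    """
    if not -1 <= rho_min <= 1:
        raise ValueError(f"rho_min must be in [-1, 1], got {rho_min}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    g = nx.Graph()
    g.add_nodes_from(corr.taxon_ids)
    k = len(corr.taxon_ids)
    iu, ju = np.triu_indices(k, k=1)
    rho, p = corr.rho[iu, ju], corr.p[iu, ju]
    ok = (rho > rho_min) & (p < alpha)
    if positive_only:
        ok &= rho > 0
    for a, b, r, pv in zip(iu[ok], ju[ok], rho[ok], p[ok]):
        g.add_edge(corr.taxon_ids[a], corr.taxon_ids[b], rho=float(r), p=float(pv))
    return CooccurrenceNetwork(stratum=stratum, graph=g, rho_min=rho_min, alpha=alpha)


# ---------------------------------------------------------------------------
# topology

def node_metrics(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Per-node degree, unnormalized closeness and unnormalized betweenness.

    closeness(u) = 1 / sum of shortest-path distances from u to the other
    nodes of u's component (0 for isolated nodes); betweenness(u) counts
    each unordered source-target pair once.
    """
    g = net.graph
    closeness = {}
    for u in g.nodes:
        dist = nx.single_source_shortest_path_length(g, u)
        total = sum(dist.values())  # u itself contributes 0
        closeness[u] = 1.0 / total if total > 0 else 0.0
    betweenness = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame(
        {
            "taxon_id": list(g.nodes),
            "degree": [g.degree(u) for u in g.nodes],
            "closeness": [closeness[u] for u in g.nodes],
            "betweenness": [betweenness[u] for u in g.nodes],
        }
    ).sort_values("taxon_id", ignore_index=True)


def modularity_partition(
    net: CooccurrenceNetwork, seed: int = 0, resolution: float = 1.0, n_restarts: int = 5
) -> tuple[list[set], float | None]:
    """Community partition (Leiden, best of deterministic restarts) and its Q.

    Uses the Leiden algorithm (the modern refinement of Louvain-style
    modularity optimization) run to convergence; restart seeds are derived
    deterministically from ``seed`` and the highest-Q partition is kept,
    which stabilizes small graphs against poor local optima. Q is Newman
    modularity of the returned partition. Returns (partition, None) on
    edgeless graphs, where Q is undefined.
    """
    import igraph as ig
    import leidenalg

    g = net.graph
    if g.number_of_edges() == 0:
        return [{u} for u in g.nodes], None
    names = list(g.nodes)
    ig_graph = ig.Graph()
    ig_graph.add_vertices(names)
    ig_graph.add_edges(list(g.edges))
    if resolution == 1.0:
        def detect(s):
            return leidenalg.find_partition(
                ig_graph, leidenalg.ModularityVertexPartition, seed=s, n_iterations=-1
            )
    else:
        def detect(s):
            return leidenalg.find_partition(
                ig_graph, leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=resolution, seed=s, n_iterations=-1,
            )
    best_part, best_q = None, -np.inf
    for s in np.random.SeedSequence(seed).generate_state(n_restarts):
        raw = detect(int(s % (2**31)))
        part = [{ig_graph.vs[i]["name"] for i in block} for block in raw]
        q = nx.community.modularity(g, part, resolution=resolution)
        if q > best_q:
            best_part, best_q = part, q
    return best_part, float(best_q)


def topology_summary(
    net: CooccurrenceNetwork, modularity_seed: int = 0
) -> TopologySummary:
    """Whole-network topology metrics (unweighted shortest paths).

    Diameter and average path length are taken over connected node pairs
    only and reported as None (undefined) on edgeless graphs.
    """
    g = net.graph
    n_nodes = g.number_of_nodes()
    if n_nodes < 1:
        raise ValueError("network must have at least one node")
    n_edges = g.number_of_edges()
    nm = node_metrics(net)
    diameter: int | None = None
    apl: float | None = None
    if n_edges >= 1:
        dist_sum = 0
        pair_count = 0
        dmax = 0
        for comp in nx.connected_components(g):
            if len(comp) < 2:
                continue
            sub = g.subgraph(comp)
            for u, dist in nx.all_pairs_shortest_path_length(sub):
                for v, d in dist.items():
                    if u < v:  # each unordered pair once
                        dist_sum += d
                        pair_count += 1
                        dmax = max(dmax, d)
        diameter = int(dmax)
        apl = dist_sum / pair_count
    _, q = modularity_partition(net, seed=modularity_seed)
    return TopologySummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean_degree=2 * n_edges / n_nodes,
        diameter=diameter,
        avg_path_length=apl,
        mean_closeness=float(nm["closeness"].mean()),
        mean_betweenness=float(nm["betweenness"].mean()),
        modularity=q,
        n_components=nx.number_connected_components(g),
    )


def identify_keystones(
    metrics: pd.DataFrame, criteria: KeystoneCriteria
) -> list[str]:
    """Taxa passing the joint keystone thresholds, in lexicographic order.

    A taxon is keystone iff degree > degree_min AND closeness >
    closeness_min AND betweenness < betweenness_max, all strict.
    """
    sel = (
        (metrics["degree"] > criteria.degree_min)
        & (metrics["closeness"] > criteria.closeness_min)
        & (metrics["betweenness"] < criteria.betweenness_max)
    )
    return sorted(metrics.loc[sel, "taxon_id"])


def annotate_graph(net: CooccurrenceNetwork, criteria: KeystoneCriteria | None = None) -> None:
    """Attach node-level metrics (and keystone flags) as graph attributes."""
    nm = node_metrics(net).set_index("taxon_id")
    keystones = set(identify_keystones(nm.reset_index(), criteria)) if criteria else set()
    for u in net.graph.nodes:
        net.graph.nodes[u]["taxon_id"] = str(u)
        net.graph.nodes[u]["degree"] = int(nm.loc[u, "degree"])
        net.graph.nodes[u]["closeness"] = float(nm.loc[u, "closeness"])
        net.graph.nodes[u]["betweenness"] = float(nm.loc[u, "betweenness"])
        net.graph.nodes[u]["keystone"] = bool(u in keystones)


# ---------------------------------------------------------------------------
# per-stratum orchestration

def per_stratum_networks(
    matrix: CountMatrix,
    metadata: SampleMetadata,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    positive_only: bool = True,
    min_prevalence: int = 0,
) -> dict[str, CooccurrenceNetwork]:
    """One network per stratum, from that stratum's samples only.

    Every sample in the matrix must map to exactly one stratum via the
    metadata; a stratum with fewer than 4 samples is an error (rank
    correlation is meaningless at that n). Identical thresholds apply to
    all strata.
    """
    strata = metadata.strata()
    unmapped = [s for s in matrix.sample_ids if s not in strata.index]
    if unmapped:
        raise KeyError(f"samples without metadata/stratum: {unmapped[:10]}")
    nets: dict[str, CooccurrenceNetwork] = {}
    order = list(dict.fromkeys(strata.loc[matrix.sample_ids]))
    for stratum in order:
        ids = [s for s in matrix.sample_ids if strata[s] == stratum]
        if len(ids) < 4:
            raise ValueError(
                f"stratum {stratum!r} has {len(ids)} samples; need >= 4"
            )
        sub = matrix.select_samples(ids)
        corr = spearman_matrix(sub, min_prevalence=min_prevalence)
        nets[stratum] = build_network(
            corr, rho_min=rho_min, alpha=alpha, positive_only=positive_only, stratum=stratum
        )
    return nets
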