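"""Signed co-occurrence networks and their stability metrics.

An edge joins two taxa whose abundance correlation passes |r| > 0.6 with
a Benjamini-Hochberg adjusted p (q) < 0.05, the thresholds used
throughout for "significant interaction".  Correlations default to
Spearman on relative abundances (rank-based, hence invariant to the
raw-count vs proportion choice).  Taxa below the prevalence filter and
constant (zero-variance) taxa are excluded before testing; isolated taxa
are dropped from the node set, so vertices are taxa with at least one
edge.

Stability metrics:

* complexity composite -- per network, the mean over a set of topological
  indices of (index / maximum of that index across compared networks),
  so the densest network scores ~1;
* robustness -- remaining connectivity after removing a fraction p of
  vertices uniformly at random: the share of *original* vertices that
  survive and still have at least one edge (hence bounded by 1 - p);
* vulnerability -- the largest relative drop in global efficiency caused
  by deleting a single node, E = mean over ordered pairs of 1/d_ij with
  unweighted shortest paths and 1/inf = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .tables_io import FeatureTable, UNCLASSIFIED

DEFAULT_INDEX_SET = (
    "n_vertices",
    "n_edges",
    "n_positive_edges",
    "n_negative_edges",
    "average_degree",
    "clustering_coefficient",
)


@dataclass
class CooccurrenceNetwork:
    """Undirected signed graph plus the parameters that built it."""

    graph: nx.Graph
    method: str
    r_threshold: float
    q_threshold: float
    min_prevalence: float
    n_samples: int
    n_taxa_tested: int

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "r": d["r"], "q": d["q"],
             "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "q",
                                           "sign"])


def _pearson_pvalues(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[1]
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    return r, p


def build_network(
    table: FeatureTable,
    sample_ids: Sequence[str] | None = None,
    method: str = "spearman",
    r_threshold: float = 0.6,
    q_threshold: float = 0.05,
    min_prevalence: float = 1.0 / 3.0,
    taxonomy: pd.DataFrame | None = None,
) -> CooccurrenceNetwork:
    """All-pairs correlation network over the retained taxa.

    ``sample_ids`` restricts to a group's samples (>= 4 required);
    ``min_prevalence`` keeps taxa present (count > 0) in at least that
    fraction of the samples.  BH adjustment is applied across all tested
    pairs; an edge needs |r| > r_threshold and q < q_threshold.
    """
    if sample_ids is not None:
        table = table.subset_samples(sample_ids)
    n = len(table.sample_ids)
    if n < 4:
        raise ValidationError(f"need at least 4 samples, got {n}")
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")

    rel = table.relative_abundance()
    prevalence = (table.counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    variances = rel.var(axis=1)
    constant = keep & (variances <= 0)
    if constant.any():
        names = [t for t, c in zip(table.taxon_ids, constant) if c]
        warnings.warn(
            f"excluding {len(names)} constant taxa (zero variance): "
            f"{names[:5]}{'...' if len(names) > 5 else ''}",
            stacklevel=2,
        )
        keep &= ~constant
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    if len(taxa) < 2:
        raise ValidationError("fewer than 2 taxa pass the prevalence filter")
    x = rel[keep]

    if method == "spearman":
        res = stats.spearmanr(x, axis=1)
        r = np.atleast_2d(res.statistic)
        p = np.atleast_2d(res.pvalue)
        if r.shape == (1, 1):  # spearmanr collapses the 2-taxon case
            r = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
            p = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        r, p = _pearson_pvalues(x)

    iu, ju = np.triu_indices(len(taxa), k=1)
    pvals = p[iu, ju]
    qvals = stats.false_discovery_control(pvals, method="bh")
    rvals = r[iu, ju]
    mask = (np.abs(rvals) > r_threshold) & (qvals < q_threshold)

    graph = nx.Graph()
    for i, j, rv, qv in zip(iu[mask], ju[mask], rvals[mask], qvals[mask]):
        graph.add_edge(
            taxa[i], taxa[j],
            r=float(rv), q=float(qv),
            sign="positive" if rv > 0 else "negative",
        )
    for node in graph.nodes:
        phylum = UNCLASSIFIED
        if taxonomy is not None and node in taxonomy.index:
            phylum = str(taxonomy.loc[node, "phylum"])
        graph.nodes[node]["phylum"] = phylum
    return CooccurrenceNetwork(
        graph=graph,
        method=method,
        r_threshold=r_threshold,
        q_threshold=q_threshold,
        min_prevalence=min_prevalence,
        n_samples=n,
        n_taxa_tested=len(taxa),
    )


@dataclass
class TopologySummary:
    n_vertices: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    average_degree: float
    clustering_coefficient: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_vertices": self.n_vertices,
            "n_edges": self.n_edges,
            "n_positive_edges": self.n_positive_edges,
            "n_negative_edges": self.n_negative_edges,
            "average_degree": self.average_degree,
            "clustering_coefficient": self.clustering_coefficient,
        }


def topology(network: CooccurrenceNetwork | nx.Graph) -> TopologySummary:
    """Vertex/edge counts, average degree 2E/V and mean local clustering
    (nodes of degree < 2 contribute 0); all zero for an empty network."""
    graph = network if isinstance(network, nx.Graph) else network.graph
    v = graph.number_of_nodes()
    e = graph.number_of_edges()
    if v == 0:
        return TopologySummary(0, 0, 0, 0, 0.0, 0.0)
    pos = sum(1 for _, _, d in graph.edges(data=True)
              if d.get("sign", "positive") == "positive")
    return TopologySummary(
        n_vertices=v,
        n_edges=e,
        n_positive_edges=pos,
        n_negative_edges=e - pos,
        average_degree=2.0 * e / v,
        clustering_coefficient=float(nx.average_clustering(graph)),
    )


def complexity_index(
    summaries: Mapping[str, TopologySummary],
    index_set: Sequence[str] = DEFAULT_INDEX_SET,
) -> dict[str, float]:
    """Composite complexity: mean over indices of value / max-across-networks.

    Indices that are zero in every compared network are excluded with a
    warning (the ratio would be 0/0).
    """
    if len(summaries) < 2:
        raise ValidationError("need at least 2 networks to compare")
    values = {
        name: {idx: float(getattr(s, idx)) for idx in index_set}
        for name, s in summaries.items()
    }
    for name, vals in values.items():
        bad = [idx for idx, v in vals.items() if v < 0]
        if bad:
            raise ValidationError(f"negative index {bad} in network {name!r}")
    usable = []
    for idx in index_set:
        if max(values[name][idx] for name in values) > 0:
            usable.append(idx)
        else:
            warnings.warn(
                f"index {idx!r} is zero in every network; excluded",
                stacklevel=2,
            )
    if not usable:
        raise ValidationError("no usable indices (all zero everywhere)")
    return {
        name: float(
            np.mean(
                [
                    values[name][idx]
                    / max(values[other][idx] for other in values)
                    for idx in usable
                ]
            )
        )
        for name in summaries
    }


def robustness(
    network: CooccurrenceNetwork | nx.Graph,
    removal_fractions: Sequence[float] = (
        0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
    ),
    repetitions: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Remaining connectivity under random vertex removal.

    For each fraction p, ``repetitions`` times: remove floor(p*V) nodes
    uniformly at random with their incident edges; remaining
    connectivity is (surviving nodes with >= 1 surviving edge) / V.
    Returns a frame with columns p, mean, sd.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    nodes = list(graph.nodes)
    v = len(nodes)
    if v < 2:
        raise ValidationError("network must have at least 2 nodes")
    for p in removal_fractions:
        if not (0.0 <= p < 1.0):
            raise ValidationError(f"removal fraction {p} outside [0, 1)")
    index = {node: i for i, node in enumerate(nodes)}
    neighbors = [
        np.array([index[m] for m in graph.neighbors(node)], dtype=np.int64)
        for node in nodes
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for p in removal_fractions:
        n_remove = int(np.floor(p * v))
        vals = np.empty(repetitions)
        for rep in range(repetitions):
            removed = np.zeros(v, dtype=bool)
            removed[rng.choice(v, size=n_remove, replace=False)] = True
            connected = sum(
                1
                for i in range(v)
                if not removed[i]
                and neighbors[i].size
                and not removed[neighbors[i]].all()
            )
            vals[rep] = connected / v
        rows.append((p, float(vals.mean()), float(vals.std(ddof=1))))
    return pd.DataFrame(rows, columns=["p", "mean", "sd"])


def _efficiency_from_adjacency(adj) -> float:
    from scipy.sparse.csgraph import shortest_path

    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(graph: nx.Graph) -> float:
    """Mean over ordered node pairs of 1 / shortest-path length
    (unweighted; unreachable pairs contribute 0)."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    adj = nx.to_scipy_sparse_array(graph, weight=None, format="csr")
    return _efficiency_from_adjacency(adj)


def vulnerability(network: CooccurrenceNetwork | nx.Graph) -> float:
    """Max over nodes of (E - E_i) / E after single-node deletion."""
    graph = network if isinstance(network, nx.Graph) else network.graph
    n = graph.number_of_nodes()
    if n < 3:
        raise ValidationError("vulnerability needs at least 3 nodes")
    adj = nx.to_scipy_sparse_array(graph, weight=None, format="csr")
    e_full = _efficiency_from_adjacency(adj)
    if e_full == 0:
        raise ValidationError("edgeless network has zero efficiency")
    dense = adj.toarray()
    worst = -np.inf
    for i in range(n):
        keep = np.arange(n) != i
        e_i = _efficiency_from_adjacency(dense[np.ix_(keep, keep)])
        worst = max(worst, (e_full - e_i) / e_full)
    return float(worst)
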