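"""Interaction-network statistics for protein sets.

Reimplements the summary statistics typically read off a PPI-database
report for a query protein set, against a user-supplied background graph:

* observed induced-subgraph edge count for the query set;
* edge enrichment: the observed count compared with uniformly random node
  subsets of the same size drawn from the background (expected count = null
  mean; add-one permutation p-value, never exactly 0);
* mean local clustering coefficient of the induced subgraph (nodes of
  degree < 2 contribute 0);
* hypergeometric term enrichment against user-supplied annotations (GMT),
  with Benjamini–Hochberg adjustment across terms.

Graphs are undirected :class:`networkx.Graph` objects, optionally carrying
a per-edge ``score`` in [0, 1] (confidence), filterable at a threshold
(0.7 is the customary "high confidence" setting).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_edges_by_score",
    "observed_edges",
    "EdgeEnrichmentResult",
    "edge_enrichment",
    "clustering_coefficient",
    "TermEnrichmentRecord",
    "term_enrichment",
]


def filter_edges_by_score(graph: nx.Graph, min_score: float = 0.7) -> nx.Graph:
    """Keep edges with confidence ``score >= min_score``; all nodes retained."""
    missing = [(u, v) for u, v, d in graph.edges(data=True) if "score" not in d]
    if missing:
        raise ValueError(f"edges without a confidence score: {missing[:5]}")
    filtered = nx.Graph()
    filtered.add_nodes_from(graph.nodes)
    for u, v, d in graph.edges(data=True):
        if d["score"] >= min_score:
            filtered.add_edge(u, v, **d)
    return filtered


def _resolve_node_set(graph: nx.Graph, node_set: Iterable[str]) -> list:
    nodes = list(dict.fromkeys(node_set))
    known = [n for n in nodes if n in graph]
    dropped = len(nodes) - len(known)
    if dropped:
        warnings.warn(f"{dropped} query nodes absent from the graph were dropped")
    return known


def observed_edges(graph: nx.Graph, node_set: Iterable[str]) -> int:
    """Number of graph edges with both endpoints in ``node_set``."""
    members = set(_resolve_node_set(graph, node_set))
    return sum(1 for u, v in graph.edges if u in members and v in members)


@dataclasses.dataclass
class EdgeEnrichmentResult:
    query_size: int
    observed_edges: int
    expected_edges: float
    p_value: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def edge_enrichment(
    graph: nx.Graph,
    node_set: Iterable[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EdgeEnrichmentResult:
    """Permutation test for excess connectivity of a node set.

    Null model: uniformly random node subsets of the same size drawn from
    the whole graph (no degree conditioning).  ``expected_edges`` is the
    null mean; ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    members = _resolve_node_set(graph, node_set)
    k = len(members)
    if k < 2:
        raise ValueError("node_set must contain >= 2 graph nodes")
    nodes = list(graph.nodes)
    n = len(nodes)
    if k > n:
        raise ValueError("node_set larger than the graph")
    obs = observed_edges(graph, members)
    idx = {node: i for i, node in enumerate(nodes)}
    edges = np.array([(idx[u], idx[v]) for u, v in graph.edges], dtype=np.int64)
    rng = np.random.default_rng(seed)
    if edges.size == 0:
        return EdgeEnrichmentResult(k, 0, 0.0, 1.0, n_perm, seed)
    # vectorized sampling of n_perm uniform k-subsets via partial argsort
    rand = rng.random((n_perm, n))
    subsets = np.argpartition(rand, k - 1, axis=1)[:, :k]
    member_mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(member_mask, subsets, True, axis=1)
    null_counts = (member_mask[:, edges[:, 0]] & member_mask[:, edges[:, 1]]).sum(axis=1)
    expected = float(null_counts.mean())
    p = float((1 + int((null_counts >= obs).sum())) / (n_perm + 1))
    return EdgeEnrichmentResult(
        query_size=k,
        observed_edges=obs,
        expected_edges=expected,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


def clustering_coefficient(graph: nx.Graph, node_set: Iterable[str]) -> float:
    """Mean local clustering coefficient of the ``node_set``-induced subgraph.

    Nodes with induced degree < 2 contribute 0 to the average.
    """
    members = _resolve_node_set(graph, node_set)
    if len(members) < 3:
        raise ValueError("need >= 3 nodes for a clustering coefficient")
    sub = graph.subgraph(members)
    return float(nx.average_clustering(sub, count_zeros=True))


@dataclasses.dataclass
class TermEnrichmentRecord:
    term: str
    background_size: int
    term_size: int
    query_size: int
    overlap: int
    p_value: float
    q_value: float


def term_enrichment(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> list[TermEnrichmentRecord]:
    """Hypergeometric over-representation of annotation terms in the query.

    For each term, p = P(overlap >= observed) drawn from Hypergeom(M =
    |background|, K = |term ∩ background|, n = |query|); q is the BH
    adjustment across all tested terms.  Query genes outside the background
    are dropped with a warning.  Sorted by (q, p, term).
    """
    bg = set(background)
    if not bg:
        raise ValueError("background set is empty")
    q = set(query)
    outside = q - bg
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the background were dropped")
        q &= bg
    records = []
    pvals = []
    for term, genes in annotations.items():
        term_genes = set(genes) & bg
        overlap = len(q & term_genes)
        p = float(hypergeom.sf(overlap - 1, len(bg), len(term_genes), len(q)))
        p = min(p, 1.0)
        records.append((term, len(term_genes), overlap, p))
        pvals.append(p)
    if not records:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        TermEnrichmentRecord(
            term=term,
            background_size=len(bg),
            term_size=term_size,
            query_size=len(q),
            overlap=overlap,
            p_value=p,
            q_value=float(qv),
        )
        for (term, term_size, overlap, p), qv in zip(records, qvals)
    ]
    out.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return out
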