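"""GO over-representation and graph-distance term summarization.

Gene sets produced by the kinetic classifier are tested for
over-represented ontology annotations with the upper-tail
hypergeometric test, corrected by Benjamini-Hochberg. Because enriched
terms are typically redundant (parents, children and siblings of the
same biological theme), terms are then clustered on their undirected
shortest-path distance in the ``is_a`` DAG and each cluster is reduced
to a single representative: the deepest ancestor common to all of its
terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from tcresponse.containers import StructuralError

logger = logging.getLogger(__name__)

#: Finite stand-in for the distance between disconnected terms; larger
#: than any usable cut height so such terms never share a cluster.
INF_DISTANCE = 1.0e9


@dataclass
class OntologyGraph:
    """An ``is_a`` DAG over ontology terms.

    Edges are directed child -> parent. The graph must be acyclic; every
    weakly connected component has at least one root (a term without
    parents), which accommodates one root per namespace.
    """

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise StructuralError(f"is_a cycle in ontology: {cycle}")
        self._undirected = self.graph.to_undirected(as_view=True)
        roots = [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]
        if not roots:
            raise StructuralError("ontology has no root term")
        self.roots = sorted(roots)
        # depth = fewest is_a edges from any root down to the term
        rev = self.graph.reverse(copy=False)
        depth: dict[str, int] = {}
        for root in self.roots:
            for term, d in nx.single_source_shortest_path_length(rev, root).items():
                if term not in depth or d < depth[term]:
                    depth[term] = d
        self._depth = depth

    @classmethod
    def from_edges(cls, edges, names=None) -> "OntologyGraph":
        """Build from an iterable of (child, parent) pairs."""
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g, dict(names or {}))

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name(self, term: str) -> str:
        return self.names.get(term, term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by following is_a edges (excl. self)."""
        return nx.descendants(self.graph, term)

    def ancestors_or_self(self, term: str) -> set[str]:
        return self.ancestors(term) | {term}

    def depth(self, term: str) -> int:
        """Shortest-path distance (in edges) from the nearest root."""
        return self._depth[term]


def term_distance(graph: OntologyGraph, t1: str, t2: str) -> float:
    """Shortest-path distance between two terms, is_a edges undirected.

    Returns ``math.inf`` for terms in disconnected components (e.g.
    different namespaces).
    """
    for t in (t1, t2):
        if t not in graph:
            raise KeyError(f"term {t!r} not in ontology")
    try:
        return float(nx.shortest_path_length(graph._undirected, t1, t2))
    except nx.NetworkXNoPath:
        return math.inf


def propagate_annotations(
    annotation: dict[str, set[str]], graph: OntologyGraph
) -> dict[str, frozenset[str]]:
    """Close gene->term annotations under ancestors (true-path rule).

    Terms absent from the ontology are skipped with a warning.
    """
    closure_cache: dict[str, frozenset[str]] = {}
    skipped: set[str] = set()

    def closure(term: str) -> frozenset[str]:
        if term not in closure_cache:
            closure_cache[term] = frozenset(graph.ancestors_or_self(term))
        return closure_cache[term]

    out: dict[str, frozenset[str]] = {}
    for gene, terms in annotation.items():
        closed: set[str] = set()
        for t in terms:
            if t not in graph:
                skipped.add(t)
                continue
            closed |= closure(t)
        out[gene] = frozenset(closed)
    if skipped:
        logger.warning("skipped %d unknown term ids: %s", len(skipped), sorted(skipped)[:5])
    return out


def enrich(
    gene_set,
    universe,
    annotation: dict[str, frozenset[str]],
    graph: OntologyGraph | None = None,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in ``gene_set``.

    Parameters
    ----------
    gene_set, universe
        Iterables of gene ids, ``gene_set`` a subset of ``universe``.
    annotation
        Gene -> set of term ids, already closed under ancestors.
    min_term_size
        Terms annotated to fewer than this many universe genes are not
        tested.

    Returns a table with columns ``term, name, k, n, K, N, p, p_adj``
    sorted by raw p, where ``p = P(X >= k)`` for hypergeometric X with
    population N, K annotated, draws n; BH correction is applied across
    the tested terms.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe or not gene_set:
        raise ValueError("gene set and universe must be non-empty")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for t in annotation.get(gene, ()):
            term_genes.setdefault(t, set()).add(gene)

    N, n = len(universe), len(gene_set)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(genes & gene_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, graph.name(term) if graph else term, k, n, K, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "name", "k", "n", "K", "N", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


def _common_parent(terms: list[str], graph: OntologyGraph) -> str:
    """Deepest term that is an ancestor-or-self of every term in the cluster.

    Ties are broken by lexicographically smallest id.
    """
    common = graph.ancestors_or_self(terms[0])
    for t in terms[1:]:
        common &= graph.ancestors_or_self(t)
    if not common:  # disconnected roots cannot co-occur after clustering
        raise ValueError(f"terms {terms} share no common ancestor")
    return min(common, key=lambda t: (-graph.depth(t), t))


def cluster_terms(
    enriched_terms,
    graph: OntologyGraph,
    linkage: str = "average",
    cut_distance: float = 2.0,
) -> pd.DataFrame:
    """Group terms by DAG distance and pick a common-parent representative.

    Hierarchical agglomeration (``linkage`` method) on the pairwise
    undirected shortest-path distance matrix, cut at cophenetic distance
    ``cut_distance``. Infinite distances (disconnected namespaces) force
    separate clusters. The representative of a cluster is the deepest
    common ancestor of its terms; a singleton represents itself.

    Returns a table ``term, cluster, representative, representative_name``.
    """
    terms = list(dict.fromkeys(enriched_terms))
    if not terms:
        raise ValueError("need at least one enriched term")
    if len(terms) == 1:
        lab = [1]
    else:
        m = len(terms)
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                d = term_distance(graph, terms[i], terms[j])
                dist[i, j] = dist[j, i] = INF_DISTANCE if math.isinf(d) else d
        link = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        lab = hierarchy.fcluster(link, t=cut_distance, criterion="distance")
    out = pd.DataFrame({"term": terms, "cluster": lab})
    reps = {
        cl: _common_parent(sub["term"].tolist(), graph)
        for cl, sub in out.groupby("cluster")
    }
    out["representative"] = out["cluster"].map(reps)
    out["representative_name"] = out["representative"].map(graph.name)
    return out


def add_term_clusters(
    table: pd.DataFrame,
    graph: OntologyGraph,
    alpha: float = 0.05,
    p_col: str = "p_adj",
    cut_distance: float = 2.0,
    linkage: str = "average",
) -> pd.DataFrame:
    """Attach cluster ids/representatives for terms significant at ``alpha``."""
    table = table.copy()
    sig = table.loc[table[p_col] < alpha, "term"].tolist()
    if not sig:
        table["cluster"] = pd.NA
        table["representative"] = pd.NA
        return table
    clusters = cluster_terms(sig, graph, linkage=linkage, cut_distance=cut_distance)
    merged = table.merge(clusters, on="term", how="left")
    return merged
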