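"""Over-representation statistics and DAG-distance term summarization."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tcresponse import enrichment
from tcresponse.containers import StructuralError
from tcresponse.enrichment import OntologyGraph
from tcresponse.simulate import simulate_ontology


@pytest.fixture
def chain_graph():
    # root <- a <- b
    return OntologyGraph.from_edges([("a", "root"), ("b", "a")])


@pytest.fixture
def family_graph():
    # root with children p, q; p has children x, y; q has child z
    return OntologyGraph.from_edges(
        [("p", "root"), ("q", "root"), ("x", "p"), ("y", "p"), ("z", "q")]
    )


class TestOntologyGraph:
    def test_cycle_rejected(self):
        with pytest.raises(StructuralError, match="cycle"):
            OntologyGraph.from_edges([("a", "b"), ("b", "a")])

    def test_depth_and_ancestors(self, chain_graph):
        assert chain_graph.depth("root") == 0
        assert chain_graph.depth("b") == 2
        assert chain_graph.ancestors("b") == {"a", "root"}


class TestPropagation:
    def test_chain_closure(self, chain_graph):
        out = enrichment.propagate_annotations({"g": {"b"}}, chain_graph)
        assert out["g"] == {"b", "a", "root"}

    def test_closed_annotation_unchanged(self, chain_graph):
        closed = {"g": {"b", "a", "root"}}
        out = enrichment.propagate_annotations(closed, chain_graph)
        assert out["g"] == closed["g"]

    def test_unknown_term_skipped(self, chain_graph, caplog):
        with caplog.at_level("WARNING"):
            out = enrichment.propagate_annotations({"g": {"b", "GHOST"}}, chain_graph)
        assert "GHOST" not in out["g"]

    def test_matches_reachability_oracle(self):
        graph, annot = simulate_ontology(
            25, gene_ids=[f"g{i}" for i in range(15)], seed=3
        )
        terms = sorted(graph.terms)
        pos = {t: i for i, t in enumerate(terms)}
        # boolean reachability closure by repeated squaring of the adjacency
        adj = np.eye(len(terms), dtype=bool)
        for child, parent in graph.graph.edges:
            adj[pos[child], pos[parent]] = True
        reach = adj.copy()
        for _ in range(len(terms)):
            reach = reach | (reach @ adj)
        for gene, closed in annot.items():
            direct = closed  # already closed; closure must be a fixed point
            expected = set()
            for t in direct:
                expected |= {terms[j] for j in np.nonzero(reach[pos[t]])[0]}
            assert closed == expected


def enumeration_p(N, K, n, k):
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    annotated = set(range(K))
    hits = total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(annotated & set(subset)) >= k:
            hits += 1
    return hits / total


class TestEnrich:
    def make_universe(self, N, K, n, k):
        """Universe of N genes; one term with K members; a set with overlap k."""
        genes = [f"g{i}" for i in range(N)]
        annot = {g: frozenset({"T", "root"}) if i < K else frozenset({"root"})
                 for i, g in enumerate(genes)}
        gene_set = genes[:k] + genes[K:K + (n - k)]
        assert len(gene_set) == n
        return gene_set, genes, annot

    def test_worked_case(self):
        gene_set, genes, annot = self.make_universe(10, 4, 5, 3)
        tab = enrichment.enrich(gene_set, genes, annot, min_term_size=1)
        p = tab.set_index("term").loc["T", "p"]
        assert p == pytest.approx(66 / 252, abs=1e-12)
        assert p == pytest.approx(enumeration_p(10, 4, 5, 3), abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        gene_set, genes, annot = self.make_universe(10, 4, 3, 0)
        tab = enrichment.enrich(gene_set, genes, annot, min_term_size=1)
        assert tab.set_index("term").loc["T", "p"] == pytest.approx(1.0)

    def test_set_equals_universe_gives_p_one(self):
        _, genes, annot = self.make_universe(8, 3, 3, 0)
        tab = enrichment.enrich(genes, genes, annot, min_term_size=1)
        assert np.allclose(tab["p"], 1.0)

    def test_small_term_skipped(self):
        gene_set, genes, annot = self.make_universe(10, 2, 5, 2)
        tab = enrichment.enrich(gene_set, genes, annot, min_term_size=3)
        assert "T" not in set(tab["term"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            enrichment.enrich([], ["g1"], {})
        with pytest.raises(ValueError):
            enrichment.enrich(["x"], ["g1"], {})

    def test_bh_adjustment_monotone(self):
        gene_set, genes, annot = self.make_universe(12, 5, 6, 4)
        # add a second, weaker term
        annot = {g: t | {"U"} if i % 3 == 0 else t
                 for i, (g, t) in enumerate(annot.items())}
        tab = enrichment.enrich(gene_set, genes, annot, min_term_size=1)
        sorted_tab = tab.sort_values("p")
        assert sorted_tab["p_adj"].is_monotonic_increasing
        assert (tab["p_adj"] >= tab["p"] - 1e-15).all()
        assert (tab["p_adj"] <= 1.0).all()

    def test_planted_term_is_top_hit(self):
        graph, annot = simulate_ontology(
            30, gene_ids=[f"g{i}" for i in range(60)], seed=7
        )
        # deepest term with a reasonable number of genes
        by_term = {}
        for g, terms in annot.items():
            for t in terms:
                by_term.setdefault(t, set()).add(g)
        target = max(
            (t for t, gs in by_term.items() if 5 <= len(gs) <= 20),
            key=lambda t: graph.depth(t),
        )
        gene_set = sorted(by_term[target])
        tab = enrichment.enrich(gene_set, sorted(annot), annot, graph)
        top = tab.iloc[0]["term"]
        assert top == target or top in graph.ancestors(target)


class TestTermDistance:
    def test_identity_and_parent(self, chain_graph):
        assert enrichment.term_distance(chain_graph, "b", "b") == 0
        assert enrichment.term_distance(chain_graph, "b", "a") == 1

    def test_siblings(self, family_graph):
        assert enrichment.term_distance(family_graph, "x", "y") == 2

    def test_disconnected_is_infinite(self):
        g = nx.DiGraph()
        g.add_edge("a", "rootA")
        g.add_edge("b", "rootB")
        graph = OntologyGraph(g)
        assert math.isinf(enrichment.term_distance(graph, "a", "b"))

    def test_matches_bfs_oracle(self):
        graph, _ = simulate_ontology(20, seed=11)
        und = graph.graph.to_undirected()
        terms = sorted(graph.terms)
        for t1 in terms[:8]:
            # hand-rolled breadth-first search
            frontier, dist, level = {t1}, {t1: 0}, 0
            while frontier:
                level += 1
                nxt = set()
                for u in frontier:
                    for v in und.neighbors(u):
                        if v not in dist:
                            dist[v] = level
                            nxt.add(v)
                frontier = nxt
            for t2 in terms[:8]:
                assert enrichment.term_distance(graph, t1, t2) == dist[t2]


def brute_force_average_linkage(terms, dist, cut):
    """Naive agglomeration: repeatedly merge the closest pair of clusters."""
    clusters = [{t} for t in terms]

    def d(c1, c2):
        return float(np.mean([dist[(a, b)] for a in c1 for b in c2]))

    while len(clusters) > 1:
        best = min(
            ((i, j) for i in range(len(clusters)) for j in range(i + 1, len(clusters))),
            key=lambda ij: d(clusters[ij[0]], clusters[ij[1]]),
        )
        if d(clusters[best[0]], clusters[best[1]]) > cut:
            break
        merged = clusters[best[0]] | clusters[best[1]]
        clusters = [c for idx, c in enumerate(clusters) if idx not in best] + [merged]
    return {frozenset(c) for c in clusters}


class TestClusterTerms:
    def test_single_term(self, family_graph):
        out = enrichment.cluster_terms(["x"], family_graph)
        assert out["representative"].tolist() == ["x"]

    def test_siblings_share_parent_representative(self, family_graph):
        out = enrichment.cluster_terms(["x", "y"], family_graph, cut_distance=2)
        assert out["cluster"].nunique() == 1
        assert set(out["representative"]) == {"p"}

    def test_disconnected_terms_separate(self):
        g = nx.DiGraph()
        g.add_edge("a", "rootA")
        g.add_edge("b", "rootB")
        out = enrichment.cluster_terms(["a", "b"], OntologyGraph(g))
        assert out["cluster"].nunique() == 2

    def test_matches_brute_force_agglomeration(self, family_graph):
        terms = ["root", "p", "q", "x", "y", "z"]
        dist = {
            (a, b): enrichment.term_distance(family_graph, a, b)
            for a in terms for b in terms
        }
        expected = brute_force_average_linkage(terms, dist, cut=2.0)
        out = enrichment.cluster_terms(terms, family_graph, cut_distance=2.0)
        got = {
            frozenset(sub["term"]) for _, sub in out.groupby("cluster")
        }
        assert got == expected

    def test_representative_is_common_ancestor(self):
        graph, _ = simulate_ontology(30, seed=19)
        rng = np.random.default_rng(2)
        terms = list(rng.choice(graph.terms, size=8, replace=False))
        out = enrichment.cluster_terms(terms, graph, cut_distance=3.0)
        for _, sub in out.groupby("cluster"):
            rep = sub["representative"].iloc[0]
            for t in sub["term"]:
                assert rep in graph.ancestors_or_self(t)
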