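"""Gene-domain graph: joins, queries, exports, brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domainsig import (
    DomainRecord,
    GeneDomainGraph,
    GeneRecord,
    InputError,
    join_by_coordinates,
    join_by_gene_id,
)


def brute_force_join(genes, domains, min_overlap):
    """Quadratic all-pairs interval-overlap oracle."""
    out = set()
    for g in genes:
        for d in domains:
            if g.chrom == d.chrom and min(g.end, d.end) - max(g.start, d.start) >= min_overlap:
                out.add((g.gene_id, d.domain_id))
    return sorted(out)


def random_instance(rng, n_genes=50, n_domains=30, n_chroms=2, span=2000):
    genes, domains = [], []
    for i in range(n_genes):
        s = int(rng.integers(span))
        genes.append(GeneRecord(f"g{i}", f"chr{rng.integers(n_chroms) + 1}",
                                s, s + int(rng.integers(1, 300))))
    for j in range(n_domains):
        s = int(rng.integers(span))
        domains.append(DomainRecord(f"d{j}", chrom=f"chr{rng.integers(n_chroms) + 1}",
                                    start=s, end=s + int(rng.integers(1, 150))))
    return genes, domains


class TestJoinByCoordinates:
    def test_full_containment(self):
        genes = [GeneRecord("g", "chr1", 100, 200)]
        doms = [DomainRecord("d", chrom="chr1", start=150, end=160)]
        assert join_by_coordinates(genes, doms) == [("g", "d")]

    def test_half_open_abutment_is_no_overlap(self):
        genes = [GeneRecord("g", "chr1", 100, 200)]
        doms = [DomainRecord("d", chrom="chr1", start=200, end=250)]
        assert join_by_coordinates(genes, doms) == []

    def test_min_overlap_threshold(self):
        genes = [GeneRecord("g", "chr1", 100, 200)]
        doms = [DomainRecord("d", chrom="chr1", start=195, end=260)]
        assert join_by_coordinates(genes, doms, min_overlap_bp=5) == [("g", "d")]
        assert join_by_coordinates(genes, doms, min_overlap_bp=6) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            genes, doms = random_instance(rng)
            mo = int(rng.integers(1, 50))
            assert join_by_coordinates(genes, doms, mo) == brute_force_join(genes, doms, mo)

    def test_requires_coordinate_form(self):
        with pytest.raises(InputError):
            join_by_coordinates([GeneRecord("g", "c", 0, 9)], [DomainRecord("d", gene_id="g")])


def test_join_by_gene_id_checks_references():
    genes = [GeneRecord("g1", "c", 0, 9), GeneRecord("g2", "c", 10, 19)]
    doms = [DomainRecord("d1", gene_id="g1"), DomainRecord("d1", gene_id="g2")]
    assert join_by_gene_id(genes, doms) == [("g1", "d1"), ("g2", "d1")]
    with pytest.raises(InputError, match="unknown gene"):
        join_by_gene_id(genes, [DomainRecord("d1", gene_id="gX")])


class TestBuildGraph:
    def test_shared_domain_counts(self):
        g = GeneDomainGraph.from_edges([("g1", "D"), ("g2", "D")])
        assert g.genes == {"g1", "g2"}
        assert g.domains == {"D"}
        assert len(g.edges) == 2

    def test_idempotent_under_duplicates(self):
        g = GeneDomainGraph.from_edges([("g1", "D"), ("g1", "D"), ("g2", "D")])
        assert len(g.edges) == 2

    def test_isolated_declared_genes(self):
        g = GeneDomainGraph.from_edges([], genes=["a", "b"])
        assert g.genes == {"a", "b"}
        assert g.edges == set()

    def test_dangling_reference_rejected(self):
        with pytest.raises(InputError, match="undeclared"):
            GeneDomainGraph.from_edges([("g1", "D")], genes=["g2"])

    def test_gene_domain_id_collision_rejected(self):
        with pytest.raises(InputError, match="bipartite"):
            GeneDomainGraph.from_edges([("x", "x")])

    def test_random_edges_dedup_counts(self):
        rng = np.random.default_rng(3)
        edges = [(f"g{rng.integers(40)}", f"d{rng.integers(15)}") for _ in range(200)]
        g = GeneDomainGraph.from_edges(edges)
        assert len(g.edges) == len(set(edges))
        assert g.genes == {e[0] for e in edges}
        assert g.domains == {e[1] for e in edges}


class TestQueries:
    def test_shares_domain_basic(self, toy_graph):
        assert toy_graph.shares_domain("g1", "g2")
        assert toy_graph.shares_domain("g3", "g4")
        assert not toy_graph.shares_domain("g1", "g4")
        assert not toy_graph.shares_domain("g1", "g5")

    def test_shares_domain_self_pair_disallowed(self, toy_graph):
        with pytest.raises(InputError):
            toy_graph.shares_domain("g1", "g1")

    def test_shares_domain_unknown_gene(self, toy_graph):
        with pytest.raises(InputError):
            toy_graph.shares_domain("g1", "nope")

    def test_shares_domain_symmetric_and_matches_oracle(self):
        rng = np.random.default_rng(7)
        edges = [(f"g{rng.integers(30)}", f"d{rng.integers(8)}") for _ in range(60)]
        g = GeneDomainGraph.from_edges(edges)
        neigh = {}
        for gene, dom in edges:
            neigh.setdefault(gene, set()).add(dom)
        for a, b in itertools.combinations(sorted(g.genes), 2):
            expected = bool(neigh.get(a, set()) & neigh.get(b, set()))
            assert g.shares_domain(a, b) == expected == g.shares_domain(b, a)

    def test_partition_covers_universe(self, toy_graph):
        universe = ["g1", "g2", "g3", "g4", "g5", "g6", "unknown"]
        with_d, without_d = toy_graph.partition_genes(universe)
        assert with_d == ["g1", "g2", "g3", "g4"]
        assert without_d == ["g5", "g6", "unknown"]
        assert len(with_d) + len(without_d) == len(universe)

    def test_partition_all_degree_zero(self):
        g = GeneDomainGraph.from_edges([], genes=["a", "b"])
        assert g.partition_genes(["a", "b"]) == ([], ["a", "b"])

    def test_connected_components_chain_and_disjoint(self):
        chain = GeneDomainGraph.from_edges(
            [("g1", "d1"), ("g2", "d1"), ("g2", "d2"), ("g3", "d2")]
        )
        comps = chain.connected_components()
        assert len(comps) == 1 and len(comps[0]) == 5
        two = GeneDomainGraph.from_edges(
            [("g1", "d1"), ("g2", "d1"), ("g3", "d2"), ("g4", "d2")]
        )
        comps = two.connected_components()
        assert len(comps) == 2
        assert comps[0] == {"g1", "g2", "d1"}  # tie broken by smallest gene id

    def test_largest_domain_and_tie_rule(self, toy_graph):
        assert toy_graph.largest_domain(["g1", "g2", "g3", "g4"]) == "d1"
        assert toy_graph.largest_domain(["g2", "g3"]) == "d1"
        # tie between d1 (g1,g3) and d2 (g3,g4): lexicographically smallest
        assert toy_graph.largest_domain(["g1", "g3", "g4"]) == "d1"
        assert toy_graph.largest_domain(["g5", "g6"]) is None
        with pytest.raises(InputError):
            toy_graph.largest_domain([])

    def test_largest_domain_matches_brute_force(self):
        rng = np.random.default_rng(11)
        edges = [(f"g{rng.integers(60)}", f"d{rng.integers(12)}") for _ in range(150)]
        g = GeneDomainGraph.from_edges(edges)
        subset = [f"g{i}" for i in rng.choice(60, size=40, replace=False)]
        counts = {}
        for gene, dom in set(edges):
            if gene in set(subset):
                counts[dom] = counts.get(dom, 0) + 1
        best = min(counts, key=lambda d: (-counts[d], d))
        assert g.largest_domain(subset) == best


class TestExports:
    def test_edge_tsv_round_trip(self, toy_graph, tmp_path):
        path = tmp_path / "edges.tsv"
        toy_graph.write_edge_tsv(path)
        back = GeneDomainGraph.read_edge_tsv(path)
        assert back.edges == toy_graph.edges

    def test_gexf_round_trip_preserves_kinds(self, toy_graph, tmp_path):
        path = tmp_path / "graph.gexf"
        toy_graph.write_gexf(path)
        back = GeneDomainGraph.read_gexf(path)
        assert back.genes == toy_graph.genes
        assert back.domains == toy_graph.domains
        assert back.edges == toy_graph.edges

    def test_empty_graph_exports(self, tmp_path):
        g = GeneDomainGraph()
        g.write_gexf(tmp_path / "e.gexf")
        g.write_edge_tsv(tmp_path / "e.tsv")
        assert GeneDomainGraph.read_edge_tsv(tmp_path / "e.tsv").edges == set()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    edges=st.lists(
        st.tuples(
            st.integers(0, 15).map(lambda i: f"g{i}"),
            st.integers(0, 6).map(lambda i: f"d{i}"),
        ),
        max_size=40,
    )
)
def test_bipartiteness_invariant(edges):
    """Every constructed graph stays bipartite with consistent node kinds."""
    g = GeneDomainGraph.from_edges(edges)
    for gene, dom in g.edges:
        assert gene in g.genes and dom in g.domains
    assert g.genes.isdisjoint(g.domains)
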