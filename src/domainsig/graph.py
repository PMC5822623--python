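"""Bipartite gene–domain graph: construction, queries, export.

Genes and protein-family domains form a bipartite graph whose
gene–domain–gene motifs define "genes sharing a domain". Construction is
either by identifier (domain rows referencing a host gene) or by a genomic
coordinate join of domain intervals onto gene spans. The container wraps a
:class:`networkx.Graph`, so standard graph algorithms and GEXF export (for
Gephi) come for free.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

from .annotations import DomainRecord, GeneRecord
from .errors import InputError

GENE = "gene"
DOMAIN = "domain"


def join_by_coordinates(
    genes: Sequence[GeneRecord],
    domains: Sequence[DomainRecord],
    min_overlap_bp: int = 1,
) -> list[tuple[str, str]]:
    """Join domain intervals onto gene spans by genomic overlap.

    An edge (gene_id, domain_id) is emitted iff both lie on the same
    chromosome and their overlap length is at least ``min_overlap_bp``
    (coordinates 0-based half-open, strand ignored). Returns a
    deduplicated, lexicographically sorted edge list.
    """
    if min_overlap_bp < 1:
        raise InputError("min_overlap_bp must be >= 1")
    for d in domains:
        if not d.has_coordinates:
            raise InputError(
                f"domain {d.domain_id}: coordinate join requires coordinate-form records"
            )
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chrom].addi(g.start, g.end, g.gene_id)
    edges: set[tuple[str, str]] = set()
    for d in domains:
        for iv in trees.get(d.chrom, IntervalTree()).overlap(d.start, d.end):
            if min(iv.end, d.end) - max(iv.begin, d.start) >= min_overlap_bp:
                edges.add((iv.data, d.domain_id))
    return sorted(edges)


def join_by_gene_id(
    genes: Sequence[GeneRecord], domains: Sequence[DomainRecord]
) -> list[tuple[str, str]]:
    """Join domain records that reference their host gene by identifier."""
    known = {g.gene_id for g in genes}
    edges: set[tuple[str, str]] = set()
    for d in domains:
        if d.has_coordinates:
            raise InputError(
                f"domain {d.domain_id}: identifier join requires gene_id-form records"
            )
        if d.gene_id not in known:
            raise InputError(f"domain {d.domain_id} references unknown gene {d.gene_id!r}")
        edges.add((d.gene_id, d.domain_id))
    return sorted(edges)


class GeneDomainGraph:
    """Bipartite graph with gene nodes and domain nodes.

    Genes of degree 0 are "without domain"; two genes share a domain iff
    their domain neighborhoods intersect (a gene–domain–gene motif).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # ------------------------------------------------------- construction

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        genes: Optional[Iterable[str]] = None,
        domains: Optional[Iterable[str]] = None,
    ) -> "GeneDomainGraph":
        """Build from (gene_id, domain_id) pairs; idempotent under duplicates.

        ``genes``/``domains`` may declare extra (possibly isolated) nodes;
        edges referencing undeclared endpoints are allowed only when no
        declaration is given for that side.
        """
        graph = cls()
        declared_genes = set(genes) if genes is not None else None
        declared_domains = set(domains) if domains is not None else None
        if declared_genes is not None:
            for g in sorted(declared_genes):
                graph._add_node(g, GENE)
        if declared_domains is not None:
            for d in sorted(declared_domains):
                graph._add_node(d, DOMAIN)
        for g, d in edges:
            if declared_genes is not None and g not in declared_genes:
                raise InputError(f"edge references undeclared gene {g!r}")
            if declared_domains is not None and d not in declared_domains:
                raise InputError(f"edge references undeclared domain {d!r}")
            graph._add_node(g, GENE)
            graph._add_node(d, DOMAIN)
            graph._g.add_edge(g, d)
        return graph

    def _add_node(self, node_id: str, kind: str) -> None:
        existing = self._g.nodes.get(node_id)
        if existing is not None and existing["kind"] != kind:
            raise InputError(
                f"identifier {node_id!r} used both as gene and as domain; "
                "bipartite structure requires disjoint id spaces"
            )
        self._g.add_node(node_id, kind=kind, bipartite=0 if kind == GENE else 1)

    # ------------------------------------------------------------ queries

    @property
    def genes(self) -> set[str]:
        return {n for n, k in self._g.nodes(data="kind") if k == GENE}

    @property
    def domains(self) -> set[str]:
        return {n for n, k in self._g.nodes(data="kind") if k == DOMAIN}

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v in self._g.edges:
            if self._g.nodes[u]["kind"] == GENE:
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    def domains_of(self, gene_id: str) -> set[str]:
        if gene_id not in self._g or self._g.nodes[gene_id]["kind"] != GENE:
            raise InputError(f"unknown gene {gene_id!r}")
        return set(self._g[gene_id])

    def genes_of(self, domain_id: str) -> set[str]:
        if domain_id not in self._g or self._g.nodes[domain_id]["kind"] != DOMAIN:
            raise InputError(f"unknown domain {domain_id!r}")
        return set(self._g[domain_id])

    def degree(self, gene_id: str) -> int:
        return len(self.domains_of(gene_id))

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._g and self._g.nodes[gene_id]["kind"] == GENE

    def shares_domain(self, g1: str, g2: str) -> bool:
        """True iff the two (distinct) genes have a common domain neighbor."""
        if g1 == g2:
            raise InputError("shares_domain is undefined for a gene with itself")
        return not self.domains_of(g1).isdisjoint(self.domains_of(g2))

    def partition_genes(self, universe: Sequence[str]) -> tuple[list[str], list[str]]:
        """Split ``universe`` into (with_domain, without_domain), order kept.

        Genes absent from the graph count as having no domain.
        """
        with_domain, without_domain = [], []
        for g in universe:
            if self.has_gene(g) and len(self._g[g]) > 0:
                with_domain.append(g)
            else:
                without_domain.append(g)
        return with_domain, without_domain

    def connected_components(self) -> list[set[str]]:
        """Components sorted by size descending, ties by smallest gene id."""
        comps = [set(c) for c in nx.connected_components(self._g)]

        def key(c: set[str]):
            gene_ids = sorted(n for n in c if self._g.nodes[n]["kind"] == GENE)
            return (-len(c), gene_ids[0] if gene_ids else min(c))

        return sorted(comps, key=key)

    def largest_domain(self, gene_subset: Sequence[str]) -> Optional[str]:
        """Domain connected to the most genes of ``gene_subset``.

        Ties break to the lexicographically smallest domain id; returns
        None when no subset gene carries any domain.
        """
        subset = set(gene_subset)
        if not subset:
            raise InputError("gene_subset must be nonempty")
        counts: dict[str, int] = defaultdict(int)
        for g in subset:
            if self.has_gene(g):
                for d in self._g[g]:
                    counts[d] += 1
        if not counts:
            return None
        return min(counts, key=lambda d: (-counts[d], d))

    def subgraph_for_genes(self, gene_ids: Sequence[str]) -> "GeneDomainGraph":
        """Induced bipartite subgraph over the genes and their domains."""
        present = [g for g in gene_ids if self.has_gene(g)]
        edges = [(g, d) for g in present for d in sorted(self._g[g])]
        return GeneDomainGraph.from_edges(edges, genes=present)

    # ------------------------------------------------------------- export

    def write_gexf(self, path) -> None:
        """GEXF export with a node ``kind`` attribute (gene/domain), Gephi-readable."""
        nx.write_gexf(self._g, path)

    def write_edge_tsv(self, path) -> None:
        """Edge list TSV (gene_id, domain_id); round-trips via read_edge_tsv."""
        df = pd.DataFrame(sorted(self.edges), columns=["gene_id", "domain_id"])
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_edge_tsv(cls, path) -> "GeneDomainGraph":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_id", "domain_id"}.issubset(df.columns):
            raise InputError(f"{path}: expected columns gene_id, domain_id")
        return cls.from_edges(zip(df["gene_id"], df["domain_id"]))

    @classmethod
    def read_gexf(cls, path) -> "GeneDomainGraph":
        g = nx.read_gexf(path)
        graph = cls()
        for n, data in g.nodes(data=True):
            kind = data.get("kind")
            if kind not in (GENE, DOMAIN):
                raise InputError(f"GEXF node {n!r} lacks a gene/domain kind attribute")
            graph._add_node(n, kind)
        for u, v in g.edges:
            if graph._g.nodes[u]["kind"] == graph._g.nodes[v]["kind"]:
                raise InputError("GEXF contains a non-bipartite edge")
            graph._g.add_edge(u, v)
        return graph

    # ------------------------------------------------------------ dunders

    def __repr__(self) -> str:
        return (
            f"GeneDomainGraph({len(self.genes)} genes, {len(self.domains)} domains, "
            f"{self._g.number_of_edges()} edges)"
        )
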