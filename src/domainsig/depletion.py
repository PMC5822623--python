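"""Domain depletion of ranked gene lists.

The practical remedy for domain-driven feature redundancy: walk down a
significance-ranked gene list and replace domain-connected genes with
subsequent significant ones. Two constraint modes are provided, because
"depleted for genes sharing common domains" admits two readings:

* ``pairwise_free`` — no two *selected* genes may share a domain; the
  strongest gene of each domain family is kept;
* ``strictly_domainless`` — no selected gene may carry any domain at all
  (the evaluated without-domain arm).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .errors import InputError
from .graph import GeneDomainGraph
from .signatures import Signature


class DepletionMode(str, Enum):
    PAIRWISE_FREE = "pairwise_free"
    STRICTLY_DOMAINLESS = "strictly_domainless"


@dataclass
class DepletionResult:
    signature: Signature  # origin "depleted", admitted genes in ranking order
    skipped: list[tuple[str, str]]  # (gene_id, domain that excluded it)
    target_size: int

    @property
    def achieved_size(self) -> int:
        return len(self.signature)


def _domains_of(graph: GeneDomainGraph, gene: str) -> set[str]:
    return graph.domains_of(gene) if graph.has_gene(gene) else set()


def deplete_signature(
    ranked_genes: Sequence[str],
    graph: GeneDomainGraph,
    target_size: int,
    mode: DepletionMode = DepletionMode.PAIRWISE_FREE,
) -> DepletionResult:
    """Greedy single pass down the ranking, admitting constraint-satisfying genes.

    A gene is admitted iff it satisfies the mode constraint against the
    already-admitted set; the pass stops at ``target_size`` or the end of
    the ranking. Skipped genes are returned with the (lexicographically
    smallest) domain that excluded each; admitted genes keep their
    relative ranking order.
    """
    mode = DepletionMode(mode)
    if target_size < 1:
        raise InputError("target_size must be >= 1")
    if len(set(ranked_genes)) != len(ranked_genes):
        raise InputError("ranked_genes contains duplicates")
    admitted: list[str] = []
    admitted_domains: set[str] = set()
    skipped: list[tuple[str, str]] = []
    for gene in ranked_genes:
        if len(admitted) >= target_size:
            break
        doms = _domains_of(graph, gene)
        if mode is DepletionMode.STRICTLY_DOMAINLESS:
            if doms:
                skipped.append((gene, min(doms)))
                continue
        else:
            clash = doms & admitted_domains
            if clash:
                skipped.append((gene, min(clash)))
                continue
        admitted.append(gene)
        admitted_domains |= doms
    return DepletionResult(
        Signature(admitted, "depleted"), skipped, target_size
    )


def signature_graph(signature: Signature, graph: GeneDomainGraph) -> GeneDomainGraph:
    """Induced bipartite sub-graph over the signature's genes and their domains.

    The export a practitioner would load into Gephi to inspect residual
    domain connections of a biomarker panel.
    """
    return graph.subgraph_for_genes(signature.gene_ids)
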