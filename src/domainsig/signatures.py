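"""Genomic signature construction from DE results and the domain graph.

A signature is an ordered gene list used as classifier features. Two
competing constructions mirror the study design: the *with-domain*
signature takes the significant genes attached to the single domain that
is connected with the most significant genes; the *without-domain*
signature takes the top significant genes carrying no domain at all. Both
are capped at half the number of samples to avoid overtraining (the
Hughes phenomenon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import InputError
from .graph import GeneDomainGraph

ORIGINS = ("with_domain", "without_domain", "depleted")


def max_signature_size(n_samples: int) -> int:
    """Signature size cap: floor(n_samples / 2). Zero signals an unusable design."""
    if n_samples < 0:
        raise InputError("n_samples must be non-negative")
    return n_samples // 2


@dataclass
class Signature:
    """Ordered gene list with its construction origin."""

    gene_ids: list[str]
    origin: str
    anchor_domain: Optional[str] = None

    def __post_init__(self):
        if self.origin not in ORIGINS:
            raise InputError(f"unknown signature origin {self.origin!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("signature contains duplicate genes")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def is_empty(self) -> bool:
        return not self.gene_ids


def _significant_genes(de_results: pd.DataFrame) -> list[str]:
    """Significant gene ids in ranking order (p ascending, gene_id tiebreak)."""
    sig = de_results[de_results["significant"]]
    return list(sig["gene_id"])


def build_domain_signature(
    de_results: pd.DataFrame, graph: GeneDomainGraph, n_samples: int
) -> Signature:
    """Signature of significant genes attached to the most DEG-connected domain.

    The anchor is the domain adjacent to the largest number of significant
    genes; members are those genes in DE rank order, truncated at the
    sample-count cap. Returns an empty signature (anchor None) when no
    significant gene carries a domain.
    """
    sig_genes = _significant_genes(de_results)
    if not sig_genes:
        return Signature([], "with_domain")
    anchor = graph.largest_domain(sig_genes)
    if anchor is None:
        return Signature([], "with_domain")
    members = graph.genes_of(anchor)
    cap = max_signature_size(n_samples)
    chosen = [g for g in sig_genes if g in members][:cap]
    return Signature(chosen, "with_domain", anchor_domain=anchor)


def build_domainfree_signature(
    de_results: pd.DataFrame, graph: GeneDomainGraph, n_samples: int
) -> Signature:
    """Signature of the top significant genes that carry no domain."""
    sig_genes = _significant_genes(de_results)
    cap = max_signature_size(n_samples)
    free = [
        g for g in sig_genes if not (graph.has_gene(g) and graph.degree(g) > 0)
    ][:cap]
    return Signature(free, "without_domain")
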