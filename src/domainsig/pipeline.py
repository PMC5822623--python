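"""End-to-end pipeline: annotation files in, run directory out.

Ties the stages together the way the command line drives them: read gene
and domain annotations, build the gene–domain graph, compare correlation
distributions, test differential expression, evaluate the with/without
domain signatures under cross-validation, deplete the ranking, and write
the report bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .coexpression import compare_distributions
from .datasets import read_count_dataset
from .depletion import DepletionMode, deplete_signature, signature_graph
from .diffexpr import de_test, filter_genes
from .evaluate import CLASSIFIER_KINDS, ClassifierSpec, evaluate_all
from .graph import GeneDomainGraph, join_by_coordinates, join_by_gene_id
from .report import make_report, write_report, write_stage_outputs
from .signatures import build_domain_signature, build_domainfree_signature, max_signature_size
from .annotations import read_bed, read_domain_tsv, read_gff3

logger = logging.getLogger(__name__)


@dataclass
class PipelineOptions:
    """Knobs of a full run; defaults follow the study procedure
    (25000 pairs x 100 simulations, alpha 0.05, 5-fold CV)."""

    n_pairs: int = 25000
    n_sims: int = 100
    alpha: float = 0.05
    cv_folds: int = 5
    n_repeats: int = 10
    min_overlap_bp: int = 1
    use_cpm: bool = True
    depletion_mode: DepletionMode = DepletionMode.PAIRWISE_FREE
    contrast: Optional[tuple] = None


def load_graph(genes_path, domains_path, min_overlap_bp: int = 1) -> GeneDomainGraph:
    """Build the gene–domain graph from annotation files.

    Gene file format is chosen by suffix (.gff3/.gff vs .bed); the domain
    TSV's columns decide between a coordinate join and an identifier join.
    """
    genes_path = Path(genes_path)
    if genes_path.suffix.lower() in (".gff", ".gff3"):
        genes = read_gff3(genes_path)
    else:
        genes = read_bed(genes_path)
    domains = read_domain_tsv(domains_path)
    if domains and domains[0].has_coordinates:
        edges = join_by_coordinates(genes, domains, min_overlap_bp=min_overlap_bp)
    else:
        edges = join_by_gene_id(genes, domains)
    return GeneDomainGraph.from_edges(edges, genes=[g.gene_id for g in genes])


def run_pipeline(
    counts_path,
    classes_path,
    genes_path,
    domains_path,
    outdir,
    seed: int = 0,
    options: Optional[PipelineOptions] = None,
) -> dict:
    """Run every stage and write the report bundle under ``outdir``."""
    opts = options or PipelineOptions()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    counts = read_count_dataset(counts_path, classes_path)
    graph = load_graph(genes_path, domains_path, min_overlap_bp=opts.min_overlap_bp)

    comparison = compare_distributions(
        counts, graph, n_pairs=opts.n_pairs, n_sims=opts.n_sims, rng=rng,
        use_cpm=opts.use_cpm,
    )
    filtered = filter_genes(counts)
    de = de_test(filtered, alpha=opts.alpha, contrast=opts.contrast)

    sig_domain = build_domain_signature(de, graph, counts.n_samples)
    sig_free = build_domainfree_signature(de, graph, counts.n_samples)
    signatures = [s for s in (sig_domain, sig_free) if not s.is_empty]
    for sig in (sig_domain, sig_free):
        if sig.is_empty:
            logger.warning("signature %s is empty and will not be evaluated", sig.origin)
    specs = [ClassifierSpec(kind, seed=seed) for kind in CLASSIFIER_KINDS]
    evaluation = evaluate_all(
        counts, signatures, specs, k=opts.cv_folds, n_repeats=opts.n_repeats, rng=rng
    )

    ranking = list(de[de["significant"]]["gene_id"])
    target = max(1, max_signature_size(counts.n_samples))
    depletion = deplete_signature(ranking, graph, target, mode=opts.depletion_mode)
    signature_graph(depletion.signature, graph).write_edge_tsv(outdir / "depleted_signature_graph.tsv")
    graph.write_gexf(outdir / "gene_domain_graph.gexf")

    report = make_report(comparison, de, evaluation, depletion, graph=graph)
    write_stage_outputs(outdir, comparison=comparison, de_results=de, evaluation=evaluation)
    write_report(report, outdir)
    return report
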