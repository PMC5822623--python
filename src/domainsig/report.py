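"""End-to-end run report: one versioned JSON summary plus long-format TSVs.

The JSON gathers the correlation-shift summaries, DEG counts split by
domain status (the row structure of a with/without-domains DEG table),
the per-classifier misclassification summary, and the depletion outcome.
Regenerating the report from the same stage outputs is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .coexpression import CorrelationComparison
from .depletion import DepletionResult
from .errors import InputError
from .evaluate import EvaluationResult
from .graph import GeneDomainGraph

SCHEMA_VERSION = 1


def make_report(
    comparison: Optional[CorrelationComparison],
    de_results: Optional[pd.DataFrame],
    evaluation: Optional[EvaluationResult],
    depletion: Optional[DepletionResult],
    graph: Optional[GeneDomainGraph] = None,
) -> dict:
    """Assemble the run summary dictionary.

    All four stage outputs are required; missing ones are reported
    together by name. Empty signatures or empty result tables yield
    explicit null fields, never absent keys.
    """
    missing = [
        name
        for name, obj in (
            ("comparison", comparison),
            ("de_results", de_results),
            ("evaluation", evaluation),
            ("depletion", depletion),
        )
        if obj is None
    ]
    if missing:
        raise InputError(f"missing stage outputs: {', '.join(missing)}")

    deg = de_results[de_results["significant"]]
    deg_ids = list(deg["gene_id"])
    if graph is not None:
        with_domain, without_domain = graph.partition_genes(deg_ids)
        deg_split = {"with_domain": len(with_domain), "without_domain": len(without_domain)}
    else:
        deg_split = {"with_domain": None, "without_domain": None}

    summary = evaluation.summary
    classifier_summary = [
        {
            "classifier": r.classifier,
            "origin": r.origin,
            "mean_percent_misclassified": float(r.mean_pct),
            "sd_percent_misclassified": None if pd.isna(r.sd_pct) else float(r.sd_pct),
            "n_repeats": int(r.n_repeats),
        }
        for r in summary.itertuples()
    ]

    sig = depletion.signature
    return {
        "schema_version": SCHEMA_VERSION,
        "correlation_shift": {
            "mean_diff": comparison.mean_diff,
            "ks_distance": comparison.ks_distance,
            "n_pairs": comparison.n_pairs,
            "n_sims": comparison.n_sims,
            "n_skipped_genes": comparison.n_skipped_genes,
        },
        "differential_expression": {
            "n_tested": int(len(de_results)),
            "n_significant": int(len(deg)),
            "deg_by_domain_status": deg_split,
        },
        "classification": {"summary": classifier_summary},
        "depletion": {
            "target_size": depletion.target_size,
            "achieved_size": depletion.achieved_size,
            "signature_genes": sig.gene_ids if sig.gene_ids else None,
            "anchor_domain": sig.anchor_domain,
            "skipped": [{"gene_id": g, "excluded_by": d} for g, d in depletion.skipped] or None,
        },
    }


def write_report(report: dict, outdir) -> Path:
    """Write ``report.json`` deterministically (sorted keys, fixed layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


def write_stage_outputs(
    outdir,
    comparison: Optional[CorrelationComparison] = None,
    de_results: Optional[pd.DataFrame] = None,
    evaluation: Optional[EvaluationResult] = None,
) -> None:
    """Write the long-format stage files a run directory carries next to report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if comparison is not None:
        (outdir / "comparison.json").write_text(
            json.dumps(comparison.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    if de_results is not None:
        de_results.to_csv(outdir / "de_results.tsv", sep="\t", index=False, lineterminator="\n")
    if evaluation is not None:
        evaluation.write_tsv(outdir / "evaluation.tsv")
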