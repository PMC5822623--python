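"""Two-group differential expression on log-CPM.

The default test is the Wilcoxon rank-sum (Mann–Whitney U) with normal
approximation and tie correction, applied gene-wise to log-CPM, followed
by Benjamini–Hochberg adjustment. Rank statistics make no distributional
assumption about the counts, which is the same argument that motivates
Spearman correlation elsewhere in the package. External DE rankings (e.g.
from an NB-GLM tool) can be injected through
:func:`from_external_ranking` and consumed by the signature builders
unchanged.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import log_cpm
from .datasets import CountDataset
from .errors import InputError, InsufficientDataError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene_id", "statistic", "log2_fc", "p_value", "q_value", "significant"]


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Order-preserving with respect to the raw p-values; values lie in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_genes(
    counts: CountDataset, min_cpm: float = 1.0, min_samples: Optional[int] = None
) -> CountDataset:
    """Drop weakly expressed genes before testing.

    Keeps genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples
    (default: the size of the smallest class). Removed-gene count is logged.
    """
    if min_samples is None:
        min_samples = int(counts.classes.value_counts().min())
    cpm = 1e6 * counts.counts / counts.counts.sum(axis=0)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_genes removed %d/%d genes", removed, counts.n_genes)
    return CountDataset(counts.counts.loc[keep], counts.classes)


def de_test(
    counts: CountDataset,
    alpha: float = 0.05,
    contrast: Optional[tuple] = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Gene-wise Wilcoxon rank-sum DE test between two sample classes.

    Parameters
    ----------
    counts
        Filtered count dataset; its ``classes`` define the groups.
    alpha
        Significance level applied to the adjusted p-value.
    contrast
        Pair of class labels ``(reference, treatment)``. Required when the
        dataset has more than two classes; defaults to the two labels in
        sorted order.
    adjust
        If False, ``significant`` thresholds the raw p-value instead of
        the BH q-value (a literal reading of "significance level alpha").

    Returns
    -------
    DataFrame with columns gene_id, statistic (Mann–Whitney U of the
    treatment group), log2_fc (treatment minus reference mean log2-CPM),
    p_value, q_value, significant — ranked by p ascending, ties broken by
    gene_id. The test is deterministic.
    """
    levels = sorted(set(counts.classes))
    if contrast is None:
        if len(levels) != 2:
            raise InputError(
                f"dataset has {len(levels)} classes; pass contrast=(reference, treatment)"
            )
        contrast = (levels[0], levels[1])
    ref, trt = contrast
    for lab in contrast:
        if lab not in levels:
            raise InputError(f"unknown class label {lab!r}")
    mask_ref = (counts.classes == ref).to_numpy()
    mask_trt = (counts.classes == trt).to_numpy()
    if mask_ref.sum() < 3 or mask_trt.sum() < 3:
        raise InsufficientDataError("each contrasted class needs >= 3 samples")
    if counts.n_genes == 0:
        raise InsufficientDataError("no genes left to test")

    logm = log_cpm(counts).to_numpy()
    x = logm[:, mask_trt]
    y = logm[:, mask_ref]
    res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method="asymptotic")
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant across all contrasted samples: U-statistic variance is 0
    # and the p-value is indeterminate; such genes carry no evidence -> p = 1
    both = np.concatenate([x, y], axis=1)
    const = np.all(both == both[:, :1], axis=1)
    p = np.where(const, 1.0, p)
    u = np.where(const, x.shape[1] * y.shape[1] / 2.0, u)
    if np.isnan(p).any():
        raise InputError("rank-sum test produced NaN p-values for non-constant genes")

    log2_fc = x.mean(axis=1) - y.mean(axis=1)
    q = adjust_bh(p) if adjust else p.copy()
    significant = (q <= alpha) if adjust else (p <= alpha)
    out = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "statistic": u,
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": q,
            "significant": significant,
        }
    )
    out = out.sort_values(["p_value", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out


def from_external_ranking(
    table: pd.DataFrame, alpha: float = 0.05, adjust: bool = True
) -> pd.DataFrame:
    """Adapt an external (gene_id, p_value) ranking to the DE result schema.

    Lets any outside DE engine's output drive the signature builders.
    Missing statistic/log2_fc columns are filled with NaN.
    """
    if not {"gene_id", "p_value"}.issubset(table.columns):
        raise InputError("external ranking needs columns gene_id, p_value")
    out = table.copy()
    out["gene_id"] = out["gene_id"].astype(str)
    if "statistic" not in out:
        out["statistic"] = np.nan
    if "log2_fc" not in out:
        out["log2_fc"] = np.nan
    q = adjust_bh(out["p_value"].to_numpy())
    out["q_value"] = q
    out["significant"] = (q <= alpha) if adjust else (out["p_value"] <= alpha)
    out = out[RESULT_COLUMNS]
    return out.sort_values(["p_value", "gene_id"], kind="mergesort").reset_index(drop=True)
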