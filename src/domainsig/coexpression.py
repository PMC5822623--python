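"""Co-expression of gene pairs that share a protein-family domain.

The comparison repeatedly samples two groups of gene pairs — pairs sharing
a domain and pairs of domain-free genes — computes Spearman's rank
correlation of their (log-CPM) expression vectors, and summarizes the two
correlation distributions as histogram curves with min/max simulation
envelopes plus two scalar shift summaries (difference of pooled means and
the Kolmogorov–Smirnov distance of the pooled samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CountDataset
from .errors import InputError, InsufficientDataError, UndefinedStatisticError
from .graph import GeneDomainGraph

logger = logging.getLogger(__name__)

#: 81 equal-width bins of 0.025 centered on 0, covering [-1, 1]
DEFAULT_BIN_EDGES = np.linspace(-1.0125, 1.0125, 82)


def log_cpm(counts) -> pd.DataFrame:
    """log2(1 + CPM) transform of a count matrix.

    CPM divides each column by its total and scales to one million, which
    removes library-size differences before correlation or classification.

    Parameters
    ----------
    counts
        CountDataset or gene x sample DataFrame; every column sum must be
        positive.
    """
    mat = counts.counts if isinstance(counts, CountDataset) else counts
    colsum = mat.sum(axis=0).to_numpy(dtype=float)
    if (colsum <= 0).any():
        bad = list(mat.columns[colsum <= 0])
        raise InputError(f"all-zero sample column(s): {bad}")
    return np.log2(1.0 + 1e6 * mat / colsum)


def log_counts(counts) -> pd.DataFrame:
    """Plain log2(1 + count) transform (no library-size normalization)."""
    mat = counts.counts if isinstance(counts, CountDataset) else counts
    return np.log2(1.0 + mat.astype(float))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks. Raises
    :class:`~domainsig.errors.UndefinedStatisticError` when either vector
    is constant (the statistic is then undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("spearman requires two equal-length vectors")
    if x.size < 3:
        raise InputError("spearman requires length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def rank_rows(matrix: np.ndarray) -> np.ndarray:
    """Average ranks along each row (precomputation for pairwise Spearman)."""
    return stats.rankdata(matrix, axis=1)


def pairwise_spearman(ranks: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Spearman coefficients for many row pairs of a pre-ranked matrix.

    ``ranks`` is the output of :func:`rank_rows`; rows indexed by
    ``idx_a[i]``/``idx_b[i]`` must not be constant.
    """
    a = ranks[idx_a]
    b = ranks[idx_b]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    return num / den


def _same_domain_pairs(graph: GeneDomainGraph, eligible: set[str]) -> list[tuple[str, str]]:
    """All distinct unordered same-domain pairs among ``eligible`` genes, sorted."""
    pairs: set[tuple[str, str]] = set()
    for d in graph.domains:
        members = sorted(g for g in graph.genes_of(d) if g in eligible)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add((members[i], members[j]))
    return sorted(pairs)


def sample_pairs(
    graph: GeneDomainGraph,
    eligible_genes: Sequence[str],
    group: Literal["domain_sharing", "domain_free"],
    n_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Sample unordered gene pairs for one arm of the comparison.

    ``domain_sharing`` draws uniformly, without replacement, from the set
    of distinct pairs of eligible genes with a common domain;
    ``domain_free`` draws uniformly, without replacement, from pairs of
    eligible genes that carry no domain at all. Pairs are unique within
    one call and contain no self-pairs.
    """
    if n_pairs < 1:
        raise InputError("n_pairs must be >= 1")
    eligible = set(eligible_genes)
    if group == "domain_sharing":
        pool = _same_domain_pairs(graph, eligible)
        if n_pairs > len(pool):
            raise InsufficientDataError(
                f"requested {n_pairs} domain-sharing pairs but only {len(pool)} exist"
            )
        idx = rng.choice(len(pool), size=n_pairs, replace=False)
        return [pool[i] for i in idx]
    if group == "domain_free":
        free = sorted(
            g for g in eligible if not (graph.has_gene(g) and graph.degree(g) > 0)
        )
        n = len(free)
        total = n * (n - 1) // 2
        if n_pairs > total:
            raise InsufficientDataError(
                f"requested {n_pairs} domain-free pairs but only {total} exist"
            )
        if n_pairs * 2 >= total:
            pool = [(free[i], free[j]) for i in range(n) for j in range(i + 1, n)]
            idx = rng.choice(total, size=n_pairs, replace=False)
            return [pool[i] for i in idx]
        chosen: set[tuple[int, int]] = set()
        out: list[tuple[str, str]] = []
        while len(out) < n_pairs:  # rejection sampling; n_pairs << total here
            i, j = rng.integers(n, size=2)
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in chosen:
                continue
            chosen.add(key)
            out.append((free[key[0]], free[key[1]]))
        return out
    raise InputError(f"unknown group {group!r}")


@dataclass
class CorrelationComparison:
    """Paired correlation distributions for domain-sharing vs domain-free pairs."""

    n_pairs: int
    n_sims: int
    bin_edges: np.ndarray
    hist_domain: np.ndarray  # n_sims x n_bins row-proportions
    hist_free: np.ndarray
    mean_domain: np.ndarray
    mean_free: np.ndarray
    envelope_min_domain: np.ndarray
    envelope_max_domain: np.ndarray
    envelope_min_free: np.ndarray
    envelope_max_free: np.ndarray
    mean_diff: float  # pooled mean(domain) - mean(free)
    ks_distance: float  # sup-difference of pooled empirical CDFs
    n_skipped_genes: int  # constant-expression genes excluded up front

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_sims": self.n_sims,
            "bin_edges": self.bin_edges.tolist(),
            "hist_domain": self.hist_domain.tolist(),
            "hist_free": self.hist_free.tolist(),
            "mean_domain": self.mean_domain.tolist(),
            "mean_free": self.mean_free.tolist(),
            "envelope_min_domain": self.envelope_min_domain.tolist(),
            "envelope_max_domain": self.envelope_max_domain.tolist(),
            "envelope_min_free": self.envelope_min_free.tolist(),
            "envelope_max_free": self.envelope_max_free.tolist(),
            "mean_diff": self.mean_diff,
            "ks_distance": self.ks_distance,
            "n_skipped_genes": self.n_skipped_genes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationComparison":
        arrays = {
            k: np.asarray(d[k])
            for k in (
                "bin_edges", "hist_domain", "hist_free", "mean_domain", "mean_free",
                "envelope_min_domain", "envelope_max_domain",
                "envelope_min_free", "envelope_max_free",
            )
        }
        return cls(
            n_pairs=d["n_pairs"], n_sims=d["n_sims"], mean_diff=d["mean_diff"],
            ks_distance=d["ks_distance"], n_skipped_genes=d["n_skipped_genes"],
            **arrays,
        )


def compare_distributions(
    counts: CountDataset,
    graph: GeneDomainGraph,
    n_pairs: int = 25000,
    n_sims: int = 100,
    bin_edges: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    use_cpm: bool = True,
) -> CorrelationComparison:
    """Run the repeated pair-sampling comparison of correlation distributions.

    For each of ``n_sims`` simulations, ``n_pairs`` domain-sharing and
    ``n_pairs`` domain-free gene pairs are drawn and their Spearman
    correlations of log expression histogrammed; the result holds per-bin
    mean curves, min/max envelopes across simulations, and pooled shift
    summaries. Genes with constant expression are excluded up front (and
    counted), since their rank correlation is undefined.

    Set ``use_cpm=False`` to correlate plain log counts instead of log-CPM
    (library-size confounding then contributes to both arms).
    """
    rng = np.random.default_rng() if rng is None else rng
    edges = DEFAULT_BIN_EDGES if bin_edges is None else np.asarray(bin_edges)
    logm = (log_cpm(counts) if use_cpm else log_counts(counts)).to_numpy()
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    constant = np.all(logm == logm[:, :1], axis=1)
    n_skipped = int(constant.sum())
    if n_skipped:
        logger.info("excluding %d constant-expression genes from pair sampling", n_skipped)
    eligible = [g for g in counts.gene_ids if not constant[gene_index[g]]]
    ranks = rank_rows(logm)

    n_bins = len(edges) - 1
    hist_domain = np.empty((n_sims, n_bins))
    hist_free = np.empty((n_sims, n_bins))
    pooled_domain = np.empty(n_sims * n_pairs)
    pooled_free = np.empty(n_sims * n_pairs)
    for s in range(n_sims):
        for group, hist, pooled in (
            ("domain_sharing", hist_domain, pooled_domain),
            ("domain_free", hist_free, pooled_free),
        ):
            pairs = sample_pairs(graph, eligible, group, n_pairs, rng)
            ia = np.fromiter((gene_index[a] for a, _ in pairs), dtype=np.int64, count=n_pairs)
            ib = np.fromiter((gene_index[b] for _, b in pairs), dtype=np.int64, count=n_pairs)
            corr = pairwise_spearman(ranks, ia, ib)
            counts_in_bin, _ = np.histogram(corr, bins=edges)
            hist[s] = counts_in_bin / n_pairs
            pooled[s * n_pairs:(s + 1) * n_pairs] = corr

    ks = stats.ks_2samp(pooled_domain, pooled_free, method="asymp").statistic
    return CorrelationComparison(
        n_pairs=n_pairs,
        n_sims=n_sims,
        bin_edges=edges,
        hist_domain=hist_domain,
        hist_free=hist_free,
        mean_domain=hist_domain.mean(axis=0),
        mean_free=hist_free.mean(axis=0),
        envelope_min_domain=hist_domain.min(axis=0),
        envelope_max_domain=hist_domain.max(axis=0),
        envelope_min_free=hist_free.min(axis=0),
        envelope_max_free=hist_free.max(axis=0),
        mean_diff=float(pooled_domain.mean() - pooled_free.mean()),
        ks_distance=float(ks),
        n_skipped_genes=n_skipped,
    )
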