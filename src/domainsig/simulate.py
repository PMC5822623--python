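"""Synthetic RNA-seq count datasets with planted domain structure.

The generator emulates the shape of bulk RNA-seq studies used for
signature-based sample classification: tens of samples in 2–3 classes,
thousands of genes with negative-binomial counts, a gene–domain membership
structure in which a subset of genes carries one (occasionally two)
protein-family domains, and two planted effects:

* co-expression of genes sharing a domain, via a per-domain latent factor
  added to the log-mean with loading ``sqrt(rho / n_domains_of_gene)``;
* differential expression of a fraction of genes, as a class-dependent
  log2 fold-change shift.

Counts are NB(mean, phi) with variance ``mu + phi * mu**2``. All
randomness derives from a single root seed through named
``numpy.random.SeedSequence`` child streams, so the same configuration and
seed reproduce the dataset bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotations import DomainRecord, GeneRecord, write_domain_tsv, write_gff3
from .datasets import CountDataset
from .errors import ConfigurationError

# fraction of domain-carrying genes that receive a second domain, so that
# gene-domain-gene motifs overlap instead of forming disjoint cliques
SECONDARY_DOMAIN_FRACTION = 0.10

_GENE_LENGTH = 1000
_GENE_GAP = 500
_DOMAIN_LENGTH = 200
_N_CHROMS = 4

# named child streams spawned from the root seed, in spawn order
_STREAMS = ("baseline", "de_flags", "domain_structure", "latent", "library", "counts")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the co-expression study design: 2000 genes, 60
    samples in two balanced classes, 150 domain families of mean size 8
    covering half the genes, latent-factor strength ``rho`` 0.5, 10% DE
    genes at one log2 unit, NB dispersion 0.2.
    """

    n_genes: int = 2000
    n_samples: int = 60
    class_fractions: tuple[float, ...] = (0.5, 0.5)
    n_domains: int = 150
    domain_size_mean: float = 8.0
    frac_genes_with_domain: float = 0.5
    rho: float = 0.5
    de_fraction: float = 0.1
    log2_fold_change: float = 1.0
    dispersion: float = 0.2
    base_mean_log_range: tuple[float, float] = (math.log(5.0), math.log(500.0))
    library_size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_samples", "n_domains"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(name, "must be a positive integer")
        fr = tuple(self.class_fractions)
        if len(fr) not in (2, 3):
            raise ConfigurationError("class_fractions", "must have length 2 or 3")
        if any(f < 0 or f > 1 for f in fr):
            raise ConfigurationError("class_fractions", "entries must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError("class_fractions", "must sum to 1 within 1e-9")
        if self.n_samples < 2 * len(fr):
            raise ConfigurationError(
                "n_samples", f"needs >= {2 * len(fr)} samples for {len(fr)} classes"
            )
        if not 0.0 <= self.frac_genes_with_domain <= 1.0:
            raise ConfigurationError("frac_genes_with_domain", "must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction", "must lie in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError("rho", "must lie in [0, 1)")
        if self.domain_size_mean <= 0:
            raise ConfigurationError("domain_size_mean", "must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion", "must be positive")
        lo, hi = self.base_mean_log_range
        if not lo <= hi:
            raise ConfigurationError("base_mean_log_range", "must be (low, high) with low <= high")
        llo, lhi = self.library_size_factor_range
        if llo <= 0 or lhi <= 0 or llo > lhi:
            raise ConfigurationError(
                "library_size_factor_range", "must be positive with low <= high"
            )
        n_with = round(self.frac_genes_with_domain * self.n_genes)
        if 0 < n_with < 2 * self.n_domains:
            raise ConfigurationError(
                "n_domains",
                f"{self.n_domains} domains need >= {2 * self.n_domains} domain genes "
                f"(>=2 each) but frac_genes_with_domain yields only {n_with}",
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_fractions)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("class_fractions", "base_mean_log_range", "library_size_factor_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError("<yaml>", str(exc)) from exc

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """Generated counts plus the annotations and ground truth behind them."""

    counts: CountDataset
    gene_annotation: list[GeneRecord]
    domain_annotation: list[DomainRecord]
    truth: pd.DataFrame  # per gene: is_de, domain_ids (tuple of str)
    latent_factors: pd.DataFrame  # domains x samples
    config: SimulationConfig = field(repr=False)

    @property
    def membership_edges(self) -> list[tuple[str, str]]:
        """True (gene_id, domain_id) membership pairs, sorted."""
        edges = []
        for gene_id, doms in zip(self.truth.index, self.truth["domain_ids"]):
            edges.extend((gene_id, d) for d in doms)
        return sorted(edges)


def _class_vector(config: SimulationConfig) -> np.ndarray:
    """Integer class codes per sample via largest-remainder apportionment."""
    fr = np.asarray(config.class_fractions, dtype=float)
    raw = fr * config.n_samples
    counts = np.floor(raw).astype(int)
    remainder = config.n_samples - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return np.repeat(np.arange(len(fr)), counts)


def _family_sizes(n_domains: int, mean: float, pool: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-Poisson(>=2) family sizes adjusted to sum exactly to ``pool``."""
    sizes = np.empty(n_domains, dtype=int)
    for i in range(n_domains):
        s = rng.poisson(mean)
        while s < 2:
            s = rng.poisson(mean)
        sizes[i] = s
    # trim largest / grow random families so the partition covers the pool
    while sizes.sum() > pool:
        candidates = np.flatnonzero(sizes > 2)
        if candidates.size == 0:
            break
        sizes[candidates[np.argmax(sizes[candidates])]] -= 1
    while sizes.sum() < pool:
        sizes[rng.integers(n_domains)] += 1
    return sizes


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset under ``config``.

    The generative model: per-sample classes by ``class_fractions``;
    per-gene baseline means log-uniform on ``base_mean_log_range``;
    ``round(frac_genes_with_domain * n_genes)`` genes partitioned into
    ``n_domains`` families of truncated-Poisson(>=2) size, 10% of them
    receiving a second domain; per-domain, per-sample latent factors
    N(0, 1) entering the log-mean with loading ``sqrt(rho / k_g)`` for a
    gene with ``k_g`` domains; DE genes shifted by
    ``class_code * log2_fold_change * ln 2`` with a random sign per gene
    (balanced up/down regulation); sample library factors log-uniform;
    counts NB(mean, dispersion).
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rngs = dict(zip(_STREAMS, (np.random.default_rng(s) for s in root.spawn(len(_STREAMS)))))

    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"s{j + 1:03d}" for j in range(cfg.n_samples)]
    class_codes = _class_vector(cfg)
    class_labels = np.array([f"class{c}" for c in class_codes])

    lo, hi = cfg.base_mean_log_range
    log_mu = rngs["baseline"].uniform(lo, hi, size=cfg.n_genes)

    n_de = round(cfg.de_fraction * cfg.n_genes)
    rng_de = rngs["de_flags"]
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[rng_de.choice(cfg.n_genes, size=n_de, replace=False)] = True
    # random shift direction per DE gene keeps library composition stable
    # across classes, so CPM normalization does not smear apparent shifts
    # onto non-DE genes
    de_sign = np.where(rng_de.random(cfg.n_genes) < 0.5, 1.0, -1.0) * is_de

    # domain membership: partition the chosen gene pool into families
    rng_dom = rngs["domain_structure"]
    n_with = round(cfg.frac_genes_with_domain * cfg.n_genes)
    domain_ids = [f"PF{k + 1:05d}" for k in range(cfg.n_domains)]
    gene_domains: list[list[int]] = [[] for _ in range(cfg.n_genes)]
    if n_with > 0:
        pool = rng_dom.choice(cfg.n_genes, size=n_with, replace=False)
        sizes = _family_sizes(cfg.n_domains, cfg.domain_size_mean, n_with, rng_dom)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for d in range(cfg.n_domains):
            for g in pool[offsets[d]:offsets[d + 1]]:
                gene_domains[g].append(d)
        n_secondary = round(SECONDARY_DOMAIN_FRACTION * n_with)
        for g in rng_dom.choice(pool, size=n_secondary, replace=False):
            extra = int(rng_dom.integers(cfg.n_domains))
            if extra not in gene_domains[g]:
                gene_domains[g].append(extra)

    factors = rngs["latent"].standard_normal((cfg.n_domains, cfg.n_samples))

    log_mean = np.tile(log_mu[:, None], (1, cfg.n_samples))
    log_mean += de_sign[:, None] * class_codes[None, :] * (
        cfg.log2_fold_change * math.log(2.0)
    )
    for g, doms in enumerate(gene_domains):
        if doms:
            loading = math.sqrt(cfg.rho / len(doms))
            log_mean[g] += loading * factors[doms].sum(axis=0)

    llo, lhi = cfg.library_size_factor_range
    lib = np.exp(rngs["library"].uniform(math.log(llo), math.log(lhi), size=cfg.n_samples))
    mean = np.exp(log_mean) * lib[None, :]

    inv_disp = 1.0 / cfg.dispersion
    p = inv_disp / (inv_disp + mean)
    counts = rngs["counts"].negative_binomial(inv_disp, p)

    counts_df = pd.DataFrame(counts.astype(np.int64),
                             index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)
    classes = pd.Series(class_labels, index=pd.Index(sample_ids))
    dataset = CountDataset(counts_df, classes)

    gene_ann, dom_ann = _place_annotations(gene_ids, gene_domains, domain_ids)
    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "de_sign": de_sign.astype(int),
            "domain_ids": [tuple(domain_ids[d] for d in sorted(doms)) for doms in gene_domains],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    latent = pd.DataFrame(factors, index=pd.Index(domain_ids, name="domain_id"),
                          columns=sample_ids)
    return SyntheticDataset(dataset, gene_ann, dom_ann, truth, latent, cfg)


def _place_annotations(
    gene_ids: list[str], gene_domains: list[list[int]], domain_ids: list[str]
) -> tuple[list[GeneRecord], list[DomainRecord]]:
    """Lay genes on chromosomes with gaps; domain occurrences strictly inside
    their host gene's span, so any overlap rule recovers membership."""
    n = len(gene_ids)
    per_chrom = math.ceil(n / _N_CHROMS)
    genes: list[GeneRecord] = []
    doms: list[DomainRecord] = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * (_GENE_LENGTH + _GENE_GAP)
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneRecord(gid, chrom, start, start + _GENE_LENGTH, strand))
        for k, d in enumerate(sorted(gene_domains[i])):
            occ_start = start + 100 + k * 250
            doms.append(
                DomainRecord(domain_ids[d], chrom=chrom, start=occ_start,
                             end=occ_start + _DOMAIN_LENGTH)
            )
    return genes, doms


def write_annotations(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset as plain-text files under ``outdir``.

    Emits genes.gff3 (1-based inclusive), domains.tsv (coordinate form),
    counts.tsv and classes.tsv; reading them back reproduces the in-memory
    objects exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.gff3",
        "domains": outdir / "domains.tsv",
        "counts": outdir / "counts.tsv",
        "classes": outdir / "classes.tsv",
    }
    write_gff3(dataset.gene_annotation, paths["genes"])
    write_domain_tsv(dataset.domain_annotation, paths["domains"])
    dataset.counts.write_counts_tsv(paths["counts"])
    dataset.counts.write_classes_tsv(paths["classes"])
    return paths


def classification_study_config(seed: int = 0) -> SimulationConfig:
    """Study design for the signature-classification experiment.

    Fewer, larger domain families (60 of mean size 15) and a higher DE
    fraction, so the most DEG-connected domain anchors a signature of
    several correlated genes while domain-free DEGs of identical marginal
    effect size are plentiful.
    """
    return SimulationConfig(
        n_genes=2000,
        n_samples=60,
        class_fractions=(0.5, 0.5),
        n_domains=60,
        domain_size_mean=15.0,
        frac_genes_with_domain=0.5,
        rho=0.5,
        de_fraction=0.25,
        log2_fold_change=1.0,
        dispersion=0.2,
        seed=seed,
    )
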