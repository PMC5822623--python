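import numpy as np
import pandas as pd
import pytest

from domainsig import (
    CountDataset,
    GeneDomainGraph,
    SimulationConfig,
    generate_dataset,
)


def graph_of(dataset) -> GeneDomainGraph:
    """Gene-domain graph from a synthetic dataset's true memberships."""
    return GeneDomainGraph.from_edges(
        dataset.membership_edges, genes=dataset.counts.gene_ids
    )


@pytest.fixture
def toy_graph() -> GeneDomainGraph:
    """Six genes: d1 covers g1,g2,g3; d2 covers g3,g4; g5,g6 domainless."""
    edges = [("g1", "d1"), ("g2", "d1"), ("g3", "d1"), ("g3", "d2"), ("g4", "d2")]
    return GeneDomainGraph.from_edges(edges, genes=["g1", "g2", "g3", "g4", "g5", "g6"])


@pytest.fixture(scope="session")
def small_synthetic():
    """Shared mid-size synthetic dataset with planted structure."""
    cfg = SimulationConfig(
        n_genes=300,
        n_samples=40,
        n_domains=30,
        domain_size_mean=5.0,
        frac_genes_with_domain=0.5,
        rho=0.5,
        de_fraction=0.1,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture
def tiny_counts() -> CountDataset:
    """12 genes x 12 samples with equal library sizes and two classes."""
    rng = np.random.default_rng(5)
    mat = rng.integers(1, 50, size=(12, 12))
    counts = pd.DataFrame(
        mat.astype(np.int64),
        index=pd.Index([f"g{i:02d}" for i in range(12)], name="gene_id"),
        columns=[f"s{j:02d}" for j in range(12)],
    )
    classes = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.columns)
    return CountDataset(counts, classes)
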