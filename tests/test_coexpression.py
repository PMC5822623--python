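"""Spearman correlation, pair resampling and the distribution comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domainsig import (
    CountDataset,
    GeneDomainGraph,
    InputError,
    InsufficientDataError,
    UndefinedStatisticError,
    compare_distributions,
    generate_dataset,
    log_cpm,
    sample_pairs,
    spearman,
    SimulationConfig,
)
from domainsig.coexpression import pairwise_spearman, rank_rows

from conftest import graph_of


def oracle_spearman(x, y):
    """Independent oracle: average ranks by hand, then the Pearson formula."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestLogCpm:
    def test_zero_count_maps_to_zero(self):
        df = pd.DataFrame({"s1": [0, 10], "s2": [5, 5]}, index=["a", "b"])
        out = log_cpm(df)
        assert out.loc["a", "s1"] == 0.0

    def test_uniform_column_closed_form(self):
        n_genes = 8
        df = pd.DataFrame(np.full((n_genes, 3), 7), index=[f"g{i}" for i in range(n_genes)])
        out = log_cpm(df)
        expected = math.log2(1 + 1e6 / n_genes)
        assert np.allclose(out.to_numpy(), expected)

    def test_matches_independent_formula(self, tiny_counts):
        out = log_cpm(tiny_counts).to_numpy()
        raw = tiny_counts.counts.to_numpy().astype(float)
        for j in range(raw.shape[1]):
            col = raw[:, j]
            expected = np.log2(1.0 + 1e6 * col / col.sum())
            assert np.allclose(out[:, j], expected)

    def test_all_zero_column_rejected(self):
        df = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]}, index=["a", "b"])
        with pytest.raises(InputError, match="all-zero"):
            log_cpm(df)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [3.0, 1.0, 2.0, 5.0]
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [9, 7, 5, 2]) == pytest.approx(-1.0)

    def test_tied_example_equals_hand_oracle(self):
        x, y = (1, 2, 2, 4), (3, 1, 4, 4)
        assert oracle_spearman(x, y) == pytest.approx(0.5)  # frozen from the oracle
        assert spearman(x, y) == pytest.approx(0.5, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_and_shape_checks(self):
        with pytest.raises(InputError):
            spearman([1, 2], [3, 4])
        with pytest.raises(InputError):
            spearman([1, 2, 3], [1, 2])

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            assert spearman(x, y) == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.integers(-500, 500), min_size=4, max_size=20, unique=True)
        .map(lambda v: [x / 7.0 for x in v]),
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 4.0),
    )
    def test_invariant_under_increasing_transform(self, data, shift, scale):
        """Rank correlation only sees order, so any strictly increasing map of
        either input leaves it unchanged."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(data)).tolist()
        base = spearman(data, y)
        transformed = [scale * v + shift + math.tanh(v) for v in data]  # strictly increasing
        assert spearman(transformed, y) == pytest.approx(base, abs=1e-9)

    def test_pairwise_matches_single(self, tiny_counts):
        logm = log_cpm(tiny_counts).to_numpy()
        ranks = rank_rows(logm)
        ia = np.array([0, 1, 2, 5])
        ib = np.array([3, 4, 6, 7])
        vec = pairwise_spearman(ranks, ia, ib)
        for k in range(len(ia)):
            assert vec[k] == pytest.approx(spearman(logm[ia[k]], logm[ib[k]]), abs=1e-12)


class TestSamplePairs:
    def test_exhaustive_three_gene_domain(self, toy_graph):
        rng = np.random.default_rng(0)
        pairs = sample_pairs(toy_graph, ["g1", "g2", "g3"], "domain_sharing", 3, rng)
        assert sorted(pairs) == [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]

    def test_domain_sharing_pairs_actually_share(self, toy_graph):
        rng = np.random.default_rng(1)
        for a, b in sample_pairs(toy_graph, list(toy_graph.genes), "domain_sharing", 4, rng):
            assert toy_graph.shares_domain(a, b)

    def test_domain_free_needs_two_free_genes(self, toy_graph):
        rng = np.random.default_rng(0)
        with pytest.raises(InsufficientDataError, match="only 0"):
            sample_pairs(toy_graph, ["g1", "g2", "g5"], "domain_free", 1, rng)

    def test_over_request_reports_maximum(self, toy_graph):
        rng = np.random.default_rng(0)
        with pytest.raises(InsufficientDataError, match="only 1"):
            sample_pairs(toy_graph, ["g5", "g6"], "domain_free", 5, rng)

    def test_no_self_pairs_and_uniqueness(self, toy_graph):
        rng = np.random.default_rng(2)
        pairs = sample_pairs(toy_graph, list(toy_graph.genes), "domain_sharing", 4, rng)
        assert len(set(pairs)) == len(pairs)
        assert all(a != b for a, b in pairs)

    def test_sampling_is_uniform_over_pair_space(self, toy_graph):
        """Single-pair draws hit each of the 4 same-domain pairs at the
        multinomial rate (within 3 sigma)."""
        rng = np.random.default_rng(3)
        n_draws = 20000
        counts = {}
        for _ in range(n_draws):
            (pair,) = sample_pairs(toy_graph, list(toy_graph.genes), "domain_sharing", 1, rng)
            counts[pair] = counts.get(pair, 0) + 1
        assert set(counts) == {("g1", "g2"), ("g1", "g3"), ("g2", "g3"), ("g3", "g4")}
        p = 1 / 4
        sigma = math.sqrt(n_draws * p * (1 - p))
        for c in counts.values():
            assert abs(c - n_draws * p) < 3 * sigma


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(n_genes=300, n_samples=30, n_domains=25,
                           domain_size_mean=5.0, de_fraction=0.0, rho=0.5, seed=9)
    d = generate_dataset(cfg)
    comp = compare_distributions(
        d.counts, graph_of(d), n_pairs=300, n_sims=8, rng=np.random.default_rng(9)
    )
    return d, comp


class TestCompareDistributions:
    def test_histograms_are_proportions(self, planted):
        _, comp = planted
        assert np.allclose(comp.hist_domain.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(comp.hist_free.sum(axis=1), 1.0, atol=1e-9)

    def test_envelopes_bracket_means(self, planted):
        _, comp = planted
        assert (comp.envelope_min_domain <= comp.mean_domain + 1e-12).all()
        assert (comp.mean_domain <= comp.envelope_max_domain + 1e-12).all()
        assert (comp.envelope_min_free <= comp.mean_free + 1e-12).all()
        assert (comp.mean_free <= comp.envelope_max_free + 1e-12).all()

    def test_bins_cover_correlation_range(self, planted):
        _, comp = planted
        assert comp.bin_edges[0] <= -1.0 and comp.bin_edges[-1] >= 1.0

    def test_planted_effect_shifts_right(self, planted):
        _, comp = planted
        assert comp.mean_diff > 0
        assert 0 < comp.ks_distance <= 1

    def test_deterministic_under_same_seed(self, planted):
        d, comp = planted
        again = compare_distributions(
            d.counts, graph_of(d), n_pairs=300, n_sims=8, rng=np.random.default_rng(9)
        )
        assert np.array_equal(again.hist_domain, comp.hist_domain)
        assert again.mean_diff == comp.mean_diff
        assert again.ks_distance == comp.ks_distance

    def test_round_trip_dict(self, planted):
        _, comp = planted
        from domainsig.coexpression import CorrelationComparison
        back = CorrelationComparison.from_dict(comp.to_dict())
        assert back.mean_diff == comp.mean_diff
        assert np.array_equal(back.hist_free, comp.hist_free)
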