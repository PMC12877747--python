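"""Divergence metrics against naive brute-force reimplementations."""

import numpy as np
import pytest

from cnaevo.divergence import (
    METRICS,
    divergence,
    mean_pga_difference,
    pairwise_divergence,
    pairwise_matrix,
    proportion_subclonal,
)
from cnaevo.grid import BinGrid, CopyNumberProfile, baseline_ploidy
from conftest import random_profile


# -- naive oracles: per-bin python loops, no shared code with the package --

def naive_states(p):
    b = sorted(p.cn.tolist())[(len(p.cn) - 1) // 2]
    return ["gain" if c > b else "loss" if c < b else "base" for c in p.cn]


def naive_metric(a, b, metric, weights=None):
    sa, sb = naive_states(a), naive_states(b)
    n = len(sa)
    if metric == "GeneticDistance":
        return sum(abs(int(x) - int(y)) for x, y in zip(a.cn, b.cn)) / n
    if metric == "BreakpointDivergence":
        bounds = set(a.grid.chrom_boundaries().tolist())
        bp_a = {i for i in range(1, n) if sa[i] != sa[i - 1] and i not in bounds}
        bp_b = {i for i in range(1, n) if sb[i] != sb[i - 1] and i not in bounds}
        union = bp_a | bp_b
        return len(bp_a ^ bp_b) / len(union) if union else 0.0
    w = [1.0] * n if weights is None else list(weights)
    diff = sum(w[i] for i in range(n) if sa[i] != sb[i])
    if metric in ("FracDiffBins", "GeneDoseFDB"):
        return diff / sum(w)
    alt = sum(w[i] for i in range(n) if sa[i] != "base" or sb[i] != "base")
    return diff / alt if alt > 0 else 0.0


class TestPairwiseMetrics:
    @pytest.mark.parametrize("metric", METRICS)
    def test_identical_profiles_are_zero(self, small_grid, rng, metric):
        p = random_profile(small_grid, rng)
        q = CopyNumberProfile(small_grid, p.cn, "q")
        w = rng.uniform(1, 5, small_grid.n_bins)
        assert pairwise_divergence(p, q, metric, w).value == 0.0

    def test_single_gained_bin(self):
        g = BinGrid.uniform({"chr1": 1000}, 10)
        a = CopyNumberProfile(g, [3] + [2] * 99, "a")
        b = CopyNumberProfile(g, [2] * 100, "b")
        assert pairwise_divergence(a, b, "FracDiffBins").value == pytest.approx(0.01)
        assert pairwise_divergence(a, b, "FracDiffAltBins").value == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_bruteforce_oracle(self, small_grid, rng, metric):
        w = rng.uniform(0.5, 5.0, small_grid.n_bins)
        for _ in range(40):
            a = random_profile(small_grid, rng, high=5, sample_id="a")
            b = random_profile(small_grid, rng, high=5, sample_id="b")
            got = pairwise_divergence(a, b, metric, w).value
            use_w = w if metric.startswith("GeneDose") else None
            assert got == pytest.approx(naive_metric(a, b, metric, use_w))

    @pytest.mark.parametrize("metric", METRICS)
    def test_symmetry(self, small_grid, rng, metric):
        w = rng.uniform(0.5, 5.0, small_grid.n_bins)
        for _ in range(10):
            a = random_profile(small_grid, rng, sample_id="a")
            b = random_profile(small_grid, rng, sample_id="b")
            assert pairwise_divergence(a, b, metric, w).value == pytest.approx(
                pairwise_divergence(b, a, metric, w).value
            )

    def test_fracdiffbins_bounded_by_fracdiffaltbins(self, small_grid, rng):
        for _ in range(30):
            a = random_profile(small_grid, rng, sample_id="a")
            b = random_profile(small_grid, rng, sample_id="b")
            fdb = pairwise_divergence(a, b, "FracDiffBins").value
            fdab = pairwise_divergence(a, b, "FracDiffAltBins").value
            if fdab > 0:
                assert fdb <= fdab + 1e-12

    def test_uniform_weights_reduce_to_unweighted(self, small_grid, rng):
        w = np.ones(small_grid.n_bins)
        for _ in range(10):
            a = random_profile(small_grid, rng, sample_id="a")
            b = random_profile(small_grid, rng, sample_id="b")
            assert pairwise_divergence(a, b, "GeneDoseFDB", w).value == pytest.approx(
                pairwise_divergence(a, b, "FracDiffBins").value
            )
            assert pairwise_divergence(a, b, "GeneDoseFDAB", w).value == pytest.approx(
                pairwise_divergence(a, b, "FracDiffAltBins").value
            )

    def test_unknown_metric_rejected(self, small_grid):
        p = CopyNumberProfile(small_grid, np.full(16, 2))
        with pytest.raises(ValueError):
            pairwise_divergence(p, p, "Hamming")


class TestCohortAggregation:
    def test_identical_samples_zero_divergence(self, small_grid):
        ps = [CopyNumberProfile(small_grid, [2] * 10 + [3] * 6, f"s{i}") for i in range(3)]
        assert divergence(ps)["mean"] == 0.0

    def test_mean_equals_average_of_matrix(self, small_grid, rng):
        ps = [random_profile(small_grid, rng, sample_id=f"s{i}") for i in range(4)]
        d = divergence(ps, metric="GeneticDistance")
        m = pairwise_matrix(ps, metric="GeneticDistance").to_numpy()
        iu = np.triu_indices(4, k=1)
        assert d["mean"] == pytest.approx(m[iu].mean())

    def test_cross_set_uses_all_cross_pairs(self, small_grid, rng):
        a = [random_profile(small_grid, rng, sample_id=f"a{i}") for i in range(2)]
        b = [random_profile(small_grid, rng, sample_id=f"b{i}") for i in range(3)]
        d = divergence(a, b, metric="GeneticDistance")
        assert d["n_pairs"] == 6


class TestProportionSubclonal:
    def test_identical_partly_altered_is_zero(self, small_grid):
        cn = [2] * 10 + [3] * 6
        ps = [CopyNumberProfile(small_grid, cn, f"s{i}") for i in range(3)]
        assert proportion_subclonal(ps) == 0.0

    def test_fully_private_alterations_is_one(self):
        g = BinGrid.uniform({"chr1": 100}, 10)
        a = CopyNumberProfile(g, [3] * 2 + [2] * 8, "a")
        b = CopyNumberProfile(g, [2] * 8 + [3] * 2, "b")
        assert proportion_subclonal([a, b]) == 1.0

    def test_requires_two_samples(self, small_grid):
        with pytest.raises(ValueError):
            proportion_subclonal([CopyNumberProfile(small_grid, np.full(16, 2))])


class TestMeanPGADifference:
    def test_identical_sets_zero(self, small_grid, rng):
        ps = [random_profile(small_grid, rng, sample_id=f"s{i}") for i in range(3)]
        within = mean_pga_difference(ps)
        assert within >= 0.0

    def test_single_pair_in_percentage_points(self):
        g = BinGrid.uniform({"chr1": 1000}, 10)
        a = CopyNumberProfile(g, [3] * 10 + [2] * 90, "a")  # PGA 0.10
        b = CopyNumberProfile(g, [3] * 20 + [2] * 80, "b")  # PGA 0.20
        assert mean_pga_difference([a], [b]) == pytest.approx(10.0)

    def test_matches_double_loop(self, small_grid, rng):
        a = [random_profile(small_grid, rng, sample_id=f"a{i}") for i in range(3)]
        b = [random_profile(small_grid, rng, sample_id=f"b{i}") for i in range(2)]
        expected = np.mean(
            [
                abs(x.pga() - y.pga()) * 100
                for x in a
                for y in b
            ]
        )
        assert mean_pga_difference(a, b) == pytest.approx(expected)
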