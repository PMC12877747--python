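"""Birth-death simulator: rates, event draws, dynamics, genealogy."""

import numpy as np
import pytest

from cnaevo.divergence import divergence
from cnaevo.grid import CopyNumberProfile
from cnaevo.simulate import (
    CNASizeSampler,
    FitnessLandscape,
    SimConfig,
    bottleneck,
    draw_cnas,
    net_growth,
    sample_glands,
    simulate,
)
from cnaevo.synth import default_grid


@pytest.fixture(scope="module")
def grid():
    return default_grid()  # 22 autosomes, 10 Mb bins


@pytest.fixture(scope="module")
def go(grid):
    return CopyNumberProfile(grid, np.full(grid.n_bins, 2), "go")


class TestNetGrowth:
    def test_optimum_attains_max_growth(self, go):
        land = FitnessLandscape(go=go, alpha=3.0, b0=1.0, d0=0.2)
        b, d = net_growth(go, land)
        assert b - d == pytest.approx(0.8)

    def test_flat_landscape_ignores_karyotype(self, grid, go, rng):
        land = FitnessLandscape(go=go, alpha=0.0, b0=1.0, d0=0.2)
        k = CopyNumberProfile(grid, rng.integers(0, 6, grid.n_bins), "k")
        b, d = net_growth(k, land)
        assert b - d == pytest.approx(0.8)

    def test_formula_substitution(self, grid, go):
        land = FitnessLandscape(go=go, alpha=1.0, b0=1.0, d0=0.5)
        cn = go.cn.copy()
        cn[0] += 1  # distance 1
        b, d = net_growth(CopyNumberProfile(grid, cn, "k"), land)
        assert b - d == pytest.approx(0.25)

    def test_death_mode_keeps_birth_fixed(self, grid, go):
        land = FitnessLandscape(go=go, alpha=1.0, b0=1.0, d0=0.2, mode="death")
        cn = go.cn.copy()
        cn[:5] += 1
        b, d = net_growth(CopyNumberProfile(grid, cn, "k"), land)
        assert b == pytest.approx(1.0)
        assert d >= 0.0


class TestDrawCNAs:
    def test_mu_zero_always_empty(self, grid, rng):
        s = CNASizeSampler()
        assert all(draw_cnas(0.0, s, grid, rng) == [] for _ in range(100))

    def test_events_never_span_chromosomes(self, grid, rng):
        s = CNASizeSampler()
        slices = list(grid.chrom_slices().values())
        for _ in range(2000):
            for ev in draw_cnas(1.0, s, grid, rng):
                assert any(sl.start <= ev.start and ev.end <= sl.stop for sl in slices)
                assert ev.delta in (-1, 1)

    def test_poisson_event_rate_moment(self, grid):
        rng = np.random.default_rng(7)
        s = CNASizeSampler()
        mu = 0.2
        n = 30_000
        counts = [len(draw_cnas(mu, s, grid, rng)) for _ in range(n)]
        se = np.sqrt(mu / n)
        assert abs(np.mean(counts) - mu) < 3 * se

    def test_empirical_sampler(self, grid, rng):
        s = CNASizeSampler.from_empirical([3, 3, 3])
        for _ in range(50):
            for ev in draw_cnas(1.0, s, grid, rng):
                assert 1 <= ev.end - ev.start <= 3


class TestSimulate:
    def test_mu_zero_conserves_founder_exactly(self, go):
        land = FitnessLandscape(go=go, alpha=0.0)
        cfg = SimConfig(landscape=land, mu=0.0, n_target=200)
        res = simulate(cfg, 5)
        assert res.outcome == "reached_target"
        for c in res.alive_clones():
            assert np.array_equal(res.clone_cn[c], go.cn)
        assert divergence(sample_glands(res, 20, 1))["mean"] == 0.0

    def test_seed_reproducibility(self, go):
        land = FitnessLandscape(go=go, alpha=1.0)
        cfg = SimConfig(landscape=land, mu=0.3, n_target=300)
        r1 = simulate(cfg, 42)
        r2 = simulate(cfg, 42)
        assert r1.outcome == r2.outcome
        assert np.array_equal(r1.counts, r2.counts)
        assert all(
            np.array_equal(a, b) for a, b in zip(r1.clone_cn, r2.clone_cn)
        )

    def test_divergence_increases_with_mutation_rate(self, go):
        land = FitnessLandscape(go=go, alpha=0.0)
        means = []
        for mu in (0.1, 0.4):
            vals = []
            for seed in range(4):
                res = simulate(
                    SimConfig(landscape=land, mu=mu, n_target=400), 100 + seed
                )
                if res.outcome != "reached_target":
                    continue
                glands = sample_glands(res, 40, seed)
                vals.append(divergence(glands, metric="GeneticDistance")["mean"])
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_event_log_replay_reconstructs_karyotypes(self, go):
        land = FitnessLandscape(go=go, alpha=0.5)
        res = simulate(SimConfig(landscape=land, mu=0.5, n_target=300), 11)
        assert res.outcome == "reached_target"
        check = res.alive_clones()[:20]
        for c in check:
            assert np.array_equal(res.replay_clone(int(c)), res.clone_cn[c])

    def test_extinction_is_an_outcome_not_an_error(self, go):
        land = FitnessLandscape(go=go, alpha=0.0, b0=0.5, d0=0.45)
        for seed in range(30):
            res = simulate(SimConfig(landscape=land, mu=0.1, n_target=500), seed)
            if res.outcome == "extinct":
                assert res.population_size == 0
                return
        pytest.fail("no extinction in 30 near-critical runs")

    def test_convergence_toward_distant_optimum(self, grid, go):
        # founder diploid, optimum = diploid + chr18 gain: the population
        # climbs toward the optimum once the matching whole-chromosome gain
        # arises and sweeps.  Started from a small founder population so the
        # near-critical diploid lineage does not simply die out.
        sl = grid.chrom_slices()["chr18"]
        opt_cn = go.cn.copy()
        opt_cn[sl] = 3
        opt = CopyNumberProfile(grid, opt_cn, "opt")
        land = FitnessLandscape(go=opt, alpha=2.0)
        cfg = SimConfig(landscape=land, mu=0.2, founder=go, n_target=30_000)
        d0 = np.abs(go.cn - opt.cn).sum()
        dists, frac_opt = [], []
        for seed in range(3):
            res = simulate(cfg, 300 + seed, initial=[(go.cn, 200)])
            assert res.outcome == "reached_target"
            alive = res.alive_clones()
            w = res.counts[alive]
            d = np.array([np.abs(res.clone_cn[c] - opt.cn).sum() for c in alive])
            dists.append(np.average(d, weights=w))
            frac_opt.append(w[d <= 2].sum() / w.sum())
        assert np.mean(dists) < d0
        assert np.mean(frac_opt) > 0.3  # the optimum sweeps to high frequency


@pytest.fixture(scope="module")
def result(go):
    land = FitnessLandscape(go=go, alpha=0.0)
    return simulate(SimConfig(landscape=land, mu=0.4, n_target=500), 21)


class TestSamplingAndBottleneck:

    def test_full_population_sample(self, result):
        glands = sample_glands(result, result.population_size, 1)
        assert len(glands) == result.population_size

    def test_same_seed_same_sample(self, result):
        a = sample_glands(result, 30, 9)
        b = sample_glands(result, 30, 9)
        assert all(np.array_equal(x.cn, y.cn) for x, y in zip(a, b))

    def test_oversampling_rejected(self, result):
        with pytest.raises(ValueError):
            sample_glands(result, result.population_size + 1, 0)

    def test_full_bottleneck_is_identity_in_size(self, result):
        init = bottleneck(result, result.population_size, 3)
        assert sum(c for _, c in init) == result.population_size

    def test_bottleneck_reduces_diversity(self, result, go):
        pre = divergence(sample_glands(result, 50, 2), metric="GeneticDistance")["mean"]
        post_vals = []
        for seed in range(5):
            init = bottleneck(result, 10, seed)
            land = result.config.landscape
            regrow = simulate(
                SimConfig(landscape=land, mu=0.0, n_target=500),
                seed,
                initial=init,
            )
            post = divergence(
                sample_glands(regrow, 50, seed), metric="GeneticDistance"
            )["mean"]
            post_vals.append(post)
        assert np.mean(post_vals) <= pre
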