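import math

import numpy as np
import pytest

from clinepool.diversity import (
    WindowGrid,
    pi_site,
    pi_site_biallelic,
    tajimas_d,
    theta_site,
    watterson_denominator,
    window_average,
)


def brute_force_astar(n: int, M: int, b: int) -> float:
    """Independent double-sum oracle for the detectability-corrected
    Watterson denominator, written from the definition with math.comb."""
    total = 0.0
    for i in range(1, n):
        inner = 0.0
        for k in range(b, M - b + 1):
            inner += math.comb(M, k) * (i / n) ** k * (1 - i / n) ** (M - k)
        total += inner / i
    return total


class TestPiSite:
    def test_hand_computed_example(self):
        # 2A + 2T reads, coverage 4, pool of 10 chromosomes
        val = pi_site(np.array([2.0, 2.0, 0.0, 0.0]), np.array(4.0), 10)
        assert val == pytest.approx((10 / 9) * (4 / 3) * 0.5)
        assert val == pytest.approx(0.7407407407)

    def test_monomorphic_site_is_zero(self):
        assert pi_site(np.array([7.0, 0, 0, 0]), np.array(7.0), 50) == 0.0

    def test_large_sample_limit_is_heterozygosity(self):
        val = pi_site(np.array([5e5, 5e5, 0, 0]), np.array(1e6), 10**6)
        assert val == pytest.approx(0.5, rel=1e-4)

    def test_coverage_below_two_is_nan(self):
        assert np.isnan(pi_site(np.array([1.0, 0, 0, 0]), np.array(1.0), 10))

    def test_monte_carlo_unbiased_for_population_heterozygosity(self):
        # two-stage sampling: k ~ Bin(n, p), reads ~ Bin(M, k/n)
        rng = np.random.default_rng(42)
        n, M, p, reps = 30, 40, 0.3, 200_000
        k = rng.binomial(n, p, reps)
        minor = rng.binomial(M, k / n)
        est = pi_site_biallelic(M - minor, minor, n)
        truth = 2 * p * (1 - p)
        se = est.std() / np.sqrt(reps)
        assert abs(est.mean() - truth) < 3 * se


class TestWattersonDenominator:
    def test_minimal_case_by_enumeration(self):
        # n=2, M=2, b=1: (1/1) * P(K=1), K ~ Bin(2, 1/2) -> 0.5
        assert watterson_denominator(2, 2, 1) == pytest.approx(0.5)

    def test_approaches_harmonic_number_at_high_coverage(self):
        n = 10
        harm = sum(1 / i for i in range(1, n))
        assert watterson_denominator(n, 5000, 1) == pytest.approx(harm, rel=1e-3)

    @pytest.mark.parametrize("n,M,b", [(4, 10, 2), (7, 25, 1), (12, 33, 3), (20, 50, 2)])
    def test_matches_brute_force_double_sum(self, n, M, b):
        assert watterson_denominator(n, M, b) == pytest.approx(
            brute_force_astar(n, M, b), rel=1e-10
        )

    def test_invalid_min_count_raises(self):
        with pytest.raises(ValueError):
            watterson_denominator(10, 10, 6)

    def test_theta_recovers_simulation_theta(self):
        """Sites polymorphic at rate theta/i for derived class i; the
        detectability-corrected estimator recovers theta."""
        rng = np.random.default_rng(5)
        n, theta, b, n_sites = 40, 0.02, 2, 100_000
        i = np.arange(1, n)
        rate = theta / i
        classes = rng.choice(np.append(i, 0), p=np.append(rate, 1 - rate.sum()),
                             size=n_sites)
        M = rng.poisson(45, n_sites)
        M = np.clip(M, 2 * b, None)
        reads = rng.binomial(M, classes / n)
        minor = np.minimum(reads, M - reads)
        est = theta_site(minor, M, n, b=b)
        rec = np.nanmean(est)
        assert rec == pytest.approx(theta, rel=0.05)


class TestTajimasD:
    def test_balanced_frequencies_give_positive_d(self):
        # many intermediate-frequency sites: pi exceeds theta_W -> D > 0
        maj = np.full(200, 20)
        mnr = np.full(200, 20)
        assert tajimas_d(maj, mnr, 50, target_coverage=25, seed=1) > 0

    def test_singleton_excess_gives_negative_d(self):
        rng = np.random.default_rng(2)
        M = np.full(500, 40)
        mnr = rng.binomial(M, 0.03)  # star-genealogy-like rare variants
        assert tajimas_d(M - mnr, mnr, 50, target_coverage=25, seed=1) < 0

    def test_subsampling_is_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        M = np.full(300, 40)
        mnr = rng.binomial(M, 0.2)
        d1 = tajimas_d(M - mnr, mnr, 50, seed=11)
        d2 = tajimas_d(M - mnr, mnr, 50, seed=11)
        assert d1 == d2

    def test_no_segregating_sites_is_nan(self):
        assert np.isnan(tajimas_d(np.full(10, 30), np.zeros(10, int), 50, seed=0))


class TestWindowAverage:
    def test_simple_mean_when_all_sites_valid(self):
        out = window_average(
            np.array(["2L"] * 4), np.array([10, 20, 199_990, 200_010]),
            np.array([1.0, 3.0, 5.0, 7.0]), WindowGrid(200_000),
        )
        assert len(out) == 2
        assert out.loc[0, "mean_value"] == pytest.approx(3.0)
        assert out.loc[1, "mean_value"] == pytest.approx(7.0)
        assert out["valid"].all()

    def test_sixty_percent_validity_rule(self):
        vals = np.arange(10, dtype=float)
        valid = np.array([True] * 5 + [False] * 5)  # 50% < 60%
        out = window_average(
            np.array(["2L"] * 10), np.arange(1, 11) * 100, vals,
            WindowGrid(200_000), valid=valid,
        )
        assert not out.loc[0, "valid"]
        assert out.loc[0, "n_valid"] == 5
        # mean over the valid sites only
        assert out.loc[0, "mean_value"] == pytest.approx(vals[:5].mean())

    def test_windows_do_not_overlap_and_skip_empty(self):
        out = window_average(
            np.array(["2L", "2L"]), np.array([100, 600_001]),
            np.array([1.0, 2.0]), WindowGrid(200_000),
        )
        assert out["start"].tolist() == [1, 600_001]
        assert (out["end"] - out["start"] + 1 == 200_000).all()
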