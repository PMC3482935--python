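import numpy as np
import pandas as pd
import pytest

from clinepool.io_formats import MaskSet, PoolProfile
from clinepool.site_filtering import (
    FilterConfig,
    SnpTable,
    call_snps,
    compute_coverage_caps,
)


def make_sites(count_rows):
    """count_rows: list of per-pool A,T,C,G count 4-tuples per site."""
    counts = np.zeros((len(count_rows), len(count_rows[0]), 6), dtype=np.int64)
    for i, pools in enumerate(count_rows):
        for j, c in enumerate(pools):
            counts[i, j, :4] = c
    sites = pd.DataFrame(
        {"arm": "2L", "position": np.arange(1, len(count_rows) + 1) * 100,
         "ref": "A"}
    )
    return sites, counts


@pytest.fixture
def pools2():
    return [PoolProfile("A", 10.0, 20), PoolProfile("B", 20.0, 30)]


class TestCoverageCaps:
    def test_uniform_coverages_give_order_statistic_cap(self):
        counts = np.zeros((100, 1, 6), dtype=np.int64)
        counts[:, 0, 0] = np.arange(1, 101)  # coverage 1..100
        cap = compute_coverage_caps(counts, 0.02)
        assert cap[0] == pytest.approx(98.02)  # linear-interpolation quantile

    def test_constant_coverage_caps_at_that_value(self):
        counts = np.full((50, 2, 6), 0, dtype=np.int64)
        counts[:, :, 0] = 45
        assert np.allclose(compute_coverage_caps(counts, 0.02), 45)

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            compute_coverage_caps(np.zeros((0, 1, 6), dtype=np.int64))


class TestCallSnps:
    def test_pooled_minor_count_boundary_at_six(self, pools2):
        sites, counts = make_sites([
            [(60, 3, 0, 0), (60, 3, 0, 0)],   # pooled T = 6 -> SNP
            [(61, 2, 0, 0), (60, 3, 0, 0)],   # pooled T = 5 -> not polymorphic
        ])
        snps = call_snps(sites, counts, pools2, FilterConfig(max_coverage_quantile=0.01))
        assert snps.positions.tolist() == [100]
        assert snps.frame.loc[0, ["major", "minor"]].tolist() == ["A", "T"]

    def test_multiallelic_keeps_two_most_frequent_and_flags(self, pools2):
        sites, counts = make_sites([
            [(25, 15, 4, 0), (25, 15, 4, 0)],  # A=50 T=30 C=8
        ])
        snps = call_snps(sites, counts, pools2, FilterConfig(max_coverage_quantile=0.01))
        row = snps.frame.iloc[0]
        assert (row["major"], row["minor"]) == ("A", "T")
        assert bool(row["multiallelic"])
        assert snps.major_counts[0].tolist() == [25, 25]
        assert snps.minor_counts[0].tolist() == [15, 15]

    def test_major_minor_ties_break_alphabetically(self, pools2):
        sites, counts = make_sites([
            [(0, 20, 0, 20), (0, 0, 0, 0)],  # T=20, G=20 tie -> major G (alphabetical)
        ])
        counts[0, 1, :4] = [10, 0, 0, 0]
        snps = call_snps(sites, counts, pools2, FilterConfig(max_coverage_quantile=0.01))
        row = snps.frame.iloc[0]
        assert (row["major"], row["minor"]) == ("G", "T")

    def test_low_coverage_pool_drops_site(self, pools2):
        sites, counts = make_sites([
            [(4, 5, 0, 0), (40, 10, 0, 0)],    # pool A coverage 9 < 10
            [(30, 10, 0, 0), (40, 10, 0, 0)],
        ])
        snps = call_snps(sites, counts, pools2,
                         FilterConfig(max_coverage_quantile=0.01),
                         caps=np.array([100, 100]))
        assert snps.positions.tolist() == [200]

    def test_region_masks_include_and_exclude(self, pools2):
        sites, counts = make_sites([[(30, 10, 0, 0), (30, 10, 0, 0)]] * 4)
        cfg = FilterConfig(
            max_coverage_quantile=0.01,
            region_include=MaskSet.from_intervals({"2L": [(100, 300)]}),
            region_exclude=MaskSet.from_intervals({"2L": [(200, 200)]}),
        )
        snps = call_snps(sites, counts, pools2, cfg)
        assert snps.positions.tolist() == [100, 300]

    def test_filtering_is_idempotent_subset(self, pools2):
        rng = np.random.default_rng(0)
        n = 500
        counts = np.zeros((n, 2, 6), dtype=np.int64)
        counts[:, :, 0] = rng.poisson(40, (n, 2))
        counts[:, :, 1] = rng.poisson(6, (n, 2))
        sites = pd.DataFrame({"arm": "2L", "position": np.arange(1, n + 1), "ref": "A"})
        cfg = FilterConfig()
        first = call_snps(sites, counts, pools2, cfg)
        assert set(first.positions) <= set(sites["position"])
        # re-filter the surviving sites with the same caps: nothing changes
        caps = compute_coverage_caps(counts, cfg.max_coverage_quantile)
        surviving = np.isin(sites["position"], first.positions)
        again = call_snps(sites[surviving].reset_index(drop=True),
                          counts[surviving], pools2, cfg, caps=caps)
        assert again.positions.tolist() == first.positions.tolist()


class TestSnpTableRoundTrip:
    def test_to_frame_from_frame_round_trip(self, pools2):
        sites, counts = make_sites([
            [(30, 10, 0, 0), (35, 6, 0, 0)],
            [(20, 20, 0, 0), (25, 15, 0, 0)],
        ])
        snps = call_snps(sites, counts, pools2, FilterConfig(max_coverage_quantile=0.01))
        back = SnpTable.from_frame(snps.to_frame(), pools2)
        assert np.array_equal(back.coverage, snps.coverage)
        assert np.array_equal(back.minor_counts, snps.minor_counts)
        assert back.frame.equals(snps.frame)


def test_planted_snps_pass_filter_on_clean_synthetic_data():
    """With no sequencing error and adequate coverage, nearly all planted
    SNPs whose expected pooled minor count is >= 3x the threshold pass."""
    from clinepool.synthetic_data import SimConfig, simulate_study
    from clinepool.site_filtering import FilterConfig, call_snps

    cfg = SimConfig(seed=21, arms={"2L": 4000}, error_rate=0.0, clinal_fraction=0.2)
    truth, sites, counts, _ = simulate_study(cfg)
    tf = truth.frame
    m = (truth.freqs * 45).sum(axis=1)  # expected pooled count of the truth allele
    total = 45 * 3
    strong = np.minimum(m, total - m) >= 3 * 6  # rarer allele well above threshold
    # wide coverage caps: the property concerns the allele-count filter
    snps = call_snps(sites, counts, cfg.pools,
                     FilterConfig(max_coverage_quantile=0.001))
    called = set(zip(snps.arms, snps.positions))
    hit = np.array([
        (a, p) in called for a, p in zip(tf["arm"], tf["position"])
    ])
    assert hit[strong].mean() >= 0.99
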