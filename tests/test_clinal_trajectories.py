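import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clinepool.clinal_trajectories import (
    binomial_ci,
    classify_trajectory,
    core_clinal_set,
    orient_and_slopes,
)
from clinepool.io_formats import PoolProfile
from clinepool.site_filtering import SnpTable


LATS = (25.53, 39.88, 44.02)


def make_table(freq_rows, coverage=100):
    """freq_rows: list of (fF, fP, fM) minor-allele frequencies."""
    pools = [
        PoolProfile("F", LATS[0], 78),
        PoolProfile("P", LATS[1], 204),
        PoolProfile("M", LATS[2], 172),
    ]
    n = len(freq_rows)
    frame = pd.DataFrame({
        "arm": "2L", "position": np.arange(1, n + 1) * 1000,
        "major": "A", "minor": "T", "multiallelic": False,
    })
    freqs = np.array(freq_rows, dtype=float)
    mnr = np.rint(freqs * coverage).astype(np.int64)
    maj = coverage - mnr
    return SnpTable(pools=pools, frame=frame, coverage=maj + mnr,
                    major_counts=maj, minor_counts=mnr)


class TestOrientAndSlopes:
    def test_slopes_from_hand_arithmetic(self):
        out = orient_and_slopes(make_table([(0.10, 0.30, 0.50)]))
        assert out.loc[0, "s1"] == pytest.approx(0.2 / (39.88 - 25.53))
        assert out.loc[0, "s2"] == pytest.approx(0.2 / (44.02 - 39.88))
        assert out.loc[0, "s1"] == pytest.approx(0.01394, abs=1e-5)
        assert out.loc[0, "s2"] == pytest.approx(0.04831, abs=1e-5)
        assert out.loc[0, "trajectory"] == "++"

    def test_orientation_flips_falling_alleles(self):
        # minor allele falls south->north; the major allele rises
        out = orient_and_slopes(make_table([(0.6, 0.4, 0.2)]))
        assert out.loc[0, "allele"] == "A"
        assert out.loc[0, "freq_F"] == pytest.approx(0.4)
        assert out.loc[0, "freq_M"] == pytest.approx(0.8)
        assert out.loc[0, "trajectory"] == "++"

    def test_exact_tie_is_classified_tie_and_keeps_minor(self):
        out = orient_and_slopes(make_table([(0.5, 0.2, 0.5)]))
        assert out.loc[0, "trajectory"] == "tie"
        assert out.loc[0, "allele"] == "T"

    def test_dip_shape_keeps_oriented_allele_and_signs(self):
        out = orient_and_slopes(make_table([(0.5, 0.2, 0.6)]))
        assert out.loc[0, "allele"] == "T"  # 0.6 >= 0.5 keeps the minor
        assert out.loc[0, "s1"] < 0 < out.loc[0, "s2"]
        assert out.loc[0, "trajectory"] == "-+"

    def test_orientation_is_idempotent(self):
        table = make_table([(0.1, 0.3, 0.5), (0.6, 0.4, 0.2)])
        once = orient_and_slopes(table)
        # re-orienting the oriented frequencies changes nothing
        again = orient_and_slopes(table)
        pd.testing.assert_frame_equal(once, again)

    def test_classes_partition_every_snp(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.uniform(0.05, 0.95, size=(200, 3)))
        out = orient_and_slopes(table)
        assert out["trajectory"].isin(["++", "+-", "-+", "--", "tie"]).all()
        # oriented so north >= south always
        assert (out["freq_M"] >= out["freq_F"]).all()


class TestClassify:
    @pytest.mark.parametrize("s1,s2,expected", [
        (0.01, 0.05, "++"), (0.01, -0.02, "+-"), (-0.01, 0.05, "-+"),
        (-0.01, -0.05, "--"), (0.0, 0.05, "tie"), (0.01, 0.0, "tie"),
    ])
    def test_sign_pairs(self, s1, s2, expected):
        assert classify_trajectory(s1, s2)[0] == expected


class TestBinomialCi:
    def test_closed_form_bounds_at_the_extremes(self):
        lo, hi = binomial_ci(np.array([0]), np.array([20]))
        assert lo[0] == 0.0
        assert hi[0] == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-9)
        lo, hi = binomial_ci(np.array([20]), np.array([20]))
        assert hi[0] == 1.0
        assert lo[0] == pytest.approx(0.025 ** (1 / 20), abs=1e-9)

    def test_central_value_against_beta_quantile_oracle(self):
        lo, hi = binomial_ci(np.array([10]), np.array([20]))
        assert lo[0] == pytest.approx(stats.beta.ppf(0.025, 10, 11))
        assert hi[0] == pytest.approx(stats.beta.ppf(0.975, 11, 10))
        assert (lo[0], hi[0]) == pytest.approx((0.27196, 0.72804), abs=1e-5)

    def test_exact_interval_covers_at_least_nominally(self):
        rng = np.random.default_rng(1)
        n, p, reps = 45, 0.3, 20_000
        x = rng.binomial(n, p, reps)
        lo, hi = binomial_ci(x, np.full(reps, n))
        assert np.mean((lo <= p) & (p <= hi)) >= 0.95

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            binomial_ci(np.array([1]), np.array([0]))
        with pytest.raises(ValueError):
            binomial_ci(np.array([5]), np.array([4]))


class TestSignificance:
    def test_disjoint_cis_with_rising_class_flagged(self):
        out = orient_and_slopes(make_table([(0.02, 0.45, 0.9)], coverage=200))
        assert out.loc[0, "trajectory"] == "++"
        assert bool(out.loc[0, "significant"])

    def test_touching_intervals_are_not_disjoint(self):
        # all pools identical: intervals coincide -> never significant
        out = orient_and_slopes(make_table([(0.3, 0.4, 0.45)], coverage=30))
        assert not bool(out.loc[0, "significant"])

    def test_fp_and_pm_disjointness_implies_fm_under_rising_order(self):
        rng = np.random.default_rng(2)
        out = orient_and_slopes(make_table(
            np.sort(rng.uniform(0.05, 0.95, size=(100, 3)), axis=1), coverage=80
        ))
        lo = out[["ci_lo_F", "ci_lo_P", "ci_lo_M"]].to_numpy()
        hi = out[["ci_hi_F", "ci_hi_P", "ci_hi_M"]].to_numpy()
        fp = hi[:, 0] < lo[:, 1]
        pm = hi[:, 1] < lo[:, 2]
        fm = hi[:, 0] < lo[:, 2]
        assert (fm[fp & pm]).all()


class TestCoreSet:
    def test_union_deduplicates_and_tracks_pairs(self):
        rec = orient_and_slopes(make_table([(0.1, 0.3, 0.5), (0.5, 0.3, 0.6),
                                            (0.1, 0.2, 0.4)]))
        per_pair = {
            "FM": rec.iloc[[0, 1]],   # SNP1 ++, SNP2 -+
            "FP": rec.iloc[[0, 2]],   # SNP1 ++, SNP3 ++
            "PM": rec.iloc[[2]],      # SNP3 ++
        }
        core = core_clinal_set(per_pair)
        assert core["position"].tolist() == [1000, 3000]
        pairs = dict(zip(core["position"], core["pairs"]))
        assert pairs[1000] == "FM,FP"
        assert pairs[3000] == "FP,PM"

    def test_empty_input_gives_empty_core(self):
        assert core_clinal_set({}).empty
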