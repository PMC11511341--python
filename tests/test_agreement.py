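"""agreement module: BA, RMSE, r, ICC, rm-ANOVA, Cohen's d, curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cmjkit import (
    bland_altman,
    cohens_d_from_summary,
    cohens_d_harmonic,
    compare_tables,
    icc_3_1,
    pearson_r,
    rm_anova_2way,
    rmse,
    time_normalize,
    trajectory_agreement,
)
from cmjkit.agreement import harmonic_mean_sd
from cmjkit.errors import StatsError


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.sd_diff == 0.0
        assert ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_unit_sd_differences(self):
        # differences {-1, 0, 1}: bias 0, sd 1, LoA exactly +/-1.96
        x = np.zeros(3)
        y = np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(x, y)
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_lower == pytest.approx(-1.96)
        assert ba.loa_upper == pytest.approx(1.96)

    def test_ci_formulas_match_brute_force(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(0.1, 0.2, size=25)
        ba = bland_altman(x, y)
        d = y - x
        n = len(d)
        sd = d.std(ddof=1)
        t = sps.t.ppf(0.975, n - 1)
        assert ba.bias_ci == pytest.approx(
            (d.mean() - t * sd / np.sqrt(n), d.mean() + t * sd / np.sqrt(n))
        )
        half = t * sd * np.sqrt(3.0 / n)
        assert ba.loa_upper_ci == pytest.approx(
            (d.mean() + 1.96 * sd - half, d.mean() + 1.96 * sd + half)
        )

    @given(st.floats(-5, 5), st.integers(0, 2**31 - 1))
    def test_translation_equivariance(self, k, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=10)
        y = x + r.normal(size=10)
        b0 = bland_altman(x, y)
        b1 = bland_altman(x, y + k)
        assert b1.bias == pytest.approx(b0.bias + k, abs=1e-9)
        assert b1.sd_diff == pytest.approx(b0.sd_diff, abs=1e-9)

    def test_length_mismatch_and_nan_raise(self):
        with pytest.raises(StatsError):
            bland_altman([1, 2, 3], [1, 2])
        with pytest.raises(StatsError):
            bland_altman([1, 2, np.nan], [1, 2, 3])


class TestRmse:
    def test_hand_example(self):
        # differences 3 and 4 -> sqrt(25/2)
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(3.5355339059)

    def test_decomposition_identity(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(0.3, 0.5, size=30)
        d = y - x
        n = len(d)
        lhs = rmse(x, y) ** 2
        rhs = d.mean() ** 2 + (n - 1) / n * d.std(ddof=1) ** 2
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestPearsonR:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_brute_formula(self, rng):
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12)
        r = pearson_r(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r.r == pytest.approx(num / den, rel=1e-12)
        z = np.arctanh(r.r)
        half = sps.norm.ppf(0.975) / np.sqrt(len(x) - 3)
        assert r.ci == pytest.approx((np.tanh(z - half), np.tanh(z + half)))

    def test_magnitude_labels(self, rng):
        x = np.arange(200.0)
        for target, label in ((0.1, "negligible"), (0.4, "low"), (0.6, "moderate"),
                              (0.8, "high"), (0.95, "very high")):
            # construct a sample with (nearly) the target correlation
            noise = rng.standard_normal(200)
            noise -= np.polyval(np.polyfit(x, noise, 1), x)  # orthogonal to x
            xs = (x - x.mean()) / x.std()
            ns = noise / noise.std()
            y = target * xs + np.sqrt(1 - target**2) * ns
            assert pearson_r(x, y).label == label

    def test_zero_variance_raises(self):
        with pytest.raises(StatsError, match="variance"):
            pearson_r([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestIcc:
    def brute_icc31(self, r):
        n, k = r.shape
        grand = r.mean()
        bms = k * ((r.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        jms = n * ((r.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        ems = (((r - grand) ** 2).sum() - bms * (n - 1) - jms * (k - 1)) / ((n - 1) * (k - 1))
        return (bms - ems) / (bms + (k - 1) * ems)

    def test_perfect_agreement(self):
        r = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_3_1(r).icc == pytest.approx(1.0)

    def test_constant_offset_does_not_lower_consistency_icc(self):
        a = np.arange(6.0)
        assert icc_3_1(np.column_stack([a, a + 0.5])).icc == pytest.approx(1.0)

    def test_matches_brute_mean_squares(self, rng):
        r = rng.normal(size=(10, 2)) + np.arange(10)[:, None]
        res = icc_3_1(r)
        assert res.icc == pytest.approx(self.brute_icc31(r), rel=1e-10)
        assert (res.df1, res.df2) == (9, 9)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        r = rng.normal(size=(12, 2)) + 2.0 * np.arange(12)[:, None]
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["A", "B"], 12),
                "scores": r.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        res = icc_3_1(r)
        # "ICC(C,1)": consistency, single measures = ICC(3,1)
        assert res.icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(C,1)", "CI95"]
        assert res.ci[0] == pytest.approx(lo, abs=0.006)  # pingouin rounds to 2dp
        assert res.ci[1] == pytest.approx(hi, abs=0.006)

    def test_degenerate_tables_raise(self):
        with pytest.raises(StatsError):
            icc_3_1(np.ones((5, 2)))
        with pytest.raises(StatsError):
            icc_3_1(np.zeros((2, 2)))


def make_long_table(rng, nc=10, method_shift=0.3, side_shift=0.0, noise=0.5):
    rows = []
    base = rng.normal(0.0, 2.0, size=nc)
    for ci, b in enumerate(base):
        for m in ("A", "B"):
            for s in ("left", "right"):
                val = (
                    b
                    + (method_shift if m == "B" else 0.0)
                    + (side_shift if s == "right" else 0.0)
                    + rng.normal(0.0, noise)
                )
                rows.append({"case": ci, "method": m, "side": s, "value": val})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        df = make_long_table(np.random.default_rng(1), noise=0.0, method_shift=0.0)
        res = rm_anova_2way(df)
        assert res.method.f == pytest.approx(0.0, abs=1e-9)
        assert res.side.f == pytest.approx(0.0, abs=1e-9)

    def test_ss_conservation(self, rng):
        df = make_long_table(rng)
        res = rm_anova_2way(df)
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert res.ss_total == pytest.approx(total, rel=1e-10)

    def test_case_relabeling_invariance(self, rng):
        df = make_long_table(rng)
        res1 = rm_anova_2way(df)
        df2 = df.copy()
        df2["case"] = df2["case"].map(lambda c: f"trial_{(c * 7) % 10:02d}")
        res2 = rm_anova_2way(df2)
        assert res2.method.f == pytest.approx(res1.method.f, rel=1e-10)
        assert res2.interaction.f == pytest.approx(res1.interaction.f, rel=1e-10)

    def test_matches_brute_force_decomposition(self, rng):
        df = make_long_table(rng, nc=8, method_shift=0.5, side_shift=-0.2)
        res = rm_anova_2way(df)
        piv = df.pivot_table(index="case", columns=["method", "side"], values="value")
        cube = piv.to_numpy().reshape(8, 2, 2)
        grand = cube.mean()
        ss = lambda m: float(((m - grand) ** 2).sum())
        ss_a = 8 * 2 * ss(cube.mean(axis=(0, 2)))
        ss_ca = 2 * ss(cube.mean(axis=2)) - 4 * ss(cube.mean(axis=(1, 2))) - ss_a
        f_method = (ss_a / 1) / (ss_ca / 7)
        assert res.method.f == pytest.approx(f_method, rel=1e-9)
        assert (res.method.df1, res.method.df2) == (1, 7)
        assert res.interaction.df2 == 7

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = make_long_table(rng, nc=12, method_shift=0.4, side_shift=0.3)
        res = rm_anova_2way(df)
        ref = pingouin.rm_anova(
            data=df, dv="value", within=["method", "side"], subject="case",
            detailed=True,
        ).set_index("Source")
        assert res.method.f == pytest.approx(ref.loc["method", "F"], rel=1e-6)
        assert res.side.f == pytest.approx(ref.loc["side", "F"], rel=1e-6)
        assert res.interaction.f == pytest.approx(
            ref.loc["method * side", "F"], rel=1e-6
        )
        assert res.method.p == pytest.approx(ref.loc["method", "p_unc"], abs=1e-9)

    def test_incomplete_design_raises(self, rng):
        df = make_long_table(rng).iloc[:-1]
        with pytest.raises(StatsError, match="complete"):
            rm_anova_2way(df)


class TestCohensD:
    def test_identical_groups_trivial(self, rng):
        g = rng.normal(size=20)
        d = cohens_d_harmonic(g, g)
        assert d.d == 0.0 and d.magnitude == "trivial"

    def test_published_summary_example(self):
        # means 0.243 (SD 0.038) vs 0.210 (SD 0.036), n = 60 each:
        # harmonic SD = 2*0.038*0.036/0.074 and d = -0.033 / that
        assert harmonic_mean_sd(0.038, 0.036) == pytest.approx(0.036973, abs=5e-7)
        d = cohens_d_from_summary(0.243, 0.038, 60, 0.210, 0.036, 60)
        assert d.d == pytest.approx(-0.8925, abs=5e-5)
        assert d.magnitude == "large"
        assert d.clearness == "clear"

    def test_sign_flips_under_group_exchange(self, rng):
        g1 = rng.normal(0.0, 1.0, size=15)
        g2 = rng.normal(0.5, 1.2, size=15)
        assert cohens_d_harmonic(g1, g2).d == pytest.approx(
            -cohens_d_harmonic(g2, g1).d
        )

    def test_equal_sds_reduce_to_plain_standardisation(self):
        d = cohens_d_from_summary(1.0, 0.5, 30, 1.6, 0.5, 30)
        assert d.d == pytest.approx(0.6 / 0.5)

    def test_se_formula(self):
        d = cohens_d_from_summary(0.0, 1.0, 20, 0.5, 1.0, 25)
        se = np.sqrt(45 / 500 + d.d**2 / 90)
        assert d.ci == pytest.approx((d.d - 1.96 * se, d.d + 1.96 * se))

    def test_unclear_call_requires_spanning_both_substantial_signs(self):
        wide = cohens_d_from_summary(0.0, 1.0, 4, 0.05, 1.0, 4)
        assert wide.clearness == "unclear"
        narrow = cohens_d_from_summary(0.0, 1.0, 2000, 0.05, 1.0, 2000)
        assert narrow.clearness == "clear"

    def test_magnitude_thresholds(self):
        for d_val, label in ((0.1, "trivial"), (0.3, "small"), (0.6, "moderate"),
                             (1.0, "large"), (1.5, "very large")):
            d = cohens_d_from_summary(0.0, 1.0, 50, d_val, 1.0, 50)
            assert d.magnitude == label

    def test_non_positive_sd_raises(self):
        with pytest.raises(StatsError):
            harmonic_mean_sd(0.0, 1.0)


class TestTimeNormalize:
    def test_constant(self):
        np.testing.assert_allclose(time_normalize(np.full(37, 2.0)), 2.0)

    def test_endpoints_and_linearity(self):
        y = np.linspace(3.0, 7.0, 23)
        out = time_normalize(y)
        assert len(out) == 101
        assert out[0] == 3.0 and out[-1] == 7.0
        np.testing.assert_allclose(out, np.linspace(3.0, 7.0, 101), atol=1e-12)

    def test_grid_coincidence_is_identity(self, rng):
        y = rng.normal(size=101)
        np.testing.assert_array_equal(time_normalize(y, 101), y)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            time_normalize([1.0])
        with pytest.raises(ValueError):
            time_normalize([1.0, 2.0], n_points=1)


class TestTrajectoryAgreement:
    def test_identical_curves(self, rng):
        c = rng.normal(size=(8, 101))
        res = trajectory_agreement(c, c)
        assert res.pooled.bias == 0.0
        assert res.pooled_rmse == 0.0
        np.testing.assert_allclose(res.mean_x, res.mean_y)

    def test_constant_offset_recovered_exactly(self, rng):
        c = rng.normal(size=(8, 101))
        res = trajectory_agreement(c, c + 0.02)
        assert res.pooled.bias == pytest.approx(0.02)
        assert res.pooled.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_ci_band_shrinks_with_trials(self, rng):
        c4 = rng.normal(size=(4, 50))
        c40 = rng.normal(size=(40, 50))
        w4 = np.mean(trajectory_agreement(c4, c4).ci_x[1] - trajectory_agreement(c4, c4).ci_x[0])
        w40 = np.mean(trajectory_agreement(c40, c40).ci_x[1] - trajectory_agreement(c40, c40).ci_x[0])
        assert w40 < w4

    def test_station_count_mismatch_raises(self):
        with pytest.raises(StatsError, match="station"):
            trajectory_agreement(np.zeros((3, 50)), np.zeros((3, 60)))


class TestCompareTables:
    def make_tables(self, rng, n_trials=12, shift=0.0, noise=0.0):
        rows_a, rows_b = [], []
        for k in range(n_trials):
            for side in ("left", "right"):
                base = rng.normal(0.3, 0.05)
                rows_a.append({"trial": f"t{k:02d}", "side": side, "subject": k // 3,
                               "jump_height_m": base})
                rows_b.append({"trial": f"t{k:02d}", "side": side, "subject": k // 3,
                               "jump_height_m": base + shift + rng.normal(0, noise)})
        return pd.DataFrame(rows_a), pd.DataFrame(rows_b)

    def test_self_comparison_is_perfect(self, rng):
        a, b = self.make_tables(rng)
        rep = compare_tables(a, a, ["jump_height_m"])
        assert set(rep["side"]) == {"left", "right"}
        assert (rep["bias"] == 0).all()
        assert np.allclose(rep["icc31"], 1.0, atol=1e-9)
        assert (rep["rmse"] == 0).all()
        assert rep["f_method"].eq(0).all()

    def test_known_shift_recovered_and_row_order_irrelevant(self, rng):
        a, b = self.make_tables(rng, shift=0.02, noise=0.005)
        rep1 = compare_tables(a, b, ["jump_height_m"])
        shuffled = b.sample(frac=1.0, random_state=3).reset_index(drop=True)
        rep2 = compare_tables(a, shuffled, ["jump_height_m"])
        assert rep1["bias"].iloc[0] == pytest.approx(0.02, abs=0.01)
        pd.testing.assert_frame_equal(rep1, rep2)

    def test_subject_mean_aggregation(self, rng):
        a, b = self.make_tables(rng, shift=0.02, noise=0.005)
        rep = compare_tables(a, b, ["jump_height_m"], aggregation="subject_mean")
        assert np.isfinite(rep["cohen_d"]).all()

    def test_orphan_keys_raise(self, rng):
        a, b = self.make_tables(rng)
        with pytest.raises(StatsError, match="unmatched"):
            compare_tables(a, b.iloc[:-1], ["jump_height_m"])
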