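"""Statistical battery: closed-form agreement and simulation behaviour."""

import numpy as np
import pandas as pd
import pytest

from megmarkers import (
    check_normality,
    fit_model,
    run_battery,
    welch_t_test,
    wilcoxon_rank_sum,
)


def welch_by_hand(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, df


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_toy_arrays(self):
        res = welch_t_test([1, 2, 3], [2, 4, 6])
        t, df = welch_by_hand([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        # hand values: t = -2/sqrt(5/3), df = 50/17
        assert res.statistic == pytest.approx(-1.549, abs=1e-3)
        assert res.df == pytest.approx(2.941, abs=1e-3)

    def test_translation_invariance(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12)
        r1, r2 = welch_t_test(a, b), welch_t_test(a + 100, b + 100)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestWilcoxon:
    def test_exact_enumeration_toy_arrays(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 3.0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-10)
        assert res.group_summary["p_method"] == "exact"

    def test_identical_multisets_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(9)
        r1 = wilcoxon_rank_sum(a, b)
        r2 = wilcoxon_rank_sum(np.exp(a), np.exp(b))
        assert r1.statistic == r2.statistic
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        a = np.round(rng.standard_normal(30), 1)
        b = np.round(rng.standard_normal(30), 1)
        res = wilcoxon_rank_sum(a, b)
        assert res.group_summary["p_method"] == "asymptotic"
        assert 0 <= res.p_value <= 1


class TestNormalityCheck:
    def test_gaussian_samples_usually_pass(self):
        verdicts = []
        for seed in range(40):
            x = np.random.default_rng(seed).standard_normal(200)
            verdicts.append(check_normality(x).verdict)
        assert np.mean(verdicts) >= 0.9

    def test_lognormal_samples_usually_fail(self):
        verdicts = []
        for seed in range(40):
            x = np.exp(np.random.default_rng(seed).standard_normal(200))
            verdicts.append(check_normality(x).verdict)
        assert np.mean(verdicts) <= 0.05

    def test_small_or_constant_input_inconclusive(self):
        assert check_normality([1.0, 2.0, 3.0]).verdict is None
        assert check_normality([2.0] * 50).verdict is None


def marker_frame(n=40, seed=0, group_shift_lz=0.0, group_shift_tar=0.0):
    rng = np.random.default_rng(seed)
    group = np.repeat(["control", "patient"], n // 2)
    lz = 0.6 + 0.02 * rng.standard_normal(n) - group_shift_lz * (group == "patient")
    tar = 1.0 + 0.3 * rng.standard_normal(n) + group_shift_tar * (group == "patient")
    return pd.DataFrame({
        "participant_id": [f"sub-{i:03d}" for i in range(n)],
        "group": group,
        "age": rng.integers(54, 84, n),
        "sex": rng.choice(["M", "F"], n),
        "site": np.tile(["CBU", "CTB"], n // 2),
        "mmse": rng.integers(20, 31, n),
        "lzsum": lz,
        "tar": tar,
    })


class TestFitModel:
    def test_perfect_linear_fit(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2.0 * np.arange(10.0)})
        res = fit_model(df, "y", ["x"])
        assert res.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_ols_matches_hand_computation(self):
        # simple regression: beta = cov(x,y)/var(x) on a fixed 5-point set
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        beta = np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1)
        alpha = y.mean() - beta * x.mean()
        r2 = 1 - ((y - alpha - beta * x) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        res = fit_model(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert res.coefficients["x"] == pytest.approx(beta, abs=1e-10)
        assert res.coefficients["Intercept"] == pytest.approx(alpha, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_null_predictors_give_flat_fits(self):
        nonsig = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"x": rng.standard_normal(200),
                               "y": rng.standard_normal(200)})
            res = fit_model(df, "y", ["x"])
            nonsig += res.f_pvalue > 0.05
        assert nonsig >= 36  # >= 90% of seeds

    def test_collinear_terms_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["z"] = 2 * df["x"]
        df["y"] = df["x"] + 1
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_model(df, "y", ["x", "z"])

    def test_missing_columns_named(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="nope"):
            fit_model(df, "y", ["nope"])

    def test_categorical_reference_is_control(self):
        df = marker_frame(n=60, seed=1, group_shift_lz=0.05)
        res = fit_model(df, "lzsum", ["group"])
        term = [k for k in res.coefficients if "patient" in k]
        assert len(term) == 1
        assert res.coefficients[term[0]] < 0  # patients lower than reference


class TestBattery:
    def test_report_structure_complete(self):
        report = run_battery(marker_frame(n=60, seed=2))
        assert set(report.group_tests) == {"lzsum", "tar"}
        assert report.group_tests["lzsum"]["test_name"] == "welch_t"
        assert report.group_tests["tar"]["test_name"] == "wilcoxon_rank_sum"
        expected_models = {
            "lzsum_group", "tar_group", "lzsum_group_age", "lzsum_group_site",
            "lzsum_group_sex", "lzsum_group_tar", "tar_group_age",
            "tar_group_site", "lzsum_mmse_all", "tar_mmse_all",
            "lzsum_mmse_patients", "tar_mmse_patients",
        }
        assert set(report.models) == expected_models
        assert set(report.descriptives) == {"control", "patient"}
        assert len(report.bh_adjusted) == 2 + len(expected_models)

    def test_effects_recovered_in_expected_direction(self):
        df = marker_frame(n=120, seed=3, group_shift_lz=0.02,
                          group_shift_tar=0.4)
        report = run_battery(df)
        gs = report.group_tests
        assert gs["lzsum"]["group_summary"]["mean_a"] > \
            gs["lzsum"]["group_summary"]["mean_b"]
        assert gs["tar"]["group_summary"]["median_b"] > \
            gs["tar"]["group_summary"]["median_a"]

    def test_missing_marker_column_rejected(self):
        df = marker_frame().drop(columns=["tar"])
        with pytest.raises(ValueError, match="tar"):
            run_battery(df)

    def test_single_subject_group_rejected(self):
        df = marker_frame(n=40)
        df = pd.concat([df[df.group == "control"],
                        df[df.group == "patient"].iloc[:1]])
        with pytest.raises(ValueError, match=">= 2"):
            run_battery(df)

    def test_duplicate_ids_rejected(self):
        df = marker_frame(n=40)
        df.loc[1, "participant_id"] = df.loc[0, "participant_id"]
        with pytest.raises(ValueError, match="duplicated"):
            run_battery(df)
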