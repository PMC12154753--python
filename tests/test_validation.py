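"""Validation statistics: z-summaries, suitability, set ranking, rank tests."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spirolms.cohort import CohortSpec, generate_cohort
from spirolms.equations import equation_set_to_dict, load_equation_set
from spirolms.validation import (
    ZSummary,
    compare_equation_sets,
    ks_normality,
    mann_whitney_u,
    sample_size_check,
    suitability_check,
    summarize_validation,
    validation_report,
)


def inflate_mu(eq, index, factor):
    """Copy of an equation set with the index's median scaled by `factor`."""
    doc = equation_set_to_dict(eq)
    model = doc["indices"][index]["mu"]
    assert model["link"] == "log", "mu inflation helper assumes a log link"
    model["intercept"] = model["intercept"] + float(np.log(factor))
    doc["name"] = f"{doc['name']}-x{factor}"
    return load_equation_set(doc)


class TestSummarize:
    def test_truth_generated_cohort_is_calibrated(self, ise):
        df = generate_cohort(CohortSpec(n=10_000, seed=29))
        for sex in ("male", "female"):
            s = summarize_validation(ise[sex], df, "fvc")
            assert -0.05 < s.mean_z < 0.05
            assert 0.95 < s.sd_z < 1.05

    def test_single_record_at_predicted_median(self, ise):
        model = ise["male"]["fvc"]
        h, a = 175.0, 30.0
        df = pd.DataFrame(
            {
                "sex": ["male"],
                "age_years": [a],
                "height_cm": [h],
                "fvc_l": [float(model.mu(h, a))],
            }
        )
        s = summarize_validation(ise["male"], df, "fvc")
        assert s.mean_z == pytest.approx(0.0, abs=1e-10)
        assert s.median_percent == pytest.approx(100.0)

    def test_empty_cohort_raises(self, ise):
        df = pd.DataFrame({"sex": [], "age_years": [], "height_cm": [], "fvc_l": []})
        with pytest.raises(ValueError):
            summarize_validation(ise["male"], df, "fvc")

    def test_other_sex_is_ignored(self, ise, small_cohort):
        s = summarize_validation(ise["male"], small_cohort, "fev1")
        assert s.n == int((small_cohort["sex"] == "male").sum())


class TestSuitability:
    def test_small_mean_passes(self):
        s = dataclasses.replace(_dummy_summary(), mean_z=0.06)
        passed, margin = suitability_check(s)
        assert passed and margin == pytest.approx(0.44)

    def test_boundary_is_strict(self):
        s = dataclasses.replace(_dummy_summary(), mean_z=0.5)
        passed, margin = suitability_check(s)
        assert not passed and margin == pytest.approx(0.0)

    def test_negative_excess_fails_with_negative_margin(self):
        s = dataclasses.replace(_dummy_summary(), mean_z=-0.51)
        passed, margin = suitability_check(s)
        assert not passed and margin == pytest.approx(-0.01)


def _dummy_summary():
    return ZSummary(
        index="fvc", sex="male", n=100, mean_z=0.0, sd_z=1.0, median_z=0.0,
        q1_z=-0.6, q3_z=0.6, median_predicted=4.5, q1_predicted=4.0,
        q3_predicted=5.0, median_percent=100.0, q1_percent=95.0, q3_percent=105.0,
    )


class TestCompareSets:
    def test_truth_beats_inflated_copy(self, ise):
        df = generate_cohort(CohortSpec(n=2000, seed=41))
        males = df[df["sex"] == "male"]
        sets = {
            "truth": ise["male"],
            "inflated": inflate_mu(ise["male"], "fvc", 1.10),
        }
        table = compare_equation_sets(males, sets, "fvc")
        assert table.loc[0, "equation_set"] == "truth"
        inflated_row = table[table["equation_set"] == "inflated"].iloc[0]
        assert inflated_row["mean_z"] < 0  # overestimation shows negative mean z
        assert inflated_row["bias"] == "overestimates"

    def test_single_set_ranks_first(self, ise, small_cohort):
        table = compare_equation_sets(
            small_cohort[small_cohort["sex"] == "female"], {"only": ise["female"]}, "fvc"
        )
        assert list(table["rank"]) == [1]

    def test_sign_convention(self, ise):
        # measured below predicted => z < 0
        model = ise["male"]["fvc"]
        h, a = 175.0, 30.0
        df = pd.DataFrame(
            {
                "sex": ["male"],
                "age_years": [a],
                "height_cm": [h],
                "fvc_l": [0.8 * float(model.mu(h, a))],
            }
        )
        s = summarize_validation(ise["male"], df, "fvc")
        assert s.mean_z < 0


def brute_force_mw(a, b):
    """Independent oracle: U by pairwise comparisons, p by label enumeration."""
    a, b = list(a), list(b)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = u_stat(a, b)
    pooled = a + b
    n_a = len(a)
    mean_u = n_a * len(b) / 2.0
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        xa = [pooled[i] for i in combo]
        xb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(u_stat(xa, xb) - mean_u) >= dev - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_identical_samples(self):
        u, _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n_a*n_b/2 with midranks
        assert p == pytest.approx(1.0)

    def test_fully_separated_samples(self):
        u, _, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_shift_invariance(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=25)
        u1, _, p1 = mann_whitney_u(a, b)
        u2, _, p2 = mann_whitney_u(a + 17.3, b + 17.3)
        assert u1 == u2 and p1 == p2

    def test_exact_branch_matches_brute_force_with_ties(self, rng):
        layouts = [([1, 1, 2, 3], [2, 2, 4]), ([5.0, 5.0], [5.0, 6.0, 7.0]),
                   ([1, 2], [1, 2, 3, 4])]
        for a, b in layouts:
            u, _, p = mann_whitney_u(a, b)
            u_ref, p_ref = brute_force_mw(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_branch_matches_scipy_without_ties(self, rng):
        for _ in range(5):
            a = rng.normal(size=6)
            b = rng.normal(size=5)
            u, _, p = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_asymptotic_branch_close_to_scipy(self, rng):
        a = rng.normal(size=120)
        b = rng.normal(0.3, 1.0, size=140)
        _, _, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue), rel=0.02)


class TestSampleSize:
    def test_study_validation_sample_passes(self, ise):
        df = pd.DataFrame({"sex": ["male"] * 164 + ["female"] * 180})
        assert sample_size_check(df)["passed"]

    def test_female_minimum_fails(self):
        df = pd.DataFrame({"sex": ["male"] * 200 + ["female"] * 90})
        res = sample_size_check(df)
        assert not res["passed"] and any("female" in f for f in res["failures"])

    def test_both_minima_and_total_fail(self):
        df = pd.DataFrame({"sex": ["male"] * 149 + ["female"] * 149})
        res = sample_size_check(df)
        assert len(res["failures"]) == 3


class TestKSNormality:
    def test_large_normal_sample_not_rejected(self, rng):
        stat, p = ks_normality(rng.standard_normal(2000))
        assert p > 0.01
        assert 0.0 <= stat <= 1.0

    def test_constant_sample_statistic(self):
        stat, _ = ks_normality(np.zeros(50))
        assert stat >= 0.5


class TestValidationReport:
    def test_truth_cohort_report_all_suitable(self, ise, small_cohort):
        doc = validation_report(ise, small_cohort)
        assert doc["all_suitable"]
        assert len(doc["rows"]) == 8
        assert doc["sample"]["passed"]
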