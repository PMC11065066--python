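"""Covariate coding rules and logistic trajectory-outcome association."""

import numpy as np
import pandas as pd
import pytest

from worktraj import (
    code_birth_cohort,
    code_covariates,
    code_covariate_table,
    filter_outcome_site,
    fit_trajectory_outcome_model,
    make_association_table,
)


def make_2x2_data(a, b, c, d, labels=("exposed", "reference")):
    """Individual rows for a 2x2 cancer-by-trajectory table.

    a/b = cases/non-cases in the exposed trajectory, c/d in the reference.
    """
    y = [1] * a + [0] * b + [1] * c + [0] * d
    labs = [labels[0]] * (a + b) + [labels[1]] * (c + d)
    return pd.Series(y), pd.Series(labs)


RAW_OK = {
    "subject_id": "s1",
    "birth_year": 1930,
    "age_baseline": 72,
    "weight_kg": 70.0,
    "height_m": 1.65,
    "smoker": 0,
    "n_chronic": 1,
    "vigorous_activity": 2,
    "moderate_activity": 1,
    "attrition": "no_dropout",
}


class TestBirthCohort:
    @pytest.mark.parametrize(
        "year,expected",
        [
            (1913, "no_crisis"),
            (1925, "no_crisis"),
            (1919, "no_crisis"),
            (1928, "no_crisis"),
            (1946, "no_crisis"),
            (1914, "war"),
            (1918, "war"),
            (1939, "war"),
            (1940, "war"),
            (1945, "war"),
            (1929, "great_depression"),
            (1930, "great_depression"),
            (1938, "great_depression"),
        ],
    )
    def test_crisis_window_boundaries(self, year, expected):
        assert code_birth_cohort(year) == expected


class TestCodeCovariates:
    def test_one_chronic_condition_is_below_threshold(self):
        rec = code_covariates({**RAW_OK, "n_chronic": 1})
        assert rec.chronic_2plus == 0

    def test_two_chronic_conditions_meet_threshold(self):
        rec = code_covariates({**RAW_OK, "n_chronic": 2})
        assert rec.chronic_2plus == 1

    def test_low_activity_when_neither_item_more_than_weekly(self):
        # vigorous "once a week" (2), moderate "hardly ever" (4)
        rec = code_covariates(
            {**RAW_OK, "vigorous_activity": 2, "moderate_activity": 4}
        )
        assert rec.low_activity == 1

    def test_high_activity_when_any_item_more_than_weekly(self):
        rec = code_covariates(
            {**RAW_OK, "vigorous_activity": 4, "moderate_activity": 1}
        )
        assert rec.low_activity == 0

    def test_bmi_is_weight_over_height_squared(self):
        rec = code_covariates(RAW_OK)
        assert rec.bmi == pytest.approx(70.0 / 1.65**2)

    def test_birth_cohort_derived_from_birth_year(self):
        assert code_covariates({**RAW_OK, "birth_year": 1940}).birth_cohort == "war"

    def test_missing_field_flags_subject_for_exclusion(self):
        raw = pd.DataFrame([RAW_OK, {**RAW_OK, "subject_id": "s2", "bad": 1}])
        raw.loc[1, "weight_kg"] = np.nan
        coded, excluded = code_covariate_table(raw)
        assert len(coded) == 1
        assert excluded == ["s2"]


class TestLogisticFit:
    def test_crude_or_on_2x2_equals_cross_product_ratio(self):
        # cancer x trajectory counts (120, 905; 707, 3984)
        y, labs = make_2x2_data(120, 905, 707, 3984)
        result = fit_trajectory_outcome_model(y, labs, reference="reference")
        expected = (120 * 3984) / (905 * 707)
        assert result.odds_ratios.loc["exposed", "odds_ratio"] == pytest.approx(
            expected, abs=1e-6
        )
        assert result.converged

    def test_ci_brackets_or_and_all_positive(self):
        y, labs = make_2x2_data(120, 905, 707, 3984)
        r = fit_trajectory_outcome_model(y, labs, reference="reference").odds_ratios
        assert (r["ci_low"] <= r["odds_ratio"]).all()
        assert (r["odds_ratio"] <= r["ci_high"]).all()
        assert (r["ci_low"] > 0).all()

    def test_null_simulation_or_near_one_and_coverage(self, rng):
        # outcome independent of trajectory: ORs ~ 1, 95% CIs cover 1 ~95% of
        # reps. 2000 replicates keep the Monte-Carlo SE of the coverage
        # estimate (~0.5%) well inside the 93-97% band being checked.
        n, reps, covered, ors = 400, 2000, 0, []
        for _ in range(reps):
            labs = pd.Series(rng.integers(0, 2, size=n)).map({0: "a", 1: "b"})
            y = pd.Series(rng.integers(0, 2, size=n))
            r = fit_trajectory_outcome_model(y, labs, reference="a").odds_ratios
            ors.append(r.loc["b", "odds_ratio"])
            covered += int(r.loc["b", "ci_low"] <= 1 <= r.loc["b", "ci_high"])
        assert np.mean(ors) == pytest.approx(1.0, abs=0.05)
        assert 0.93 <= covered / reps <= 0.97

    def test_irrelevant_covariate_leaves_or_nearly_unchanged(self, rng):
        y, labs = make_2x2_data(60, 440, 55, 445)
        noise = pd.DataFrame({"bmi": rng.normal(26, 4, size=len(y))})
        crude = fit_trajectory_outcome_model(y, labs, reference="reference")
        adj = fit_trajectory_outcome_model(y, labs, noise, reference="reference")
        assert adj.odds_ratios.loc["exposed", "odds_ratio"] == pytest.approx(
            crude.odds_ratios.loc["exposed", "odds_ratio"], rel=0.02
        )

    def test_reference_swap_follows_ratio_rule(self, rng):
        n = 900
        labs = pd.Series(rng.choice(["a", "b", "c"], size=n))
        p = labs.map({"a": 0.1, "b": 0.2, "c": 0.3})
        y = pd.Series((rng.random(n) < p).astype(int))
        ra = fit_trajectory_outcome_model(y, labs, reference="a").odds_ratios
        rb = fit_trajectory_outcome_model(y, labs, reference="b").odds_ratios
        # OR'_c (vs b) = OR_c (vs a) / OR_b (vs a)
        expected = ra.loc["c", "odds_ratio"] / ra.loc["b", "odds_ratio"]
        assert rb.loc["c", "odds_ratio"] == pytest.approx(expected, rel=1e-6)

    def test_default_reference_is_largest_cluster(self):
        y, labs = make_2x2_data(10, 40, 60, 240)
        result = fit_trajectory_outcome_model(y, labs)
        assert result.reference == "reference"

    def test_separation_flagged_not_silently_fit(self):
        y = pd.Series([1] * 30 + [0] * 30)
        labs = pd.Series(["a"] * 30 + ["b"] * 25 + ["a"] * 5)
        # trajectory a contains both outcomes but b has none: separation-ish
        result = fit_trajectory_outcome_model(y, labs, reference="a")
        assert not result.converged
        assert result.message

    def test_reference_without_both_outcomes_rejected(self):
        y = pd.Series([0, 0, 1, 0])
        labs = pd.Series(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="both outcome values"):
            fit_trajectory_outcome_model(y, labs, reference="a")

    def test_missing_reference_rejected(self):
        y, labs = make_2x2_data(5, 5, 5, 5)
        with pytest.raises(ValueError, match="not present"):
            fit_trajectory_outcome_model(y, labs, reference="nope")


class TestAssociationTable:
    def test_formats_or_and_ci_to_two_decimals(self):
        y, labs = make_2x2_data(120, 905, 707, 3984)
        result = fit_trajectory_outcome_model(y, labs, reference="reference")
        result.odds_ratios.loc["exposed", ["odds_ratio", "ci_low", "ci_high"]] = [
            1.7321,
            1.401,
            2.158,
        ]
        table = make_association_table(result)
        assert table.iloc[1]["OR (95%CI)"] == "1.73 (1.40–2.16)"

    def test_reference_row_marked_ref(self):
        y, labs = make_2x2_data(10, 90, 20, 180)
        table = make_association_table(
            fit_trajectory_outcome_model(y, labs, reference="reference")
        )
        assert table.iloc[0]["trajectory"] == "reference"
        assert table.iloc[0]["OR (95%CI)"] == "Ref."

    def test_rounding_to_one(self):
        y, labs = make_2x2_data(10, 90, 20, 180)
        result = fit_trajectory_outcome_model(y, labs, reference="reference")
        result.odds_ratios.loc["exposed", ["odds_ratio", "ci_low", "ci_high"]] = [
            0.999,
            0.5,
            1.5,
        ]
        assert "1.00" in make_association_table(result).iloc[1]["OR (95%CI)"]


class TestSiteFilter:
    def toy(self):
        return pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3"],
                "cancer": [1, 1, 0],
                "site": ["breast", "colon", None],
            }
        )

    def test_breast_filter_on_toy_table(self):
        y = filter_outcome_site(self.toy(), "breast")
        assert y.tolist() == [1, 0, 0]

    def test_all_negative_outcomes_stay_zero(self):
        df = self.toy()
        df["cancer"] = 0
        assert filter_outcome_site(df, "breast", known_sites=["breast"]).tolist() == [
            0,
            0,
            0,
        ]

    def test_overall_is_superset_of_every_site(self, rng):
        sites = ["breast", "colon", "lung", None]
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(50)],
                "cancer": rng.integers(0, 2, size=50),
                "site": rng.choice(sites, size=50),
            }
        )
        df.loc[df["cancer"] == 0, "site"] = None
        overall = filter_outcome_site(df)
        for site in ("breast", "colon", "lung"):
            per_site = filter_outcome_site(df, site, known_sites=sites[:3])
            assert ((per_site == 1) <= (overall == 1)).all()

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError, match="unknown cancer site"):
            filter_outcome_site(self.toy(), "elbow", known_sites=["breast", "colon"])
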