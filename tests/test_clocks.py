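"""Clock families, metrics, age acceleration and the subset search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ddclock import (
    EpigeneticClock,
    age_acceleration,
    clock_age_acceleration,
    evaluate,
    evaluate_predictions,
    fit_clock,
    simulate_cohort,
    split_cohort,
    subset_search,
)
from ddclock.simulate_cohort import CpGAgeModel


@pytest.fixture(scope="module")
def cohort_split():
    cohort = simulate_cohort(seed=42)
    return split_cohort(cohort, seed=42)


class TestMetrics:
    def test_identity_predictions(self):
        age = np.array([1.0, 20, 45, 70, 90])
        m = evaluate_predictions(age, age)
        assert (m.r, m.r2, m.mae, m.rmse) == (1.0, 1.0, 0.0, 0.0)

    def test_null_predictor(self):
        age = np.array([10.0, 20, 30, 40])
        m = evaluate_predictions(age, np.full(4, age.mean()))
        assert m.r2 == pytest.approx(0.0)
        assert not m.r_defined

    def test_hand_computed_vector_pair(self):
        age = np.array([0.0, 10, 20, 30, 40])
        pred = np.array([2.0, 8, 24, 33, 35])
        err = pred - age
        m = evaluate_predictions(age, pred)
        assert m.mae == pytest.approx(np.mean(np.abs(err)))
        assert m.rmse == pytest.approx(np.sqrt(np.mean(err**2)))
        assert m.r2 == pytest.approx(1 - np.sum(err**2) / np.sum((age - 20) ** 2))
        assert m.r == pytest.approx(np.corrcoef(age, pred)[0, 1])

    @settings(max_examples=100, deadline=None)
    @given(
        age=arrays(np.float64, 8, elements=st.floats(0, 95)),
        noise=arrays(np.float64, 8, elements=st.floats(-20, 20)),
    )
    def test_mae_never_exceeds_rmse(self, age, noise):
        m = evaluate_predictions(age, age + noise)
        assert m.mae <= m.rmse + 1e-12


class TestAgeAcceleration:
    def test_perfect_clock_zero_absolute(self):
        age = np.linspace(0, 95, 50)
        assert np.allclose(age_acceleration(age, age, mode="absolute"), 0)

    def test_relative_sums_to_zero(self, rng):
        age = rng.uniform(0, 95, 100)
        pred = 0.7 * age + rng.normal(0, 5, 100)
        rel = age_acceleration(age, pred, mode="relative")
        assert abs(rel.sum()) < 1e-8

    def test_slope_bias_removed_by_relative_mode(self, rng):
        """A clock with slope bias: absolute acceleration correlates with
        age, the relative residual does not."""
        age = rng.uniform(0, 95, 351)
        pred = 10 + 0.5 * age + rng.normal(0, 2, 351)
        absolute = age_acceleration(age, pred, mode="absolute")
        relative = age_acceleration(age, pred, mode="relative")
        assert abs(np.corrcoef(age, absolute)[0, 1]) > 0.9
        assert abs(np.corrcoef(age, relative)[0, 1]) < 0.05

    def test_relative_needs_three_samples(self):
        with pytest.raises(ValueError):
            age_acceleration(np.array([1.0, 2]), np.array([1.0, 2]), mode="relative")


class TestClockFamilies:
    def test_enr_exact_on_noiseless_linear_cohort(self):
        models = [
            CpGAgeModel("ASPA", -1, "linear", baseline=0.66, slope=-0.004, noise_sd=1e-9),
            CpGAgeModel("FHL2", 1, "linear", baseline=0.08, slope=0.006, noise_sd=1e-9),
        ]
        df = simulate_cohort(models=models, n=100, seed=3)
        clock = fit_clock("enr", df, cpg_subset=("ASPA", "FHL2"), transform=False)
        m = evaluate(clock, df)
        assert m.r == pytest.approx(1.0, abs=1e-9)
        assert m.mae < 1e-6

    def test_gbr_interpolates_training_better_than_enr(self, cohort_split):
        train, _ = cohort_split
        gbr = evaluate(fit_clock("gbr", train, seed=0), train)
        enr = evaluate(fit_clock("enr", train, seed=0), train)
        assert gbr.mae <= enr.mae

    @pytest.mark.parametrize("family", ["enr", "kdr", "svml"])
    def test_deterministic_serialization(self, family, cohort_split):
        train, test = cohort_split
        a = fit_clock(family, train, seed=1)
        b = fit_clock(family, train, seed=1)
        assert a.to_json() == b.to_json()
        reloaded = EpigeneticClock.from_json(a.to_json())
        np.testing.assert_array_equal(a.predict(test), reloaded.predict(test))

    def test_kdr_ba_ec_needs_age_column(self, cohort_split):
        train, test = cohort_split
        clock = fit_clock("kdr", train, kdr_variant="BA_EC")
        with pytest.raises(ValueError, match="chronological_age"):
            clock.predict(test.drop(columns=["age"]))
        # BA_E predicts age-blind
        blind = fit_clock("kdr", train, kdr_variant="BA_E")
        pred = blind.predict(test.drop(columns=["age"]))
        assert np.corrcoef(pred, test["age"])[0, 1] > 0.95

    def test_clock_age_acceleration_interface(self, cohort_split):
        train, test = cohort_split
        clock = fit_clock("kdr", train, kdr_variant="BA_E")
        rel = clock_age_acceleration(clock, test, mode="relative")
        assert abs(rel.sum()) < 1e-6

    def test_invalid_inputs(self, cohort_split):
        train, _ = cohort_split
        with pytest.raises(ValueError):
            fit_clock("kdr", train, cpg_subset=("ELOVL2",))  # too few
        with pytest.raises(ValueError):
            fit_clock("kdr", train, cpg_subset=("ELOVL2", "NOPE"))
        with pytest.raises(ValueError):
            fit_clock("nope", train)


class TestSubsetSearch:
    def test_combination_count_is_57_per_family(self, cohort_split):
        train, test = cohort_split
        table = subset_search(["kdr"], train, test, kdr_variant="BA_E")
        assert len(table) == 57
        assert table["n_cpgs"].value_counts().to_dict() == {2: 15, 3: 20, 4: 15, 5: 6, 6: 1}
        assert (table["status"] == "ok").all()

    def test_single_family_single_size(self, cohort_split):
        train, test = cohort_split
        table = subset_search("kdr", train, test, sizes=(6,), kdr_variant="BA_E")
        assert len(table) == 1
        assert table.loc[0, "cpg_subset"].count(",") == 5

    def test_ranking_is_deterministic_and_by_test_mae(self, cohort_split):
        train, test = cohort_split
        a = subset_search(["kdr"], train, test, kdr_variant="BA_E")
        b = subset_search(["kdr"], train, test, kdr_variant="BA_E")
        pd.testing.assert_frame_equal(a, b)
        maes = a["test_mae"].to_numpy()
        assert np.all(np.diff(maes) >= -1e-12)

    def test_failures_flagged_not_fatal(self, cohort_split):
        train, test = cohort_split
        bad_train = train.assign(ASPA=0.5)  # zero variance breaks the fit
        table = subset_search(["kdr"], bad_train, test, kdr_variant="BA_E", sizes=(2,))
        assert len(table) == 15
        errs = table["status"].str.startswith("error")
        assert errs.sum() == 5  # the 5 pairs containing ASPA
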