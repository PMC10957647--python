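import numpy as np
import pandas as pd
import pytest
from lifelines import NelsonAalenFitter

from hazdiff import (
    AalenAdditive,
    AdditiveHazardSCM,
    DegenerateModifier,
    GammaFrailty,
    StepCurve,
    aalen_fit,
    confidence_band,
    generate_rct,
    homogeneity_overlay,
)
from hazdiff.estimands import bhn_integrated_curve


def nelson_aalen_difference(df: pd.DataFrame) -> pd.Series:
    """Independent oracle: difference of per-arm Nelson-Aalen estimators."""
    curves = {}
    for a in (0, 1):
        sub = df[df["exposure"] == a]
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(sub["time"], event_observed=sub["status"])
        curves[a] = naf.cumulative_hazard_.iloc[:, 0]
    return curves


def step_eval(index, values, t):
    """Right-continuous step evaluation (0 before the first jump)."""
    idx = np.searchsorted(np.asarray(index, float), t, side="right") - 1
    return 0.0 if idx < 0 else float(np.asarray(values)[idx])


def random_two_arm_dataset(rng, n: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "time": rng.exponential(1.0, size=n).round(2) + 0.01,  # rounded to force ties
            "status": (rng.uniform(size=n) < 0.8).astype(int),
            "exposure": rng.integers(0, 2, size=n),
        }
    )
    # ensure both arms present with at least one event each
    df.loc[0, ["status", "exposure"]] = [1, 0]
    df.loc[1, ["status", "exposure"]] = [1, 1]
    return df


class TestToyDataset:
    def test_hand_computed_increments(self, toy_dataset):
        fit = aalen_fit(toy_dataset)
        treatment = fit.curves_[1]
        np.testing.assert_allclose(treatment.times, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(treatment.estimate, [0.5, 0.0, 1.0], atol=1e-12)

    def test_hand_computed_variance_and_band(self, toy_dataset):
        fit = aalen_fit(toy_dataset)
        treatment = fit.curves_[1]
        assert treatment.variance[0] == pytest.approx(0.25, abs=1e-12)
        lower, upper = treatment.band(0.95)
        half = upper[0] - treatment.estimate[0]
        assert half == pytest.approx(1.959963984540054 * 0.5, rel=1e-9)

    def test_baseline_curve_present_first(self, toy_dataset):
        fit = aalen_fit(toy_dataset)
        assert fit.curves_[0].label == "baseline"
        assert fit.n_used_ == 4 and fit.n_events_ == 3


class TestNelsonAalenOracle:
    def test_intercept_only_equals_nelson_aalen(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "time": rng.exponential(1.0, size=n) + 1e-3,
                "status": (rng.uniform(size=n) < 0.7).astype(int),
            }
        )
        df.loc[0, "status"] = 1
        model = AalenAdditive().fit(
            np.empty((n, 0)), (df["time"].to_numpy(), df["status"].to_numpy())
        )
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(df["time"], event_observed=df["status"])
        na = naf.cumulative_hazard_.iloc[:, 0]
        na = na[na.index > 0]
        np.testing.assert_allclose(model.curves_[0](na.index.to_numpy()), na.to_numpy(), atol=1e-10)

    def test_binary_covariate_equals_na_difference_many_random_datasets(self):
        """The treatment curve of the single-binary-covariate fit equals the
        difference of the two per-arm Nelson-Aalen estimators at every event
        time (exact algebraic identity), on 100 random censored datasets."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            df = random_two_arm_dataset(rng, int(rng.integers(10, 60)))
            fit = aalen_fit(df)
            curves = nelson_aalen_difference(df)
            for t, est in zip(fit.times_, fit.cum_coef_[:, 1]):
                expected = step_eval(curves[1].index, curves[1], t) - step_eval(
                    curves[0].index, curves[0], t
                )
                assert est == pytest.approx(expected, abs=1e-9), f"t={t}"

    def test_estimation_stops_when_one_arm_is_exhausted(self):
        df = pd.DataFrame(
            {
                "id": range(4),
                "time": [1.0, 2.0, 3.0, 4.0],
                "status": [1, 1, 1, 1],
                "exposure": [1, 1, 0, 0],
            }
        )
        fit = aalen_fit(df)
        # after t=2 no exposed subject remains at risk: design deficient at t=3
        assert fit.stop_time_ == 3.0
        np.testing.assert_allclose(fit.times_, [1.0, 2.0])


class TestInvarianceAndValidation:
    def test_row_permutation_and_relabeling_invariance(self, rng):
        df = random_two_arm_dataset(rng, 80)
        fit1 = aalen_fit(df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["id"] = shuffled["id"] + 1000
        fit2 = aalen_fit(shuffled)
        np.testing.assert_allclose(fit1.cum_coef_, fit2.cum_coef_, atol=1e-12)
        np.testing.assert_allclose(fit1.cum_var_, fit2.cum_var_, atol=1e-12)

    def test_no_events_raises(self):
        df = pd.DataFrame({"id": [0, 1], "time": [1.0, 2.0], "status": [0, 0], "exposure": [0, 1]})
        with pytest.raises(ValueError, match="no events"):
            aalen_fit(df)

    def test_singular_first_design_raises(self):
        df = pd.DataFrame({"id": [0, 1], "time": [1.0, 2.0], "status": [1, 1], "exposure": [1, 1]})
        with pytest.raises(ValueError, match="singular"):
            aalen_fit(df)

    def test_sklearn_protocol(self, toy_dataset):
        model = AalenAdditive(cond_threshold=1e8)
        assert model.get_params()["cond_threshold"] == 1e8
        model.set_params(cond_threshold=1e10)
        X = toy_dataset[["exposure"]].to_numpy(float)
        y = np.array(
            list(zip(toy_dataset["status"].astype(bool), toy_dataset["time"])),
            dtype=[("event", bool), ("time", float)],
        )
        fitted = model.fit(X, y)
        np.testing.assert_allclose(fitted.cum_coef_[:, 1], [0.5, 0.0, 1.0], atol=1e-12)
        ch = fitted.predict_cumulative_hazard(np.array([[0.0], [1.0]]), [2.5])
        assert ch.shape == (2, 1)

    def test_step_curve_validation(self):
        with pytest.raises(ValueError):
            StepCurve(np.array([1.0, 1.0]), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            StepCurve(np.array([1.0, 2.0]), np.zeros(2), np.array([0.1, -0.1]))


class TestConfidenceBands:
    def test_zero_variance_collapses(self):
        c = StepCurve(np.array([1.0, 2.0]), np.array([0.3, 0.5]), np.zeros(2))
        lower, upper = c.band(0.95)
        np.testing.assert_allclose(lower, c.estimate)
        np.testing.assert_allclose(upper, c.estimate)

    def test_nested_levels(self, toy_dataset):
        fit = aalen_fit(toy_dataset)
        bands95 = confidence_band(fit, 0.95)["exposure"]
        bands99 = confidence_band(fit, 0.99)["exposure"]
        assert (bands99["lower"] <= bands95["lower"]).all()
        assert (bands99["upper"] >= bands95["upper"]).all()

    def test_invalid_level(self, toy_dataset):
        fit = aalen_fit(toy_dataset)
        with pytest.raises(ValueError):
            confidence_band(fit, 1.5)

    def test_homogeneous_band_coverage(self):
        """On data from an effect-homogeneous model the true line c*t should be
        inside the pointwise 95% band at the landmark times in >= 90% of fits."""
        c = -0.1
        scm = AdditiveHazardSCM(
            frailty=GammaFrailty(1.0, 1.0), modifier=DegenerateModifier(c),
            baseline_family="constant", ell=0.3,
        )
        landmarks = np.array([0.5, 1.0, 1.5, 2.0])
        covered = []
        for rep in range(100):
            df = generate_rct(scm, 2_000, seed=1_000 + rep)
            fit = aalen_fit(df)
            treatment = fit.curves_[1]
            idx = np.searchsorted(treatment.times, landmarks, side="right") - 1
            est = treatment.estimate[idx]
            half = 1.959963984540054 * np.sqrt(treatment.variance[idx])
            covered.append(np.abs(est - c * landmarks) <= half)
        assert np.mean(covered) >= 0.90


class TestHomogeneityOverlay:
    def test_degenerate_modifier_line(self):
        scm = AdditiveHazardSCM(
            frailty=GammaFrailty(1, 1), modifier=DegenerateModifier(0.2),
            baseline_family="constant", ell=0.1,
        )
        df = generate_rct(scm, 400, seed=3)
        fit = aalen_fit(df)
        table = homogeneity_overlay(fit, scm)
        np.testing.assert_allclose(table["homogeneous_line"], 0.2 * table["time"], atol=1e-12)
        np.testing.assert_allclose(table["integrated_smchd"], table["homogeneous_line"], atol=1e-8)

    def test_case_study_overlay_is_bhn_curve(self, case_scm):
        df = generate_rct(case_scm, 300, seed=4)
        fit = aalen_fit(df)
        table = homogeneity_overlay(fit, case_scm)
        np.testing.assert_allclose(
            table["integrated_smchd"],
            bhn_integrated_curve(case_scm.modifier, table["time"].to_numpy()),
            atol=1e-9,
        )

    def test_selection_signature(self, case_scm):
        """The fitted treatment curve follows the survivor-marginalized curve,
        not the naive constant-effect line 0.15 t."""
        df = generate_rct(case_scm, 10_000, seed=5)
        fit = aalen_fit(df)
        treatment = fit.curves_[1]
        mask = treatment.times <= 4.0
        t = treatment.times[mask]
        fitted = treatment.estimate[mask]
        mad_smchd = np.mean(np.abs(fitted - bhn_integrated_curve(case_scm.modifier, t)))
        mad_chd = np.mean(np.abs(fitted - 0.15 * t))
        assert mad_smchd < mad_chd
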