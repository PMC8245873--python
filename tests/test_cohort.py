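"""Cohort statistics: geometric summaries, accuracy scoring, curve fitting."""

import numpy as np
import pytest

from ridsim import (
    RIDTrajectory,
    SubjectSpec,
    evaluate_sampling_days,
    fit_biexponential,
    geometric_mean,
    geometric_sd,
    summarize_fas,
)

from conftest import make_adult_system


def make_rid_cohort(assigned, sap, fas, days=(1.0,)):
    """Hand-built subjects and trajectories with prescribed FaS and SAp."""
    system = make_adult_system()
    subjects, trajectories = [], []
    n_t = len(days)
    for i, (tbs, sap_i, fas_i) in enumerate(zip(assigned, sap, fas)):
        sid = f"s{i}"
        subjects.append(SubjectSpec(id=sid, group="adult", system=system,
                                    M5=1.0, assigned_tbs=tbs))
        ones = np.ones(n_t)
        trajectories.append(RIDTrajectory(
            subject_id=sid, times=np.asarray(days, dtype=float),
            Fa=ones * 0.5, FDp=ones * sap_i, SAp=ones * sap_i,
            SAs=ones * 0.5 / tbs, S=ones, FaS=ones * fas_i,
            defined=np.ones(n_t, dtype=bool)))
    return subjects, trajectories


class TestGeometricStatistics:
    @pytest.mark.parametrize("values, expected", [((2, 2, 2), 2.0), ((1, 4), 2.0)])
    def test_geometric_mean_small_cases(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    def test_geometric_mean_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            geometric_mean([1.0, 0.0])
        with pytest.raises(ValueError):
            geometric_mean([])

    def test_lognormal_monte_carlo(self):
        """GM of many log-normal draws approaches exp(mu) (oracle: closed form)."""
        rng = np.random.default_rng(9)
        draws = rng.lognormal(mean=0.5, sigma=0.3, size=100_000)
        assert geometric_mean(draws) == pytest.approx(np.exp(0.5), rel=0.01)

    def test_geometric_sd_constant_is_one(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # scipy moment precision
            assert geometric_sd([3.0, 3.0, 3.0]) == pytest.approx(1.0)


class TestSummarizeFas:
    def test_identical_curves_have_zero_cv(self):
        subjects, trajs = make_rid_cohort(
            assigned=[100, 100], sap=[0.01, 0.01], fas=[1.0, 1.0])
        out = summarize_fas(trajs, days=[1.0])
        assert out[0].cv_pct == pytest.approx(0.0)
        assert out[0].gm_fas == pytest.approx(1.0)

    def test_cv_conventions(self):
        subjects, trajs = make_rid_cohort(
            assigned=[100, 100], sap=[0.01, 0.01], fas=[1.0, 4.0])
        arith = summarize_fas(trajs, days=[1.0], cv_convention="arithmetic")[0]
        geom = summarize_fas(trajs, days=[1.0], cv_convention="geometric")[0]
        vals = np.array([1.0, 4.0])
        assert arith.gm_fas == pytest.approx(2.0)
        assert arith.sd_fas == pytest.approx(np.std(vals, ddof=1))
        assert arith.cv_pct == pytest.approx(100 * np.std(vals, ddof=1) / vals.mean())
        sigma = np.std(np.log(vals), ddof=1)
        assert geom.sd_fas == pytest.approx(np.exp(sigma))
        assert geom.cv_pct == pytest.approx(100 * np.sqrt(np.exp(sigma**2) - 1))

    def test_undefined_day_raises(self, adult_trajectory):
        with pytest.raises(ValueError, match="not on trajectory grid"):
            summarize_fas([adult_trajectory, adult_trajectory], days=[2.5])

    def test_cv_declines_as_stores_equilibrate(self, adult_cohort_20):
        """Cohort FaS dispersion narrows between the first and third week."""
        _, trajs = adult_cohort_20
        summ = {s.day: s.cv_pct for s in summarize_fas(trajs, range(1, 31))}
        assert summ[21] < summ[7]


class TestEvaluateSamplingDays:
    def test_perfect_predictor(self):
        """When all subjects share one FaS and SAp ∝ 1/TBS, predictions are
        exact: r² = 1 and every subject within every threshold."""
        assigned = np.array([100.0, 300.0, 900.0])
        fas = np.ones(3) * 0.6
        sap = 0.6 / assigned  # prediction = GM(FaS)/SAp = assigned exactly
        subjects, trajs = make_rid_cohort(assigned, sap, fas)
        rep = evaluate_sampling_days(subjects, trajs, days=[1.0],
                                     thresholds=(10, 25, 50), selected_days=[1.0])
        assert rep.regressions.loc[1.0, "r_squared"] == pytest.approx(1.0)
        assert rep.regressions.loc[1.0, "rank_r_squared"] == pytest.approx(1.0)
        assert (rep.pct_within.loc[1.0] == 100.0).all()
        assert rep.regressions.loc[1.0, "slope"] == pytest.approx(1.0)

    def test_pct_within_hand_enumeration(self):
        """Three subjects with prediction errors of +10%, −30% and +29.87%:
        exactly one of three lands within the 25% band (GM-aggregation pins
        the product of the error factors at 1, so the third factor is
        1/(1.1·0.7) rather than the round 1.3)."""
        factors = np.array([1.1, 0.7, 1.0 / (1.1 * 0.7)])
        assigned = np.array([100.0, 200.0, 400.0])
        fas = factors * 0.5  # GM(fas) = 0.5 since GM(factors) = 1
        sap = 0.5 / (assigned * factors)  # prediction = GM/sap = assigned*factors
        subjects, trajs = make_rid_cohort(assigned, sap, fas)
        rep = evaluate_sampling_days(subjects, trajs, days=[1.0],
                                     thresholds=(10, 25, 50), selected_days=[1.0])
        np.testing.assert_allclose(
            rep.predictions[1.0].to_numpy(), assigned * factors, rtol=1e-12)
        assert rep.pct_within.loc[1.0, 25] == pytest.approx(100.0 / 3.0)
        assert rep.pct_within.loc[1.0, 10] == pytest.approx(100.0 / 3.0)
        assert rep.pct_within.loc[1.0, 50] == pytest.approx(100.0)

    def test_gm_equality_and_monotone_thresholds(self, small_cohort):
        subjects, trajs = small_cohort
        rep = evaluate_sampling_days(subjects, trajs)
        gm_assigned = geometric_mean(rep.assigned)
        for day in rep.predictions.columns:
            assert geometric_mean(rep.predictions[day]) == pytest.approx(
                gm_assigned, rel=1e-10)
        pw = rep.pct_within
        assert (pw[10] <= pw[25]).all() and (pw[25] <= pw[50]).all()
        assert sum(rep.best_day_frequency.values()) == len(subjects)

    def test_too_few_subjects(self):
        subjects, trajs = make_rid_cohort([100, 200], [0.01, 0.01], [1.0, 1.0])
        with pytest.raises(ValueError, match="at least 3"):
            evaluate_sampling_days(subjects, trajs, days=[1.0], selected_days=[1.0])


class TestFitBiexponential:
    T = np.arange(1.0, 31.0)

    def test_noiseless_self_consistency(self):
        y = 1.2 * np.exp(-0.9 * self.T) + 0.6 * np.exp(-0.05 * self.T)
        fit = fit_biexponential(self.T, y)
        assert fit["A1"] == pytest.approx(1.2, abs=1e-6)
        assert fit["k1"] == pytest.approx(0.9, abs=1e-6)
        assert fit["A2"] == pytest.approx(0.6, abs=1e-6)
        assert fit["k2"] == pytest.approx(0.05, abs=1e-6)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(314)
        y = 1.2 * np.exp(-0.9 * self.T) + 0.6 * np.exp(-0.05 * self.T)
        y_noisy = y * (1.0 + 0.01 * rng.standard_normal(self.T.size))
        fit = fit_biexponential(self.T, y_noisy)
        for key, truth in [("A1", 1.2), ("k1", 0.9), ("A2", 0.6), ("k2", 0.05)]:
            assert fit[key] == pytest.approx(truth, rel=0.10)

    def test_phase_ordering_enforced(self):
        y = 0.6 * np.exp(-0.05 * self.T) + 1.2 * np.exp(-0.9 * self.T)
        fit = fit_biexponential(self.T, y)
        assert fit["k1"] > fit["k2"] >= 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_biexponential([1, 2, 3], [1.0, 0.5, 0.2])
        with pytest.raises(ValueError, match="positive"):
            fit_biexponential(self.T, np.zeros_like(self.T))

    def test_cohort_gm_fas_is_nearly_biexponential(self, adult_cohort_20):
        """Once the absorptive phase has cleared (day 2 on), the
        geometric-mean FaS curve follows a biexponential decline."""
        _, trajs = adult_cohort_20
        summ = summarize_fas(trajs, range(2, 31))
        days = np.array([s.day for s in summ])
        gm = np.array([s.gm_fas for s in summ])
        fit = fit_biexponential(days, gm)
        assert fit["r_squared"] > 0.999
        assert fit["k1"] > fit["k2"] > 0
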