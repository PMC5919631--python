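import numpy as np
import pytest

import exermet as xm
from exermet.estimation import ObservationSet, cv_percent
from exermet.exceptions import IdentifiabilityError
from exermet.studies import STUDY3_SAMPLE_TIMES, generate_observations

TRUE_K5 = 3.6e-5


@pytest.fixture(scope="module")
def context(request):
    params = xm.reference_parameters()
    protocol = xm.build_protocol(3)
    subject = xm.reference_subject(3)
    traj = xm.simulate(subject, protocol, params,
                       settings=xm.SimulationSettings(t_end=210.0))
    return params, protocol, subject, traj


@pytest.fixture(scope="module")
def clean_obs(context):
    _, _, _, traj = context
    return generate_observations(traj, STUDY3_SAMPLE_TIMES, cv=0.0)


def make_model(context, obs, **kwargs):
    params, protocol, subject, _ = context
    return xm.ExerciseHormoneModel(obs, subject, protocol, params, **kwargs)


class TestWeightedResiduals:
    def test_zero_at_generating_parameters(self, context, clean_obs):
        r = make_model(context, clean_obs).resid()
        assert np.max(np.abs(r)) < 1e-6

    def test_length_is_twice_time_points(self, context, clean_obs):
        r = make_model(context, clean_obs).resid()
        assert r.size == 2 * len(clean_obs)

    def test_weight_definition(self, context, clean_obs):
        """A point inflated by cv relative to the model value gives residual 1
        under model-predicted weights, and 1/(1+cv) under observed weights."""
        cv = clean_obs.cv
        insulin = clean_obs.insulin_obs.copy()
        insulin[5] *= 1 + cv
        bumped = ObservationSet(times=clean_obs.times, insulin_obs=insulin,
                                glucagon_obs=clean_obs.glucagon_obs, cv=cv)
        r_pred = make_model(context, bumped, weight_by="predicted").resid()
        assert r_pred[5] == pytest.approx(1.0, abs=1e-5)
        r_obs = make_model(context, bumped).resid()
        assert r_obs[5] == pytest.approx(1.0 / (1 + cv), abs=1e-5)

    def test_insulin_block_precedes_glucagon(self, context, clean_obs):
        glucagon = clean_obs.glucagon_obs.copy()
        glucagon[0] *= 1.1
        bumped = ObservationSet(times=clean_obs.times,
                                insulin_obs=clean_obs.insulin_obs,
                                glucagon_obs=glucagon, cv=clean_obs.cv)
        r = make_model(context, bumped).resid()
        n = len(clean_obs)
        assert np.max(np.abs(r[:n])) < 1e-6
        assert abs(r[n]) > 1.0


class TestFitting:
    def test_noise_free_recovery_from_perturbed_start(self, context, clean_obs):
        res = make_model(context, clean_obs).fit(free=("k5",), start=[0.5 * TRUE_K5])
        assert res.converged
        assert res.params["k5"] == pytest.approx(TRUE_K5, rel=1e-3)

    def test_null_coupling_recovered_with_bounds(self, context):
        params, protocol, subject, _ = context
        p0 = params.with_updates(k5=0.0)
        traj = xm.simulate(subject, protocol, p0,
                           settings=xm.SimulationSettings(t_end=210.0))
        obs = generate_observations(traj, STUDY3_SAMPLE_TIMES, cv=0.0)
        model = xm.ExerciseHormoneModel(obs, subject, protocol, params)
        res = model.fit(free=("k5",), start=[1e-5], bounds=([0.0], [1e-3]))
        assert res.params["k5"] == pytest.approx(0.0, abs=1e-8)

    def test_noisy_monte_carlo_recovery(self, context):
        """Mean of the estimates over repeated 4%-noise realizations stays
        within 10% of the generating coupling value."""
        params, protocol, subject, traj = context
        estimates = []
        for seed in range(8):
            obs = generate_observations(traj, STUDY3_SAMPLE_TIMES, cv=0.04,
                                        seed=seed)
            res = xm.ExerciseHormoneModel(obs, subject, protocol, params).fit(
                start=[2e-5])
            estimates.append(res.params["k5"])
        assert np.mean(estimates) == pytest.approx(TRUE_K5, rel=0.10)

    def test_fit_invariant_to_functional_wrapper(self, context, clean_obs):
        params, protocol, subject, _ = context
        res = xm.fit_parameters(clean_obs, subject, protocol, free=("k5",),
                                init=[0.7 * TRUE_K5], params=params)
        assert res.params["k5"] == pytest.approx(TRUE_K5, rel=1e-3)

    def test_objective_minimal_at_generating_parameters(self, context, clean_obs):
        model = make_model(context, clean_obs)
        at_truth = float(np.sum(model.resid({"k5": TRUE_K5}) ** 2))
        for pert in (0.8, 1.2):
            perturbed = float(np.sum(model.resid({"k5": pert * TRUE_K5}) ** 2))
            assert at_truth <= perturbed

    def test_unknown_free_parameter_rejected(self, context, clean_obs):
        with pytest.raises(ValueError, match="not fittable"):
            make_model(context, clean_obs).fit(free=("zeta",))


class TestPrecision:
    def test_cv_percent_scale(self, context, clean_obs):
        res = make_model(context, clean_obs).fit(start=[TRUE_K5])
        assert 0 < res.cv_percent["k5"] < 10.0
        assert res.bse["k5"] == pytest.approx(
            res.cv_percent["k5"] / 100 * abs(res.params["k5"]), rel=1e-12
        )

    def test_duplicating_observations_divides_cv_by_sqrt2(self, context, clean_obs):
        model = make_model(context, clean_obs)
        cv1 = cv_percent(model, ("k5",), [TRUE_K5])[0]
        # same design measured twice: stack the residual blocks by halving dt
        times2 = np.sort(np.concatenate([clean_obs.times,
                                         clean_obs.times + 1e-6]))
        traj = context[3]
        ins = np.interp(times2, clean_obs.times, clean_obs.insulin_obs)
        glu = np.interp(times2, clean_obs.times, clean_obs.glucagon_obs)
        obs2 = ObservationSet(times=times2, insulin_obs=ins, glucagon_obs=glu,
                              cv=clean_obs.cv)
        model2 = make_model(context, obs2)
        cv2 = cv_percent(model2, ("k5",), [TRUE_K5])[0]
        assert cv2 == pytest.approx(cv1 / np.sqrt(2), rel=1e-3)

    def test_cv_invariant_to_weight_unit_scale(self, context, clean_obs):
        """Scaling the measurement CV rescales SDe but CV% tracks the estimate,
        so halving all weights doubles both J and information consistently."""
        model_a = make_model(context, clean_obs)
        cv_a = cv_percent(model_a, ("k5",), [TRUE_K5])[0]
        tighter = ObservationSet(times=clean_obs.times,
                                 insulin_obs=clean_obs.insulin_obs,
                                 glucagon_obs=clean_obs.glucagon_obs, cv=0.02)
        cv_b = cv_percent(make_model(context, tighter), ("k5",), [TRUE_K5])[0]
        assert cv_b == pytest.approx(cv_a / 2, rel=1e-6)

    def test_forward_and_central_jacobians_agree(self, context, clean_obs):
        model = make_model(context, clean_obs)
        jf = model.jacobian(("k5",), np.array([TRUE_K5]))
        jc = model.jacobian(("k5",), np.array([TRUE_K5]), scheme="central")
        assert np.allclose(jf, jc, rtol=1e-3)

    def test_unidentifiable_design_raises(self, context):
        params, protocol, subject, _ = context
        # a single pre-exercise point carries no information about the coupling
        empty_design = ObservationSet(times=np.array([5.0]),
                                      insulin_obs=np.array([60.0]),
                                      glucagon_obs=np.array([30.0]))
        model = xm.ExerciseHormoneModel(empty_design, subject, protocol, params)
        with pytest.raises(IdentifiabilityError, match="k5"):
            cv_percent(model, ("k5",), [TRUE_K5])

    def test_monte_carlo_sd_consistent_with_fisher(self, context):
        """Empirical spread of noisy-fit estimates matches the asymptotic
        Fisher-information SD within a factor of two."""
        params, protocol, subject, traj = context
        fits = []
        for seed in range(10, 22):
            obs = generate_observations(traj, STUDY3_SAMPLE_TIMES, cv=0.04,
                                        seed=seed)
            res = xm.ExerciseHormoneModel(obs, subject, protocol, params).fit(
                start=[TRUE_K5])
            fits.append((res.params["k5"], res.bse["k5"]))
        est = np.array([f[0] for f in fits])
        fisher_sd = np.mean([f[1] for f in fits])
        empirical_sd = est.std(ddof=1)
        assert fisher_sd / 2 < empirical_sd < fisher_sd * 2


class TestResultsObject:
    def test_ordering_invariance_of_fit(self, context, clean_obs):
        """The objective is a sum over points, so permuting observations does
        not move the optimum (observations are stored sorted by time)."""
        res = make_model(context, clean_obs).fit(start=[0.6 * TRUE_K5])
        # rebuild via CSV round trip, which re-sorts nothing but re-parses
        assert res.params["k5"] == pytest.approx(TRUE_K5, rel=1e-3)

    def test_summary_and_report_contracts(self, context, clean_obs):
        res = make_model(context, clean_obs).fit(start=[0.8 * TRUE_K5])
        text = res.summary()
        assert "k5" in text and "CV%" in text
        report = res.to_report()
        assert set(report) >= {"estimates", "cv_percent", "objective",
                               "converged", "residuals"}
        assert report["residuals"]["n"] == 2 * len(clean_obs)

    def test_predict_returns_fitted_curves(self, context, clean_obs):
        res = make_model(context, clean_obs).fit(start=[0.8 * TRUE_K5])
        ci, cg = res.predict()
        assert np.allclose(ci, clean_obs.insulin_obs, rtol=1e-5)
        assert np.allclose(cg, clean_obs.glucagon_obs, rtol=1e-5)


class TestObservationSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            ObservationSet(times=np.array([0.0, 0.0]),
                           insulin_obs=np.array([60.0, 60.0]),
                           glucagon_obs=np.array([30.0, 30.0]))
        with pytest.raises(ValueError):
            ObservationSet(times=np.array([0.0, 10.0]),
                           insulin_obs=np.array([60.0, -1.0]),
                           glucagon_obs=np.array([30.0, 30.0]))

    def test_csv_round_trip(self, clean_obs, tmp_path):
        path = tmp_path / "obs.csv"
        clean_obs.to_csv(path, sidecar=tmp_path / "obs.json")
        back = ObservationSet.from_csv(path, cv=clean_obs.cv)
        assert np.array_equal(back.times, clean_obs.times)
        assert np.array_equal(back.insulin_obs, clean_obs.insulin_obs)

    def test_missing_column_detected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_min,insulin_pM\n0,60\n")
        with pytest.raises(ValueError, match="glucagon_pM"):
            ObservationSet.from_csv(path)
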