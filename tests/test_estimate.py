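"""Joint objective closed forms, empirical Bayes behavior, OFV limits, fits."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import siropk as sp
from siropk.errors import EstimationError
from siropk.estimate import _Compiled, _predict, _tv_arrays

TAU = 24.0


def noise_free_troughs(model, wt, pos, dose_ug, n_doses, obs_days, eta=0.0):
    """Independent predictions by explicit superposition of single doses."""
    params = sp.individual_params(model, wt, pos, eta)
    out = []
    for day in obs_days:
        t_obs = day * TAU
        conc = sum(
            sp.conc_single_dose(params, dose_ug, t_obs - d * TAU)
            for d in range(n_doses)
            if d * TAU < t_obs
        )
        out.append((t_obs, conc))
    return out


def make_subject(model, sid=1, wt=20.0, pos=0.0, dose_per_kg=0.06, n_doses=28,
                 obs_days=(3, 7, 28), eta=0.0, dv_scale=1.0):
    dose = dose_per_kg * wt * 1000.0
    obs = [
        (t, c * dv_scale)
        for t, c in noise_free_troughs(model, wt, pos, dose, n_doses, obs_days, eta)
    ]
    return sp.Subject(
        id=sid, weight=wt, covariates={"POS": pos},
        doses=[(d * TAU, dose) for d in range(n_doses)], observations=obs,
    )


class TestJointObjective:
    def test_exact_observation_closed_form(self, final_model):
        """Single exact obs at eta=0: J = ln sigma^2 + ln omega^2 (zero quadratics)."""
        subj = make_subject(final_model, obs_days=(28,))
        j = sp.subject_joint_objective(subj, final_model, 0.0)
        expected = math.log(3.674**2) + math.log(0.303**2)
        assert j == pytest.approx(expected, abs=1e-9)

    def test_one_sigma_residual_adds_one(self, final_model):
        subj = make_subject(final_model, obs_days=(28,))
        t, c = subj.observations[0]
        shifted = subj.copy()
        shifted.observations = [(t, c + 3.674)]
        j0 = sp.subject_joint_objective(subj, final_model, 0.0)
        j1 = sp.subject_joint_objective(shifted, final_model, 0.0)
        assert j1 - j0 == pytest.approx(1.0, abs=1e-9)

    def test_omega_zero_rejects_nonzero_eta(self, final_model):
        model = final_model.replace(iiv=sp.RandomEffectSpec(0.0))
        subj = make_subject(model, obs_days=(28,))
        with pytest.raises(EstimationError):
            sp.subject_joint_objective(subj, model, 0.5)

    def test_additive_error_has_no_interaction(self, final_model):
        """With additive error the residual variance is independent of eta,
        so FOCE and FOCE-I coincide: g^2 is identical at any eta."""
        subj = make_subject(final_model)
        c = _Compiled(sp.Dataset([subj]))
        tvcl, tvv, ka = _tv_arrays(final_model, c)
        f0, _ = _predict(c, tvcl, tvv, ka, np.array([0.0]))
        f1, _ = _predict(c, tvcl, tvv, ka, np.array([1.0]))
        g0 = final_model.residual.variance(f0)
        g1 = final_model.residual.variance(f1)
        assert np.array_equal(g0, g1)


class TestEmpiricalBayes:
    def test_exact_typical_data_gives_zero(self, final_model):
        subj = make_subject(final_model)
        assert sp.empirical_bayes(subj, final_model) == pytest.approx(0.0, abs=1e-4)

    def test_doubled_observations_imply_lower_clearance(self, final_model):
        wide = final_model.replace(iiv=sp.RandomEffectSpec(2.0))
        subj = make_subject(wide, dv_scale=2.0)
        assert sp.empirical_bayes(subj, wide) < -0.05

    def test_tiny_omega_shrinks_to_zero(self, final_model):
        tight = final_model.replace(iiv=sp.RandomEffectSpec(1e-4))
        subj = make_subject(tight, dv_scale=2.0)
        assert abs(sp.empirical_bayes(subj, tight)) < 5e-4


class TestOfv:
    def test_laplace_close_to_quadrature(self, final_model):
        """Independent oracle: adaptive quadrature of the marginal likelihood
        (minus n ln 2pi).  Laplace is approximate; agreement within 0.1."""
        subj = make_subject(final_model, dv_scale=1.3)
        c = _Compiled(sp.Dataset([subj]))
        tvcl, tvv, ka = _tv_arrays(final_model, c)
        omega = final_model.iiv.sd

        def lik(eta):
            f, _ = _predict(c, tvcl, tvv, ka, np.array([eta]))
            g = np.sqrt(final_model.residual.variance(f))
            return float(np.prod(norm.pdf(c.y, f, g)) * norm.pdf(eta, 0, omega))

        integral, _err = quad(lik, -8 * omega, 8 * omega, limit=200)
        oracle = -2 * math.log(integral) - c.n_obs * math.log(2 * math.pi)
        assert sp.focei_ofv(sp.Dataset([subj]), final_model) == pytest.approx(oracle, abs=0.1)

    def test_omega_zero_limit_single_exact_obs(self, final_model):
        model = final_model.replace(iiv=sp.RandomEffectSpec(0.0))
        subj = make_subject(model, obs_days=(28,))
        assert sp.focei_ofv(sp.Dataset([subj]), model) == pytest.approx(
            math.log(3.674**2), abs=1e-9
        )

    def test_omega_zero_extra_obs_adds_one_plus_log(self, final_model):
        model = final_model.replace(iiv=sp.RandomEffectSpec(0.0))
        one = make_subject(model, obs_days=(28,))
        two = make_subject(model, obs_days=(27, 28))
        t, c = two.observations[0]
        two.observations[0] = (t, c + 3.674)
        delta = sp.focei_ofv(sp.Dataset([two]), model) - sp.focei_ofv(sp.Dataset([one]), model)
        assert delta == pytest.approx(1.0 + math.log(3.674**2), abs=1e-9)

    def test_omega_zero_duplication_doubles(self, final_model):
        model = final_model.replace(iiv=sp.RandomEffectSpec(0.0))
        s1 = make_subject(model, sid=1, dv_scale=1.2)
        s2 = s1.copy(new_id=2)
        single = sp.focei_ofv(sp.Dataset([s1]), model)
        double = sp.focei_ofv(sp.Dataset([s1, s2]), model)
        assert double == pytest.approx(2 * single, rel=1e-12)


class TestFit:
    def test_small_sample_recovery(self, final_model):
        """Recovery smoke check at modest size (the full-scale check lives in
        the acceptance suite)."""
        truth = final_model.replace(effects=())
        cohort = sp.generate_cohort(sp.CohortSpec(n=60, exact_counts=False), seed=5)
        ds = sp.simulate_observations(cohort, truth, seed=6)
        res = sp.fit(ds, truth)
        assert res.converged
        assert res.theta["theta_cl"] == pytest.approx(10.4, rel=0.25)
        assert res.theta["theta_v"] == pytest.approx(583.0, rel=0.35)

    def test_refit_at_optimum_is_stationary(self, study_dataset, final_model):
        base = final_model.replace(effects=())
        first = sp.fit(study_dataset, base)
        second = sp.fit(study_dataset, first.model, start="model")
        assert abs(second.ofv - first.ofv) < 1e-6

    def test_subject_order_invariance(self, study_dataset, final_model):
        base = final_model.replace(effects=())
        res = sp.fit(study_dataset, base)
        reversed_ds = sp.Dataset([s.copy(new_id=100 - s.id) for s in study_dataset.subjects[::-1]])
        res_rev = sp.fit(reversed_ds, base)
        for name in res.theta:
            assert res_rev.theta[name] == pytest.approx(res.theta[name], rel=1e-3)

    def test_constant_covariate_is_inestimable(self, study_dataset, final_model):
        no_pos = sp.Dataset([s.copy() for s in study_dataset.subjects])
        for s in no_pos.subjects:
            s.covariates["POS"] = 0.0
        with pytest.raises(EstimationError, match="no variation"):
            sp.fit(no_pos, sp.sirolimus_final_model())

    def test_requires_two_subjects(self, final_model):
        ds = sp.Dataset([make_subject(final_model)])
        with pytest.raises(EstimationError):
            sp.fit(ds, final_model.replace(effects=()))


class TestEstimatorFacade:
    def test_sklearn_interface(self, study_dataset):
        est = sp.FOCEIEstimator()
        assert "fixed" in est.get_params()
        est.fit(study_dataset)
        assert est.converged_
        assert est.ofv_ == pytest.approx(est.result_.ofv)
        assert set(est.eta_) == {s.id for s in study_dataset.subjects}
        pred = est.predict(study_dataset, kind="population")
        ipred = est.predict(study_dataset, kind="individual")
        assert pred.shape == ipred.shape == (study_dataset.n_observations,)
        assert est.score(study_dataset) == pytest.approx(-0.5 * est.ofv_)

    def test_clone_compatible(self, final_model):
        from sklearn.base import clone

        est = sp.FOCEIEstimator(model=final_model, maxiter=100)
        cloned = clone(est)
        assert cloned.get_params()["maxiter"] == 100
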