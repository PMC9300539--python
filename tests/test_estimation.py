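"""Likelihood machinery: penalized individual objective, Laplace marginal,
likelihood-ratio thresholds, and degenerate-case equivalences.

The Laplace/penalized layer is exercised on analytically tractable toy
subjects by replacing the ODE prediction function with linear maps, so
every expected value here comes from a closed form or an independent
brute-force oracle.
"""

import dataclasses

import numpy as np
import pytest
from scipy import optimize, stats

from oralpax import estimate as est
from oralpax.errors import ParameterError
from oralpax.params import default_config
from oralpax.synthetic import TrialDesignSpec, generate_trial


def toy_subject(y, sid="t1"):
    y = np.asarray(y, dtype=float)
    return est.SubjectData(sid=sid, pac_doses=(), occasions=(),
                           pk_t=np.arange(len(y), dtype=float), pk_y=y,
                           pd_t=np.empty(0), pd_y=np.empty(0),
                           rtv_profile=None)


def linear_predictor(a, b):
    """Patched prediction: yhat_j = a + b * eta (constant over j)."""

    def fake(subject, config, eta, options, need_pd):
        n = len(subject.pk_t)
        return np.full(n, a + b * eta.get("clint0", 0.0)), np.empty(0)

    return fake


OMEGA_TOY = {"alpha": 0.0, "clint0": 0.3, "vc": 0.0, "rf_gut": 0.0,
             "bov_rf_gut": 0.0, "ebase": 0.0}
OPTS = est.EstimationOptions(error_model="additive")


class TestPenalizedNLL:
    def test_perfect_fit_reduces_to_log_variance_terms(self, monkeypatch,
                                                       config):
        """At eta = 0 with yhat = y the residual part of g is exactly
        sum_j log(2 pi sigma^2 y_j^2) (proportional errors)."""
        y = np.array([10.0, 20.0, 40.0])
        monkeypatch.setattr(est, "_predict",
                            lambda s, c, e, o, p: (y.copy(), np.empty(0)))
        opts = est.EstimationOptions(error_model="proportional")
        sigma = 0.25
        g = est.individual_penalized_nll(
            np.zeros(1), toy_subject(y), config, OMEGA_TOY, sigma,
            options=opts, eta_names=["clint0"])
        penalty_const = np.log(2 * np.pi * 0.3 ** 2)
        expected = np.sum(np.log(2 * np.pi * sigma ** 2 * y ** 2))
        assert g - penalty_const == pytest.approx(expected, rel=1e-12)

    def test_zero_prediction_against_nonzero_observation_is_infinite(
            self, monkeypatch, config):
        monkeypatch.setattr(est, "_predict", lambda s, c, e, o, p:
                            (np.zeros(2), np.empty(0)))
        opts = est.EstimationOptions(error_model="proportional")
        g = est.individual_penalized_nll(
            np.zeros(1), toy_subject([5.0, 1.0]), config, OMEGA_TOY, 0.25,
            options=opts, eta_names=["clint0"])
        assert g == np.inf

    def test_quadratic_toy_minimizer_matches_grid_search(self, monkeypatch,
                                                         config):
        """The inner optimizer lands on the brute-force grid optimum of
        the quadratic toy objective to 1e-6."""
        y = np.array([4.1, 5.2, 3.8, 4.6])
        a, b, sigma = 3.0, 2.0, 0.5
        monkeypatch.setattr(est, "_predict", linear_predictor(a, b))
        subject = toy_subject(y)

        def g(ev):
            return est.individual_penalized_nll(
                np.atleast_1d(ev), subject, config, OMEGA_TOY, sigma,
                options=OPTS, eta_names=["clint0"])

        coarse = np.arange(-2.0, 2.0, 1e-3)
        e0 = coarse[np.argmin([g(e) for e in coarse])]
        fine = np.arange(e0 - 2e-3, e0 + 2e-3, 1e-6)
        eta_grid = fine[np.argmin([g(e) for e in fine])]

        _, eta_hat, _, ok = est._subject_ofv(
            subject, config, OMEGA_TOY, sigma, 0.0, OPTS, False)
        assert ok
        assert eta_hat[0] == pytest.approx(eta_grid, abs=1e-6)

    def test_infinite_omega_limit_drops_penalty(self, monkeypatch, config):
        """As Omega grows the quadratic penalty vanishes and only the
        log|2 pi Omega| constant remains."""
        y = np.array([4.0, 5.0])
        monkeypatch.setattr(est, "_predict", linear_predictor(3.0, 2.0))
        subject = toy_subject(y)
        omega_big = dict(OMEGA_TOY, clint0=1e6)
        eta = np.array([0.7])
        g = est.individual_penalized_nll(eta, subject, config, omega_big,
                                         0.5, options=OPTS,
                                         eta_names=["clint0"])
        data_only = est._data_nll(y, 3.0 + 2.0 * 0.7 * np.ones(2), 0.5,
                                  "additive")
        assert g - np.log(2 * np.pi * 1e12) == pytest.approx(data_only,
                                                             abs=1e-9)


class TestLaplaceMarginal:
    def _closed_form(self, ys, a, b, sigma, omega):
        """Exact -2 log marginal likelihood of the linear-Gaussian toy."""
        total = 0.0
        for y in ys:
            n = len(y)
            cov = sigma ** 2 * np.eye(n) + b ** 2 * omega ** 2 * np.ones((n, n))
            total += -2.0 * stats.multivariate_normal.logpdf(
                y, mean=np.full(n, a), cov=cov)
        return total

    def test_exact_on_linear_gaussian_subjects(self, monkeypatch, config):
        """Laplace equals the closed-form Gaussian integral to 1e-4."""
        a, b, sigma = 3.0, 2.0, 0.5
        monkeypatch.setattr(est, "_predict", linear_predictor(a, b))
        ys = [np.array([4.1, 5.2, 3.8]), np.array([2.2, 2.9, 3.4, 4.0])]
        subjects = [toy_subject(y, sid=i) for i, y in enumerate(ys)]
        ofv = est.laplace_marginal_nll(config, subjects, OMEGA_TOY, sigma,
                                       options=OPTS)
        assert ofv == pytest.approx(
            self._closed_form(ys, a, b, sigma, 0.3), abs=1e-4)

    def test_additivity_over_duplicated_subjects(self, monkeypatch, config):
        monkeypatch.setattr(est, "_predict", linear_predictor(3.0, 2.0))
        s = toy_subject([4.1, 5.2, 3.8])
        one = est.laplace_marginal_nll(config, [s], OMEGA_TOY, 0.5,
                                       options=OPTS)
        two = est.laplace_marginal_nll(
            config, [s, dataclasses.replace(s, sid="t2")], OMEGA_TOY, 0.5,
            options=OPTS)
        assert two == pytest.approx(2.0 * one, abs=1e-6)

    def test_ofv_decreases_monotonically_as_sigma_shrinks(self, monkeypatch,
                                                          config):
        """With exact data the OFV heads to -inf as sigma -> 0."""
        y = np.array([3.0, 3.0, 3.0])
        monkeypatch.setattr(est, "_predict", linear_predictor(3.0, 2.0))
        s = toy_subject(y)
        ofvs = [est.laplace_marginal_nll(config, [s], OMEGA_TOY, sig,
                                         options=OPTS)
                for sig in (0.3, 0.1, 0.03, 0.01)]
        assert all(b < a for a, b in zip(ofvs, ofvs[1:]))


class TestLRT:
    @pytest.mark.parametrize("dofv,df,expected", [
        (6.64, 1, True),
        (6.62, 1, False),
        (9.22, 2, True),
        (9.20, 2, False),
    ])
    def test_thresholds(self, dofv, df, expected):
        r = est.lrt_compare(100.0, 100.0 + dofv, df)
        assert r.significant is expected
        assert r.dofv == pytest.approx(dofv)

    def test_threshold_values_are_chi2_quantiles(self):
        assert est.lrt_compare(0, 10, 1).threshold == pytest.approx(6.63, abs=5e-3)
        assert est.lrt_compare(0, 10, 2).threshold == pytest.approx(9.21, abs=5e-3)

    def test_negative_dofv_warns(self):
        with pytest.warns(UserWarning, match="numerical noise"):
            r = est.lrt_compare(101.0, 100.0, 1)
        assert not r.significant


@pytest.fixture(scope="module")
def pooled_trial():
    """Zero-BSV/BOV trial: all subjects identical up to residual noise."""
    cfg = default_config()
    re = dataclasses.replace(
        cfg.random_effects, bsv_cv={k: 0.0 for k in cfg.random_effects.bsv_cv},
        bov_cv_rf_gut=0.0, sigma_prop_pk=10.0)
    cfg0 = cfg.replace(random_effects=re)
    spec = TrialDesignSpec(template="study3", n_subjects=3, n_days=1,
                           pd_sampling_days=())
    ds, _ = generate_trial(spec, cfg0, seed=9)
    return ds, cfg0


class TestFitPopulation:
    def test_zero_variance_reduces_to_least_squares(self, pooled_trial):
        """With all omegas fixed at 0 the fit is a pooled nonlinear
        least-squares problem; the optimum matches a direct least-squares
        oracle to 1e-4 (relative, on the parameters)."""
        ds, cfg0 = pooled_trial
        start = cfg0.replace(paclitaxel=dataclasses.replace(
            cfg0.paclitaxel, clint0=820.0, vc=110.0))
        opts = est.EstimationOptions(error_model="additive", maxiter=1500,
                                     xatol=1e-6, fatol=1e-10)
        problem = est.EstimationProblem(
            dataset=ds, config=start, estimate=("clint0", "vc"),
            options=opts)
        res = est.fit_population(problem)

        subjects = est.prepare_subjects(ds, cfg0)

        def residuals(x):
            cfg = est._set_thetas(start, {"clint0": np.exp(x[0]),
                                          "vc": np.exp(x[1])})
            out = []
            for s in subjects:
                f, _ = est._predict(s, cfg, {}, opts, False)
                out.append(s.pk_y - f)
            return np.concatenate(out)

        x0 = np.log([820.0, 110.0])
        ls = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14)
        assert res.theta["clint0"] == pytest.approx(np.exp(ls.x[0]),
                                                    rel=1e-4)
        assert res.theta["vc"] == pytest.approx(np.exp(ls.x[1]), rel=1e-4)

    def test_refit_from_optimum_is_stable(self, pooled_trial):
        """Restarting the optimizer at the optimum moves OFV < 0.01."""
        ds, cfg0 = pooled_trial
        opts = est.EstimationOptions(error_model="additive", maxiter=800,
                                     xatol=1e-5, fatol=1e-8)
        p1 = est.EstimationProblem(dataset=ds, config=cfg0,
                                   estimate=("clint0", "vc"), options=opts)
        r1 = est.fit_population(p1)
        p2 = est.EstimationProblem(dataset=ds, config=r1.config,
                                   estimate=("clint0", "vc"), options=opts)
        r2 = est.fit_population(p2)
        assert abs(r2.ofv - r1.ofv) < 0.01

    def test_unknown_parameter_names_rejected(self, pooled_trial):
        ds, cfg0 = pooled_trial
        with pytest.raises(ParameterError):
            est.EstimationProblem(dataset=ds, config=cfg0,
                                  estimate=("not_a_param",))
        with pytest.raises(ParameterError):
            est.EstimationProblem(dataset=ds, config=cfg0,
                                  estimate_omega=("bogus",))
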