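"""Design matrix, GLM fitting, nested tests, deviance, synergy, GoF."""

import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize

import spindlepp as sp
from spindlepp.model import (
    SPEC_TOKENS,
    ModelSpec,
    build_design_matrix,
    deviance_fractions,
    fit_point_process_glm,
    fit_spec,
    ks_uniform_statistic,
    likelihood_ratio_test,
    synergy_index,
    time_rescaling_from_intensity,
)

from conftest import constant_rate_covariates


def _poisson_train(rng, rate, T):
    ts = np.cumsum(rng.exponential(1 / rate, size=int(rate * T * 2) + 50))
    return ts[ts < T]


class TestDesignMatrix:
    def test_column_arithmetic_full_model(self, paper_night):
        spec = SPEC_TOKENS["stage+phase+interaction+history15"]
        basis = sp.HistoryBasis(tuple(np.linspace(0, 15, 10)))
        d = build_design_matrix(paper_night.cov, spec, basis)
        assert d.X.shape[1] == 5 + 2 + 10 + 10  # stage+phase+interaction+history

    def test_stage_block_is_one_hot(self, paper_night):
        d = build_design_matrix(paper_night.cov, SPEC_TOKENS["stage"])
        np.testing.assert_array_equal(d.X.sum(axis=1), 1.0)

    def test_history_columns_zero_without_recent_event(self):
        cov = constant_rate_covariates(100.0, 0.1, 0.1, [80.0])
        d = build_design_matrix(cov, SPEC_TOKENS["history15"])
        hist = d.X[:, 1:]  # after intercept
        assert np.all(hist[:800] == 0.0)       # before the only event
        assert np.any(hist[801:] != 0.0)

    def test_history_lag_is_causal(self):
        cov = constant_rate_covariates(10.0, 0.1, 0.1, [0.55])
        d = build_design_matrix(cov, SPEC_TOKENS["history15"])
        hist = d.X[:, 1:]
        assert np.all(hist[5] == 0.0)   # event's own bin sees no history
        assert np.any(hist[6] != 0.0)


class TestFitting:
    def test_intercept_only_closed_form(self, rng):
        ts = np.sort(rng.uniform(0, 3600.0, 600))
        cov = constant_rate_covariates(3600.0, 0.1, 600 / 3600, ts)
        m = fit_spec(cov, "null")
        n_binned = cov.counts.sum()  # closed-form MLE: total count / time
        assert np.exp(m.coef("intercept")) == pytest.approx(
            n_binned / 3600.0, rel=1e-10
        )

    def test_stage_only_equals_empirical_stage_rates(self, paper_night):
        m = fit_spec(paper_night.cov, "stage")
        cov = paper_night.cov
        for s in sp.STAGES:
            mask = cov.stage == s
            if mask.sum() == 0:
                continue
            empirical = cov.counts[mask].sum() / (mask.sum() * cov.dt_s)
            assert np.exp(m.coef(f"stage[{s}]")) == pytest.approx(
                empirical, rel=1e-8
            )

    def test_toy_design_matches_direct_optimizer(self, rng):
        # 20-bin, 2-column toy problem vs brute-force likelihood optimization
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = (rng.random(20) < 0.4).astype(float)
        dt = 0.5

        def negll(beta):
            eta = X @ beta + np.log(dt)
            return -(y @ eta - np.exp(eta).sum())

        oracle = optimize.minimize(negll, np.zeros(2), method="Nelder-Mead",
                                   options={"xatol": 1e-12, "fatol": 1e-14,
                                            "maxiter": 10000})
        d = sp.model.DesignMatrix(
            X=X,
            columns=["intercept", "x"],
            terms={"intercept": ["intercept"], "x": ["x"]},
            response=y,
            exposure_s=dt,
            spec=SPEC_TOKENS["null"],
        )
        m = fit_point_process_glm(d)
        np.testing.assert_allclose(m.params.to_numpy(), oracle.x, atol=1e-6)

    def test_full_night_fit_matches_statsmodels(self, paper_night, paper_fit):
        spec = SPEC_TOKENS["stage+phase+history15"]
        m = fit_spec(paper_night.cov, spec)
        d = build_design_matrix(paper_night.cov, spec)
        keep = [i for i, c in enumerate(d.columns) if c in m.params.index]
        res = sm.GLM(
            d.response,
            d.X[:, keep],
            family=sm.families.Poisson(),
            exposure=np.full(d.n_bins, d.exposure_s),
        ).fit()
        np.testing.assert_allclose(m.params.to_numpy(), res.params, atol=1e-6)
        np.testing.assert_allclose(m.log_likelihood, res.llf, rtol=1e-10)
        np.testing.assert_allclose(m.deviance, res.deviance, rtol=1e-10)
        np.testing.assert_allclose(
            m.cov_params.to_numpy(), res.cov_params(), atol=1e-8
        )

    def test_collinear_interaction_block_dropped(self, paper_fit):
        # global phase + all five stage interactions are rank-deficient by 2
        assert paper_fit.dropped == [
            "stagephase[Wake]_cos", "stagephase[Wake]_sin"
        ]

    def test_no_events_rejected(self):
        cov = constant_rate_covariates(100.0, 0.1, 0.0, [])
        with pytest.raises(ValueError, match="no events"):
            fit_spec(cov, "null")

    def test_loglik_never_decreases_with_nesting(self, paper_night):
        tokens = ["null", "stage", "stage+phase", "stage+phase+history15"]
        lls = [fit_spec(paper_night.cov, t).log_likelihood for t in tokens]
        assert np.all(np.diff(lls) >= -1e-6)


class TestLikelihoodRatio:
    def test_identical_models_give_zero_stat(self, paper_fit):
        stat, dof, p = likelihood_ratio_test(paper_fit, paper_fit)
        assert stat == 0.0 and dof == 0 and p == 1.0

    def test_dof_equals_added_columns(self, paper_night):
        m0 = fit_spec(paper_night.cov, "stage")
        m1 = fit_spec(paper_night.cov, "stage+phase")
        _, dof, _ = likelihood_ratio_test(m1, m0)
        assert dof == 2

    def test_non_nested_rejected(self, paper_night):
        m_stage = fit_spec(paper_night.cov, "stage")
        m_phase = fit_spec(paper_night.cov, "phase")
        with pytest.raises(ValueError, match="subset"):
            likelihood_ratio_test(m_stage, m_phase)

    def test_different_data_rejected(self, paper_night, rng):
        m_a = fit_spec(paper_night.cov, "stage")
        cov = constant_rate_covariates(
            600.0, 0.1, 0.2, _poisson_train(rng, 0.2, 600.0)
        )
        m_b = fit_spec(cov, "null")
        with pytest.raises(ValueError, match="identical data"):
            likelihood_ratio_test(m_a, m_b)


class TestDevianceDecomposition:
    def test_single_step_explains_100_percent(self, paper_night):
        m0 = fit_spec(paper_night.cov, "null")
        m1 = fit_spec(paper_night.cov, "stage+phase+history15")
        dec = deviance_fractions([m0, m1], names=["all"])
        assert dec.sequential_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_sequential_fractions_telescope(self, paper_night):
        tokens = ["null", "stage", "stage+phase", "stage+phase+history15"]
        chain = [fit_spec(paper_night.cov, t) for t in tokens]
        dec = deviance_fractions(chain, names=tokens[1:])
        assert sum(dec.sequential_pct) == pytest.approx(100.0, abs=1e-9)

    def test_increasing_deviance_rejected(self, paper_night):
        m0 = fit_spec(paper_night.cov, "null")
        m1 = fit_spec(paper_night.cov, "stage")
        with pytest.raises(ValueError, match="increases"):
            deviance_fractions([m1, m0])


class TestSynergy:
    def _stub(self, llf, key=(1, 100, 0)):
        import pandas as pd

        return sp.FittedModel(
            params=pd.Series(dtype=float),
            cov_params=pd.DataFrame(),
            log_likelihood=llf,
            deviance=0.0,
            n_events=100,
            n_bins=1,
            spec=ModelSpec(),
            basis=None,
            terms={},
            dropped=[],
            data_key=key,
        )

    def test_exactly_additive_gains_give_zero(self):
        null = self._stub(-1000.0)
        a = self._stub(-950.0)       # gain 50
        b = self._stub(-920.0)       # gain 80
        ab = self._stub(-870.0)      # gain 130 = 50 + 80
        assert synergy_index(null, a, b, ab).index == 0.0

    def test_duplicated_covariate_is_redundant(self, paper_night):
        # B duplicates A's covariate: joint gain equals each marginal gain,
        # so the index is -(I_A / I_AB) = -1
        cov = paper_night.cov
        null = fit_spec(cov, "null")
        a = fit_spec(cov, "phase")
        ab = fit_spec(cov, "phase")  # adding the same block adds nothing
        res = synergy_index(null, a, a, ab)
        assert res.index == pytest.approx(-1.0)
        assert res.index < 0

    def test_no_joint_gain_rejected(self, paper_night):
        m = fit_spec(paper_night.cov, "null")
        with pytest.raises(ValueError, match="undefined|no information"):
            synergy_index(m, m, m, m)


class TestTimeRescaling:
    def test_mid_quantile_grid_closed_form(self):
        for n in (10, 35, 200):
            z = (np.arange(1, n + 1) - 0.5) / n
            assert ks_uniform_statistic(z) == pytest.approx(1 / (2 * n))

    def test_too_few_events_rejected(self):
        lam = np.full(1000, 0.1)
        with pytest.raises(ValueError, match="10 events"):
            time_rescaling_from_intensity(lam, 0.1, np.arange(5) + 1.0)

    def test_fitted_model_passes_on_its_own_data(self, paper_night, paper_fit):
        g = sp.time_rescaling_ks(paper_fit, paper_night.train, paper_night.cov)
        assert g.n == paper_night.train.n_events - 1
        assert 0.0 <= g.ks_statistic <= 1.0
        assert g.pass_05

    def test_doubled_rate_fails(self, rng):
        rate = 10 / 60
        ts = _poisson_train(rng, rate, 3600.0)
        lam = np.full(36000, 2 * rate)
        g = time_rescaling_from_intensity(lam, 0.1, ts)
        assert not g.pass_05


class TestSpecTokens:
    def test_unknown_token_rejected(self, paper_night):
        with pytest.raises(KeyError, match="unknown model token"):
            fit_spec(paper_night.cov, "bogus")

    def test_invalid_spec_combinations_rejected(self):
        with pytest.raises(ValueError, match="stage×phase|stage"):
            ModelSpec(include_stage_phase=True)
        with pytest.raises(ValueError, match="history"):
            ModelSpec(history="medium")
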