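"""History-curve read-outs, feature extraction, phase coupling."""

import numpy as np
import pandas as pd
import pytest

import spindlepp as sp
from spindlepp.interpret import (
    HistoryCurve,
    extract_history_features,
    history_modulation_curve,
    infraslow_multiplier,
    phase_tuning,
    preferred_phase_vs_depth,
)
from spindlepp.model import FittedModel, ModelSpec


def make_model(coeffs: dict, cov: np.ndarray = None, spec=None, basis=None,
               terms=None):
    """Hand-built FittedModel for closed-form read-out checks."""
    labels = list(coeffs)
    if cov is None:
        cov = np.zeros((len(labels), len(labels)))
    return FittedModel(
        params=pd.Series(coeffs),
        cov_params=pd.DataFrame(cov, index=labels, columns=labels),
        log_likelihood=0.0,
        deviance=0.0,
        n_events=100,
        n_bins=1000,
        spec=spec or ModelSpec(include_phase=True),
        basis=basis,
        terms=terms or {"phase": ["phase_cos", "phase_sin"]},
        dropped=[],
        data_key=(1000, 100, 0),
    )


def synthetic_curve(lags, mid, half_width):
    """Curve with analytically placed CI crossings of 1."""
    return HistoryCurve(
        lags=lags,
        modulation=mid,
        ci_low=mid - half_width,
        ci_high=mid + half_width,
    )


class TestHistoryCurve:
    def test_null_history_curve_is_one(self, paper_night):
        m = sp.fit_spec(
            sp.simulate_night(
                sp.paper_like_scenario("null_history"), seed=3, dt_model=0.1
            ).cov,
            "stage+phase+history15",
        )
        curve = history_modulation_curve(m)
        # true modulation is 1 everywhere; CI must cover 1 nearly everywhere
        covered = (curve.ci_low <= 1.0) & (1.0 <= curve.ci_high)
        assert covered.mean() > 0.8
        assert np.all(np.abs(curve.modulation - 1.0) < 0.5)

    def test_exactly_one_beyond_last_knot(self, paper_fit):
        # the basis vanishes past its support, so the modulation snaps to 1
        h = np.array([paper_fit.coef(f"hist[{k}]") for k in range(15)])
        beyond = np.exp(paper_fit.basis.spline(np.array([15.5, 40.0, 90.0]), h))
        np.testing.assert_array_equal(beyond, 1.0)

    def test_lag_outside_support_rejected(self, paper_fit):
        with pytest.raises(ValueError, match="lag"):
            history_modulation_curve(paper_fit, np.array([16.0]))

    def test_model_without_history_rejected(self, paper_night):
        m = sp.fit_spec(paper_night.cov, "stage")
        with pytest.raises(ValueError, match="history"):
            history_modulation_curve(m)

    def test_recovers_known_modulation_within_15pct(self):
        # hard-refractory + peak-2 construction, one long night
        knots = (0.0, 1.0, 2.0, 2.75, 3.5, 4.5, 6.0, 8.0, 10.0)
        coeffs = (-4.0, -4.0, 0.0, 0.5, np.log(2.0), 0.35, 0.0, 0.0, 0.0)
        params = sp.TrueParameters(
            stage_log_rates={s: np.log(10 / 60) for s in sp.STAGES},
            history_coeffs=coeffs,
            history_knots=knots,
            seed=0,
        )
        scen = sp.SimulationScenario(
            duration_s=8 * 3600.0,
            params=params,
            stage_transition=tuple(
                tuple(float(i == j) for j in range(5)) for i in range(5)
            ),
            name="known_mod",
        )
        night = sp.simulate_night(scen, seed=17)
        basis = sp.HistoryBasis(knots)
        m = sp.fit_spec(night.cov, ModelSpec(history="short", dt_s=0.1),
                        basis=basis)
        grid = np.linspace(0.5, 10.0, 96)
        fitted = history_modulation_curve(m, grid).modulation
        truth = np.exp(basis.spline(grid, np.array(coeffs)))
        # compare where the truth is not essentially zero
        ok = truth > 0.2
        assert np.all(np.abs(fitted[ok] / truth[ok] - 1.0) < 0.15)


class TestFeatureExtraction:
    def test_reference_feature_values(self):
        # CI crossings placed analytically: upper CI crosses 1 at 1.8 s,
        # lower CI > 1 exactly on [2.0, 4.9], max 1.9 at 3.5 -> features
        # (1.8, 2.9, 3.5, 1.9)
        lags = np.arange(0.0, 15.0001, 0.001)
        upper = 0.1 + 0.5 * lags            # crosses 1 exactly at 1.8 s
        # positive exactly on (2.0, 4.9); parabola peak scaled to +0.9
        lower = 1.0 + 0.9 * (lags - 2.0) * (4.9 - lags) / (1.45**2)
        mid = 1.9 - 0.4 * np.abs(lags - 3.5)  # maximum 1.9 exactly at 3.5 s
        curve = HistoryCurve(lags=lags, modulation=mid, ci_low=lower,
                             ci_high=upper)
        f = extract_history_features(curve)
        assert f.refractory_s == pytest.approx(1.8, abs=0.002)
        assert f.excitatory_s == pytest.approx(2.9, abs=0.002)
        assert f.peak_time_s == pytest.approx(3.5, abs=0.002)
        assert f.peak_height == pytest.approx(1.9, abs=0.002)

    def test_flat_curve_has_empty_features(self):
        lags = np.linspace(0, 15, 301)
        curve = synthetic_curve(lags, np.ones(301), np.full(301, 0.1))
        f = extract_history_features(curve)
        assert f.refractory_s == 0.0
        assert f.excitatory_s == 0.0
        assert np.isnan(f.peak_time_s) and np.isnan(f.peak_height)

    def test_longest_run_wins(self):
        lags = np.linspace(0, 15, 1501)
        mid = np.ones(lags.size)
        mid[(lags > 1.0) & (lags < 2.0)] = 1.5        # 1-s run
        mid[(lags > 5.0) & (lags < 8.0)] = 1.4        # 3-s run
        curve = synthetic_curve(lags, mid, np.full(lags.size, 0.2))
        f = extract_history_features(curve)
        assert f.excitatory_s == pytest.approx(3.0, abs=0.05)
        assert 5.0 < f.peak_time_s < 8.0

    def test_zeroed_history_gives_null_features(self):
        # scale-consistency: h_k == 0 -> features (0, 0, NaN, NaN, 1.0)
        basis = sp.long_term_basis()
        curve = sp.true_history_curve(basis, np.zeros(basis.K))
        curve.ci_low = curve.modulation - 0.05
        curve.ci_high = curve.modulation + 0.05
        f = sp.features_with_infraslow(curve)
        assert (f.refractory_s, f.excitatory_s) == (0.0, 0.0)
        assert np.isnan(f.peak_time_s) and np.isnan(f.peak_height)
        assert f.infraslow_multiplier == pytest.approx(1.0)

    def test_refinement_stability_of_crossings(self, paper_fit):
        coarse = history_modulation_curve(
            paper_fit, np.arange(0, 15.0001, 0.1)
        )
        fine = history_modulation_curve(
            paper_fit, np.arange(0, 15.0001, 0.05)
        )
        fc, ff = extract_history_features(coarse), extract_history_features(fine)
        assert abs(fc.refractory_s - ff.refractory_s) < 0.1
        assert abs(fc.excitatory_s - ff.excitatory_s) < 0.1


class TestInfraslow:
    def _curve(self, mod_fn):
        lags = np.arange(0.0, 90.0001, 0.1)
        m = mod_fn(lags)
        return synthetic_curve(lags, m, np.full(lags.size, 0.01))

    def test_null_curve_gives_one(self):
        assert infraslow_multiplier(self._curve(lambda t: np.ones_like(t))) == \
            pytest.approx(1.0)

    def test_constant_two_gives_two(self):
        c = self._curve(lambda t: np.where((t >= 40) & (t <= 70), 2.0, 1.0))
        assert infraslow_multiplier(c) == pytest.approx(2.0, abs=0.02)

    def test_linear_ramp_gives_three_halves(self):
        c = self._curve(
            lambda t: np.where(
                (t >= 40) & (t <= 70), 1.0 + (t - 40) / 30.0, 1.0
            )
        )
        assert infraslow_multiplier(c) == pytest.approx(1.5, abs=1e-9)

    def test_short_curve_rejected(self):
        lags = np.linspace(0, 15, 100)
        c = synthetic_curve(lags, np.ones(100), np.full(100, 0.1))
        with pytest.raises(ValueError, match="span"):
            infraslow_multiplier(c)


class TestPhaseTuning:
    @pytest.mark.parametrize(
        "b1,b2,M,phi",
        [
            (1.0, 0.0, 1.0, 0.0),
            (0.0, 1.0, 1.0, np.pi / 2),
            (-0.3, 0.4, 0.5, 2.214297435588181),
        ],
    )
    def test_magnitude_and_angle_arithmetic(self, b1, b2, M, phi):
        m = make_model({"phase_cos": b1, "phase_sin": b2},
                       cov=np.eye(2) * 1e-6)
        pc = phase_tuning(m)
        assert pc.magnitude == pytest.approx(M, abs=1e-12)
        assert pc.phi_pref == pytest.approx(phi, abs=1e-12)

    def test_cosine_identity_on_dense_grid(self):
        # b1 cos(phi) + b2 sin(phi) == M cos(phi - phi_pref) to 1e-12
        b1, b2 = -0.37, 0.81
        m = make_model({"phase_cos": b1, "phase_sin": b2},
                       cov=np.eye(2) * 1e-6)
        pc = phase_tuning(m)
        grid = np.linspace(-np.pi, np.pi, 10001)
        lhs = b1 * np.cos(grid) + b2 * np.sin(grid)
        rhs = pc.magnitude * np.cos(grid - pc.phi_pref)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_phi_invariant_to_magnitude_scaling(self):
        for c in (0.1, 1.0, 7.3):
            m = make_model(
                {"phase_cos": -0.3 * c, "phase_sin": 0.4 * c},
                cov=np.eye(2) * 1e-6,
            )
            assert phase_tuning(m).phi_pref == pytest.approx(
                2.214297435588181, abs=1e-12
            )

    def test_stage_context_uses_interaction_deviation(self, paper_fit):
        pc_n2 = phase_tuning(paper_fit, "N2")
        pc_n3 = phase_tuning(paper_fit, "N3")
        # generative truth: N2 at the SO peak, N3 shifted to ~ -pi/8
        assert abs(pc_n2.phi_pref) < 0.45
        assert pc_n3.phi_pref < pc_n2.phi_pref

    def test_vacuous_stage_flags_no_preferred_phase(self):
        labels = ["phase_cos", "phase_sin",
                  "stagephase[N1]_cos", "stagephase[N1]_sin"]
        cov = np.diag([1e-6, 1e-6, 100.0, 100.0])
        m = make_model(
            dict(zip(labels, [0.2, 0.0, 0.01, 0.01])),
            cov=cov,
            terms={"phase": labels[:2], "stage_phase": labels[2:]},
        )
        pc = phase_tuning(m, "N1")
        assert pc.no_preferred_phase
        assert pc.ci == (-np.pi, np.pi)

    def test_phase_term_required(self, paper_night):
        m = sp.fit_spec(paper_night.cov, "stage")
        with pytest.raises(ValueError, match="phase"):
            phase_tuning(m)


class TestPhaseDepth:
    def test_zero_interaction_gives_flat_curve(self):
        labels = ["phase_cos", "phase_sin", "sopphase_cos", "sopphase_sin"]
        m = make_model(
            dict(zip(labels, [0.3, 0.1, 0.0, 0.0])),
            cov=np.eye(4) * 1e-6,
            terms={"phase": labels[:2], "sop_phase": labels[2:]},
        )
        c = preferred_phase_vs_depth(m)
        np.testing.assert_allclose(
            c.phi_pref, np.arctan2(0.1, 0.3), atol=1e-12
        )

    def test_grid_outside_unit_interval_rejected(self):
        labels = ["phase_cos", "phase_sin", "sopphase_cos", "sopphase_sin"]
        m = make_model(
            dict(zip(labels, [0.3, 0.1, 0.0, 0.0])),
            cov=np.eye(4) * 1e-6,
            terms={"phase": labels[:2], "sop_phase": labels[2:]},
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            preferred_phase_vs_depth(m, np.array([-0.1, 0.5]))

    def test_interaction_block_required(self, paper_fit):
        with pytest.raises(ValueError, match="SOP"):
            preferred_phase_vs_depth(paper_fit)
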