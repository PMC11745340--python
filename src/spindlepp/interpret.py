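"""Scientific read-outs of a fitted spindle point-process model.

Turns fitted coefficients into the quantities a sleep scientist reads:
the history modulation curve (multiplicative effect of a past spindle on
the current rate, with 95% CI), its summary features (refractory period,
excitatory period, peak time/height, infraslow multiplier), and SO
phase-coupling estimates — coupling magnitude M and preferred phase φ_pref
with delta-method CIs — per sleep stage or along the continuous sleep-depth
(SOP) axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import STAGES, wrap_phase
from .model import FittedModel

Z95 = 1.959963984540054


# --------------------------------------------------------------------------
# history curve


@dataclass
class HistoryCurve:
    """Multiplicative history modulation vs lag, with pointwise 95% CI."""

    lags: np.ndarray
    modulation: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": self.lags,
                "modulation": self.modulation,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def history_modulation_curve(model: FittedModel, lag_grid=None) -> HistoryCurve:
    """History modulation exp(Σ h_k g_k(lag)) with delta-method CI.

    The CI is pointwise: exp(linear predictor ± 1.96·SE), SE from the h_k
    covariance block.  Beyond the last knot the basis vanishes, so the
    modulation is exactly 1 with a degenerate CI.
    """
    if model.spec.history == "none" or model.basis is None:
        raise ValueError("model has no history term")
    basis = model.basis
    if lag_grid is None:
        lag_grid = np.arange(0.0, basis.max_lag_s + 1e-9, 0.05)
    lag_grid = np.asarray(lag_grid, dtype=float)
    if np.any(lag_grid < 0) or np.any(lag_grid > basis.max_lag_s):
        raise ValueError("lag grid outside [0, max_lag]")
    labels = [f"hist[{k}]" for k in range(basis.K)]
    h = np.array([model.coef(c) for c in labels])
    present = [c for c in labels if c in model.params.index]
    G = basis.evaluate(lag_grid)
    eta = G @ h
    cov = model.cov_params.loc[present, present].to_numpy()
    Gp = G[:, [labels.index(c) for c in present]]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Gp, cov, Gp), 0.0))
    return HistoryCurve(
        lags=lag_grid,
        modulation=np.exp(eta),
        ci_low=np.exp(eta - Z95 * se),
        ci_high=np.exp(eta + Z95 * se),
    )


def true_history_curve(basis, coeffs, lag_grid=None) -> HistoryCurve:
    """Ground-truth modulation curve of a generative parameter set.

    CIs collapse onto the curve; useful as the comparison target in
    parameter-recovery studies.
    """
    if lag_grid is None:
        lag_grid = np.arange(0.0, basis.max_lag_s + 1e-9, 0.05)
    lag_grid = np.asarray(lag_grid, dtype=float)
    m = np.exp(basis.spline(lag_grid, np.asarray(coeffs, float)))
    return HistoryCurve(lags=lag_grid, modulation=m, ci_low=m.copy(), ci_high=m.copy())


# --------------------------------------------------------------------------
# history features


@dataclass
class HistoryFeatures:
    """Summary features of a history curve (NaN when undefined)."""

    refractory_s: float        # run from lag 0 with upper CI < 1
    excitatory_s: float        # longest run with lower CI > 1
    peak_time_s: float         # lag of max modulation in that run
    peak_height: float
    infraslow_multiplier: float = np.nan   # mean modulation over 40-70 s

    def as_dict(self) -> dict:
        return {
            "refractory_s": self.refractory_s,
            "excitatory_s": self.excitatory_s,
            "peak_time_s": self.peak_time_s,
            "peak_height": self.peak_height,
            "infraslow_multiplier": self.infraslow_multiplier,
        }


def _crossing(lags, values, i, level=1.0):
    """Linear-interpolated lag where values crosses `level` in [i, i+1]."""
    x0, x1 = lags[i], lags[i + 1]
    y0, y1 = values[i], values[i + 1]
    if y1 == y0:
        return x1
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def _significant_runs(mask):
    """(start, end) index pairs of contiguous True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[splits + 1]]
    ends = np.r_[idx[splits], idx[-1]]
    return list(zip(starts, ends))


def extract_history_features(curve: HistoryCurve) -> HistoryFeatures:
    """Refractory / excitatory / peak features from a curve with CIs.

    Refractory period: length of the maximal contiguous run starting at lag
    0 where the upper CI stays below 1.  Excitatory period: length of the
    longest contiguous run (anywhere) with the lower CI above 1; the peak is
    the modulation maximum inside it.  Run edges are located by linear
    interpolation between grid points; empty windows give NaN features.
    """
    lags, lo, hi, m = curve.lags, curve.ci_low, curve.ci_high, curve.modulation
    # refractory, anchored at lag 0
    refractory = 0.0
    below = hi < 1.0
    if below[0]:
        end = int(np.argmin(below)) if not below.all() else below.size - 1
        if below.all():
            refractory = lags[-1] - lags[0]
        else:
            refractory = _crossing(lags, hi, end - 1) - lags[0]
    # excitatory: longest run of lower CI > 1
    runs = _significant_runs(lo > 1.0)
    excitatory = np.nan
    peak_t = np.nan
    peak_h = np.nan
    if runs:
        best, best_len = None, -1.0
        for s, e in runs:
            left = lags[s] if s == 0 else _crossing(lags, lo, s - 1)
            right = lags[e] if e == lo.size - 1 else _crossing(lags, lo, e)
            if right - left > best_len:
                best, best_len = (s, e, left, right), right - left
        s, e, left, right = best
        excitatory = best_len
        j = s + int(np.argmax(m[s : e + 1]))
        peak_t = float(lags[j])
        peak_h = float(m[j])
    else:
        excitatory = 0.0 if np.any(lo > 0) else np.nan
    return HistoryFeatures(
        refractory_s=float(refractory),
        excitatory_s=float(excitatory),
        peak_time_s=peak_t,
        peak_height=peak_h,
    )


def infraslow_multiplier(
    curve: HistoryCurve, window=(40.0, 70.0)
) -> float:
    """Mean modulation over the infraslow window (trapezoid / width).

    A null curve (modulation ≡ 1) gives exactly 1; values above 1 mean an
    excess likelihood of a spindle 40–70 s after the previous one.
    """
    lo, hi = window
    if curve.lags[-1] < hi:
        raise ValueError(f"curve must span at least {hi} s of lag")
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    x, y = curve.lags[mask], curve.modulation[mask]
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def features_with_infraslow(curve: HistoryCurve) -> HistoryFeatures:
    """Full feature set; infraslow multiplier only when the span allows."""
    f = extract_history_features(curve)
    if curve.lags[-1] >= 70.0:
        f.infraslow_multiplier = infraslow_multiplier(curve)
    return f


# --------------------------------------------------------------------------
# phase coupling


@dataclass
class PhaseCoupling:
    """Cosine phase-tuning summary M·cos(φ − φ_pref)."""

    magnitude: float
    phi_pref: float
    ci: tuple            # (low, high) radians, arc containing phi_pref
    context: str = "all"
    no_preferred_phase: bool = False


def _effective_pair(model: FittedModel, context: str | None):
    """Context-specific (b1, b2) with labels contributing to each entry."""
    if "phase_cos" not in model.params.index:
        raise ValueError("model has no phase term")
    cos_labels = ["phase_cos"]
    sin_labels = ["phase_sin"]
    if context is not None and context != "all":
        if context not in STAGES:
            raise ValueError(f"unknown stage context {context!r}")
        if "stage_phase" not in model.terms:
            raise ValueError("stage context requires stage×phase terms")
        cos_labels.append(f"stagephase[{context}]_cos")
        sin_labels.append(f"stagephase[{context}]_sin")
    b1 = sum(model.coef(c) for c in cos_labels)
    b2 = sum(model.coef(c) for c in sin_labels)
    labels = [c for c in cos_labels + sin_labels if c in model.params.index]
    grad = {c: 0.0 for c in labels}
    return b1, b2, labels, grad, cos_labels, sin_labels


def _angle_ci(model, b1, b2, labels, cos_labels, sin_labels, scale_cos=1.0, scale_sin=1.0):
    """Delta-method variance of atan2(b2, b1) over the coefficient cov."""
    m2 = b1 * b1 + b2 * b2
    if m2 == 0:
        return np.inf
    grad = []
    for c in labels:
        g = 0.0
        if c in cos_labels:
            g += -b2 / m2 * scale_cos
        if c in sin_labels:
            g += b1 / m2 * scale_sin
        grad.append(g)
    grad = np.asarray(grad)
    cov = model.cov_params.loc[labels, labels].to_numpy()
    return float(grad @ cov @ grad)


def phase_tuning(model: FittedModel, context: str | None = None) -> PhaseCoupling:
    """Coupling magnitude and preferred phase, optionally per sleep stage.

    The fitted pair (b1, b2) — global phase coefficients plus the stage's
    interaction deviation when a stage context is given — maps to
    M = √(b1²+b2²) and φ_pref = atan2(b2, b1).  The φ_pref CI comes from the
    delta method on the angle; an arc of 2π or more is flagged as "no
    statistically relevant preferred phase".
    """
    b1, b2, labels, _, cosl, sinl = _effective_pair(model, context)
    M = float(np.hypot(b1, b2))
    phi = float(np.arctan2(b2, b1))
    var = _angle_ci(model, b1, b2, labels, cosl, sinl)
    half = Z95 * np.sqrt(var) if np.isfinite(var) else np.inf
    none_flag = bool(2 * half >= 2 * np.pi)
    if none_flag:
        ci = (-np.pi, np.pi)
    else:
        ci = (float(wrap_phase(phi - half)), float(wrap_phase(phi + half)))
    return PhaseCoupling(
        magnitude=M,
        phi_pref=phi,
        ci=ci,
        context=context or "all",
        no_preferred_phase=none_flag,
    )


@dataclass
class PhaseDepthCurve:
    """Preferred phase as a function of normalized SO power."""

    sop_grid: np.ndarray
    phi_pref: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sop": self.sop_grid,
                "phi_pref": self.phi_pref,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def preferred_phase_vs_depth(model: FittedModel, sop_grid=None) -> PhaseDepthCurve:
    """φ_pref along the sleep-depth continuum from SOP×phase interactions.

    At depth u the effective pair is (β1 + β_{u,1}·u, β2 + β_{u,2}·u); the
    point curve is unwrapped along the grid for continuity before the
    delta-method CI band is attached, then re-wrapped for reporting.
    """
    if "sop_phase" not in model.terms:
        raise ValueError("model has no SOP×phase interaction block")
    if sop_grid is None:
        sop_grid = np.linspace(0.0, 1.0, 21)
    sop_grid = np.asarray(sop_grid, dtype=float)
    if np.any(sop_grid < 0) or np.any(sop_grid > 1):
        raise ValueError("SOP grid must lie within [0, 1]")
    base = np.array([model.coef("phase_cos"), model.coef("phase_sin")])
    inter = np.array([model.coef("sopphase_cos"), model.coef("sopphase_sin")])
    labels = [
        c
        for c in ("phase_cos", "phase_sin", "sopphase_cos", "sopphase_sin")
        if c in model.params.index
    ]
    cov = model.cov_params.loc[labels, labels].to_numpy()
    phis, halves = [], []
    for u in sop_grid:
        b1 = base[0] + inter[0] * u
        b2 = base[1] + inter[1] * u
        m2 = b1 * b1 + b2 * b2
        phis.append(np.arctan2(b2, b1))
        grad_map = {
            "phase_cos": -b2 / m2,
            "phase_sin": b1 / m2,
            "sopphase_cos": -b2 * u / m2,
            "sopphase_sin": b1 * u / m2,
        }
        g = np.array([grad_map[c] for c in labels])
        halves.append(Z95 * np.sqrt(max(g @ cov @ g, 0.0)))
    phis = np.unwrap(np.asarray(phis))
    halves = np.asarray(halves)
    return PhaseDepthCurve(
        sop_grid=sop_grid,
        phi_pref=wrap_phase(phis),
        ci_low=wrap_phase(phis - halves),
        ci_high=wrap_phase(phis + halves),
    )


# --------------------------------------------------------------------------
# plotting


def plot_history_curve(curve: HistoryCurve, ax=None, **kwargs):
    """History modulation with shaded 95% CI band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve.lags, curve.ci_low, curve.ci_high, alpha=0.3, color="gray")
    ax.plot(curve.lags, curve.modulation, color="black", **kwargs)
    ax.axhline(1.0, ls=":", color="gray")
    ax.set_xlabel("lag since last spindle (s)")
    ax.set_ylabel("rate modulation")
    return ax
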