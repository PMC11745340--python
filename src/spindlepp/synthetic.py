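"""Ground-truth night simulator for the spindle point-process model.

Generates a full synthetic night — Markov-chain hypnogram, a band-limited
slow-oscillation proxy (phase + normalized power), and a history-dependent
spindle train drawn from the conditional-intensity model with known
parameters — so that every downstream stage (fitting, interpretation,
population comparison) has a parameter-recovery test surface with no data
download.

The default ``paper_default`` scenario is calibrated to the regime reported
for healthy sleepers: N2 baseline ≈ 11 events/min, a history curve crossing
1 at 1.8 s (refractory), peaking at 1.9× at 3.5 s with a ≈2.9-s excitatory
window, and a preferred SO phase at the up-state peak in N2 shifting to
≈ −π/8 in N3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .events import (
    STAGES,
    CovariateSeries,
    EventTrain,
    Hypnogram,
    assemble_covariates,
    wrap_phase,
)
from .splines import LONG_KNOTS, SHORT_KNOTS, HistoryBasis

# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class TrueParameters:
    """Generative coefficients of the conditional-intensity model.

    ``stage_log_rates`` are log baseline rates (log events/s) per stage;
    optional blocks (phase pair, stage×phase deviations, quadratic SOP pair,
    SOP×phase pair, history control values on ``history_knots``) are simply
    omitted (None) when inactive.
    """

    stage_log_rates: dict
    phase_beta: tuple | None = None
    stage_phase_beta: dict | None = None
    sop_alpha: tuple | None = None
    sop_phase_beta: tuple | None = None
    history_coeffs: tuple | None = None
    history_knots: tuple = SHORT_KNOTS
    history_tension: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.stage_log_rates) - set(STAGES)
        if missing:
            raise ValueError(f"unknown stages in stage_log_rates: {missing}")
        rates = np.exp(list(self.stage_log_rates.values()))
        if np.any(~np.isfinite(rates)) or np.any(rates <= 0) or np.any(rates > 2):
            raise ValueError("exp(stage_log_rates) must lie in (0, 2] events/s")
        knots = np.asarray(self.history_knots, float)
        if np.any(np.diff(knots) <= 0) or knots[0] < 0 or knots[-1] > 90:
            raise ValueError("history_knots must increase within [0, 90] s")
        if self.history_coeffs is not None and len(self.history_coeffs) != len(knots):
            raise ValueError("history_coeffs length must match history_knots")

    def history_basis(self) -> HistoryBasis:
        return HistoryBasis(self.history_knots, self.history_tension)


@dataclass(frozen=True)
class SimulationScenario:
    """A complete recipe for one synthetic night."""

    duration_s: float
    params: TrueParameters
    epoch_s: float = 30.0
    stage_transition: tuple = ()          # row-stochastic 5x5, STAGES order
    so_freq_hz: float = 0.85
    initial_stage: str = "N2"
    sop_stage_coupling: float = 0.8       # 1 = SOP fully stage-linked
    history_mode: str = "last"            # last | sum
    name: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0.4 <= self.so_freq_hz <= 1.5:
            raise ValueError("so_freq_hz must lie in [0.4, 1.5]")
        P = np.asarray(self.stage_transition, dtype=float)
        if P.shape != (5, 5):
            raise ValueError("stage_transition must be 5x5 over the stage set")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12) or np.any(P < 0):
            raise ValueError("stage_transition rows must be stochastic")
        object.__setattr__(
            self, "stage_transition", tuple(map(tuple, P.tolist()))
        )
        if self.history_mode not in ("last", "sum"):
            raise ValueError("history_mode must be 'last' or 'sum'")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "duration_s": self.duration_s,
            "epoch_s": self.epoch_s,
            "stage_transition": [list(r) for r in self.stage_transition],
            "so_freq_hz": self.so_freq_hz,
            "initial_stage": self.initial_stage,
            "sop_stage_coupling": self.sop_stage_coupling,
            "history_mode": self.history_mode,
            "params": {
                "stage_log_rates": dict(self.params.stage_log_rates),
                "phase_beta": self.params.phase_beta,
                "stage_phase_beta": (
                    {k: list(v) for k, v in self.params.stage_phase_beta.items()}
                    if self.params.stage_phase_beta
                    else None
                ),
                "sop_alpha": self.params.sop_alpha,
                "sop_phase_beta": self.params.sop_phase_beta,
                "history_coeffs": self.params.history_coeffs,
                "history_knots": list(self.params.history_knots),
                "history_tension": self.params.history_tension,
                "seed": self.params.seed,
            },
        }
        return d


# --------------------------------------------------------------------------
# hypnogram


def simulate_hypnogram(
    duration_s: float,
    epoch_s: float,
    stage_transition,
    seed,
    initial_stage: str = "N2",
) -> Hypnogram:
    """Markov-chain hypnogram on scoring epochs."""
    P = np.asarray(stage_transition, dtype=float)
    if P.shape != (5, 5) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12) or np.any(P < 0):
        raise ValueError("stage_transition must be a row-stochastic 5x5 matrix")
    if duration_s < epoch_s or epoch_s <= 0:
        raise ValueError("need duration_s >= epoch_s > 0")
    rng = np.random.default_rng(seed)
    n_epochs = int(np.ceil(duration_s / epoch_s))
    state = STAGES.index(initial_stage)
    out = []
    cum = np.cumsum(P, axis=1)
    draws = rng.random(n_epochs)
    for k in range(n_epochs):
        out.append(STAGES[state])
        state = int(np.searchsorted(cum[state], draws[k], side="right"))
        state = min(state, 4)
    return Hypnogram(stages=tuple(out), epoch_s=epoch_s)


# --------------------------------------------------------------------------
# slow-oscillation proxy


@dataclass
class SoSeries:
    """Simulated SO covariates on a fine grid (bin centers)."""

    dt_s: float
    phase: np.ndarray       # ground-truth oscillation phase, (−π, π]
    sop: np.ndarray         # normalized SO power, [0, 1]
    raw_db: np.ndarray      # pre-normalization band power (dB)
    amplitude: np.ndarray

    @property
    def t(self) -> np.ndarray:
        return (np.arange(self.phase.size) + 0.5) * self.dt_s


def simulate_so_covariates(
    duration_s: float,
    dt_s: float,
    so_freq_hz: float,
    amplitude_profile=None,
    seed=0,
) -> SoSeries:
    """Slow-oscillation phase and power series.

    The SO proxy is A(t)·cos(θ(t)) with θ = 2π·f·t, so phase 0 falls
    exactly on oscillation maxima.  ``amplitude_profile`` is a scalar or a
    per-bin array; raw power is 20·log10 A (dB) and the normalized SOP is
    its 5th–95th percentile rescaling clipped to [0, 1].
    """
    if not (0 < dt_s <= 0.5):
        raise ValueError("dt_s must lie in (0, 0.5]")
    if not 0.4 <= so_freq_hz <= 1.5:
        raise ValueError("so_freq_hz must lie in [0.4, 1.5]")
    if dt_s >= 0.5 / so_freq_hz:
        raise ValueError("dt_s too coarse to resolve the SO frequency")
    n = int(np.round(duration_s / dt_s))
    t = (np.arange(n) + 0.5) * dt_s
    if amplitude_profile is None:
        amplitude = np.ones(n)
    else:
        amplitude = np.broadcast_to(
            np.asarray(amplitude_profile, dtype=float), (n,)
        ).copy()
    if np.any(amplitude <= 0):
        raise ValueError("amplitude profile must be positive")
    phase = wrap_phase(2.0 * np.pi * so_freq_hz * t)
    raw_db = 20.0 * np.log10(amplitude)
    p5, p95 = np.percentile(raw_db, [5, 95])
    if p95 - p5 < 1e-12:
        sop = np.full(n, 0.5)
    else:
        sop = np.clip((raw_db - p5) / (p95 - p5), 0.0, 1.0)
    return SoSeries(dt_s=dt_s, phase=phase, sop=sop, raw_db=raw_db, amplitude=amplitude)


#: relative SO amplitude by stage (deeper sleep -> larger slow waves)
_STAGE_AMPLITUDE = {"Wake": 0.25, "REM": 0.35, "N1": 0.55, "N2": 1.0, "N3": 1.9}


def stage_amplitude_profile(
    hypnogram: Hypnogram,
    dt_s: float,
    coupling: float = 0.8,
    seed=0,
    smooth_s: float = 60.0,
) -> np.ndarray:
    """Slow SO-amplitude envelope tied to sleep stage.

    ``coupling`` in [0, 1] blends the stage-linked envelope with slow
    log-normal noise so stage and SOP correlate as in real sleep, without
    being redundant.
    """
    rng = np.random.default_rng(seed)
    n = int(np.round(hypnogram.duration_s / dt_s))
    t = (np.arange(n) + 0.5) * dt_s
    base = np.array(
        [_STAGE_AMPLITUDE[s] for s in hypnogram.stage_at(t)], dtype=float
    )
    win = max(int(smooth_s / dt_s), 1)
    smooth = uniform_filter1d(base, size=win, mode="nearest")
    noise = rng.standard_normal(max(n // win + 2, 2))
    noise_t = np.interp(t, np.linspace(0, hypnogram.duration_s, noise.size), noise)
    log_amp = coupling * np.log(smooth) + (1.0 - coupling) * 0.4 * noise_t
    return np.exp(log_amp)


# --------------------------------------------------------------------------
# event train

_SIM_DT = 0.05  # simulation bin (s); finer than the fitting grid


def _baseline_log_rate(
    params: TrueParameters,
    stage: np.ndarray,
    phase: np.ndarray,
    sop: np.ndarray,
) -> np.ndarray:
    """Per-bin log intensity from everything except history."""
    rate_map = {s: params.stage_log_rates.get(s, -np.inf) for s in STAGES}
    base = np.array([rate_map[s] for s in stage], dtype=float)
    cosp, sinp = np.cos(phase), np.sin(phase)
    if params.phase_beta is not None:
        b1, b2 = params.phase_beta
        base += b1 * cosp + b2 * sinp
    if params.stage_phase_beta:
        for s, (d1, d2) in params.stage_phase_beta.items():
            mask = stage == s
            base[mask] += d1 * cosp[mask] + d2 * sinp[mask]
    if params.sop_alpha is not None:
        a1, a2 = params.sop_alpha
        base += a1 * sop + a2 * sop**2
    if params.sop_phase_beta is not None:
        u1, u2 = params.sop_phase_beta
        base += sop * (u1 * cosp + u2 * sinp)
    return base


def simulate_event_train(
    scenario: SimulationScenario,
    dt_s: float = _SIM_DT,
    seed=None,
    hypnogram: Hypnogram | None = None,
    so: SoSeries | None = None,
) -> EventTrain:
    """Draw a spindle train from the conditional-intensity model.

    Discrete-time sampling: each bin fires with probability
    1 − exp(−λ·dt), λ evaluated at the bin center with the running event
    history.  With ``history_mode='last'`` the history term is the spline at
    the lag since the most recent event (the fitted model's form, sampled
    exactly via exponential thresholds on the cumulative hazard); with
    ``'sum'`` log-contributions of all past events within the basis support
    add up.
    """
    params = scenario.params
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    ss_hyp, ss_so, ss_ev = root.spawn(3)
    if hypnogram is None:
        hypnogram = simulate_hypnogram(
            scenario.duration_s,
            scenario.epoch_s,
            scenario.stage_transition,
            ss_hyp,
            scenario.initial_stage,
        )
    if so is None:
        amp = stage_amplitude_profile(
            hypnogram, dt_s, scenario.sop_stage_coupling, ss_so
        )
        so = simulate_so_covariates(
            scenario.duration_s, dt_s, scenario.so_freq_hz, amp, ss_so
        )
    n = so.phase.size
    t_centers = (np.arange(n) + 0.5) * dt_s
    stage = hypnogram.stage_at(t_centers)
    base = _baseline_log_rate(params, stage, so.phase, so.sop)
    if np.any(np.isnan(base)) or np.any(base == np.inf):
        raise FloatingPointError("non-finite log intensity; simulation aborted")
    lam0 = np.exp(base)
    if lam0.max() * dt_s >= 0.2:
        raise FloatingPointError(
            f"max λ·dt = {lam0.max() * dt_s:.3f} ≥ 0.2; shrink dt_s"
        )
    rng = np.random.default_rng(ss_ev)
    if params.history_coeffs is None or not np.any(params.history_coeffs):
        mod = None
    else:
        basis = params.history_basis()
        W = int(np.floor(basis.max_lag_s / dt_s))
        logmod = basis.spline(np.arange(1, W + 1) * dt_s, params.history_coeffs)
        mod = np.exp(logmod)
    haz0 = lam0 * dt_s
    if scenario.history_mode == "sum" and mod is not None:
        return _simulate_sum_mode(haz0, np.log(mod), dt_s, scenario, rng)
    C = np.concatenate([[0.0], np.cumsum(haz0)])  # C[k] = hazard of bins < k
    events: list[int] = []
    e = -1  # bin index of last event
    while True:
        E = rng.standard_exponential()
        k_new = None
        if mod is not None and e >= 0:
            w0, w1 = e + 1, min(e + 1 + mod.size, n)
            hz = haz0[w0:w1] * mod[: w1 - w0]
            cum = np.cumsum(hz)
            if cum.size and cum[-1] >= E:
                k_new = w0 + int(np.searchsorted(cum, E, side="left"))
            else:
                E -= cum[-1] if cum.size else 0.0
                tail0 = w1
                k = int(np.searchsorted(C, C[tail0] + E, side="left")) - 1
                k_new = k if k < n else None
        else:
            tail0 = e + 1
            k = int(np.searchsorted(C, C[tail0] + E, side="left")) - 1
            k_new = k if k < n else None
        if k_new is None:
            break
        events.append(k_new)
        e = k_new
    times = (np.asarray(events, dtype=float) + 0.5) * dt_s
    return EventTrain(times=times, duration_s=n * dt_s, subject_id=scenario.name)


def _simulate_sum_mode(haz0, logmod, dt_s, scenario, rng) -> EventTrain:
    """Per-bin sampling with additive log-contributions of all past events."""
    n = haz0.size
    W = logmod.size
    contrib = np.zeros(n)
    u = rng.random(n)
    events = []
    for k in range(n):
        p = 1.0 - np.exp(-haz0[k] * np.exp(contrib[k]))
        if u[k] < p:
            events.append(k)
            hi = min(k + 1 + W, n)
            contrib[k + 1 : hi] += logmod[: hi - k - 1]
    times = (np.asarray(events, dtype=float) + 0.5) * dt_s
    return EventTrain(times=times, duration_s=n * dt_s, subject_id=scenario.name)


# --------------------------------------------------------------------------
# whole-night convenience


@dataclass
class SimulatedNight:
    """One synthetic night: hypnogram, SO series, train, model-grid covariates."""

    scenario: SimulationScenario
    hypnogram: Hypnogram
    so: SoSeries
    train: EventTrain
    cov: CovariateSeries
    seed: int


def simulate_night(
    scenario: SimulationScenario,
    seed=None,
    dt_model: float = 0.1,
    dt_sim: float = _SIM_DT,
) -> SimulatedNight:
    """Generate a night and assemble covariates on the fitting grid."""
    used_seed = scenario.params.seed if seed is None else seed
    root = np.random.SeedSequence(used_seed)
    ss_hyp, ss_so, ss_ev = root.spawn(3)
    hyp = simulate_hypnogram(
        scenario.duration_s,
        scenario.epoch_s,
        scenario.stage_transition,
        ss_hyp,
        scenario.initial_stage,
    )
    amp = stage_amplitude_profile(hyp, dt_sim, scenario.sop_stage_coupling, ss_so)
    so = simulate_so_covariates(
        scenario.duration_s, dt_sim, scenario.so_freq_hz, amp, ss_so
    )
    train = simulate_event_train(
        scenario, dt_sim, seed=used_seed, hypnogram=hyp, so=so
    )
    cov = assemble_covariates(
        train, hyp, so.phase, so.sop, dt_model, phase_t=so.t, sop_t=so.t
    )
    return SimulatedNight(
        scenario=scenario, hypnogram=hyp, so=so, train=train, cov=cov,
        seed=used_seed if isinstance(used_seed, int) else -1,
    )


# --------------------------------------------------------------------------
# scenario registry

#: epoch-to-epoch stage transition probabilities (rows: from, STAGES order)
DEFAULT_TRANSITION = (
    (0.78, 0.15, 0.00, 0.03, 0.04),   # N1
    (0.015, 0.915, 0.040, 0.020, 0.010),  # N2
    (0.000, 0.060, 0.930, 0.005, 0.005),  # N3
    (0.010, 0.040, 0.000, 0.935, 0.015),  # REM
    (0.060, 0.050, 0.000, 0.010, 0.880),  # Wake
)

#: true history control values (log modulation at the short-term knots),
#: calibrated so the true curve crosses 1 at 1.8 s and peaks at 1.9x at 3.5 s
PAPER_HISTORY_COEFFS = (
    -2.80, -2.80, -2.20, -0.42, 0.18, 0.47, 0.50, 0.642, 0.50,
    -0.15, -0.05, 0.0, 0.0, 0.0, 0.0,
)

#: long-term extension: a small infraslow bump near 50-60 s
PAPER_HISTORY_COEFFS_90 = PAPER_HISTORY_COEFFS + (
    0.0, 0.02, 0.05, 0.05, 0.02, 0.0, 0.0,
)

#: preferred-phase shift at deep sleep (rad): up-state peak -> rising phase
N3_PHASE_SHIFT = -np.pi / 8

_M_PHASE = 0.22  # phase-coupling magnitude

_BASE_RATES = {
    "N1": np.log(1.5 / 60.0),
    "N2": np.log(11.0 / 60.0),
    "N3": np.log(5.0 / 60.0),
    "REM": np.log(0.5 / 60.0),
    "Wake": np.log(0.5 / 60.0),
}


def _rotated_deviation(m: float, shift: float) -> tuple:
    """Interaction pair turning a (m, 0) global pair into phase `shift`."""
    return (m * (np.cos(shift) - 1.0), m * np.sin(shift))


def _paper_params(seed: int = 0, history=PAPER_HISTORY_COEFFS, knots=SHORT_KNOTS):
    return TrueParameters(
        stage_log_rates=dict(_BASE_RATES),
        phase_beta=(_M_PHASE, 0.0),
        stage_phase_beta={"N3": _rotated_deviation(_M_PHASE, N3_PHASE_SHIFT)},
        history_coeffs=history,
        history_knots=knots,
        seed=seed,
    )


def _scenario_paper_default(seed: int = 0) -> SimulationScenario:
    return SimulationScenario(
        duration_s=8 * 3600.0,
        params=_paper_params(seed),
        stage_transition=DEFAULT_TRANSITION,
        name="paper_default",
    )


def _scenario_paper_long(seed: int = 0) -> SimulationScenario:
    return SimulationScenario(
        duration_s=8 * 3600.0,
        params=_paper_params(seed, PAPER_HISTORY_COEFFS_90, LONG_KNOTS),
        stage_transition=DEFAULT_TRANSITION,
        name="paper_long",
    )


def _scenario_null_history(seed: int = 0) -> SimulationScenario:
    params = TrueParameters(
        stage_log_rates=dict(_BASE_RATES),
        phase_beta=(_M_PHASE, 0.0),
        stage_phase_beta={"N3": _rotated_deviation(_M_PHASE, N3_PHASE_SHIFT)},
        history_coeffs=tuple(0.0 for _ in SHORT_KNOTS),
        seed=seed,
    )
    return SimulationScenario(
        duration_s=8 * 3600.0,
        params=params,
        stage_transition=DEFAULT_TRANSITION,
        name="null_history",
    )


def _scenario_phase_shift(seed: int = 0) -> SimulationScenario:
    """φpref(N2) = 0, φpref(N3) = −π/8; no history (pure coupling study)."""
    params = TrueParameters(
        stage_log_rates=dict(_BASE_RATES),
        phase_beta=(_M_PHASE, 0.0),
        stage_phase_beta={"N3": _rotated_deviation(_M_PHASE, N3_PHASE_SHIFT)},
        history_coeffs=None,
        seed=seed,
    )
    return SimulationScenario(
        duration_s=8 * 3600.0,
        params=params,
        stage_transition=DEFAULT_TRANSITION,
        name="phase_shift",
    )


def _scenario_history_only(seed: int = 0) -> SimulationScenario:
    """All stages share one baseline; no phase coupling; history on."""
    rate = np.log(8.0 / 60.0)
    params = TrueParameters(
        stage_log_rates={s: rate for s in STAGES},
        phase_beta=None,
        history_coeffs=PAPER_HISTORY_COEFFS,
        seed=seed,
    )
    return SimulationScenario(
        duration_s=8 * 3600.0,
        params=params,
        stage_transition=DEFAULT_TRANSITION,
        name="history_only",
    )


def _scenario_constant_rate(seed: int = 0) -> SimulationScenario:
    rate = np.log(10.0 / 60.0)
    params = TrueParameters(
        stage_log_rates={s: rate for s in STAGES},
        seed=seed,
    )
    return SimulationScenario(
        duration_s=3600.0,
        params=params,
        stage_transition=DEFAULT_TRANSITION,
        name="constant_rate",
    )


def _scenario_phase_drift(seed: int = 0) -> SimulationScenario:
    """Preferred phase drifting from 0 at SOP=0 to −π/8 at SOP=1."""
    rate = np.log(10.0 / 60.0)
    params = TrueParameters(
        stage_log_rates={s: rate for s in STAGES},
        phase_beta=(_M_PHASE, 0.0),
        sop_alpha=(0.6, -0.2),
        sop_phase_beta=_rotated_deviation(_M_PHASE, N3_PHASE_SHIFT),
        history_coeffs=PAPER_HISTORY_COEFFS,
        seed=seed,
    )
    return SimulationScenario(
        duration_s=8 * 3600.0,
        params=params,
        stage_transition=DEFAULT_TRANSITION,
        name="phase_drift",
    )


_REGISTRY = {
    "paper_default": _scenario_paper_default,
    "paper_long": _scenario_paper_long,
    "null_history": _scenario_null_history,
    "phase_shift": _scenario_phase_shift,
    "history_only": _scenario_history_only,
    "constant_rate": _scenario_constant_rate,
    "phase_drift": _scenario_phase_drift,
}


def scenario_registry() -> tuple:
    """Names of the registered simulation scenarios."""
    return tuple(sorted(_REGISTRY))


def paper_like_scenario(name: str, seed: int = 0, **overrides) -> SimulationScenario:
    """Look up a registered scenario (optionally overriding scenario fields)."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown scenario {name!r}; registry: {list(scenario_registry())}"
        )
    scen = _REGISTRY[name](seed)
    if overrides:
        d = {
            "duration_s": scen.duration_s,
            "params": scen.params,
            "epoch_s": scen.epoch_s,
            "stage_transition": scen.stage_transition,
            "so_freq_hz": scen.so_freq_hz,
            "initial_stage": scen.initial_stage,
            "sop_stage_coupling": scen.sop_stage_coupling,
            "history_mode": scen.history_mode,
            "name": scen.name,
        }
        d.update(overrides)
        scen = SimulationScenario(**d)
    return scen
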