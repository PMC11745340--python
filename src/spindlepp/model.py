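"""Discrete-time point-process GLM for spindle conditional intensity.

The conditional intensity λ(t|H_t) — instantaneous spindle rate given the
covariates and the event history — is log-linear in:

    log λ(t|H_t) = Σ_s β_s I_s(t)                       (sleep stage)
                 + β_1 cos φ_t + β_2 sin φ_t            (SO phase)
                 + Σ_s I_s(t)[β_{s,1} cos φ_t + β_{s,2} sin φ_t]
                                                        (stage × phase)
                 + α_1 SOP_t + α_2 SOP_t²               (sleep depth, quadratic)
                 + Σ_k h_k g_k(H_t)                     (spline history)

with the history term a cardinal spline over the lag since the most recent
event.  On a fine bin grid (dt ≪ refractory scale) the point-process
likelihood is a Poisson GLM with log link and exposure dt, fitted by IRLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import STAGES, CovariateSeries, EventTrain
from .splines import HistoryBasis, long_term_basis, short_term_basis

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the conditional-intensity model."""

    include_stage: bool = False
    include_sop: bool = False
    include_phase: bool = False
    include_stage_phase: bool = False
    include_sop_phase: bool = False
    history: str = "none"  # none | short (≤15 s) | long (≤90 s)
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.history not in ("none", "short", "long"):
            raise ValueError("history must be 'none', 'short' or 'long'")
        if self.include_stage_phase and not (self.include_stage and self.include_phase):
            raise ValueError("stage×phase requires stage and phase terms")
        if self.include_sop_phase and not (self.include_sop and self.include_phase):
            raise ValueError("SOP×phase requires SOP and phase terms")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    @property
    def needs_intercept(self) -> bool:
        # the one-hot stage block already spans the constant
        return not self.include_stage


#: model-menu tokens accepted by the pipeline driver
SPEC_TOKENS = {
    "null": ModelSpec(),
    "stage": ModelSpec(include_stage=True),
    "sop": ModelSpec(include_sop=True),
    "phase": ModelSpec(include_phase=True),
    "history15": ModelSpec(history="short"),
    "history90": ModelSpec(history="long"),
    "stage+phase": ModelSpec(include_stage=True, include_phase=True),
    "stage+history15": ModelSpec(include_stage=True, history="short"),
    "stage+phase+history15": ModelSpec(
        include_stage=True, include_phase=True, history="short"
    ),
    "stage+phase+interaction": ModelSpec(
        include_stage=True, include_phase=True, include_stage_phase=True
    ),
    "stage+phase+interaction+history15": ModelSpec(
        include_stage=True,
        include_phase=True,
        include_stage_phase=True,
        history="short",
    ),
    "sop+phase+history15": ModelSpec(
        include_sop=True, include_phase=True, history="short"
    ),
    "sop+phase+sopphase+history15": ModelSpec(
        include_sop=True,
        include_phase=True,
        include_sop_phase=True,
        history="short",
    ),
    "full90": ModelSpec(
        include_stage=True,
        include_phase=True,
        include_stage_phase=True,
        history="long",
    ),
}


def default_basis(spec: ModelSpec) -> HistoryBasis | None:
    if spec.history == "short":
        return short_term_basis()
    if spec.history == "long":
        return long_term_basis()
    return None


@dataclass
class DesignMatrix:
    """Labeled design with binary response and common exposure dt."""

    X: np.ndarray
    columns: list
    terms: dict            # term name -> list of column labels
    response: np.ndarray
    exposure_s: float
    spec: ModelSpec
    basis: HistoryBasis | None = None

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]


def lags_since_last_event(cov: CovariateSeries) -> np.ndarray:
    """Lag (s) at each bin center since the most recent event strictly
    before the bin start; inf where no prior event."""
    starts = np.arange(cov.n_bins) * cov.dt_s
    times = np.asarray(cov.event_times, dtype=float)
    if times.size == 0:
        idx = np.where(cov.counts > 0)[0]
        times = (idx + 0.5) * cov.dt_s
    pos = np.searchsorted(times, starts, side="left") - 1
    lags = np.full(cov.n_bins, np.inf)
    has = pos >= 0
    lags[has] = starts[has] + 0.5 * cov.dt_s - times[pos[has]]
    return lags


def build_design_matrix(
    cov: CovariateSeries,
    spec: ModelSpec,
    basis: HistoryBasis | None = None,
) -> DesignMatrix:
    """Assemble the labeled design matrix for a covariate series.

    History columns are the spline basis evaluated causally at the lag since
    the last event before each bin; bins with no event within the basis
    support get all-zero history columns (modulation 1).
    """
    if spec.history != "none" and basis is None:
        basis = default_basis(spec)
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    terms: dict[str, list] = {}

    def add(term, cols, names):
        blocks.append(np.column_stack(cols) if isinstance(cols, list) else cols)
        labels.extend(names)
        terms[term] = list(names)

    n = cov.n_bins
    if spec.needs_intercept:
        add("intercept", np.ones((n, 1)), ["intercept"])
    if spec.include_stage:
        onehot = [(cov.stage == s).astype(float) for s in STAGES]
        add("stage", onehot, [f"stage[{s}]" for s in STAGES])
    if spec.include_sop:
        add("sop", [cov.sop, cov.sop**2], ["sop", "sop2"])
    if spec.include_phase:
        cosp, sinp = np.cos(cov.phase), np.sin(cov.phase)
        add("phase", [cosp, sinp], ["phase_cos", "phase_sin"])
    if spec.include_stage_phase:
        cols, names = [], []
        for s in STAGES:
            ind = (cov.stage == s).astype(float)
            cols += [ind * np.cos(cov.phase), ind * np.sin(cov.phase)]
            names += [f"stagephase[{s}]_cos", f"stagephase[{s}]_sin"]
        add("stage_phase", cols, names)
    if spec.include_sop_phase:
        add(
            "sop_phase",
            [cov.sop * np.cos(cov.phase), cov.sop * np.sin(cov.phase)],
            ["sopphase_cos", "sopphase_sin"],
        )
    if spec.history != "none":
        lags = lags_since_last_event(cov)
        H = np.zeros((n, basis.K))
        inside = lags <= basis.max_lag_s
        H[inside] = basis.evaluate(lags[inside])
        add("history", H, [f"hist[{k}]" for k in range(basis.K)])
    X = np.hstack(blocks) if blocks else np.ones((n, 1))
    return DesignMatrix(
        X=X,
        columns=labels,
        terms=terms,
        response=np.asarray(cov.counts, dtype=float),
        exposure_s=cov.dt_s,
        spec=spec,
        basis=basis,
    )


def _rank_filter(X: np.ndarray, labels, tol: float = 1e-8):
    """Greedy left-to-right selection of a full-rank column subset."""
    G = X.T @ X
    norms = np.sqrt(np.diag(G))
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        if norms[j] == 0:
            dropped.append(labels[j])
            continue
        if keep:
            Gk = G[np.ix_(keep, keep)]
            gj = G[keep, j]
            try:
                sol = np.linalg.solve(
                    Gk + 1e-12 * np.eye(len(keep)), gj
                )
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(Gk, gj, rcond=None)[0]
            resid = G[j, j] - gj @ sol
            if resid <= tol * G[j, j]:
                dropped.append(labels[j])
                continue
        keep.append(j)
    return keep, dropped


@dataclass
class FittedModel:
    """Maximum-likelihood point-process GLM fit."""

    params: pd.Series
    cov_params: pd.DataFrame
    log_likelihood: float      # nats
    deviance: float
    n_events: int
    n_bins: int
    spec: ModelSpec
    basis: HistoryBasis | None
    terms: dict
    dropped: list
    data_key: tuple = field(default=())

    @property
    def k_params(self) -> int:
        return len(self.params)

    def coef(self, label: str, default: float = 0.0) -> float:
        """Coefficient by label; dropped/absent columns count as 0."""
        return float(self.params.get(label, default))

    def predict_intensity(self, cov: CovariateSeries) -> np.ndarray:
        """Conditional intensity λ(t|H_t) in events/s on a covariate grid."""
        design = build_design_matrix(cov, self.spec, self.basis)
        beta = np.array([self.coef(c) for c in design.columns])
        return np.exp(design.X @ beta)

    def to_dict(self) -> dict:
        return {
            "spec": vars(self.spec),
            "coefficients": self.params.to_dict(),
            "covariance": {
                "labels": list(self.params.index),
                "matrix": self.cov_params.to_numpy().tolist(),
            },
            "log_likelihood": self.log_likelihood,
            "deviance": self.deviance,
            "n_events": self.n_events,
            "n_bins": self.n_bins,
            "dropped_columns": list(self.dropped),
            "history_knots": list(self.basis.knots) if self.basis else None,
        }


def _newton_poisson(X, y, log_exposure, tol=1e-10, maxiter=100):
    """Newton/IRLS for the Poisson log-link likelihood with fixed exposure.

    For the canonical log link Newton's method and IRLS coincide; the
    Hessian is the Fisher information X'WX with W = diag(mu).  Step-halving
    guards the rare overshoot in early iterations.
    """
    beta = np.zeros(X.shape[1])
    ll_prev = -np.inf
    for _ in range(maxiter):
        eta = X @ beta + log_exposure
        mu = np.exp(eta)
        ll = float(y @ eta - mu.sum())
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Fisher information during fitting") from exc
        shrink, ok = 1.0, False
        for _half in range(30):
            cand = beta + shrink * step
            eta_c = X @ cand + log_exposure
            ll_c = float(y @ eta_c - np.exp(eta_c).sum())
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                ok = True
                break
            shrink *= 0.5
        if not ok:
            raise RuntimeError("line search failed; likelihood not improvable")
        beta = cand
        if abs(ll_c - ll_prev) < tol * (abs(ll_c) + 1.0):
            ll_prev = ll_c
            break
        ll_prev = ll_c
    else:
        raise RuntimeError(f"Newton did not converge in {maxiter} iterations")
    eta = X @ beta + log_exposure
    mu = np.exp(eta)
    cov = np.linalg.inv((X * mu[:, None]).T @ X)
    llf = float(y @ eta - mu.sum())  # log(y!) = 0 for binary counts
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0) - (y - mu)
    deviance = float(2.0 * dev_terms.sum())
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
        raise RuntimeError(
            "GLM fit diverged (possible separation); "
            f"max|coef|={np.max(np.abs(beta)):.3g}"
        )
    return beta, cov, llf, deviance


def fit_point_process_glm(design: DesignMatrix) -> FittedModel:
    """Fit the discrete-time point-process GLM by maximum likelihood.

    Newton/IRLS on the Poisson log-link likelihood with exposure dt.
    Zero-occupancy and collinear columns are dropped (with a warning)
    before fitting; the coefficient covariance is the inverse observed
    Fisher information at the MLE.
    """
    y = design.response
    n_events = int(y.sum())
    if n_events < 1:
        raise ValueError("cannot fit a point-process model with no events")
    keep, dropped = _rank_filter(design.X, design.columns)
    if dropped:
        warnings.warn(
            f"dropped zero/collinear design columns: {dropped}", stacklevel=2
        )
    X = design.X[:, keep]
    labels = [design.columns[j] for j in keep]
    beta, cov, llf, deviance = _newton_poisson(
        X, y, np.log(design.exposure_s)
    )
    covm = pd.DataFrame(cov, index=labels, columns=labels)
    data_key = (design.n_bins, n_events, hash(y.tobytes()))
    return FittedModel(
        params=pd.Series(beta, index=labels),
        cov_params=covm,
        log_likelihood=llf,
        deviance=deviance,
        n_events=n_events,
        n_bins=design.n_bins,
        spec=design.spec,
        basis=design.basis,
        terms=design.terms,
        dropped=dropped,
        data_key=data_key,
    )


def fit_spec(cov: CovariateSeries, spec: ModelSpec | str,
             basis: HistoryBasis | None = None) -> FittedModel:
    """Convenience: build the design for ``spec`` and fit it."""
    if isinstance(spec, str):
        if spec not in SPEC_TOKENS:
            raise KeyError(
                f"unknown model token {spec!r}; known: {sorted(SPEC_TOKENS)}"
            )
        spec = SPEC_TOKENS[spec]
    if spec.dt_s != cov.dt_s:
        spec = ModelSpec(**{**vars(spec), "dt_s": cov.dt_s})
    return fit_point_process_glm(build_design_matrix(cov, spec, basis))


def _check_same_data(*models: FittedModel) -> None:
    keys = {m.data_key for m in models}
    if len(keys) > 1:
        raise ValueError("models were not fitted on identical data")


def likelihood_ratio_test(full: FittedModel, reduced: FittedModel):
    """χ² likelihood-ratio test of a reduced model nested in a full one.

    Returns ``(stat, dof, p)`` with stat = deviance_reduced − deviance_full.
    """
    _check_same_data(full, reduced)
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("reduced model terms are not a subset of the full model")
    dof = full.k_params - reduced.k_params
    stat = max(reduced.deviance - full.deviance, 0.0)
    p = 1.0 if dof == 0 else float(stats.chi2.sf(stat, dof))
    return stat, dof, p


@dataclass
class DevianceDecomposition:
    """Fraction of the null→full deviance reduction per added factor."""

    factors: list
    sequential_pct: list
    single_factor_pct: dict | None = None
    ordering: str = ""

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"factor": self.factors, "sequential_pct": self.sequential_pct}
        )
        if self.single_factor_pct:
            df["single_factor_pct"] = [
                self.single_factor_pct.get(f, np.nan) for f in self.factors
            ]
        return df


def deviance_fractions(
    chain,
    names=None,
    single_factor: dict | None = None,
    ordering: str = "",
) -> DevianceDecomposition:
    """Sequential deviance decomposition over a nested model chain.

    ``chain`` runs null → … → full on identical data.  Each step's fraction
    is its deviance drop as a percentage of the total null→full drop, so the
    steps telescope to exactly 100%.  ``single_factor`` optionally maps
    factor name → its single-factor model, giving the one-factor-at-a-time
    fractions (D_null − D_factor)/(D_null − D_full)·100.
    """
    chain = list(chain)
    if len(chain) < 2:
        raise ValueError("need at least null and full models")
    _check_same_data(*chain)
    dev = np.array([m.deviance for m in chain])
    if np.any(np.diff(dev) > 1e-6 * max(dev[0], 1.0)):
        raise ValueError("deviance increases along the chain; models not nested")
    total = dev[0] - dev[-1]
    if total <= 0:
        raise ValueError("full model does not improve on the null")
    if names is None:
        names = [f"step{i}" for i in range(1, len(chain))]
    seq = (-np.diff(dev) / total * 100.0).tolist()
    sf = None
    if single_factor:
        logger.info("single-factor fractions computed for %s", list(single_factor))
        sf = {
            name: (dev[0] - m.deviance) / total * 100.0
            for name, m in single_factor.items()
        }
    logger.info("deviance decomposition ordering: %s", ordering or "->".join(names))
    return DevianceDecomposition(
        factors=list(names),
        sequential_pct=seq,
        single_factor_pct=sf,
        ordering=ordering or "->".join(names),
    )


@dataclass
class SynergyResult:
    """Normalized excess of joint over summed marginal information."""

    index: float
    gain_a: float      # bits/event
    gain_b: float
    gain_joint: float


def synergy_index(
    null: FittedModel,
    model_a: FittedModel,
    model_b: FittedModel,
    model_ab: FittedModel,
) -> SynergyResult:
    """Synergy index of two covariate groups from per-event information gains.

    I_X = (LL_X − LL_null)/(n_events · ln 2) bits/event; the index is
    (I_AB − I_A − I_B)/I_AB.  Zero means the two groups contribute
    independent information; negative means redundancy.
    """
    _check_same_data(null, model_a, model_b, model_ab)
    n = null.n_events
    gain = lambda m: (m.log_likelihood - null.log_likelihood) / (n * LN2)
    ia, ib, iab = gain(model_a), gain(model_b), gain(model_ab)
    if iab <= 0:
        raise ValueError("joint model carries no information gain; index undefined")
    return SynergyResult(
        index=(iab - ia - ib) / iab, gain_a=ia, gain_b=ib, gain_joint=iab
    )


@dataclass
class GofResult:
    """Time-rescaling Kolmogorov–Smirnov goodness of fit."""

    ks_statistic: float
    n: int
    pass_05: bool


def ks_uniform_statistic(z: np.ndarray) -> float:
    """Two-sided KS sup-distance of a sample against Uniform(0,1)."""
    z = np.sort(np.asarray(z, dtype=float))
    n = z.size
    grid = np.arange(1, n + 1) / n
    return float(max(np.max(grid - z), np.max(z - (grid - 1.0 / n))))


def time_rescaling_from_intensity(
    lam: np.ndarray, dt_s: float, event_times: np.ndarray
) -> GofResult:
    """KS test of time-rescaled intervals under a given intensity λ(t).

    Under a correctly specified model, the rescaled intervals
    τ_j = ∫ λ dt between consecutive events are i.i.d. Exp(1), so
    z_j = 1 − exp(−τ_j) are Uniform(0,1); the KS statistic is compared to
    the 0.05-level bound 1.36/√n.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size < 10:
        raise ValueError("need at least 10 events for the rescaling test")
    cumhaz_edges = np.concatenate([[0.0], np.cumsum(lam * dt_s)])

    def hazard_at(t):
        k = np.clip((t // dt_s).astype(int), 0, lam.size - 1)
        return cumhaz_edges[k] + lam[k] * (t - k * dt_s)

    tau = np.diff(hazard_at(event_times))
    z = 1.0 - np.exp(-tau)
    ks = ks_uniform_statistic(z)
    n = z.size
    return GofResult(ks_statistic=ks, n=n, pass_05=bool(ks < 1.36 / np.sqrt(n)))


def time_rescaling_ks(
    model: FittedModel, train: EventTrain, cov: CovariateSeries
) -> GofResult:
    """Goodness of fit of a fitted model by the time-rescaling theorem."""
    lam = model.predict_intensity(cov)
    return time_rescaling_from_intensity(lam, cov.dt_s, train.times)
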