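"""Population-level comparisons of history curves and features.

Cross-recording analyses: Pearson correlations between history curves
(intra- vs inter-subject similarity), Welch t-tests on curve features with
Bonferroni correction, Watson–Williams tests for shifts in preferred phase,
and global permutation tests on whole curve families using a max-|t|
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# curve correlation


def curve_correlation(curve_a, curve_b) -> float:
    """Pearson r between two history curves on identical lag grids."""
    a = np.asarray(getattr(curve_a, "modulation", curve_a), dtype=float)
    b = np.asarray(getattr(curve_b, "modulation", curve_b), dtype=float)
    la = getattr(curve_a, "lags", None)
    lb = getattr(curve_b, "lags", None)
    if la is not None and lb is not None and not np.array_equal(la, lb):
        raise ValueError("curves are not on identical lag grids")
    if a.size != b.size:
        raise ValueError("curves are not on identical lag grids")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance curve; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_curve_correlations(curves) -> np.ndarray:
    """All pairwise Pearson r over a list of curves (upper triangle)."""
    out = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            out.append(curve_correlation(curves[i], curves[j]))
    return np.asarray(out)


def intra_inter_correlations(night1_curves, night2_curves):
    """Within-subject (night 1 vs 2) and between-subject (night 1) pools."""
    if len(night1_curves) != len(night2_curves):
        raise ValueError("need one curve per subject and night")
    intra = np.array(
        [curve_correlation(a, b) for a, b in zip(night1_curves, night2_curves)]
    )
    inter = pairwise_curve_correlations(night1_curves)
    return intra, inter


# --------------------------------------------------------------------------
# Watson-Williams circular test


def _kappa_ml(r: float) -> float:
    """ML estimate of the von Mises concentration from resultant length."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams_test(*groups):
    """Circular one-way test of equal mean directions.

    The classical Watson–Williams high-concentration F approximation with
    the standard 1 + 3/(8κ̂) correction.  Returns ``(F, p)``.  Warns when
    the pooled concentration is low (κ̂ < 1), where the approximation is
    unreliable.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if any(g.size < 5 for g in groups):
        warnings.warn("group with n < 5; Watson-Williams is unreliable", stacklevel=2)
    k = len(groups)
    N = sum(g.size for g in groups)
    Ri = np.array(
        [np.hypot(np.sum(np.cos(g)), np.sum(np.sin(g))) for g in groups]
    )
    all_angles = np.concatenate(groups)
    R = np.hypot(np.sum(np.cos(all_angles)), np.sum(np.sin(all_angles)))
    rw = Ri.sum() / N
    kappa = _kappa_ml(rw)
    if kappa < 1.0:
        warnings.warn(
            "low concentration (kappa < 1); Watson-Williams approximation poor",
            stacklevel=2,
        )
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - Ri.sum()
    if denom <= 0:
        return 0.0, 1.0
    F = K * ((N - k) * (Ri.sum() - R)) / ((k - 1) * denom)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p


# --------------------------------------------------------------------------
# global permutation test on curve families


@dataclass
class PermutationCurveResult:
    """Global (family-wise) permutation test over a lag grid."""

    global_p: float
    pointwise_mask: np.ndarray     # lags where |t| exceeds the null max-|t| 95th pct
    observed_stat: float
    n_permutations: int
    seed: int


def _welch_t_curves(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-lag Welch t statistic between two curve stacks (rows=subjects)."""
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    denom = np.sqrt(va / A.shape[0] + vb / B.shape[0])
    denom = np.where(denom == 0, np.inf, denom)
    return (ma - mb) / denom


def global_permutation_curve_test(
    curves_a,
    curves_b,
    n_perm: int = 499,
    seed: int = 0,
) -> PermutationCurveResult:
    """Max-|t| permutation test for a difference between curve families.

    The statistic is the maximum over lags of the absolute Welch t between
    groups; its null distribution comes from random label permutations.
    global p = (1 + #{perm ≥ observed})/(n_perm + 1); the pointwise mask
    marks lags where the observed |t| exceeds the null 95th-percentile
    max statistic (controlling the family-wise rate at 0.05).
    """
    A = np.vstack([np.asarray(getattr(c, "modulation", c), float) for c in curves_a])
    B = np.vstack([np.asarray(getattr(c, "modulation", c), float) for c in curves_b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("curve families are not on a common lag grid")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least two curves per group")
    if n_perm < 199:
        raise ValueError("n_perm must be at least 199")
    rng = np.random.default_rng(seed)
    pooled = np.vstack([A, B])
    na = A.shape[0]
    obs_t = np.abs(_welch_t_curves(A, B))
    obs = float(obs_t.max())
    null_max = np.empty(n_perm)
    idx = np.arange(pooled.shape[0])
    for i in range(n_perm):
        rng.shuffle(idx)
        pa, pb = pooled[idx[:na]], pooled[idx[na:]]
        null_max[i] = np.abs(_welch_t_curves(pa, pb)).max()
    global_p = (1.0 + np.sum(null_max >= obs)) / (n_perm + 1.0)
    crit = np.quantile(null_max, 0.95)
    return PermutationCurveResult(
        global_p=float(global_p),
        pointwise_mask=obs_t > crit,
        observed_stat=obs,
        n_permutations=n_perm,
        seed=seed,
    )


# --------------------------------------------------------------------------
# feature panels


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def feature_group_tests(
    features: pd.DataFrame,
    grouping: str,
    feature_cols=None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Welch t-tests of feature means between two groups, Bonferroni-corrected.

    ``features`` is tidy (one row per recording); ``grouping`` names a
    two-level column.  NaN feature values are dropped per comparison with a
    logged count; a group left with n < 2 skips that comparison with a
    warning.  Returns one row per feature with raw/corrected p and the
    star annotation (*, **, *** for p < 0.05, 0.01, 0.001).
    """
    levels = list(pd.unique(features[grouping]))
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    if feature_cols is None:
        feature_cols = [
            c
            for c in features.columns
            if c != grouping and pd.api.types.is_numeric_dtype(features[c])
        ]
    n_tests = len(feature_cols)
    rows = []
    for col in feature_cols:
        ga = features.loc[features[grouping] == levels[0], col].dropna()
        gb = features.loc[features[grouping] == levels[1], col].dropna()
        n_dropped = features[col].isna().sum()
        if n_dropped:
            warnings.warn(
                f"{col}: dropped {n_dropped} NaN value(s)", stacklevel=2
            )
        if len(ga) < 2 or len(gb) < 2:
            warnings.warn(f"{col}: group too small after NaN removal; skipped",
                          stacklevel=2)
            continue
        t, p = stats.ttest_ind(ga, gb, equal_var=False)
        if correction == "bonferroni":
            p_corr = min(1.0, p * n_tests)
        elif correction in (None, "none"):
            p_corr = p
        else:
            raise ValueError(f"unknown correction {correction!r}")
        rows.append(
            {
                "feature": col,
                "group_a": levels[0],
                "group_b": levels[1],
                "mean_a": ga.mean(),
                "sd_a": ga.std(ddof=1),
                "mean_b": gb.mean(),
                "sd_b": gb.std(ddof=1),
                "t": float(t),
                "p_raw": float(p),
                "p_corrected": float(p_corr),
                "stars": _stars(p_corr),
            }
        )
    return pd.DataFrame(rows)
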