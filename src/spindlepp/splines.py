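"""Cardinal-spline basis for the lag-since-last-event history term.

The history term of the log-intensity is a cardinal (Catmull–Rom-type)
interpolating spline through control values h_k placed at a set of lag
knots: log-modulation(τ) = Σ_k h_k g_k(τ).  Each basis function g_k(τ) is
the interpolation weight of control point k at lag τ, so the spline passes
exactly through (knot_k, h_k), the weights form a partition of unity inside
the knot span, and every g_k vanishes beyond the last knot — the modulation
returns to exactly 1 at long lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default knot layout (s): dense where short-term structure lives
SHORT_KNOTS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.5, 8.0, 10.0, 12.5, 15.0)
#: extension out to the infraslow range
LONG_KNOTS = SHORT_KNOTS + (20.0, 30.0, 40.0, 50.0, 60.0, 75.0, 90.0)


@dataclass(frozen=True)
class HistoryBasis:
    """Cardinal-spline basis over lag-since-last-event.

    Parameters
    ----------
    knots
        Strictly increasing lag positions (s); ≥ 4 required.
    tension
        Cardinal tangent coefficient c; 0.5 gives the Catmull–Rom spline.
    """

    knots: tuple
    tension: float = 0.5

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 4:
            raise ValueError("need at least 4 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if knots[0] < 0:
            raise ValueError("first knot must be ≥ 0")

    @property
    def K(self) -> int:
        return len(self.knots)

    @property
    def max_lag_s(self) -> float:
        return self.knots[-1]

    def evaluate(self, lags: np.ndarray) -> np.ndarray:
        """Basis matrix: rows = lags, columns = the K weights g_k(lag).

        Lags beyond the last knot (or negative) get an all-zero row; lags
        must otherwise lie inside the knot span.
        """
        lags = np.atleast_1d(np.asarray(lags, dtype=float))
        t = np.asarray(self.knots)
        c = self.tension
        out = np.zeros((lags.size, self.K))
        inside = (lags >= t[0]) & (lags <= t[-1])
        if np.any(lags < 0):
            raise ValueError("negative lags are invalid")
        lag_in = lags[inside]
        if lag_in.size == 0:
            return out
        # segment index i: lag in [t_i, t_{i+1})
        i = np.clip(np.searchsorted(t, lag_in, side="right") - 1, 0, self.K - 2)
        dt_i = t[i + 1] - t[i]
        u = (lag_in - t[i]) / dt_i
        h00 = 2 * u**3 - 3 * u**2 + 1
        h10 = u**3 - 2 * u**2 + u
        h01 = -2 * u**3 + 3 * u**2
        h11 = u**3 - u**2
        rows = np.flatnonzero(inside)
        w = np.zeros((lag_in.size, self.K))
        idx = np.arange(lag_in.size)
        w[idx, i] += h00
        w[idx, i + 1] += h01
        # tangent at knot i: central difference (one-sided at the ends)
        interior_l = i >= 1
        span_l = np.where(interior_l, t[np.maximum(i + 1, 1)] - t[np.maximum(i - 1, 0)], dt_i)
        coef_l = c * dt_i * h10 / span_l
        w[idx[interior_l], i[interior_l] - 1] -= coef_l[interior_l]
        w[idx[interior_l], i[interior_l] + 1] += coef_l[interior_l]
        w[idx[~interior_l], i[~interior_l]] -= coef_l[~interior_l]
        w[idx[~interior_l], i[~interior_l] + 1] += coef_l[~interior_l]
        # tangent at knot i+1
        interior_r = i + 1 <= self.K - 2
        span_r = np.where(
            interior_r, t[np.minimum(i + 2, self.K - 1)] - t[i], dt_i
        )
        coef_r = c * dt_i * h11 / span_r
        w[idx[interior_r], i[interior_r]] -= coef_r[interior_r]
        w[idx[interior_r], i[interior_r] + 2] += coef_r[interior_r]
        w[idx[~interior_r], i[~interior_r]] -= coef_r[~interior_r]
        w[idx[~interior_r], i[~interior_r] + 1] += coef_r[~interior_r]
        out[rows] = w
        return out

    def spline(self, lags: np.ndarray, control: np.ndarray) -> np.ndarray:
        """Evaluate the interpolating spline with control values h_k."""
        control = np.asarray(control, dtype=float)
        if control.size != self.K:
            raise ValueError("control vector length must equal K")
        return self.evaluate(lags) @ control


def short_term_basis(tension: float = 0.5) -> HistoryBasis:
    """Default short-term (≤ 15 s) history basis."""
    return HistoryBasis(SHORT_KNOTS, tension)


def long_term_basis(tension: float = 0.5) -> HistoryBasis:
    """Long-term (≤ 90 s) basis covering the infraslow range."""
    return HistoryBasis(LONG_KNOTS, tension)
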