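"""LLPS classification and critical-temperature estimation.

Two estimators for the critical temperature T_Cr act on a binodal-like
series of (temperature, P_H - P_L) points:

* a threshold rule -- phase separation is considered gone where
  P_H - P_L drops below 0.07 (and "obvious" above 0.15); T_Cr is read off
  by linear interpolation at the first downward 0.07 crossing;
* a power-law fit of the order parameter,
  P_H - P_L = A (T_Cr - T)^beta for T < T_Cr, with beta either free or
  fixed to the 3D-Ising value 0.325.

Both are deterministic; the fit multi-starts over T_Cr to avoid local
minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

OBVIOUS_THRESHOLD = 0.15
DISAPPEAR_THRESHOLD = 0.07
ISING_BETA = 0.325


@dataclass
class BinodalSeries:
    temperatures: np.ndarray          # strictly increasing, T0 units
    values: np.ndarray                # P_H - P_L, in [0, 1]
    sigma: np.ndarray | None = None   # optional per-point uncertainty

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if len(self.temperatures) != len(self.values):
            raise ValueError("temperature and value lengths differ")


@dataclass
class TcrFit:
    amplitude: float
    t_cr: float
    beta: float
    residual_norm: float
    success: bool
    n_points: int
    message: str = ""


def _series(series_or_t, values=None) -> BinodalSeries:
    if isinstance(series_or_t, BinodalSeries):
        return series_or_t
    return BinodalSeries(series_or_t, values)


def classify_llps(series_or_t, values=None,
                  obvious_threshold: float = OBVIOUS_THRESHOLD,
                  disappear_threshold: float = DISAPPEAR_THRESHOLD
                  ) -> list[str]:
    """Label each point 'obvious' (> 0.15), 'none' (< 0.07) or 'marginal'."""
    s = _series(series_or_t, values)
    labels = []
    for v in s.values:
        if v > obvious_threshold:
            labels.append("obvious")
        elif v < disappear_threshold:
            labels.append("none")
        else:
            labels.append("marginal")
    return labels


def tcr_threshold(series_or_t, values=None,
                  threshold: float = DISAPPEAR_THRESHOLD):
    """T_Cr by linear interpolation at the first downward threshold crossing.

    Returns ``(estimate, status)`` where status is 'ok', or a censoring
    note ('>= T_max' when the series never drops below the threshold,
    '<= T_min' when it starts below) with the corresponding grid edge as
    the estimate.
    """
    s = _series(series_or_t, values)
    t, v = s.temperatures, s.values
    if v[0] < threshold:
        return float(t[0]), "<= T_min"
    for i in range(len(t) - 1):
        if v[i] >= threshold and v[i + 1] < threshold:
            frac = (v[i] - threshold) / (v[i] - v[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i])), "ok"
        if v[i + 1] == threshold:
            return float(t[i + 1]), "ok"
    return float(t[-1]), ">= T_max"


def tcr_fit(series_or_t, values=None, beta_mode: str = "fixed",
            beta0: float = ISING_BETA,
            disappear_threshold: float = DISAPPEAR_THRESHOLD,
            n_starts: int = 7) -> TcrFit:
    """Least-squares fit of P_H - P_L = A (T_Cr - T)^beta below T_Cr.

    Only points above ``disappear_threshold`` enter the fit (at least 3
    required).  ``beta_mode`` is 'fixed' (beta = beta0, the 3D Ising
    exponent by default) or 'free'.  T_Cr is multi-started on a grid above
    the hottest included point; the best converged start wins.
    Deterministic.
    """
    if beta_mode not in ("fixed", "free"):
        raise ValueError("beta_mode must be 'fixed' or 'free'")
    s = _series(series_or_t, values)
    sel = s.values > disappear_threshold
    t, v = s.temperatures[sel], s.values[sel]
    if len(t) < 3:
        raise ValueError(
            f"need at least 3 points above the {disappear_threshold} "
            f"threshold to fit, have {len(t)}"
        )
    t_max_all = s.temperatures[-1]
    t_hi = t.max()
    span = max(t_max_all - t.min(), 1.0)

    def model(params, tt):
        if beta_mode == "fixed":
            a, tcr = params
            beta = beta0
        else:
            a, tcr, beta = params
        gap = np.clip(tcr - tt, 1e-12, None)
        return a * gap**beta

    def resid(params):
        return model(params, t) - v

    best = None
    starts = t_hi + np.linspace(0.05, 1.5, n_starts) * span
    for tcr0 in starts:
        a0 = v.max() / max((tcr0 - t.min()) ** beta0, 1e-12)
        x0 = [a0, tcr0] if beta_mode == "fixed" else [a0, tcr0, beta0]
        lo = [0.0, t_hi + 1e-9] + ([0.05] if beta_mode == "free" else [])
        hi = [np.inf, t_max_all + 10 * span] + (
            [2.0] if beta_mode == "free" else [])
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14,
                                ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return TcrFit(np.nan, np.nan, np.nan, np.inf, False, len(t),
                      "no start converged")
    if beta_mode == "fixed":
        a, tcr = best.x
        beta = beta0
    else:
        a, tcr, beta = best.x
    return TcrFit(float(a), float(tcr), float(beta),
                  float(np.sqrt(2 * best.cost)), bool(best.success),
                  len(t), "")
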