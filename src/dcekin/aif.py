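"""Arterial input function: biexponential washout model and its fit.

The plasma concentration after a bolus is modeled as

    Cp(t) = A1·exp(-m1·t) + A2·exp(-m2·t),      t >= 0 (min),

with amplitudes in mM and rates in min^-1.  The four constants are
estimated from the post-contrast arterial samples by Levenberg-Marquardt
least squares; nonnegativity is enforced by fitting on the log scale.
Parameters are reported in the canonical order m1 <= m2 (the model is
invariant under exchanging the two terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .series import ARTERY, ConcentrationSeries

_LS_TOL = dict(ftol=1e-14, xtol=1e-14, gtol=1e-14)
_RESTART_SEED = 20140620  # fixed: perturbed-restart reproducibility


@dataclass(frozen=True)
class AIFParams:
    """Constants of the biexponential arterial model (mM, min^-1)."""

    A1: float
    A2: float
    m1: float
    m2: float

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("decay rates m1, m2 must be strictly positive")
        if self.A1 + self.A2 < 0:
            raise ValueError("peak plasma concentration A1 + A2 must be nonnegative")

    def canonical(self) -> "AIFParams":
        """Return with terms ordered so that m1 <= m2."""
        if self.m1 <= self.m2:
            return self
        return AIFParams(self.A2, self.A1, self.m2, self.m1)

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.m1, self.m2])


@dataclass(frozen=True)
class AIFFitResult:
    params: AIFParams | None
    rss: float
    converged: bool
    n_points: int
    message: str = ""


def cp_model(t, params: AIFParams):
    """Evaluate Cp(t) = A1·e^(−m1·t) + A2·e^(−m2·t) at t (minutes, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cp_model is defined for t >= 0")
    out = params.A1 * np.exp(-params.m1 * t) + params.A2 * np.exp(-params.m2 * t)
    return out if out.ndim else float(out)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    peak = float(np.max(y))
    i_peak = int(np.argmax(y))
    t_peak = t[i_peak]
    if t_peak <= 0:
        # peak on the first post-contrast frame: fall back to the frame spacing
        t_peak = t[1] - t[0] if t.size > 1 else 1.0
    m1 = 1.0 / max(t[-1], 1e-6)
    m2 = 1.0 / max(t_peak, 1e-6)
    if m1 > m2:
        m1, m2 = m2, m1
    return np.log([peak / 2.0, peak / 2.0, m1, m2])


def fit_aif(conc: ConcentrationSeries) -> AIFFitResult:
    """Fit the four AIF constants to post-contrast arterial concentrations.

    Returns an explicit failure result (``converged=False``) when the data
    are degenerate (no enhancement) or the restart schedule is exhausted
    without convergence — never silently wrong parameters.
    """
    if conc.compartment != ARTERY:
        raise ValueError("fit_aif expects an artery concentration series")
    post = conc.times >= 0.0
    t, y = conc.times[post], conc.values[post]
    if t.size < 8:
        raise ValueError(f"need >= 8 post-contrast samples, got {t.size}")

    peak = float(np.max(y))
    if peak <= 0 or np.ptp(y) < 1e-12 * max(1.0, abs(peak)):
        return AIFFitResult(None, float(np.sum(y**2)), False, t.size,
                            "degenerate series: no enhancement to fit")

    def resid(theta: np.ndarray) -> np.ndarray:
        A1, A2, m1, m2 = np.exp(theta)
        return A1 * np.exp(-m1 * t) + A2 * np.exp(-m2 * t) - y

    theta0 = _initial_guess(t, y)
    rng = np.random.default_rng(_RESTART_SEED)
    best = None
    for attempt in range(3):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0.0, 0.3, 4)
        res = least_squares(resid, start, method="lm", max_nfev=20000, **_LS_TOL)
        if best is None or res.cost < best.cost:
            best = res
        if res.success:
            best = res if res.cost <= best.cost else best
            if attempt == 0 or res.cost <= best.cost:
                break

    if best is None or not best.success:
        return AIFFitResult(None, float("nan"), False, t.size,
                            "Levenberg-Marquardt did not converge after restarts")
    A1, A2, m1, m2 = np.exp(best.x)
    params = AIFParams(A1, A2, m1, m2).canonical()
    rss = float(np.sum(best.fun**2))
    return AIFFitResult(params, rss, True, t.size, best.message)
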