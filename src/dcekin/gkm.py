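"""General kinetic model (two-compartment Tofts model).

Tissue concentration follows

    dCt/dt = Ktrans·Cp(t) − Kep·Ct(t),      Ct(0) = 0,

whose solution for the biexponential AIF is the closed form

    Ct(t) = Ktrans · Σ_i A_i · (exp(−Kep·t) − exp(−m_i·t)) / (m_i − Kep),

with the analytic limit Ktrans·A_i·t·exp(−Kep·t) when m_i ≈ Kep.  Ktrans
(min^-1) is the plasma→EES transfer constant used as the indicator of
blood-brain-barrier disruption; Kep is the back-transfer constant and
ve = Ktrans/Kep the derived distribution-volume ratio.

Fitting is Levenberg-Marquardt on log-scale parameters (nonnegativity by
construction), on concentration units, with the AIF estimated upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif import AIFParams
from .series import ConcentrationSeries

#: |m_i - Kep| below which the degenerate-pole limit branch is used (min^-1)
POLE_TOL = 1e-8

_LS_TOL = dict(ftol=1e-14, xtol=1e-14, gtol=1e-14)
_RESTART_SEED = 20140621


@dataclass(frozen=True)
class GKMParams:
    """Transfer rate constants (min^-1)."""

    Ktrans: float
    Kep: float

    def __post_init__(self) -> None:
        if self.Ktrans < 0 or self.Kep < 0:
            raise ValueError("Ktrans and Kep must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a GKM fit for one ROI.

    ``ve`` is NaN (and ``ve_defined`` False) when Kep = 0.  ``offset`` is
    the fitted constant baseline when the stage-2 nuisance offset is
    enabled, else None.
    """

    params: GKMParams | None
    ve: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""
    offset: float | None = None

    @property
    def ve_defined(self) -> bool:
        return not math.isnan(self.ve)


def compute_ve(params: GKMParams) -> float:
    """Distribution-volume ratio ve = Ktrans/Kep (requires Kep > 0)."""
    if params.Kep == 0:
        if params.Ktrans == 0:
            return 0.0
        raise ValueError("ve is undefined for Kep = 0")
    return params.Ktrans / params.Kep


def _conv_terms(t: np.ndarray, amps, rates, kep: float) -> np.ndarray:
    """Σ_i A_i (e^{-Kep t} - e^{-m_i t})/(m_i - Kep), stable near poles."""
    out = np.zeros_like(t)
    ekep = np.exp(-kep * t)
    tmax = float(np.max(t, initial=0.0))
    for A, m in zip(amps, rates):
        delta = m - kep
        if abs(delta) < POLE_TOL:
            # analytic limit with Taylor correction in delta·t, so the
            # branch agrees with the exact form to machine precision
            dt = delta * t
            out += A * t * ekep * (1.0 - dt / 2.0 + dt * dt / 6.0)
        elif abs(delta) * tmax < 1.0:
            # cancellation-safe: e^{-Kep t} - e^{-m t} = -e^{-Kep t}·expm1(-delta·t)
            out += A * ekep * (-np.expm1(-delta * t)) / delta
        else:
            # well-separated exponents: plain difference, no overflow risk
            out += A * (ekep - np.exp(-m * t)) / delta
    return out


def ct_model(t, aif: AIFParams, params: GKMParams):
    """Closed-form tissue concentration Ct(t) for the biexponential AIF."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("ct_model is defined for t >= 0")
    out = params.Ktrans * _conv_terms(t, (aif.A1, aif.A2), (aif.m1, aif.m2), params.Kep)
    return out if out.ndim else float(out)


def fit_gkm(
    conc_tissue: ConcentrationSeries,
    aif: AIFParams,
    with_offset: bool = False,
) -> FitResult:
    """Estimate (Ktrans, Kep) from post-contrast tissue concentrations.

    ``with_offset`` adds a free constant baseline to the model (used for
    the second stage of the two-stage analysis, where carryover from the
    first stage violates the Ct(0) = 0 assumption).
    """
    post = conc_tissue.times >= 0.0
    t, y = conc_tissue.times[post], conc_tissue.values[post]
    if t.size < 6:
        raise ValueError(f"need >= 6 post-contrast samples, got {t.size}")

    if np.max(np.abs(y)) < 1e-14:
        # flat-zero tissue: no uptake, ve undefined
        return FitResult(GKMParams(0.0, 0.0), float("nan"), 0.0, True, t.size,
                         "all-zero tissue series: Ktrans = 0, ve undefined")

    amps, rates = (aif.A1, aif.A2), (aif.m1, aif.m2)

    def resid(theta: np.ndarray) -> np.ndarray:
        kt, kep = np.exp(theta[:2])
        model = kt * _conv_terms(t, amps, rates, kep)
        if with_offset:
            model = model + theta[2]
        return model - y

    theta0 = np.log([0.05, 0.05])
    if with_offset:
        theta0 = np.append(theta0, float(np.min(y)))
    rng = np.random.default_rng(_RESTART_SEED)
    best = None
    for attempt in range(4):
        start = theta0.copy()
        if attempt > 0:
            start[:2] += rng.normal(0.0, 0.5, 2)
        res = least_squares(resid, start, method="lm", max_nfev=20000, **_LS_TOL)
        if best is None or res.cost < best.cost:
            best = res
        if res.success and attempt == 0:
            break

    if best is None or not best.success:
        return FitResult(None, float("nan"), float("nan"), False, t.size,
                         "Levenberg-Marquardt did not converge after restarts",
                         None)
    kt, kep = np.exp(best.x[:2])
    params = GKMParams(kt, kep)
    return FitResult(
        params,
        compute_ve(params),
        float(np.sum(best.fun**2)),
        True,
        t.size,
        best.message,
        float(best.x[2]) if with_offset else None,
    )
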