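"""Two-stage kinetic analysis for repeated focused-ultrasound irradiation.

When the blood-brain barrier is opened twice (a second ultrasound
treatment during the acquisition), a single set of transfer constants
cannot describe the tissue curve.  The two-stage procedure:

1. smooth the tissue concentration samples with a 5th-order Fourier
   series (or a linear / nearest-neighbor interpolant);
2. split the smooth curve at the time of the second irradiation;
3. resample each part on 40 equally spaced times;
4. fit stage-wise (Ktrans, Kep) to each resampled part against the single
   AIF estimated from all frames;
5. report a duration-weighted mean ve across stages.

Stage 2 starts at a nonzero tissue concentration, violating the
Ct(0) = 0 assumption of the closed-form model; two handling modes are
provided (see :func:`fit_two_stage`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d
from scipy.optimize import least_squares

from .aif import AIFParams
from .gkm import FitResult, fit_gkm
from .series import ConcentrationSeries

FOURIER5 = "fourier5"
LINEAR = "linear"
NEAREST = "nearest"
SMOOTHING_METHODS = (FOURIER5, LINEAR, NEAREST)

GLOBAL_OFFSET = "global_offset"
REORIGIN = "reorigin"
STAGE2_MODES = (GLOBAL_OFFSET, REORIGIN)

_DOMAIN_EPS = 1e-9


@dataclass(frozen=True)
class SmoothCurve:
    """A fitted trend curve for the tissue concentration samples.

    For ``fourier5`` the parameters are a0, (a_k, b_k) for k = 1..5 and
    the fundamental angular frequency omega (12 parameters, the MATLAB
    'fourier5' convention with free omega).  For ``linear``/``nearest``
    the knots are the samples themselves.  Evaluation outside
    [t_start, t_end] is an error.
    """

    method: str
    t_start: float
    t_end: float
    coefficients: np.ndarray | None = None   # fourier5: [a0, a1, b1, ..., a5, b5]
    omega: float | None = None
    knots_t: np.ndarray | None = None
    knots_y: np.ndarray | None = None

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_start - _DOMAIN_EPS) or np.any(t > self.t_end + _DOMAIN_EPS):
            raise ValueError(
                f"evaluation outside curve domain [{self.t_start}, {self.t_end}]"
            )
        t = np.clip(t, self.t_start, self.t_end)
        if self.method == FOURIER5:
            return _fourier_eval(self.coefficients, self.omega, t)
        interp = interp1d(self.knots_t, self.knots_y, kind=self.method)
        out = interp(t)
        return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class StageWindow:
    label: str
    t_start: float
    t_end: float
    n_resample: int = 40

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.n_resample < 4:
            raise ValueError("n_resample must be >= 4")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class TwoStageResult:
    stage1: FitResult
    stage2: FitResult
    split_time: float
    weighted_ve: float
    method: str = FOURIER5
    stage2_mode: str = GLOBAL_OFFSET

    @property
    def converged(self) -> bool:
        return self.stage1.converged and self.stage2.converged


def _fourier_eval(coef: np.ndarray, omega: float, t: np.ndarray) -> np.ndarray:
    out = np.full_like(t, coef[0], dtype=float)
    for k in range(1, 6):
        out += coef[2 * k - 1] * np.cos(k * omega * t)
        out += coef[2 * k] * np.sin(k * omega * t)
    return out


def _fourier_design(omega: float, t: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t)]
    for k in range(1, 6):
        cols.append(np.cos(k * omega * t))
        cols.append(np.sin(k * omega * t))
    return np.column_stack(cols)


def _fit_fourier5(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    span = t[-1] - t[0]

    def resid(theta: np.ndarray) -> np.ndarray:
        return _fourier_eval(theta[:11], theta[11], t) - y

    # omega is a free parameter with several shallow local minima; start
    # from a few fundamental periods around 1.2x the observation span
    best = None
    for factor in (1.2, 0.6, 2.4, 4.8):
        omega0 = 2.0 * np.pi / (factor * span)
        coef0, *_ = np.linalg.lstsq(_fourier_design(omega0, t), y, rcond=None)
        res = least_squares(resid, np.append(coef0, omega0), method="lm",
                            max_nfev=50000, ftol=1e-15, xtol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    return best.x[:11], float(abs(best.x[11]))


def smooth_ct(conc_tissue: ConcentrationSeries, method: str = FOURIER5) -> SmoothCurve:
    """Fit a trend curve to the post-contrast tissue samples."""
    if method not in SMOOTHING_METHODS:
        raise ValueError(f"method must be one of {SMOOTHING_METHODS}")
    post = conc_tissue.times >= 0.0
    t, y = conc_tissue.times[post], conc_tissue.values[post]
    if method == FOURIER5:
        if t.size < 13:
            raise ValueError(
                f"fourier5 smoothing needs >= 13 samples (12 parameters), got {t.size}"
            )
        coef, omega = _fit_fourier5(t, y)
        return SmoothCurve(FOURIER5, float(t[0]), float(t[-1]),
                           coefficients=coef, omega=omega)
    if t.size < 2:
        raise ValueError("interpolation needs >= 2 samples")
    return SmoothCurve(method, float(t[0]), float(t[-1]), knots_t=t, knots_y=y)


def split_and_resample(
    curve: SmoothCurve, split_time: float, n: int = 40
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """Resample the curve on n equally spaced times per stage.

    Both stages own the split time (closed intervals); the duplicated
    sample is harmless because it comes from the same smooth curve.
    """
    if not curve.t_start < split_time < curve.t_end:
        raise ValueError(
            f"split time {split_time} not strictly inside "
            f"[{curve.t_start}, {curve.t_end}]"
        )
    if n < 4:
        raise ValueError("n must be >= 4")
    t1 = np.linspace(curve.t_start, split_time, n)
    t2 = np.linspace(split_time, curve.t_end, n)
    return (
        ConcentrationSeries(t1, curve(t1), "tissue"),
        ConcentrationSeries(t2, curve(t2), "tissue"),
    )


def weighted_ve(ve_list: Sequence[float], durations: Sequence[float]) -> float:
    """Duration-weighted arithmetic mean of stage ve values (any k >= 1)."""
    ve_arr = np.asarray(ve_list, dtype=float)
    dur = np.asarray(durations, dtype=float)
    if ve_arr.size == 0:
        raise ValueError("weighted_ve requires at least one stage")
    if ve_arr.shape != dur.shape:
        raise ValueError("ve_list and durations must have equal length")
    if np.any(dur <= 0):
        raise ValueError("durations must be strictly positive")
    return float(np.sum(ve_arr * dur) / np.sum(dur))


def fit_two_stage(
    conc_tissue: ConcentrationSeries,
    aif: AIFParams,
    split_time: float,
    method: str = FOURIER5,
    n: int = 40,
    stage2_mode: str = GLOBAL_OFFSET,
) -> TwoStageResult:
    """Stage-wise transfer-constant estimation around a known split time.

    The AIF must have been fit from all frames; it is shared by both
    stages.  Stage-2 handling:

    * ``global_offset`` (default): fit on the global time axis with a
      constant-offset nuisance parameter absorbing stage-1 carryover;
    * ``reorigin``: shift stage-2 times to start at zero and subtract the
      concentration at the split before fitting.
    """
    if stage2_mode not in STAGE2_MODES:
        raise ValueError(f"stage2_mode must be one of {STAGE2_MODES}")
    curve = smooth_ct(conc_tissue, method)
    s1, s2 = split_and_resample(curve, split_time, n)

    stage1 = fit_gkm(s1, aif)
    if stage2_mode == GLOBAL_OFFSET:
        stage2 = fit_gkm(s2, aif, with_offset=True)
    else:
        baseline = s2.values[0]
        shifted = ConcentrationSeries(
            s2.times - split_time, s2.values - baseline, "tissue"
        )
        stage2 = fit_gkm(shifted, aif)

    d1 = split_time - curve.t_start
    d2 = curve.t_end - split_time
    if stage1.converged and stage2.converged and stage1.ve_defined and stage2.ve_defined:
        wve = weighted_ve([stage1.ve, stage2.ve], [d1, d2])
    else:
        wve = float("nan")
    return TwoStageResult(stage1, stage2, split_time, wve, method, stage2_mode)
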