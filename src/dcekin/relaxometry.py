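"""Signal-intensity <-> gadolinium-concentration conversion.

The T1-weighted acquisition (TR/TE = 500/13 ms, spin echo) is modeled with
the saturation-recovery signal equation

    S(T1) ∝ 1 − exp(−TR / T1),

so the post/pre signal ratio of a frame is

    S_post / S_pre = (1 − exp(−TR/T1)) / (1 − exp(−TR/T10)),

where T10 is the pre-contrast longitudinal relaxation time of the
compartment.  Solving for T1 per frame and applying the fast-exchange
relaxivity relation 1/T1 = 1/T10 + r1·C yields the gadolinium
concentration C (mM).  A linearized alternative,
C = (S_post/S_pre − 1)/(r1·T10), is available via
``signal_model="linear"``.

For the cerebral artery the converted concentration is multiplied by the
plasma fraction 0.55, because the tracer is confined to plasma (55% of
whole blood); the tissue compartment is not scaled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .series import ARTERY, ConcentrationSeries, SignalSeries

logger = logging.getLogger(__name__)

SATURATION_RECOVERY = "saturation_recovery"
LINEAR = "linear"

# Floor on 1 - (S_post/S_pre)·(1 - exp(-TR/T10)): ratios at or beyond the
# asymptote of the signal model are clamped to the concentration this floor
# implies ("largest representable"), flagged, and logged.
_RATIO_FLOOR = 1e-12


@dataclass(frozen=True)
class AcquisitionConstants:
    """Scanner and protocol constants of the T1-weighted DCE acquisition.

    Defaults reproduce the 3 T rat protocol: T10 = 0.9 s (tissue) /
    1.5 s (artery), r1 = 4.62 mM^-1 s^-1, plasma fraction 0.55,
    TR = 0.5 s, 97 s per frame, 2 pre-contrast frames.
    """

    T10_tissue: float = 0.9          # s
    T10_artery: float = 1.5          # s
    r1: float = 4.62                 # mM^-1 s^-1
    plasma_fraction: float = 0.55    # dimensionless, in (0, 1]
    TR: float = 0.5                  # s
    frame_interval: float = 97.0     # s
    n_precontrast_frames: int = 2
    signal_model: str = SATURATION_RECOVERY

    def __post_init__(self) -> None:
        for name in ("T10_tissue", "T10_artery", "r1", "TR", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.plasma_fraction <= 1.0:
            raise ValueError("plasma_fraction must lie in (0, 1]")
        if self.n_precontrast_frames < 0:
            raise ValueError("n_precontrast_frames must be nonnegative")
        if self.signal_model not in (SATURATION_RECOVERY, LINEAR):
            raise ValueError(f"unknown signal_model {self.signal_model!r}")

    def T10(self, compartment: str) -> float:
        return self.T10_artery if compartment == ARTERY else self.T10_tissue

    def with_model(self, signal_model: str) -> "AcquisitionConstants":
        return replace(self, signal_model=signal_model)


def precontrast_baseline(signal: SignalSeries, consts: AcquisitionConstants) -> float:
    """Arithmetic mean of the first ``n_precontrast_frames`` signal values."""
    n_pre = consts.n_precontrast_frames
    if n_pre < 1:
        raise ValueError("signal conversion needs at least one pre-contrast frame")
    if len(signal) <= n_pre:
        raise ValueError("series has no post-contrast frames")
    s_pre = float(np.mean(signal.values[:n_pre]))
    if s_pre <= 0:
        raise ValueError(f"pre-contrast baseline must be positive, got {s_pre}")
    return s_pre


def signal_to_concentration(
    signal: SignalSeries, consts: AcquisitionConstants
) -> ConcentrationSeries:
    """Convert a signal series to gadolinium concentration (mM).

    The pre-contrast baseline S_pre is the mean of the first
    ``n_precontrast_frames`` values; those frames map to exactly 0 mM.
    Arterial output is multiplied by ``plasma_fraction``.  Frames whose
    ratio exceeds the invertible range of the saturation-recovery model
    are clamped to the largest representable concentration and flagged
    in the returned series' ``clamped`` mask.
    """
    s_pre = precontrast_baseline(signal, consts)
    n_pre = consts.n_precontrast_frames
    T10 = consts.T10(signal.compartment)
    ratio = signal.values / s_pre

    clamped = np.zeros(len(signal), dtype=bool)
    if consts.signal_model == SATURATION_RECOVERY:
        E0 = math.exp(-consts.TR / T10)
        x = 1.0 - ratio * (1.0 - E0)
        bad = x <= _RATIO_FLOOR
        if np.any(bad):
            clamped |= bad
            x = np.where(bad, _RATIO_FLOOR, x)
        # 1/T1 = -ln(x)/TR; C = (1/T1 - 1/T10)/r1
        conc = (-np.log(x) / consts.TR - 1.0 / T10) / consts.r1
    else:
        conc = (ratio - 1.0) / (consts.r1 * T10)

    if signal.compartment == ARTERY:
        conc = conc * consts.plasma_fraction

    conc = conc.copy()
    conc[:n_pre] = 0.0
    clamped[:n_pre] = False
    if clamped.any():
        logger.warning(
            "%d/%d %s frames exceeded the invertible signal range and were clamped",
            int(clamped.sum()), len(signal), signal.compartment,
        )
    return ConcentrationSeries(signal.times, conc, signal.compartment, clamped)


def concentration_to_signal(
    conc: ConcentrationSeries, s_pre: float, consts: AcquisitionConstants
) -> SignalSeries:
    """Forward signal model: exact functional inverse of
    :func:`signal_to_concentration` on valid inputs (used by the simulator).

    For the artery compartment the stored concentration is understood to be
    plasma-corrected and is divided by ``plasma_fraction`` before inversion.
    """
    if s_pre <= 0:
        raise ValueError("s_pre must be strictly positive")
    values = conc.values
    if np.any(values < 0):
        raise ValueError("concentrations must be nonnegative")
    T10 = consts.T10(conc.compartment)
    if conc.compartment == ARTERY:
        values = values / consts.plasma_fraction

    R1 = 1.0 / T10 + consts.r1 * values
    if consts.signal_model == SATURATION_RECOVERY:
        E0 = math.exp(-consts.TR / T10)
        ratio = (1.0 - np.exp(-consts.TR * R1)) / (1.0 - E0)
    else:
        ratio = 1.0 + consts.r1 * T10 * values
    return SignalSeries(conc.times, s_pre * ratio, conc.compartment)
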