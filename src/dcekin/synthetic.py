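"""Forward simulator of the DCE-MRI permeability experiment.

Emulates the acquisition: 40 T1-weighted frames of 97 s each, the first
2 before contrast injection, then ~1 h of continuous post-contrast
imaging.  Tissue kinetics follow dCt/dt = Ktrans·Cp − Kep·Ct with
stage-active constants: for a two-stage (repeated-irradiation) design the
constants switch at the split time while Ct remains continuous — the
piecewise equation is integrated exactly, term by term, rather than
restarting the single-stage closed form (physical tissue concentration
cannot jump).

Concentration curves are converted to image signals through the inverse
relaxometry model, and optional Gaussian or Rician noise (seeded,
bit-reproducible) is applied, yielding fixture datasets for every
estimator in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aif import AIFParams, cp_model
from .gkm import GKMParams, _conv_terms, ct_model
from .relaxometry import AcquisitionConstants, concentration_to_signal
from .series import ARTERY, TISSUE, ConcentrationSeries

GAUSSIAN = "gaussian"
RICIAN = "rician"
NONE = "none"

#: default simulation truths: Table-scale rate constants per experimental arm
SINGLE_150 = GKMParams(0.059, 0.049)
SINGLE_450 = GKMParams(0.126, 0.044)
REPEATED_STAGE1 = GKMParams(0.093, 0.053)
REPEATED_STAGE2 = GKMParams(0.068, 0.015)

#: default arterial truth: plausible partial-volume rat-artery ROI after
#: plasma correction (peak 0.3 mM; distribution half-life ~1.7 min,
#: terminal ~14 min)
DEFAULT_AIF = AIFParams(A1=0.2, A2=0.1, m1=0.05, m2=0.4)

DEFAULT_S_PRE = {ARTERY: 1000.0, TISSUE: 800.0}


@dataclass(frozen=True)
class ExperimentDesign:
    """Acquisition schedule plus simulation ground truth.

    ``split_min`` and ``truth_stage2`` are present together for a
    repeated-irradiation (two-stage) design and absent for a single one.
    """

    n_frames: int = 40
    frame_interval: float = 97.0       # s
    n_precontrast: int = 2
    truth_aif: AIFParams = DEFAULT_AIF
    truth_stage1: GKMParams = SINGLE_150
    truth_stage2: GKMParams | None = None
    split_min: float | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 1 <= self.n_precontrast < self.n_frames:
            raise ValueError("n_precontrast must be in [1, n_frames)")
        if (self.split_min is None) != (self.truth_stage2 is None):
            raise ValueError("split_min and truth_stage2 must be given together")
        if self.split_min is not None and not 0.0 < self.split_min < self.duration_min:
            raise ValueError("split_min must fall inside the post-contrast window")

    @property
    def times_min(self) -> np.ndarray:
        """Frame times in minutes, t = 0 at the first post-contrast frame."""
        idx = np.arange(self.n_frames) - self.n_precontrast
        return idx * self.frame_interval / 60.0

    @property
    def duration_min(self) -> float:
        return float(self.times_min[-1])

    @classmethod
    def single_150(cls) -> "ExperimentDesign":
        return cls(truth_stage1=SINGLE_150)

    @classmethod
    def single_450(cls) -> "ExperimentDesign":
        return cls(truth_stage1=SINGLE_450)

    @classmethod
    def repeated_150_450(cls) -> "ExperimentDesign":
        """Second irradiation 20 min after the first."""
        return cls(truth_stage1=REPEATED_STAGE1, truth_stage2=REPEATED_STAGE2,
                   split_min=20.0)


@dataclass(frozen=True)
class NoiseModel:
    kind: str = NONE
    sigma: float = 0.0      # fraction of each series' peak signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (NONE, GAUSSIAN, RICIAN):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def _ct_piecewise(t: np.ndarray, aif: AIFParams, stage1: GKMParams,
                  stage2: GKMParams, ts: float) -> np.ndarray:
    """Exact solution of the stage-switching tissue ODE, continuous at ts."""
    out = np.empty_like(t)
    before = t <= ts
    out[before] = ct_model(t[before], aif, stage1)
    if np.any(~before):
        c_split = ct_model(ts, aif, stage1)
        dt = t[~before] - ts
        # fresh uptake after the switch: amplitudes decayed to the split time
        amps = (aif.A1 * np.exp(-aif.m1 * ts), aif.A2 * np.exp(-aif.m2 * ts))
        fresh = stage2.Ktrans * _conv_terms(dt, amps, (aif.m1, aif.m2), stage2.Kep)
        out[~before] = c_split * np.exp(-stage2.Kep * dt) + fresh
    return out


def simulate_concentrations(
    design: ExperimentDesign,
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """Noise-free artery and tissue concentration curves on the frame grid."""
    t = design.times_min
    post = t >= 0.0
    cp = np.zeros_like(t)
    ct = np.zeros_like(t)
    cp[post] = cp_model(t[post], design.truth_aif)
    if design.split_min is None:
        ct[post] = ct_model(t[post], design.truth_aif, design.truth_stage1)
    else:
        ct[post] = _ct_piecewise(t[post], design.truth_aif, design.truth_stage1,
                                 design.truth_stage2, design.split_min)
    return (
        ConcentrationSeries(t, cp, ARTERY),
        ConcentrationSeries(t, ct, TISSUE),
    )


def _apply_noise(values: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    if noise.kind == NONE or noise.sigma == 0.0:
        return values.copy()
    scale = noise.sigma * float(np.max(values))
    if noise.kind == GAUSSIAN:
        return values + rng.normal(0.0, scale, values.shape)
    # Rician: magnitude of a complex signal with iid Gaussian channel noise
    re = values + rng.normal(0.0, scale, values.shape)
    im = rng.normal(0.0, scale, values.shape)
    return np.hypot(re, im)


def simulate_signals(
    design: ExperimentDesign,
    noise: NoiseModel = NoiseModel(),
    consts: AcquisitionConstants | None = None,
    s_pre: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulated signal table ``time_min, artery_signal, tissue_signal``.

    Pre-contrast frames carry the baseline signal (plus noise).  Rerunning
    with the same seed reproduces the table bit for bit.
    """
    if consts is None:
        consts = AcquisitionConstants(
            frame_interval=design.frame_interval,
            n_precontrast_frames=design.n_precontrast,
        )
    s_pre = {**DEFAULT_S_PRE, **(s_pre or {})}
    cp, ct = simulate_concentrations(design)
    artery = concentration_to_signal(cp, s_pre[ARTERY], consts)
    tissue = concentration_to_signal(ct, s_pre[TISSUE], consts)

    rng = np.random.default_rng(noise.seed)
    artery_vals = _apply_noise(artery.values, noise, rng)
    tissue_vals = _apply_noise(tissue.values, noise, rng)
    return pd.DataFrame(
        {
            "time_min": design.times_min,
            "artery_signal": artery_vals,
            "tissue_signal": tissue_vals,
        }
    )
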