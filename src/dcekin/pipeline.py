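"""End-to-end analysis: convert -> fit AIF -> fit kinetics -> report.

The pipeline reads one signal (or concentration) table, estimates the
AIF from all arterial frames, fits either the single-stage model or the
two-stage procedure on the tissue curve, and writes a JSON report plus a
fitted-vs-observed plot.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np

from . import two_stage as ts
from .aif import cp_model, fit_aif
from .config import AnalysisConfig
from .gkm import ct_model, fit_gkm
from .io import read_concentration_table, read_signal_table
from .relaxometry import signal_to_concentration
from .report import AIFReport, AnalysisReport, TwoStageReport, gkm_report

logger = logging.getLogger(__name__)


class FitFailure(RuntimeError):
    """A model fit failed to converge; the stage name is in the message."""


def run_pipeline(config: AnalysisConfig, plot: bool = True) -> AnalysisReport:
    if config.io.input is None:
        raise ValueError("config.io.input is not set")
    path = Path(config.io.input)
    if config.io.input_kind == "signal":
        artery_sig, tissue_sig = read_signal_table(path)
        cp = signal_to_concentration(artery_sig, config.acquisition)
        ct = signal_to_concentration(tissue_sig, config.acquisition)
    elif config.io.input_kind == "concentration":
        cp, ct = read_concentration_table(path)
    else:
        raise ValueError(f"unknown input_kind {config.io.input_kind!r}")

    aif_fit = fit_aif(cp)
    if not aif_fit.converged:
        raise FitFailure(f"aif: {aif_fit.message} (input {path})")
    aif = aif_fit.params
    logger.info("AIF fit: A1=%.4g A2=%.4g m1=%.4g m2=%.4g rss=%.3g",
                aif.A1, aif.A2, aif.m1, aif.m2, aif_fit.rss)

    report = AnalysisReport(
        input=str(path),
        mode=config.mode,
        aif=AIFReport(A1=aif.A1, A2=aif.A2, m1=aif.m1, m2=aif.m2,
                      rss=aif_fit.rss, converged=aif_fit.converged),
    )
    out_dir = Path(config.io.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "two_stage":
        result = ts.fit_two_stage(
            ct, aif, config.two_stage.split_min,
            method=config.two_stage.smoothing,
            n=config.two_stage.n_resample,
            stage2_mode=config.two_stage.stage2_mode,
        )
        for label, stage in (("stage1", result.stage1), ("stage2", result.stage2)):
            if not stage.converged:
                raise FitFailure(f"{label}: {stage.message} (input {path})")
        report = report.model_copy(update={"two_stage": TwoStageReport(
            split_min=result.split_time,
            method=result.method,
            stage2_mode=result.stage2_mode,
            stage1=gkm_report(result.stage1),
            stage2=gkm_report(result.stage2),
            weighted_ve=None if math.isnan(result.weighted_ve) else result.weighted_ve,
        )})
        fitted = _two_stage_curve(ct, aif, result)
    else:
        fit = fit_gkm(ct, aif)
        if not fit.converged:
            raise FitFailure(f"gkm: {fit.message} (input {path})")
        report = report.model_copy(update={"gkm": gkm_report(fit)})
        post = ct.times >= 0
        fitted = (ct.times[post], ct_model(ct.times[post], aif, fit.params))

    report.write(out_dir / "report.json")
    if plot:
        _plot(cp, ct, aif, fitted, out_dir / "fit.png")
    return report


def _two_stage_curve(ct_series, aif, result):
    t_post = ct_series.times[ct_series.times >= 0]
    grid1 = np.linspace(t_post[0], result.split_time, 100)
    grid2 = np.linspace(result.split_time, t_post[-1], 100)
    y1 = ct_model(grid1, aif, result.stage1.params)
    if result.stage2_mode == ts.GLOBAL_OFFSET:
        y2 = ct_model(grid2, aif, result.stage2.params) + (result.stage2.offset or 0.0)
    else:
        y2 = ct_model(grid2 - result.split_time, aif, result.stage2.params)
        y2 = y2 + y1[-1]
    return (np.concatenate([grid1, grid2]), np.concatenate([y1, y2]))


def _plot(cp, ct, aif, fitted, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    post = cp.times >= 0
    ax1.plot(cp.times[post], cp.values[post], "o", ms=3, label="observed")
    grid = np.linspace(0, cp.times[-1], 200)
    ax1.plot(grid, cp_model(grid, aif), "-", label="biexponential fit")
    ax1.set(xlabel="time (min)", ylabel="Cp (mM)", title="arterial input")
    ax1.legend(fontsize=8)
    post_t = ct.times >= 0
    ax2.plot(ct.times[post_t], ct.values[post_t], "o", ms=3, label="observed")
    ax2.plot(fitted[0], fitted[1], "-", label="kinetic model")
    ax2.set(xlabel="time (min)", ylabel="Ct (mM)", title="tissue uptake")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
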