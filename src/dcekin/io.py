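"""Readers and writers for the package's tabular dialects, plus optional
NIfTI ROI reduction.

CSV dialects:

* signal tables:        ``time_min,artery_signal,tissue_signal``
* concentration tables: ``time_min,Cp_mM,Ct_mM``

Volume input is a 4D NIfTI image plus a 3D binary mask; the ROI is
reduced to its per-frame mean signal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .relaxometry import AcquisitionConstants
from .series import ARTERY, TISSUE, ConcentrationSeries, SignalSeries

SIGNAL_COLUMNS = ["time_min", "artery_signal", "tissue_signal"]
CONCENTRATION_COLUMNS = ["time_min", "Cp_mM", "Ct_mM"]


class ParseError(ValueError):
    """Malformed tabular input (bad header, bad times, missing values)."""


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise ParseError(
            f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}"
        )
    for col in columns:
        nan_rows = df.index[df[col].isna()]
        if len(nan_rows):
            raise ParseError(f"{path}: missing/NaN value in column {col!r} "
                             f"at data row {int(nan_rows[0]) + 1}")
    t = df["time_min"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError(
            f"{path}: time_min not strictly increasing at data row {int(bad[0]) + 2} "
            f"(t = {t[bad[0] + 1]})"
        )
    return df


def read_signal_table(path: str | Path) -> tuple[SignalSeries, SignalSeries]:
    """Read a signal CSV; returns (artery, tissue) series."""
    df = _read_table(path, SIGNAL_COLUMNS)
    t = df["time_min"].to_numpy(dtype=float)
    return (
        SignalSeries(t, df["artery_signal"].to_numpy(dtype=float), ARTERY),
        SignalSeries(t, df["tissue_signal"].to_numpy(dtype=float), TISSUE),
    )


def read_concentration_table(
    path: str | Path,
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """Read a concentration CSV; returns (artery, tissue) series."""
    df = _read_table(path, CONCENTRATION_COLUMNS)
    t = df["time_min"].to_numpy(dtype=float)
    return (
        ConcentrationSeries(t, df["Cp_mM"].to_numpy(dtype=float), ARTERY),
        ConcentrationSeries(t, df["Ct_mM"].to_numpy(dtype=float), TISSUE),
    )


def read_series(path: str | Path, dialect: str):
    """Dispatch on dialect name ('signal' or 'concentration')."""
    if dialect == "signal":
        return read_signal_table(path)
    if dialect == "concentration":
        return read_concentration_table(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_signal_table(path: str | Path, artery: SignalSeries,
                       tissue: SignalSeries) -> None:
    if not np.array_equal(artery.times, tissue.times):
        raise ValueError("artery and tissue series must share one time grid")
    pd.DataFrame({
        "time_min": artery.times,
        "artery_signal": artery.values,
        "tissue_signal": tissue.values,
    }).to_csv(path, index=False)


def write_concentration_table(path: str | Path, artery: ConcentrationSeries,
                              tissue: ConcentrationSeries) -> None:
    if not np.array_equal(artery.times, tissue.times):
        raise ValueError("artery and tissue series must share one time grid")
    pd.DataFrame({
        "time_min": artery.times,
        "Cp_mM": artery.values,
        "Ct_mM": tissue.values,
    }).to_csv(path, index=False)


def roi_mean_series(
    image_path: str | Path,
    mask_path: str | Path,
    consts: AcquisitionConstants,
    compartment: str = TISSUE,
) -> SignalSeries:
    """Reduce a 4D NIfTI volume to the per-frame mean signal over a mask.

    Frame times are built from the acquisition constants (frame interval,
    number of pre-contrast frames), t = 0 at the first post-contrast frame.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data.shape}")
    if data.shape[3] < 3:
        raise ValueError("need at least 3 frames along the 4th axis")
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask grid {mask.shape} does not match image grid {data.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    values = data[mask].mean(axis=0)
    n = data.shape[3]
    times = (np.arange(n) - consts.n_precontrast_frames) * consts.frame_interval / 60.0
    return SignalSeries(times, values, compartment)
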