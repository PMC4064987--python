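"""Time-series containers for ROI-averaged DCE-MRI data.

Two containers are used throughout the package:

* :class:`SignalSeries` — raw T1-weighted image signal intensities
  (arbitrary units) for one compartment (cerebral artery or brain tissue).
* :class:`ConcentrationSeries` — gadolinium concentration in millimolar
  for the same compartments.

Times are stored in **minutes**, with t = 0 at the first post-contrast
frame; pre-contrast baseline frames carry negative times.  Rate constants
derived from these series are therefore in min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARTERY = "artery"
TISSUE = "tissue"
_COMPARTMENTS = (ARTERY, TISSUE)


def _validate_grid(times: np.ndarray, values: np.ndarray, compartment: str) -> None:
    if compartment not in _COMPARTMENTS:
        raise ValueError(f"compartment must be one of {_COMPARTMENTS}, got {compartment!r}")
    if times.ndim != 1 or values.ndim != 1:
        raise ValueError("times and values must be one-dimensional")
    if times.shape != values.shape:
        raise ValueError(
            f"times and values differ in length ({times.size} vs {values.size})"
        )
    if times.size < 3:
        raise ValueError("a series needs at least 3 samples")
    if not np.all(np.isfinite(times)):
        raise ValueError("times contain non-finite entries")
    dt = np.diff(times)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"times must be strictly increasing (violated at row {row})")


@dataclass(frozen=True)
class SignalSeries:
    """ROI-mean image signal intensities on a strictly increasing time grid."""

    times: np.ndarray
    values: np.ndarray
    compartment: str

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        _validate_grid(times, values, self.compartment)
        if not np.all(np.isfinite(values)):
            row = int(np.argmax(~np.isfinite(values))) + 1
            raise ValueError(f"signal values contain non-finite entry at row {row}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ConcentrationSeries:
    """Gadolinium concentration (mM) on a strictly increasing time grid.

    ``clamped`` optionally marks samples whose signal ratio fell outside
    the invertible range of the signal model and was clamped during
    conversion (see :mod:`dcekin.relaxometry`).
    """

    times: np.ndarray
    values: np.ndarray
    compartment: str
    clamped: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        _validate_grid(times, values, self.compartment)
        if not np.all(np.isfinite(values)):
            row = int(np.argmax(~np.isfinite(values))) + 1
            raise ValueError(f"concentration values contain non-finite entry at row {row}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.clamped is not None:
            clamped = np.asarray(self.clamped, dtype=bool)
            if clamped.shape != times.shape:
                raise ValueError("clamped mask must match the time grid")
            object.__setattr__(self, "clamped", clamped)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_clamped(self) -> int:
        return 0 if self.clamped is None else int(self.clamped.sum())

    def postcontrast(self) -> "ConcentrationSeries":
        """Restrict to the post-contrast window (t >= 0)."""
        mask = self.times >= 0.0
        if mask.sum() < 3:
            raise ValueError("fewer than 3 post-contrast samples")
        return ConcentrationSeries(
            self.times[mask],
            self.values[mask],
            self.compartment,
            None if self.clamped is None else self.clamped[mask],
        )
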