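"""Delay-line geometry and Raman-shift axis calibration.

In a spectral-focusing SRS microscope the Stokes pulse is scanned along a
blazed grating held in Littrow configuration.  The grating acts as a
retro-reflecting wedge: sweeping the beam along a scan line of length ``L``
introduces a continuously increasing optical path, and hence a time delay
between the chirped pump and Stokes pulses.  Because both pulses are linearly
chirped, inter-pulse delay maps linearly onto Raman shift, so the spectral
axis of an acquired stack is recovered by an ordinary least-squares line
through a handful of samples with known Raman shifts.

The geometric span of the delay line is ``L * sin(theta) * tan(alpha)`` where
``theta`` is the angle between the laser scan line and the grating blaze line
and ``alpha`` is the blaze angle; rotating the grating (``theta``) fine-tunes
the delay range without any realignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_MM_PER_PS",
    "DelayGeometry",
    "LinearCalibration",
    "SpectralAxis",
    "effective_delay_length",
    "delay_length_to_time",
    "fit_linear_calibration",
    "apply_calibration",
    "read_peak_table",
    "CalibrationError",
]

#: c in mm per picosecond (2.9979e8 m/s).
SPEED_OF_LIGHT_MM_PER_PS = 0.29979245800


class CalibrationError(ValueError):
    """Raised when a spectral-axis calibration cannot be performed."""


@dataclass(frozen=True)
class DelayGeometry:
    """Geometry of the polygon-scanned Littrow delay line.

    Parameters
    ----------
    scan_line_length_mm
        Length ``L`` of the laser scan line on the grating, in mm.
    grating_rotation_deg
        Angle ``theta`` between scan line and blaze line, degrees in [0, 90].
    blaze_angle_deg
        Grating blaze angle ``alpha``, degrees in (0, 90).
    round_trip_factor
        Path multiplier for the retro-reflected beam.  The default of 2
        accounts for the beam traversing the added path twice.
    """

    scan_line_length_mm: float
    grating_rotation_deg: float
    blaze_angle_deg: float
    round_trip_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.scan_line_length_mm < 0:
            raise ValueError("scan line length must be non-negative")
        if not 0.0 <= self.grating_rotation_deg <= 90.0:
            raise ValueError("grating rotation theta must lie in [0, 90] degrees")
        if not 0.0 < self.blaze_angle_deg < 90.0:
            raise ValueError("blaze angle alpha must lie in (0, 90) degrees")
        if self.round_trip_factor <= 0:
            raise ValueError("round_trip_factor must be positive")


@dataclass(frozen=True)
class LinearCalibration:
    """Least-squares line mapping acquisition sample index to Raman shift."""

    slope: float  # cm^-1 per sample
    intercept: float  # cm^-1 at sample index 0
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise ValueError("a calibration needs at least 2 points")


@dataclass(frozen=True)
class SpectralAxis:
    """Per-channel Raman shifts (cm^-1) of a hyperspectral stack."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        if wn.ndim != 1 or wn.size < 1:
            raise ValueError("spectral axis must be a non-empty 1-D vector")
        if not np.all(np.isfinite(wn)):
            raise ValueError("spectral axis must be finite")
        if wn.size > 1:
            d = np.diff(wn)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("spectral axis must be strictly monotone")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def nearest_channel(self, shift_cm1: float) -> int:
        """Index of the channel closest to a given Raman shift."""
        return int(np.argmin(np.abs(self.wavenumbers - shift_cm1)))


def effective_delay_length(geom: DelayGeometry) -> float:
    """Geometric path-length span ``L sin(theta) tan(alpha)`` in mm."""
    theta = math.radians(geom.grating_rotation_deg)
    alpha = math.radians(geom.blaze_angle_deg)
    return geom.scan_line_length_mm * math.sin(theta) * math.tan(alpha)


def delay_length_to_time(path_span_mm: float, round_trip_factor: float = 2.0) -> float:
    """Convert a geometric path span (mm) to an optical delay in picoseconds.

    The retro-reflected beam traverses the added path ``round_trip_factor``
    times, so the optical delay is ``factor * span / c``.
    """
    if path_span_mm < 0:
        raise ValueError("path span must be non-negative")
    if round_trip_factor <= 0:
        raise ValueError("round_trip_factor must be positive")
    return round_trip_factor * path_span_mm / SPEED_OF_LIGHT_MM_PER_PS


def fit_linear_calibration(
    sample_indices: np.ndarray, known_shifts_cm1: np.ndarray
) -> LinearCalibration:
    """Ordinary least-squares line through (sample index, known Raman shift).

    The calibration samples come from significant Raman peaks of standard
    chemicals whose shifts are known from spontaneous Raman spectroscopy.
    R-squared is the standard coefficient of determination,
    ``1 - SS_res / SS_tot`` with ``SS_tot`` taken about the mean.
    """
    x = np.asarray(sample_indices, dtype=float)
    y = np.asarray(known_shifts_cm1, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise CalibrationError("sample indices and shifts must be equal-length vectors")
    if x.size < 2:
        raise CalibrationError("calibration requires at least 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise CalibrationError("calibration points must be finite")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise CalibrationError("sample indices have zero variance")

    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())

    residuals = y - (slope * x + intercept)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # all shifts identical: a flat line fits exactly
        r_squared = 1.0
    else:
        r_squared = 1.0 - ss_res / ss_tot
    r_squared = float(min(max(r_squared, 0.0), 1.0))
    return LinearCalibration(
        slope=slope, intercept=intercept, r_squared=r_squared, n_points=int(x.size)
    )


def apply_calibration(cal: LinearCalibration, n_channels: int) -> SpectralAxis:
    """Build the per-channel Raman-shift axis ``slope * k + intercept``."""
    if n_channels < 1:
        raise ValueError("need at least one spectral channel")
    if cal.slope == 0.0 and n_channels > 1:
        raise CalibrationError("zero slope produces a degenerate (constant) axis")
    k = np.arange(n_channels, dtype=float)
    return SpectralAxis(cal.slope * k + cal.intercept)


def read_peak_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a calibration peak table CSV: ``sample_index,raman_shift_cm1``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"sample_index", "raman_shift_cm1"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"peak table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df["sample_index"].to_numpy(float), df["raman_shift_cm1"].to_numpy(float)
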