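"""Idealized spatially fractionated microbeam field model.

The lateral field is a top-hat comb: beamlets of width ``width_um`` at
``pitch_um`` spacing carry the peak dose, the gaps carry the valley
dose, optionally smoothed by a Gaussian penumbra. Depth dependence is a
per-component exponential-decay curve queried by log-linear
interpolation. The delivered dose of a vertically scanned field follows
the scan-speed relation dose = rate * field_height / speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ArraySpec",
    "DoseProfile1D",
    "DepthDoseCurve",
    "DeliverySpec",
    "comb_profile",
    "measure_pvdr",
    "dose_at_depth",
    "calibrate_scan_speed",
    "delivered_dose",
]


@dataclass(frozen=True)
class ArraySpec:
    """Microbeam array geometry (defaults: 50 um beamlets at 400 um pitch)."""

    width_um: float = 50.0
    pitch_um: float = 400.0
    field_width_mm: float = 8.0
    field_height_mm: float = 8.0
    penumbra_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.width_um < self.pitch_um:
            raise ValueError("require 0 < beam width < pitch")
        if self.field_width_mm <= 0 or self.field_height_mm <= 0:
            raise ValueError("field dimensions must be positive")
        if self.penumbra_um < 0:
            raise ValueError("penumbra sigma must be >= 0")

    @property
    def f_peak(self) -> float:
        """Areal fraction of the field inside beamlets (width / pitch)."""
        return self.width_um / self.pitch_um


@dataclass(frozen=True)
class DoseProfile1D:
    """Lateral dose profile: strictly increasing positions (um) and doses (Gy)."""

    positions_um: np.ndarray
    dose_gy: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        dose = np.asarray(self.dose_gy, dtype=float)
        if pos.shape != dose.shape or pos.ndim != 1:
            raise ValueError("positions and doses must be 1-D arrays of equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(dose < 0):
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "dose_gy", dose)


@dataclass(frozen=True)
class DepthDoseCurve:
    """Peak and valley dose versus depth from the skin surface.

    Queries between grid points use log-linear interpolation, exact for
    exponential attenuation.
    """

    depth_mm: np.ndarray
    peak_gy: np.ndarray
    valley_gy: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_mm, dtype=float)
        p = np.asarray(self.peak_gy, dtype=float)
        v = np.asarray(self.valley_gy, dtype=float)
        if d.ndim != 1 or d.shape != p.shape or d.shape != v.shape:
            raise ValueError("depth, peak and valley arrays must share one shape")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("depths must be non-negative and strictly increasing")
        if np.any(p <= 0) or np.any(v <= 0):
            raise ValueError("doses must be positive")
        if np.any(p < v):
            raise ValueError("peak dose must be >= valley dose at every depth")
        object.__setattr__(self, "depth_mm", d)
        object.__setattr__(self, "peak_gy", p)
        object.__setattr__(self, "valley_gy", v)

    def pvdr(self) -> np.ndarray:
        return self.peak_gy / self.valley_gy


@dataclass(frozen=True)
class DeliverySpec:
    """Scan-delivery configuration of the intrinsic (unscanned) field."""

    peak_rate_gy_s: float
    valley_rate_gy_s: float
    field_height_mm: float = 0.5

    def __post_init__(self) -> None:
        if min(self.peak_rate_gy_s, self.valley_rate_gy_s, self.field_height_mm) <= 0:
            raise ValueError("rates and field height must be positive")


def comb_profile(
    spec: ArraySpec, peak_gy: float, valley_gy: float, step_um: float = 5.0
) -> DoseProfile1D:
    """Ideal lateral comb profile of the microbeam array.

    A top-hat comb centered on the field: ``peak_gy`` inside beamlets
    (half-open intervals of ``width_um`` around each beamlet center),
    ``valley_gy`` between. If the spec carries a penumbra sigma, the comb
    is smoothed with a periodic Gaussian, which preserves the integral.

    The step must resolve the beamlets (step <= width/5).
    """
    if not peak_gy >= valley_gy > 0:
        raise ValueError("require peak >= valley > 0")
    if step_um > spec.width_um / 5:
        raise ValueError(
            f"grid step {step_um} um too coarse for {spec.width_um} um beamlets "
            "(must be <= width/5)"
        )
    half_width_um = spec.field_width_mm * 500.0
    n = int(round(2 * half_width_um / step_um))
    x = np.arange(n) * step_um - half_width_um
    # Beamlet centers at integer multiples of the pitch; field centered on one.
    offset = (x + spec.pitch_um / 2) % spec.pitch_um - spec.pitch_um / 2
    in_beam = (offset >= -spec.width_um / 2) & (offset < spec.width_um / 2)
    dose = np.where(in_beam, float(peak_gy), float(valley_gy))
    if spec.penumbra_um > 0:
        dose = gaussian_filter1d(dose, sigma=spec.penumbra_um / step_um, mode="wrap")
    return DoseProfile1D(positions_um=x, dose_gy=dose)


def measure_pvdr(profile: DoseProfile1D, spec: ArraySpec) -> tuple[float, float]:
    """Measure PVDR across the 5 central beamlets of a lateral profile.

    The peak of each beamlet is the maximum dose within its half-pitch
    window; its associated valley is the mean dose over the central 20%
    of the following inter-beam gap (near-midway between peaks, robust
    to penumbra). Returns (PVDR, sd) where PVDR is the mean of the 5
    central peak maxima over the mean of the associated valleys and sd
    is one standard deviation of the 5 per-pair ratios.
    """
    x, dose = profile.positions_um, profile.dose_gy
    pitch = spec.pitch_um
    n_centers = int(np.floor((x[-1] - x[0]) / pitch))
    centers = np.arange(math.ceil(x[0] / pitch), math.floor(x[-1] / pitch) + 1) * pitch
    # Keep centers whose valley midpoint (center + pitch/2) is still in range.
    centers = centers[(centers - pitch / 2 >= x[0]) & (centers + pitch * 0.6 <= x[-1])]
    if len(centers) < 5:
        raise ValueError(
            f"profile spans only {max(len(centers), n_centers)} usable beamlets; "
            ">= 5 required"
        )
    mid = len(centers) // 2
    central = centers[mid - 2 : mid + 3]

    peaks = np.empty(5)
    valleys = np.empty(5)
    for i, c in enumerate(central):
        in_peak_win = np.abs(x - c) <= pitch / 4
        peaks[i] = dose[in_peak_win].max()
        v_mid = c + pitch / 2
        in_valley_win = np.abs(x - v_mid) <= 0.1 * (pitch - spec.width_um)
        valleys[i] = dose[in_valley_win].mean()

    pvdr = float(peaks.mean() / valleys.mean())
    sd = float(np.std(peaks / valleys, ddof=1))
    return pvdr, sd


def dose_at_depth(curve: DepthDoseCurve, depth_mm: float, component: str = "valley") -> float:
    """Dose at a depth by log-linear interpolation of the stored curve.

    ``component`` selects the peak or valley curve. Depths outside the
    stored span raise rather than extrapolate.
    """
    d = curve.depth_mm
    if not d[0] <= depth_mm <= d[-1]:
        raise ValueError(
            f"depth {depth_mm} mm outside curve span [{d[0]}, {d[-1]}] mm"
        )
    if component == "peak":
        y = curve.peak_gy
    elif component == "valley":
        y = curve.valley_gy
    else:
        raise ValueError(f"component must be 'peak' or 'valley', got {component!r}")
    return float(np.exp(np.interp(depth_mm, d, np.log(y))))


def calibrate_scan_speed(delivery: DeliverySpec, prescription_gy: float,
                         component: str = "valley") -> float:
    """Scan speed (mm/s) delivering a prescribed dose of one component.

    A field of height h scanned at speed s exposes each point for h/s
    seconds, so speed = rate * height / prescription.
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    rate = delivery.valley_rate_gy_s if component == "valley" else delivery.peak_rate_gy_s
    return rate * delivery.field_height_mm / prescription_gy


def delivered_dose(delivery: DeliverySpec, speed_mm_s: float,
                   component: str = "valley") -> float:
    """Dose delivered by a vertical scan at a given speed (inverse of calibration)."""
    if speed_mm_s <= 0:
        raise ValueError("scan speed must be positive")
    rate = delivery.valley_rate_gy_s if component == "valley" else delivery.peak_rate_gy_s
    return rate * delivery.field_height_mm / speed_mm_s
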