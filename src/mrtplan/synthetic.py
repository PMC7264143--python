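"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the study's data sources so the full analysis is
testable end to end without animal, dosimeter or Monte Carlo data:

* contrast-CT-like voxel phantoms (ellipsoidal tumor on a uniform
  background, additive Gaussian noise, 97 um default in-plane pixels),
* Poisson-count clonogenic assays driven by LQ survival,
* exponential-decay peak/valley depth-dose curves through anchor points,
* survival cohorts with log-normal event times and a cure fraction
  handled as administrative censoring at the observation horizon.

Every generator is deterministic under its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import VolumetricImage
from .microbeam import DepthDoseCurve

__all__ = [
    "PhantomSpec",
    "AssaySpec",
    "CohortSpec",
    "generate_phantom",
    "generate_clonogenic",
    "generate_depth_dose",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Ellipsoidal-tumor voxel phantom specification.

    Intensities are HU-like arbitrary units; geometry is in mm in the
    image frame (voxel centers at origin + index * spacing). The default
    in-plane spacing matches the 97 um pixels of the study's micro-CT.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.097, 0.097, 0.097)
    center_mm: tuple[float, float, float] = (3.1, 3.1, 3.1)
    semi_axes_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_intensity: float = 200.0
    background_intensity: float = 100.0
    noise_sd: float = 0.0
    beam_axis: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be >= 1 voxel per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("tumor semi-axes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for c, a, n, s in zip(self.center_mm, self.semi_axes_mm, self.shape,
                              self.spacing_mm):
            if c - a < 0 or c + a > (n - 1) * s:
                raise ValueError(
                    "tumor ellipsoid exceeds the grid: "
                    f"center {c} mm, semi-axis {a} mm on a [0, {(n - 1) * s:.3f}] mm axis"
                )


@dataclass(frozen=True)
class AssaySpec:
    """Clonogenic-assay generator: LQ truth, plating efficiency, dish layout."""

    alpha: float
    beta: float
    pe_control: float = 0.5
    doses_gy: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    seeded: int = 1000
    dishes: int = 3  # triplicate seeding
    condition: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not 0 < self.pe_control <= 1:
            raise ValueError("control plating efficiency must lie in (0, 1]")
        if any(d < 0 for d in self.doses_gy):
            raise ValueError("doses must be >= 0")
        if self.seeded < 1:
            raise ValueError("cells seeded must be >= 1")
        if self.dishes < 1:
            raise ValueError("need >= 1 dish per dose")


@dataclass(frozen=True)
class CohortSpec:
    """Survival-cohort generator: log-normal event times plus a cure fraction."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 5, "treated": 5}
    )
    lognormal_mu: dict[str, float] = field(
        default_factory=lambda: {"control": 3.04, "treated": 3.78}
    )
    lognormal_sigma: dict[str, float] = field(
        default_factory=lambda: {"control": 0.15, "treated": 0.55}
    )
    cure_probability: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "treated": 0.2}
    )
    horizon_days: float = 528.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be positive")
        if any(not 0 <= p <= 1 for p in self.cure_probability.values()):
            raise ValueError("cure probabilities must lie in [0, 1]")
        for key in ("lognormal_mu", "lognormal_sigma", "cure_probability"):
            if set(getattr(self, key)) < set(self.group_sizes):
                raise ValueError(f"{key} must cover every group")


def generate_phantom(spec: PhantomSpec) -> tuple[VolumetricImage, np.ndarray]:
    """Voxel phantom with an ellipsoidal tumor and its ground-truth mask.

    The mask marks voxels whose centers fall inside the ellipsoid; the
    image is tumor/background intensity plus i.i.d. Gaussian noise of
    ``noise_sd``. Identical specs (including seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    coords = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing_mm)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    mask = (
        ((xx - spec.center_mm[0]) / spec.semi_axes_mm[0]) ** 2
        + ((yy - spec.center_mm[1]) / spec.semi_axes_mm[1]) ** 2
        + ((zz - spec.center_mm[2]) / spec.semi_axes_mm[2]) ** 2
    ) <= 1.0
    data = np.where(mask, spec.tumor_intensity, spec.background_intensity)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    image = VolumetricImage(
        data=data, spacing_mm=spec.spacing_mm, beam_axis=spec.beam_axis
    )
    return image, mask


def generate_clonogenic(spec: AssaySpec) -> pd.DataFrame:
    """Poisson clonogenic-assay table driven by LQ survival.

    Each dish at dose D draws a colony count from Poisson with mean
    seeded * PE_control * exp(-alpha*D - beta*D^2); dose-0 control
    dishes are always included. Columns: condition, dose_gy, seeded,
    colonies (one row per dish).
    """
    rng = np.random.default_rng(spec.seed)
    doses = sorted({0.0, *map(float, spec.doses_gy)})
    rows = []
    for d in doses:
        sf = np.exp(-spec.alpha * d - spec.beta * d**2)
        mean = spec.seeded * spec.pe_control * sf
        counts = rng.poisson(mean, size=spec.dishes)
        for c in counts:
            rows.append(
                {"condition": spec.condition, "dose_gy": d,
                 "seeded": spec.seeded, "colonies": int(c)}
            )
    return pd.DataFrame(rows)


def generate_depth_dose(
    anchors: list[tuple[float, float, float]]
) -> DepthDoseCurve:
    """Exponential-decay peak/valley depth-dose curve through anchor points.

    Fits one exponential per component by least squares on log dose
    against depth (exact interpolation for exactly two anchors) and
    returns the curve evaluated at the anchor depths; log-linear
    interpolation between those grid points reproduces the fitted
    exponential everywhere in the span.

    Anchors are (depth mm, peak Gy, valley Gy) with >= 2 distinct depths
    and strictly positive doses.
    """
    if len(anchors) < 2:
        raise ValueError("need >= 2 depth-dose anchors")
    arr = np.asarray(anchors, dtype=float)
    depths, peaks, valleys = arr[:, 0], arr[:, 1], arr[:, 2]
    if len(np.unique(depths)) < 2:
        raise ValueError("anchor depths must be distinct")
    if np.any(peaks <= 0) or np.any(valleys <= 0):
        raise ValueError("anchor doses must be positive (log-linear fit)")
    order = np.argsort(depths)
    depths = depths[order]
    if len(depths) == 2:
        # exact interpolation: the curve passes through both anchors bit-for-bit
        return DepthDoseCurve(
            depth_mm=depths, peak_gy=peaks[order], valley_gy=valleys[order]
        )

    def _fit(doses: np.ndarray) -> np.ndarray:
        slope, intercept = np.polyfit(depths, np.log(doses[order]), 1)
        return np.exp(intercept + slope * depths)

    return DepthDoseCurve(
        depth_mm=depths, peak_gy=_fit(peaks), valley_gy=_fit(valleys)
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic survival cohort (columns: id, group, days, event).

    Each animal is cured with its group's cure probability — observed to
    the administrative horizon and censored there — otherwise it dies at
    a log-normal event time (times beyond the horizon are likewise
    censored at the horizon).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    for group, n in spec.group_sizes.items():
        mu = spec.lognormal_mu[group]
        sigma = spec.lognormal_sigma[group]
        p_cure = spec.cure_probability[group]
        for _ in range(n):
            counter += 1
            cured = rng.random() < p_cure
            if cured:
                days, event = spec.horizon_days, 0
            else:
                t = float(np.exp(mu + sigma * rng.standard_normal()))
                if t >= spec.horizon_days:
                    days, event = spec.horizon_days, 0
                else:
                    days, event = t, 1
            rows.append(
                {"id": f"{group}-{counter:02d}", "group": group,
                 "days": days, "event": event}
            )
    return pd.DataFrame(rows)
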