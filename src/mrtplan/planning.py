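"""Dose-volume histograms, coverage metrics and equivalent uniform dose.

A tumor-volume-versus-depth profile and a peak/valley depth-dose curve
combine into per-structure (dose, volume) pairs, from which cumulative
DVHs and the planning endpoints are computed: V at the prescription
(percent of volume receiving at least the prescribed dose), the
under-dosed volume, D90 (dose covering 90% of the volume) and the
equivalent uniform dose

    EUD = D_ref * ln( sum_i w_i * SF_ref**(D_i / D_ref) ) / ln(SF_ref)

with volume-normalized weights w_i = v_i / sum_j v_j, which reduces to
the equal-voxel (1/N) sum when all voxels have the same volume. D_ref
defaults to 8 Gy, the minimum valley dose a tumor voxel can receive
inside the treatment field, with SF_ref the cell survival at that dose.

Tumor coverage is evaluated on the valley component by default: the
prescription is a valley dose, and in the two-population survival
picture cells in the beamlet paths are ablated outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import TumorVolumeProfile
from .microbeam import DepthDoseCurve, dose_at_depth

__all__ = [
    "DoseVolumePairs",
    "DVH",
    "PlanMetrics",
    "EUDConfig",
    "assign_doses",
    "build_dvh",
    "coverage_metrics",
    "eud",
    "oar_metrics",
]


@dataclass(frozen=True)
class DoseVolumePairs:
    """(dose Gy, volume mm^3) elements of one structure, one dose component."""

    dose_gy: np.ndarray
    volume_mm3: np.ndarray
    structure: str = "GTV"
    component: str = "valley"

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.dose_gy, dtype=float))
        v = np.atleast_1d(np.asarray(self.volume_mm3, dtype=float))
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("doses and volumes must be 1-D arrays of equal length")
        if np.any(d < 0) or np.any(v < 0):
            raise ValueError("doses and volumes must be >= 0")
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "volume_mm3", v)

    @property
    def total_volume_mm3(self) -> float:
        return float(self.volume_mm3.sum())


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram: fraction of volume receiving >= dose."""

    structure: str
    dose_gy: np.ndarray
    cum_volume_fraction: np.ndarray
    total_volume_mm3: float

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_gy, dtype=float)
        f = np.asarray(self.cum_volume_fraction, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("dose grid and fractions must be 1-D of equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose grid must be strictly increasing")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("cumulative curve must be monotone non-increasing")
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "cum_volume_fraction", f)

    def fraction_at_least(self, dose: float) -> float:
        """Fraction of the structure volume receiving >= ``dose`` Gy."""
        if dose <= self.dose_gy[0]:
            return float(self.cum_volume_fraction[0])
        if dose > self.dose_gy[-1]:
            return 0.0
        # The curve is constant between consecutive pair doses (all of which
        # sit on the grid), so the value at the next grid dose >= the query
        # is the exact fraction receiving >= dose.
        i = int(np.searchsorted(self.dose_gy, dose, side="left"))
        return float(self.cum_volume_fraction[i])


@dataclass(frozen=True)
class PlanMetrics:
    """Coverage endpoints of one plan/structure at one prescription."""

    v_prescription_pct: float
    underdosed_volume_mm3: float
    d90_gy: float
    eud_gy: float
    total_volume_mm3: float
    prescription_gy: float

    def rounded(self) -> dict[str, float]:
        """Report-precision view: volumes/percentages 2 dp, doses 1 dp."""
        return {
            "tumor_volume_mm3": round(self.total_volume_mm3, 2),
            "v_prescription_pct": round(self.v_prescription_pct, 2),
            "underdosed_volume_mm3": round(self.underdosed_volume_mm3, 2),
            "d90_gy": round(self.d90_gy, 1),
            "eud_gy": round(self.eud_gy, 1),
        }


@dataclass(frozen=True)
class EUDConfig:
    """Reference point of the EUD formula: dose D_ref and survival SF_ref at D_ref."""

    d_ref_gy: float = 8.0
    sf_ref: float = 0.115

    def __post_init__(self) -> None:
        if self.d_ref_gy <= 0:
            raise ValueError("reference dose must be positive")
        if not 0 < self.sf_ref < 1:
            raise ValueError("reference survival must lie in (0, 1)")


def assign_doses(
    profile: TumorVolumeProfile, curve: DepthDoseCurve, component: str = "valley",
    structure: str = "GTV",
) -> DoseVolumePairs:
    """Map each depth bin of a volume profile to its dose at the bin center."""
    doses = np.array(
        [dose_at_depth(curve, c, component) for c in profile.bin_centers_mm]
    )
    return DoseVolumePairs(dose_gy=doses, volume_mm3=profile.volume_mm3.copy(),
                           structure=structure, component=component)


def build_dvh(pairs: DoseVolumePairs, grid_step_gy: float = 0.1) -> DVH:
    """Cumulative DVH of a structure from its dose-volume pairs.

    The dose grid is a regular grid of ``grid_step_gy`` extended to one
    step past the maximum dose, with the exact pair doses inserted so
    every step of the cumulative curve is placed exactly.
    """
    if pairs.total_volume_mm3 <= 0:
        raise ValueError("total structure volume must be positive")
    if grid_step_gy <= 0:
        raise ValueError("grid step must be positive")
    d_max = float(pairs.dose_gy.max())
    regular = np.arange(0.0, d_max + 2 * grid_step_gy, grid_step_gy)
    grid = np.unique(np.concatenate([regular, pairs.dose_gy]))
    # fraction receiving >= d for each grid dose
    order = np.argsort(pairs.dose_gy)
    d_sorted = pairs.dose_gy[order]
    v_sorted = pairs.volume_mm3[order]
    cum_from_above = np.concatenate([np.cumsum(v_sorted[::-1])[::-1], [0.0]])
    idx = np.searchsorted(d_sorted, grid, side="left")
    frac = cum_from_above[idx] / pairs.total_volume_mm3
    return DVH(structure=pairs.structure, dose_gy=grid, cum_volume_fraction=frac,
               total_volume_mm3=pairs.total_volume_mm3)


def _d90(pairs: DoseVolumePairs, coverage: float = 0.9) -> float:
    """Dose received by at least ``coverage`` of the volume.

    Linear interpolation between the step corner points (d_k, F(d_k)) of
    the cumulative curve, where F(d_k) is the fraction receiving >= d_k;
    ties broken toward the lower dose (conservative coverage).
    """
    d = np.unique(pairs.dose_gy)
    total = pairs.total_volume_mm3
    frac = np.array([pairs.volume_mm3[pairs.dose_gy >= dk].sum() / total for dk in d])
    if frac[-1] >= coverage:  # even the hottest step covers >= 90%
        return float(d[-1])
    # first step k with F(d_k) < coverage; interpolate from the previous corner
    k = int(np.argmax(frac < coverage))
    if k == 0:
        return float(d[0])
    d0, f0, d1, f1 = d[k - 1], frac[k - 1], d[k], frac[k]
    return float(d0 + (f0 - coverage) / (f0 - f1) * (d1 - d0))


def eud(pairs: DoseVolumePairs, config: EUDConfig) -> float:
    """Equivalent uniform dose of a non-uniform dose distribution.

    The uniform dose giving the same overall clonogenic survival, under
    exponential cell kill pinned at (D_ref, SF_ref). Uniform
    distributions return their own dose identically; cold spots pull the
    EUD below the mean dose.
    """
    total = pairs.total_volume_mm3
    if total <= 0:
        raise ValueError("total volume must be positive")
    w = pairs.volume_mm3 / total
    log_sf = math.log(config.sf_ref)
    # sum_i w_i * SF_ref**(D_i/D_ref), evaluated in log space for stability
    surv = float(np.sum(w * np.exp(pairs.dose_gy / config.d_ref_gy * log_sf)))
    return config.d_ref_gy * math.log(surv) / log_sf


def coverage_metrics(
    dvh: DVH, prescription_gy: float, config: EUDConfig, pairs: DoseVolumePairs
) -> PlanMetrics:
    """Planning endpoints of one structure at a prescription dose."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    total = pairs.total_volume_mm3
    frac = float(pairs.volume_mm3[pairs.dose_gy >= prescription_gy].sum() / total)
    return PlanMetrics(
        v_prescription_pct=100.0 * frac,
        underdosed_volume_mm3=total * (1.0 - frac),
        d90_gy=_d90(pairs),
        eud_gy=eud(pairs, config),
        total_volume_mm3=total,
        prescription_gy=prescription_gy,
    )


def oar_metrics(
    valley_pairs: DoseVolumePairs,
    thresholds_gy: list[float],
    peak_pairs: DoseVolumePairs | None = None,
    f_peak: float = 0.125,
) -> pd.DataFrame:
    """Percent of an organ-at-risk volume at or above each dose threshold.

    Computed per dose component; when peak pairs are supplied a
    composite column weights the peak percentage by the beamlet area
    fraction ``f_peak`` (the valley occupying the rest), mirroring how a
    comb field tiles the organ.
    """
    rows = []
    total_v = valley_pairs.total_volume_mm3
    for t in thresholds_gy:
        row: dict[str, float] = {"threshold_gy": float(t)}
        row["valley_pct"] = 100.0 * float(
            valley_pairs.volume_mm3[valley_pairs.dose_gy >= t].sum() / total_v
        )
        if peak_pairs is not None:
            total_p = peak_pairs.total_volume_mm3
            row["peak_pct"] = 100.0 * float(
                peak_pairs.volume_mm3[peak_pairs.dose_gy >= t].sum() / total_p
            )
            row["composite_pct"] = (1 - f_peak) * row["valley_pct"] + f_peak * row["peak_pct"]
        rows.append(row)
    return pd.DataFrame(rows)
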