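"""File I/O: CSV tables with documented headers and NIfTI volumes.

Tabular formats
---------------
assay CSV        condition,dose_gy,seeded,colonies   (one row per dish)
depth-dose CSV   depth_mm,peak_gy,valley_gy
profile CSV      depth_lo_mm,depth_hi_mm,volume_mm3
DVH CSV          dose_gy,cum_volume_fraction
cohort CSV       id,group,days,event                 (event 1 = death, 0 = censored)
curve CSV        day,fraction
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortSurvival
from .geometry import TumorVolumeProfile, VolumetricImage
from .microbeam import DepthDoseCurve
from .planning import DVH
from .radiobiology import AssayRecord

__all__ = [
    "read_assay_csv",
    "write_assay_csv",
    "assay_records_from_frame",
    "read_depth_dose_csv",
    "write_depth_dose_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_dvh_csv",
    "read_cohort_csv",
    "write_nifti",
    "read_nifti",
]

FLOAT_FMT = "%.9g"  # fixed text formatting keeps reruns byte-identical


def _require(df: pd.DataFrame, cols: list[str], path: Path | str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_assay_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: assay file is empty")
    _require(df, ["condition", "dose_gy", "seeded", "colonies"], path)
    return df


def write_assay_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def assay_records_from_frame(df: pd.DataFrame) -> list[AssayRecord]:
    """Collapse per-dish rows into one AssayRecord per (condition, dose)."""
    records = []
    for (condition, dose), sub in df.groupby(["condition", "dose_gy"], sort=True):
        seeded = sub["seeded"].unique()
        if len(seeded) != 1:
            raise ValueError(
                f"{condition} at {dose} Gy mixes seeding numbers {seeded.tolist()}"
            )
        records.append(
            AssayRecord(
                condition=str(condition),
                dose_gy=float(dose),
                seeded=int(seeded[0]),
                colonies=tuple(sub["colonies"].astype(float)),
            )
        )
    return records


def read_depth_dose_csv(path: str | Path) -> DepthDoseCurve:
    df = pd.read_csv(path)
    _require(df, ["depth_mm", "peak_gy", "valley_gy"], path)
    df = df.sort_values("depth_mm")
    return DepthDoseCurve(
        depth_mm=df["depth_mm"].to_numpy(float),
        peak_gy=df["peak_gy"].to_numpy(float),
        valley_gy=df["valley_gy"].to_numpy(float),
    )


def write_depth_dose_csv(curve: DepthDoseCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"depth_mm": curve.depth_mm, "peak_gy": curve.peak_gy,
         "valley_gy": curve.valley_gy}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_profile_csv(profile: TumorVolumeProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"depth_lo_mm": profile.bin_edges_mm[:-1],
         "depth_hi_mm": profile.bin_edges_mm[1:],
         "volume_mm3": profile.volume_mm3}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_profile_csv(path: str | Path) -> TumorVolumeProfile:
    df = pd.read_csv(path)
    _require(df, ["depth_lo_mm", "depth_hi_mm", "volume_mm3"], path)
    edges = np.append(df["depth_lo_mm"].to_numpy(float),
                      df["depth_hi_mm"].to_numpy(float)[-1])
    return TumorVolumeProfile(bin_edges_mm=edges,
                              volume_mm3=df["volume_mm3"].to_numpy(float))


def write_dvh_csv(dvh: DVH, path: str | Path) -> None:
    pd.DataFrame(
        {"dose_gy": dvh.dose_gy, "cum_volume_fraction": dvh.cum_volume_fraction}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort_csv(path: str | Path) -> CohortSurvival:
    df = pd.read_csv(path)
    return CohortSurvival(table=df)


def write_nifti(image: VolumetricImage, path: str | Path,
                mask: np.ndarray | None = None, mask_path: str | Path | None = None) -> None:
    """Write a volume (and optionally its mask) as NIfTI with spacing metadata."""
    affine = np.diag([*image.spacing_mm, 1.0])
    affine[:3, 3] = image.origin_mm
    nib.save(nib.Nifti1Image(np.asarray(image.data, dtype=np.float32), affine), str(path))
    if mask is not None:
        if mask_path is None:
            raise ValueError("mask_path is required when writing a mask")
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(mask_path))


def read_nifti(path: str | Path, beam_axis: int = 2) -> VolumetricImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumetricImage(data=data, spacing_mm=spacing, origin_mm=origin,
                           beam_axis=beam_axis)
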