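"""End-to-end retrospective-planning and in-vitro report orchestration.

One declarative YAML config drives the whole analysis: per-subject
volumetric input (a NIfTI path or an inline phantom spec), segmentation
parameters, the depth-dose anchors, the prescription and EUD reference,
and the master seed. Outputs are plain CSV/JSON plus a run manifest
with the config hash and output checksums, so a rerun under the same
config and seed is byte-identical and provably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSurvival, ils, summarize
from .geometry import VolumetricImage, mask_volume, segment_threshold, volume_vs_depth
from .io import (
    assay_records_from_frame,
    read_assay_csv,
    read_nifti,
    write_dvh_csv,
    write_profile_csv,
)
from .microbeam import DepthDoseCurve
from .planning import EUDConfig, assign_doses, build_dvh, coverage_metrics
from .radiobiology import fit_lq, mixture_survival, rer, surviving_fraction
from .reference_params import MIXTURE_FIELD, default_sf_ref
from .synthetic import PhantomSpec, generate_depth_dose, generate_phantom

__all__ = ["RunConfig", "run_retrospective_plan", "run_invitro_report",
           "run_cohort_report"]

log = logging.getLogger("mrtplan")


@dataclass
class RunConfig:
    """Declarative configuration of a retrospective-planning run."""

    subjects: list[dict[str, Any]]
    depth_dose_anchors: list[tuple[float, float, float]]
    threshold: float
    keep_largest: bool = True
    skin_offset_mm: float = 0.0
    bin_width_mm: float | None = None
    prescription_gy: float = 15.0
    d_ref_gy: float = 8.0
    sf_ref: float | None = None  # None -> mixture-model default at d_ref
    dvh_step_gy: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if not self.subjects:
            raise ValueError("at least one subject is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["depth_dose_anchors"] = [tuple(a) for a in raw["depth_dose_anchors"]]
        return cls(**raw)

    def eud_config(self) -> EUDConfig:
        sf = self.sf_ref if self.sf_ref is not None else default_sf_ref(self.d_ref_gy)
        return EUDConfig(d_ref_gy=self.d_ref_gy, sf_ref=sf)

    def canonical_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_subject_image(subject: dict[str, Any], seed: int) -> VolumetricImage:
    if "image" in subject:
        return read_nifti(subject["image"], beam_axis=subject.get("beam_axis", 2))
    if "phantom" in subject:
        spec = PhantomSpec(**{**subject["phantom"], "seed": seed})
        image, _ = generate_phantom(spec)
        return image
    raise ValueError(f"subject {subject.get('id')!r} has neither 'image' nor 'phantom'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_retrospective_plan(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Segment, profile, assign doses, build DVHs and score every subject.

    Writes per-subject profile and DVH CSVs, a metrics table shaped like
    a per-subject plan summary (total volume, V at prescription,
    under-dosed volume, D90, EUD), and a JSON manifest. In batch mode a
    failing subject is recorded and skipped so one corrupt input cannot
    abort the cohort. Returns the metrics table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve: DepthDoseCurve = generate_depth_dose(config.depth_dose_anchors)
    eud_cfg = config.eud_config()

    rows: list[dict[str, Any]] = []
    failures: list[dict[str, str]] = []
    written: list[Path] = []
    for i, subject in enumerate(config.subjects):
        sid = str(subject.get("id", f"subject{i}"))
        stage = "load_image"
        try:
            image = _load_subject_image(subject, seed=config.seed + i)
            stage = "segment"
            seg = segment_threshold(image, config.threshold, config.keep_largest)
            stage = "volume_vs_depth"
            profile = volume_vs_depth(
                seg, image,
                skin_depth_offset_mm=subject.get("skin_offset_mm", config.skin_offset_mm),
                bin_width_mm=config.bin_width_mm,
            )
            stage = "assign_doses"
            pairs = assign_doses(profile, curve, component="valley", structure=sid)
            stage = "build_dvh"
            dvh = build_dvh(pairs, grid_step_gy=config.dvh_step_gy)
            stage = "coverage_metrics"
            metrics = coverage_metrics(dvh, config.prescription_gy, eud_cfg, pairs)
        except Exception as exc:
            log.error("subject %s failed at stage %s: %s", sid, stage, exc)
            failures.append({"id": sid, "stage": stage, "error": str(exc)})
            continue

        p_path = out / f"{sid}_profile.csv"
        d_path = out / f"{sid}_dvh.csv"
        write_profile_csv(profile, p_path)
        write_dvh_csv(dvh, d_path)
        written += [p_path, d_path]
        log.info("subject %s: mask %.4g mm^3 across %d depth bins",
                 sid, mask_volume(seg, image.spacing_mm), len(profile.volume_mm3))
        rows.append({"id": sid, **metrics.rounded()})

    table = pd.DataFrame(rows)
    metrics_path = out / "plan_metrics.csv"
    table.to_csv(metrics_path, index=False, float_format="%.9g")
    written.append(metrics_path)

    manifest = {
        "tool": f"mrtplan {__version__}",
        "config_sha256": config.canonical_hash(),
        "seed": config.seed,
        "sf_ref": eud_cfg.sf_ref,
        "failures": failures,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return table


def run_invitro_report(
    assay_paths: list[str | Path],
    reference_condition: str | None = None,
    valley_doses_gy: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit LQ parameters per condition and report RER10 and mixture survival.

    Reads assay CSVs (one row per dish), reduces each condition to
    survival points against its own dose-0 control, fits alpha/beta, and
    computes RER10 against ``reference_condition`` when given. A fit
    failure is reported in the table and the run continues. Also
    evaluates the two-population microbeam survival over a valley-dose
    grid using each condition's fit.
    """
    frames = [read_assay_csv(p) for p in assay_paths]
    records = assay_records_from_frame(pd.concat(frames, ignore_index=True))

    by_condition: dict[str, list] = {}
    for r in records:
        by_condition.setdefault(r.condition, []).append(r)

    fits: dict[str, Any] = {}
    rows = []
    for condition, recs in sorted(by_condition.items()):
        recs = sorted(recs, key=lambda r: r.dose_gy)
        row: dict[str, Any] = {"condition": condition}
        try:
            control = next(r for r in recs if r.dose_gy == 0)
            points = []
            for r in recs:
                if r.dose_gy == 0:
                    continue
                try:
                    points.append(surviving_fraction(r, control))
                except ValueError:
                    # all dishes empty at this dose: unscorable level, skip it
                    log.warning("condition %s: no colonies at %.3g Gy, "
                                "dose level skipped", condition, r.dose_gy)
            params = fit_lq(points, condition=condition)
            fits[condition] = params
            row.update(alpha=params.alpha, alpha_se=params.alpha_se,
                       beta=params.beta, beta_se=params.beta_se, error="")
        except (StopIteration, ValueError) as exc:
            msg = "no dose-0 control" if isinstance(exc, StopIteration) else str(exc)
            log.error("condition %s failed to fit: %s", condition, msg)
            row.update(alpha=np.nan, alpha_se=np.nan, beta=np.nan, beta_se=np.nan,
                       error=msg)
        rows.append(row)
    report = pd.DataFrame(rows)

    if reference_condition is not None:
        if reference_condition not in fits:
            raise ValueError(f"reference condition {reference_condition!r} has no fit")
        ref = fits[reference_condition]
        report["rer10"] = [
            rer(ref, fits[c]) if c in fits else np.nan for c in report["condition"]
        ]

    if valley_doses_gy is None:
        valley_doses_gy = np.arange(0.0, 8.5, 0.5)
    mix_rows = []
    for condition, params in fits.items():
        for d in valley_doses_gy:
            mix_rows.append(
                {"condition": condition, "valley_dose_gy": float(d),
                 "sf_mixture": mixture_survival(params, MIXTURE_FIELD, float(d))}
            )
    mixture = pd.DataFrame(mix_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "lq_fits.csv", index=False, float_format="%.9g")
        mixture.to_csv(out / "mixture_survival.csv", index=False, float_format="%.9g")
    return {"fits": report, "mixture": mixture}


def run_cohort_report(cohort: CohortSurvival, reference_group: str = "control",
                      out_dir: str | Path | None = None) -> pd.DataFrame:
    """Summarise every group (MST/MeST) and ILS against a reference group."""
    groups = sorted(cohort.table["group"].unique())
    summaries = {g: summarize(cohort, g) for g in groups}
    rows = []
    for g, s in summaries.items():
        row = dict(s.rounded())
        row["mst_days_raw"] = s.mst_days
        row["mest_days_raw"] = s.mest_days
        if g != reference_group and reference_group in summaries:
            row.update(ils(s, summaries[reference_group]))
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_summary.csv", index=False, float_format="%.9g")
    return table
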