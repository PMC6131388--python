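"""Subject- and cohort-level orchestration of the arch/trough analysis.

``run_subject`` drives one volume through normalization, Frankfort
reorientation, confound removal, cumulative binarization and axial arch
projection.  ``run_cohort`` superimposes the per-subject arches, derives
the average arch shape, and fits the focal trough with its thickness
profile and arch-to-ramus transition.  Every stage output is content-hashed
into a manifest so a rerun with identical inputs and configuration can be
verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arch_model import (
    ArchImage,
    AverageArch,
    arch_centerline,
    area_matched_threshold,
    build_arch_image,
    superimpose_arches,
)
from .config import PipelineConfig
from .focal_trough import (
    ThicknessProfile,
    TransitionResult,
    TroughModel,
    fit_trough,
    locate_transition,
    thickness_profile,
)
from .io_formats import (
    AnalysisReport,
    BinaryVolume3D,
    LandmarkSet,
    Volume3D,
    load_landmarks,
    load_volume,
    save_report,
)
from .preprocess import (
    frankfort_point_map,
    normalize_intensity,
    remove_cervical_vertebrae,
    remove_condyle_caps,
    remove_superior_halfplane,
    reorient_to_frankfort,
)
from .segmentation import cumulative_binarize

__all__ = ["RunManifest", "SubjectResult", "CohortResult", "run_subject", "run_cohort"]

log = logging.getLogger(__name__)


def _hash_array(arr: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Audit record of a run: config snapshot, stage hashes, warnings."""

    config: dict
    subjects: list[dict] = field(default_factory=list)
    cohort: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "subjects": self.subjects,
                       "cohort": self.cohort}, fh, indent=2)


@dataclass
class SubjectResult:
    arch: ArchImage
    mandible: BinaryVolume3D
    stop_z: float
    occlusal_z: float
    stage_hashes: dict[str, str]
    warnings: list[str]


@dataclass
class CohortResult:
    average: AverageArch
    model: TroughModel
    profile: ThicknessProfile
    transition: TransitionResult
    report: AnalysisReport


def run_subject(
    volume: Volume3D | str | Path,
    landmarks: LandmarkSet | str | Path,
    cfg: PipelineConfig | None = None,
    subject_id: str = "subject",
) -> SubjectResult:
    """Run one subject from raw volume to its binary axial arch image.

    Stage order: normalize -> reorient to Frankfort -> remove midface
    (coronal line) -> remove anterior face (sagittal occlusal line) ->
    remove cervical vertebrae -> remove condyle caps -> cumulative
    binarization up to the condyle stop plane -> axial arch projection.
    """
    cfg = cfg or PipelineConfig()
    try:
        if not isinstance(volume, Volume3D):
            volume = load_volume(volume)
        if not isinstance(landmarks, LandmarkSet):
            landmarks = load_landmarks(landmarks, volume=volume)
        hashes: dict[str, str] = {"input": _hash_array(np.asarray(volume.data))}
        caught: list[warnings.WarningMessage] = []

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            vol = normalize_intensity(volume)
            hashes["normalized"] = _hash_array(vol.data)

            vol = reorient_to_frankfort(
                vol, landmarks["frankfort_orbit"], landmarks["frankfort_meatus"]
            )
            landmarks = landmarks.transformed(
                frankfort_point_map(
                    landmarks["frankfort_orbit"], landmarks["frankfort_meatus"]
                )
            )
            hashes["reoriented"] = _hash_array(vol.data)

            vol = remove_superior_halfplane(
                vol, "Y", landmarks["coronal_right"], landmarks["coronal_left"]
            )
            vol = remove_superior_halfplane(
                vol, "X", landmarks["occlusal_anterior"], landmarks["occlusal_posterior"]
            )
            occlusal_z = float(
                0.5 * (landmarks["occlusal_anterior"][2] + landmarks["occlusal_posterior"][2])
            )
            vol = remove_cervical_vertebrae(vol, occlusal_z, cfg)
            vol, stop_z = remove_condyle_caps(
                vol, landmarks["condyle_a"], landmarks["condyle_b"], cfg
            )
            hashes["preprocessed"] = _hash_array(vol.data)

            z_lo = vol.origin[2]
            mandible = cumulative_binarize(vol, z_lo, stop_z, cfg)
            hashes["mandible"] = _hash_array(mandible.data)

            arch = build_arch_image(
                mandible,
                dental_band=(occlusal_z - cfg.tooth_length_mm, occlusal_z),
                ramus_band=(occlusal_z, stop_z),
                canines=np.vstack([landmarks["canine_right"], landmarks["canine_left"]]),
            )
            hashes["arch"] = _hash_array(arch.mask)
    except Exception as exc:
        raise type(exc)(f"[{subject_id}] {exc}") from exc
    return SubjectResult(
        arch=arch,
        mandible=mandible,
        stop_z=stop_z,
        occlusal_z=occlusal_z,
        stage_hashes=hashes,
        warnings=[str(w.message) for w in caught],
    )


def run_cohort(
    arches: list[ArchImage],
    cfg: PipelineConfig | None = None,
    report_path: str | Path | None = None,
) -> CohortResult:
    """Average the cohort's arches and analyze the resulting focal trough."""
    cfg = cfg or PipelineConfig()
    if not arches:
        raise ValueError("cohort must contain at least one arch image")
    avg = superimpose_arches(arches)
    areas = [a.area_mm2 for a in arches]
    t_star, _ = area_matched_threshold(avg, areas, cfg)
    avg_arch = avg.as_arch_image()
    centerline = arch_centerline(avg_arch)
    if avg.canines is None:
        raise ValueError("arch images lack canine points; cannot anchor the trough")
    model = fit_trough(avg_arch, centerline, avg.canines, cfg)
    profile = thickness_profile(model, cfg)
    transition = locate_transition(model, cfg)
    report = AnalysisReport(
        threshold=t_star,
        mean_individual_area_mm2=float(np.mean(areas)),
        average_arch_area_mm2=float(avg.average_area_mm2),
        anterior_min_thickness_mm=float(profile.anterior_min),
        posterior_min_thickness_mm=float(profile.posterior_min),
        transition_lateral_mm=transition.lateral_mm,
        transition_posterior_mm=transition.posterior_mm,
        transition_slope_deg=transition.slope_deg,
        splines=model.spline_records(),
        metadata={
            "n_subjects": avg.n_subjects,
            "spline_smoothing": cfg.spline_smoothing,
            "transition_smoothing": cfg.transition_smoothing,
            "spline_parameter": "arc length (mm) along the symmetrized curve",
        },
    )
    if report_path is not None:
        save_report(report, report_path)
    return CohortResult(avg, model, profile, transition, report)
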