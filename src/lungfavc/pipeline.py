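"""End-to-end orchestration: subject analysis and cohort aggregation.

``run_subject`` composes the measurement chain for one scan —
segmentation from seeds, FAVC map, partial-volume-corrected volumes,
10-shell decomposition with c/p ratio, and orthogonal profiles — and
``run_cohort`` aggregates subjects: template selection (the visit-1
subject whose total lung volume is closest to the cohort mean), radial
registration of every subject to the template, mean-image formation with
edge correction, and the summary statistics table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import summarize_cohort
from .favc import DEFAULT_RHO_T, FAVCMap, LungVolumeResult, favc_from_intensity, lung_volumes
from .image_model import (
    BinaryRegion,
    CalibrationPair,
    GridError,
    Landmarks,
    VoxelGrid,
    resample_to_cubic,
)
from .radial import ShellProfile, cp_ratio, radial_register, shell_decomposition, transform_center
from .regional import MeanVolumeImage, axis_profile, edge_correction, mean_image
from .segmentation import DEFAULT_DENSITY_THRESHOLD, SegmentationResult, segment_lungs

__all__ = ["AnalysisParams", "SubjectResult", "CohortResult", "run_subject", "run_cohort"]

logger = logging.getLogger("lungfavc")

LUNG_SIDES = (("right", -1), ("left", +1))
PROFILE_AXES = ("lateral-medial", "anterior-posterior", "superior-inferior")


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the measurement chain."""

    calibration: CalibrationPair = field(default_factory=CalibrationPair)
    rho_t: float = DEFAULT_RHO_T
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD
    refine_threshold: bool = True
    n_shells: int = 10
    cubic_edge_mm: float | None = None  # None: resample only if anisotropic


@dataclass
class SubjectResult:
    """Full measurement bundle for one scan."""

    segmentation: SegmentationResult
    favc_map: FAVCMap
    volumes: dict[str, LungVolumeResult]
    shells: dict[str, ShellProfile]
    cp: dict[str, float]
    profiles: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]

    @property
    def total_air_ml(self) -> float:
        return sum(v.air_volume_ml for v in self.volumes.values())

    def envelope(self, side: str) -> BinaryRegion:
        return (self.segmentation.right_envelope if side == "right"
                else self.segmentation.left_envelope)

    def manifest(self) -> dict:
        """Parameter echo plus content checksums for reproducibility."""
        def digest(a: np.ndarray) -> str:
            return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]

        return {
            "density_threshold": self.segmentation.density_threshold,
            "checksums": {
                "favc_map": digest(self.favc_map.values),
                "right_envelope": digest(self.segmentation.right_envelope.mask),
                "left_envelope": digest(self.segmentation.left_envelope.mask),
            },
            "volumes": {
                side: {
                    "space_ml": v.space_volume_ml,
                    "air_ml": v.air_volume_ml,
                    "mean_favc": v.mean_favc,
                }
                for side, v in self.volumes.items()
            },
            "cp": dict(self.cp),
        }


def run_subject(
    grid: VoxelGrid,
    landmarks: Landmarks,
    params: AnalysisParams = AnalysisParams(),
) -> SubjectResult:
    """Run the full single-scan measurement chain.

    Deterministic: identical inputs produce identical outputs.
    """
    if params.cubic_edge_mm is not None:
        grid = resample_to_cubic(grid, params.cubic_edge_mm,
                                 fill_value=params.calibration.i_air)
    elif not grid.is_isotropic:
        grid = resample_to_cubic(grid, float(min(grid.spacing)),
                                 fill_value=params.calibration.i_air)

    logger.info("segmenting (threshold=%.3f)", params.density_threshold)
    seg = segment_lungs(
        grid, params.calibration, landmarks,
        density_threshold=params.density_threshold,
        refine_threshold=params.refine_threshold,
    )
    favc = favc_from_intensity(grid, params.calibration, params.rho_t)

    volumes: dict[str, LungVolumeResult] = {}
    shells: dict[str, ShellProfile] = {}
    cp: dict[str, float] = {}
    profiles: dict[tuple[str, str], tuple] = {}
    for side, lat in LUNG_SIDES:
        env = seg.right_envelope if side == "right" else seg.left_envelope
        hilum = (landmarks.hilum_right if side == "right"
                 else landmarks.hilum_left)
        volumes[side] = lung_volumes(favc, env)
        shells[side] = shell_decomposition(favc, env, hilum, params.n_shells)
        cp[side] = cp_ratio(shells[side])
        for axis in PROFILE_AXES:
            profiles[(side, axis)] = axis_profile(favc, env, axis, lat)
        logger.info(
            "%s lung: space %.0f ml, air %.0f ml, FAVC %.3f, c/p %.3f",
            side, volumes[side].space_volume_ml,
            volumes[side].air_volume_ml, volumes[side].mean_favc, cp[side],
        )
    return SubjectResult(seg, favc, volumes, shells, cp, profiles)


@dataclass
class CohortResult:
    """Cohort aggregation: per-subject table, template, mean image."""

    table: pd.DataFrame
    summary: pd.DataFrame
    template_id: str
    mean_images: dict[str, MeanVolumeImage]
    subject_results: dict[tuple[str, int], SubjectResult]
    registration_flags: dict[str, int]


def _choose_template(totals: dict[str, float]) -> str:
    """Subject with total lung volume closest to the cohort mean; ties
    broken by lexicographic subject id."""
    mean_total = float(np.mean(list(totals.values())))
    return min(totals, key=lambda s: (abs(totals[s] - mean_total), s))


def run_cohort(
    subjects: list[tuple[str, int, VoxelGrid, Landmarks]],
    params: AnalysisParams = AnalysisParams(),
    template_id: str | None = None,
) -> CohortResult:
    """Analyse a cohort of (subject id, visit, volume, landmarks) scans.

    Every scan is measured with :func:`run_subject`; the visit-1 maps are
    registered to the template subject's lung shapes, averaged into a
    mean FAVC image per lung, and edge-corrected.  Summary statistics
    (mean, SD, COV, repeatability COV where a second visit exists) are
    computed per lung and parameter.
    """
    if not subjects:
        raise GridError("empty cohort")
    keys = [(s, v) for s, v, _, _ in subjects]
    if len(set(keys)) != len(keys):
        raise GridError("duplicate (subject, visit) in cohort")

    results: dict[tuple[str, int], SubjectResult] = {}
    rows = []
    landmarks_by_key: dict[tuple[str, int], Landmarks] = {}
    for sid, visit, grid, lm in subjects:
        logger.info("subject %s visit %d", sid, visit)
        res = run_subject(grid, lm, params)
        results[(sid, visit)] = res
        landmarks_by_key[(sid, visit)] = lm
        for side, _ in LUNG_SIDES:
            v = res.volumes[side]
            rows.append({
                "subject": sid, "visit": visit, "lung": side,
                "space_ml": v.space_volume_ml, "air_ml": v.air_volume_ml,
                "favc": v.mean_favc, "cp": res.cp[side],
            })
    table = pd.DataFrame(rows)

    visit1 = {s: r for (s, v), r in results.items() if v == 1}
    if not visit1:
        raise GridError("cohort has no visit-1 scans; cannot choose template")
    if template_id is None:
        template_id = _choose_template(
            {s: r.total_air_ml for s, r in visit1.items()}
        )
    elif template_id not in visit1:
        raise GridError(f"template subject {template_id!r} has no visit-1 scan")
    logger.info("template subject: %s", template_id)
    tpl = visit1[template_id]
    tpl_lm = landmarks_by_key[(template_id, 1)]

    mean_images: dict[str, MeanVolumeImage] = {}
    flags_total: dict[str, int] = {}
    for side, lat in LUNG_SIDES:
        tpl_env = tpl.envelope(side)
        tpl_hilum = (tpl_lm.hilum_right if side == "right" else tpl_lm.hilum_left)
        tpl_center = transform_center(tpl_env, tpl_hilum, lat)
        registered = []
        n_flagged = 0
        for sid, res in visit1.items():
            env = res.envelope(side)
            lm = landmarks_by_key[(sid, 1)]
            hilum = lm.hilum_right if side == "right" else lm.hilum_left
            center = transform_center(env, hilum, lat)
            reg, flags = radial_register(res.favc_map, env, center, tpl_env, tpl_center)
            registered.append(reg)
            n_flagged += int(flags.sum())
        img = mean_image(registered)
        mean_images[side] = edge_correction(img, tpl_env)
        flags_total[side] = n_flagged

    summary = summarize_cohort(table)
    return CohortResult(table, summary, template_id, mean_images, results, flags_total)
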