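"""Semi-automatic lung and airway segmentation from manual seed points.

The lung envelopes are delineated with a threshold-based technique: voxels
whose density (from the air/tissue calibration) falls below a threshold are
candidate air voxels.  The trachea and main bronchi are extracted first by
region growing from a manually placed trachea seed; each lung is then grown
from its hilum seed through the remaining candidates, and morphologically
closed so that interior high-density structures (the hilar vessels) are
included in the envelope, as they belong to the lung's space volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .favc import DEFAULT_RHO_T
from .image_model import (
    BinaryRegion,
    CalibrationPair,
    GridError,
    Landmarks,
    VoxelGrid,
    structuring_element,
)

__all__ = [
    "DEFAULT_DENSITY_THRESHOLD",
    "SegmentationError",
    "SegmentationResult",
    "segment_lungs",
    "hilum_from_bifurcation",
]

#: Default density threshold separating air-dominated from tissue voxels.
#: 0.5 is midway between pure air (0) and pure tissue (1); in FAVC terms it
#: admits voxels with more than ~52% air content (FAVC > 1 - 0.5/1.05).
DEFAULT_DENSITY_THRESHOLD = 0.5


class SegmentationError(GridError):
    """Seed placement, threshold or topology failure during segmentation."""


@dataclass
class SegmentationResult:
    """Right/left lung envelopes plus the trachea/main-bronchus region.

    The three regions are pairwise disjoint; each envelope is
    26-connected and includes interior vessels after closing.
    """

    right_envelope: BinaryRegion
    left_envelope: BinaryRegion
    trachea_region: BinaryRegion
    density_threshold: float


def _grow_from_seed(candidates: np.ndarray, seed: tuple[int, int, int],
                    struct: np.ndarray) -> np.ndarray:
    labels, _ = ndimage.label(candidates, structure=struct)
    return labels == labels[tuple(seed)]


def segment_lungs(
    grid: VoxelGrid,
    calib: CalibrationPair,
    landmarks: Landmarks,
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD,
    connectivity: int = 26,
    closing_iterations: int = 2,
    refine_threshold: bool = True,
    rho_t: float = DEFAULT_RHO_T,
) -> SegmentationResult:
    """Segment both lung envelopes and the trachea region from seeds.

    Candidate air voxels have density ``(I - I_air)/(I_tissue - I_air)``
    below ``density_threshold``.  The trachea region is grown from the
    trachea seed within the slices at or above (superior to) the more
    superior hilum; below that the air belongs to the lungs.  Each lung is
    grown from its hilum seed through the remaining candidates and closed
    with the 3x3x3 element (``closing_iterations`` times) to take interior
    vessels into the envelope.

    With ``refine_threshold`` (the default), a second pass re-thresholds
    at the midpoint between the measured core parenchyma density (mean
    over the twice-eroded first-pass envelopes) and the tissue density
    ``rho_t``.  Under symmetric blur this midpoint threshold places the
    envelope boundary at the true parenchyma/chest-wall interface; a
    fixed threshold placed well below the interface midpoint
    systematically strips the outer voxel layer.

    Raises
    ------
    SegmentationError
        If a seed voxel is not below the density threshold (mis-placed
        landmark or mis-set threshold), or if the right and left growths
        merge into a single component after trachea removal (threshold
        leakage), reporting the approximate merge location.
    """
    landmarks.validate_inside(grid.dims)
    density = (grid.values - calib.i_air) / (calib.i_tissue - calib.i_air)

    if refine_threshold:
        first = segment_lungs(
            grid, calib, landmarks, density_threshold, connectivity,
            closing_iterations, refine_threshold=False,
        )
        struct = structuring_element(connectivity)
        core = ndimage.binary_erosion(
            first.right_envelope.mask | first.left_envelope.mask,
            structure=struct, iterations=2, border_value=0,
        )
        if core.any():
            refined = 0.5 * (float(density[core].mean()) + rho_t)
            # only move the threshold toward the interface midpoint
            if refined > density_threshold:
                density_threshold = refined

    candidates = density < density_threshold

    for name, seed in (
        ("trachea_seed", landmarks.trachea_seed),
        ("hilum_right", landmarks.hilum_right),
        ("hilum_left", landmarks.hilum_left),
    ):
        if not candidates[tuple(seed)]:
            raise SegmentationError(
                f"seed {name}={tuple(seed)} has density "
                f"{density[tuple(seed)]:.3f} >= threshold {density_threshold}"
            )

    struct = structuring_element(connectivity)

    # trachea/main bronchi: grown superior to (and including) the slice of
    # the more superior hilum; z increases superior -> inferior
    z_stop = min(landmarks.hilum_right[2], landmarks.hilum_left[2])
    upper = candidates.copy()
    upper[:, :, z_stop + 1:] = False
    trachea = _grow_from_seed(upper, landmarks.trachea_seed, struct)

    remaining = candidates & ~trachea
    labels, _ = ndimage.label(remaining, structure=struct)
    lab_r = labels[tuple(landmarks.hilum_right)]
    lab_l = labels[tuple(landmarks.hilum_left)]
    if lab_r == 0 or lab_l == 0:
        raise SegmentationError("a hilum seed fell inside the trachea region")
    if lab_r == lab_l:
        comp = labels == lab_r
        mid = (np.asarray(landmarks.hilum_right) + np.asarray(landmarks.hilum_left)) / 2
        pts = np.argwhere(comp)
        near = pts[np.argmin(((pts - mid) ** 2).sum(axis=1))]
        raise SegmentationError(
            "right and left lung growths merged into one component "
            f"(leakage near voxel {tuple(int(v) for v in near)}); "
            "lower the density threshold or check landmarks"
        )
    right = labels == lab_r
    left = labels == lab_l

    if closing_iterations > 0:
        right = ndimage.binary_closing(right, structure=struct,
                                       iterations=closing_iterations)
        left = ndimage.binary_closing(left, structure=struct,
                                      iterations=closing_iterations)
    # enforce pairwise disjointness (closing can in principle spill)
    right &= ~trachea
    left &= ~trachea
    overlap = right & left
    if overlap.any():
        right &= ~overlap
        left &= ~overlap

    spacing = grid.spacing
    return SegmentationResult(
        right_envelope=BinaryRegion(right, spacing),
        left_envelope=BinaryRegion(left, spacing),
        trachea_region=BinaryRegion(trachea, spacing),
        density_threshold=density_threshold,
    )


def hilum_from_bifurcation(trachea_region: BinaryRegion) -> tuple[
    tuple[float, float, float], tuple[float, float, float]
]:
    """Locate the hila as the first bifurcation of the main bronchus.

    Scans axial slices in the inferior direction (increasing z) and
    returns the two branch centroids ``(right, left)`` — ordered by
    ascending x, i.e. subject-right first — in the first slice where the
    airway cross-section splits into exactly two 2D-connected components
    after having been a single component more superiorly.
    """
    mask = trachea_region.mask
    struct2d = np.ones((3, 3), dtype=bool)
    seen_single = False
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=struct2d)
        if n == 1:
            seen_single = True
        elif n == 2 and seen_single:
            cents = ndimage.center_of_mass(sl, labels, [1, 2])
            cents = sorted(cents, key=lambda c: c[0])
            return (
                (float(cents[0][0]), float(cents[0][1]), float(z)),
                (float(cents[1][0]), float(cents[1][1]), float(z)),
            )
    raise SegmentationError("no bifurcation found within the trachea region")
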