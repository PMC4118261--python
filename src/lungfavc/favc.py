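"""Density and fractional air volume concentration (FAVC) maps, lung volumes.

CT intensity is proportional to physical density for the soft tissues of
the thorax, so a voxel's density relative to water follows from a linear
rescaling between the pure-air and pure-tissue calibration intensities:

    rho_v = (I_vox - I_air) / (I_tissue - I_air)

The fraction of the voxel's space volume occupied by air is then

    FAVC = 1 - rho_v / rho_t

where ``rho_t`` is the mean density of lung tissue and blood, taken as
1.05 g/ml.  The air volume in a voxel is ``FAVC * v`` with ``v`` the voxel
volume, and the lung air volume is the sum over the lung envelope.

Partial volume correction: blurring at the lung boundary moves apparent
air content from boundary voxels to voxels just outside the envelope.
Because the intensity model is affine, the summed air volume is conserved
under this redistribution, so summing FAVC over the envelope dilated by
one voxel recovers the true air volume.  The space volume uses the
undilated envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import BinaryRegion, CalibrationPair, GridError, VoxelGrid, dilate

__all__ = [
    "DEFAULT_RHO_T",
    "DensityMap",
    "FAVCMap",
    "LungVolumeResult",
    "density_from_intensity",
    "favc_from_density",
    "favc_from_intensity",
    "lung_volumes",
]

#: Mean density of lung tissue and blood (g/ml relative to water).
DEFAULT_RHO_T = 1.05


@dataclass
class DensityMap:
    """Per-voxel density relative to water (dimensionless, ~g/ml).

    Values are not clamped: zero-mean image noise can produce values
    slightly below 0 or above 1; clamping would bias volume sums.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class FAVCMap:
    """Per-voxel fractional air volume concentration (unclamped)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    rho_t: float = DEFAULT_RHO_T

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def clamped(self) -> np.ndarray:
        """Copy of the values clipped to [0, 1] — for display only."""
        return np.clip(self.values, 0.0, 1.0)


@dataclass(frozen=True)
class LungVolumeResult:
    """Per-lung volume measurements in millilitres."""

    space_volume_ml: float
    air_volume_ml: float
    mean_favc: float


def density_from_intensity(grid: VoxelGrid, calib: CalibrationPair) -> DensityMap:
    """Linear intensity-to-density rescaling between the calibration points."""
    denom = calib.i_tissue - calib.i_air
    if denom == 0:
        raise GridError("degenerate calibration: i_air == i_tissue")
    rho = (grid.values - calib.i_air) / denom
    return DensityMap(rho, grid.spacing)


def favc_from_density(density: DensityMap, rho_t: float = DEFAULT_RHO_T) -> FAVCMap:
    if rho_t <= 0:
        raise GridError(f"rho_t must be positive, got {rho_t}")
    return FAVCMap(1.0 - density.values / rho_t, density.spacing, rho_t)


def favc_from_intensity(
    grid: VoxelGrid, calib: CalibrationPair, rho_t: float = DEFAULT_RHO_T
) -> FAVCMap:
    """Convenience composition of the two rescalings."""
    return favc_from_density(density_from_intensity(grid, calib), rho_t)


def lung_volumes(
    favc_map: FAVCMap,
    envelope: BinaryRegion,
    dilate_for_air: bool = True,
    connectivity: int = 26,
) -> LungVolumeResult:
    """Space and air volume of a lung envelope, in ml.

    The space volume is the voxel count of the (undilated) envelope times
    the voxel volume.  The air volume sums FAVC over the envelope dilated
    by one voxel, compensating the partial volume effect at the boundary;
    pass ``dilate_for_air=False`` for the uncorrected simple summation.
    The mean FAVC is their ratio.
    """
    if envelope.count == 0:
        raise GridError("empty lung envelope")
    if envelope.mask.shape != favc_map.values.shape or not np.allclose(
        envelope.spacing, favc_map.spacing
    ):
        raise GridError("envelope and FAVC map are on different grids")
    v_ml = favc_map.voxel_volume_ml
    space = envelope.count * v_ml
    summation_region = (
        dilate(envelope, 1, connectivity).mask if dilate_for_air else envelope.mask
    )
    air = float(favc_map.values[summation_region].sum()) * v_ml
    return LungVolumeResult(space, air, air / space)
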