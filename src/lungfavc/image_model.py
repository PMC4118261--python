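"""Voxel-grid data model, coordinate conventions, resampling and morphology.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``[x, y, z]`` with **x increasing toward subject-left**,
  **y increasing anterior -> posterior** and **z increasing superior ->
  inferior** (so z is the craniocaudal slice axis).
* Voxel indices are 0-based; the physical centre of voxel ``i`` on an axis
  with spacing ``s`` is at ``(i + 0.5) * s`` millimetres.
* Landmarks are given as 0-based voxel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "CalibrationPair",
    "BinaryRegion",
    "Landmarks",
    "structuring_element",
    "resample_to_cubic",
    "dilate",
    "erode",
    "boundary_layers",
    "read_nifti",
    "write_nifti",
    "read_mask",
    "write_mask",
]

#: Axis codes of the package-internal anatomical frame (nibabel convention):
#: first axis ends at subject Left, second at Posterior, third at Inferior.
INTERNAL_AXCODES = ("L", "P", "I")


class GridError(ValueError):
    """Invalid grid, region or landmark input."""


@dataclass
class VoxelGrid:
    """A 3D scalar intensity field with per-axis spacing (mm).

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)`` holding calibrated CT-like
        intensities.
    spacing
        Positive voxel edge lengths in mm, one per axis.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GridError(f"expected a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise GridError("grid must have at least one voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1


@dataclass(frozen=True)
class CalibrationPair:
    """Intensity calibration: pure-air and pure-soft-tissue values.

    In Hounsfield units these are about -1000 (air) and +55 (soft
    tissue/blood); any affine-equivalent calibration is accepted as long
    as ``i_air < i_tissue``.
    """

    i_air: float = -1000.0
    i_tissue: float = 55.0

    def __post_init__(self) -> None:
        if not self.i_air < self.i_tissue:
            raise GridError(
                f"calibration requires i_air < i_tissue, got {self.i_air} >= {self.i_tissue}"
            )


@dataclass
class BinaryRegion:
    """A boolean voxel mask tied to a grid geometry."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GridError("region mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GridError("region spacing must be positive")

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.count * float(np.prod(self.spacing)) / 1000.0

    def same_grid_as(self, other: "BinaryRegion | VoxelGrid") -> bool:
        shape = other.mask.shape if isinstance(other, BinaryRegion) else other.values.shape
        return self.mask.shape == shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class Landmarks:
    """Manually supplied seed points: trachea seed and the two hila.

    The hilum is the point of first bifurcation of the main bronchus,
    one per lung; all coordinates are 0-based voxel indices.
    """

    trachea_seed: tuple[int, int, int]
    hilum_right: tuple[int, int, int]
    hilum_left: tuple[int, int, int]

    def validate_inside(self, dims: tuple[int, int, int]) -> None:
        for name, c in (
            ("trachea_seed", self.trachea_seed),
            ("hilum_right", self.hilum_right),
            ("hilum_left", self.hilum_left),
        ):
            if len(c) != 3 or any(not (0 <= int(ci) < d) for ci, d in zip(c, dims)):
                raise GridError(f"landmark {name}={c} lies outside grid dims {dims}")


# ---------------------------------------------------------------------------
# Morphological primitives
# ---------------------------------------------------------------------------

def structuring_element(connectivity: int = 26) -> np.ndarray:
    """3x3x3 structuring element: full cube (26) or cross (6)."""
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise GridError(f"connectivity must be 6 or 26, got {connectivity}")


def dilate(region: BinaryRegion, radius_voxels: int = 1, connectivity: int = 26) -> BinaryRegion:
    """Dilate a region by ``radius_voxels`` applications of the 3x3x3 element."""
    if radius_voxels < 1:
        raise GridError(f"dilation radius must be >= 1, got {radius_voxels}")
    out = ndimage.binary_dilation(
        region.mask, structure=structuring_element(connectivity), iterations=radius_voxels
    )
    return BinaryRegion(out, region.spacing)


def erode(region: BinaryRegion, radius_voxels: int = 1, connectivity: int = 26) -> BinaryRegion:
    """Erode a region by ``radius_voxels`` applications of the 3x3x3 element."""
    if radius_voxels < 1:
        raise GridError(f"erosion radius must be >= 1, got {radius_voxels}")
    out = ndimage.binary_erosion(
        region.mask, structure=structuring_element(connectivity), iterations=radius_voxels,
        border_value=0,
    )
    return BinaryRegion(out, region.spacing)


def boundary_layers(
    region: BinaryRegion, n_layers: int, connectivity: int = 26
) -> list[BinaryRegion]:
    """Peel ``n_layers`` one-voxel-thick boundary layers off a region.

    Layer ``k`` (1-based) is the set difference between the region eroded
    ``k - 1`` times and the region eroded ``k`` times, so layer 1 is the
    outermost voxel shell.  The layers are pairwise disjoint and, together
    with the ``n_layers``-times-eroded core, exactly partition the region.
    """
    if n_layers < 1:
        raise GridError(f"n_layers must be >= 1, got {n_layers}")
    if region.count == 0:
        raise GridError("cannot peel layers off an empty region")
    struct = structuring_element(connectivity)
    layers: list[BinaryRegion] = []
    current = region.mask
    for _ in range(n_layers):
        eroded = ndimage.binary_erosion(current, structure=struct, border_value=0)
        layers.append(BinaryRegion(current & ~eroded, region.spacing))
        current = eroded
    return layers


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_cubic(
    grid: VoxelGrid, edge_mm: float, fill_value: float | None = None
) -> VoxelGrid:
    """Resample a grid to isotropic cubic voxels of edge ``edge_mm``.

    Intensities are interpolated trilinearly at the new voxel centres;
    the physical extent of the volume is preserved to within one output
    voxel.  Sample positions inside the physical extent but beyond the
    outermost input voxel centre are clamped to the edge value; positions
    beyond the physical extent (possible only in the final partial voxel)
    take ``fill_value`` (default: the edge-clamped value, so resampling a
    constant field returns the constant exactly).
    """
    if edge_mm <= 0:
        raise GridError(f"edge_mm must be positive, got {edge_mm}")
    if grid.values.size == 0:
        raise GridError("cannot resample an empty grid")
    extent = np.array(grid.dims) * np.array(grid.spacing)
    new_dims = np.maximum(1, np.rint(extent / edge_mm).astype(int))
    if tuple(grid.spacing) == (edge_mm,) * 3 and tuple(new_dims) == grid.dims:
        return VoxelGrid(grid.values.copy(), grid.spacing)

    # output voxel centres in mm -> fractional input indices
    axes_idx = [
        ((np.arange(n) + 0.5) * edge_mm) / s - 0.5
        for n, s in zip(new_dims, grid.spacing)
    ]
    coords = np.meshgrid(*axes_idx, indexing="ij")
    coords = np.stack(coords, axis=0)
    out = ndimage.map_coordinates(grid.values, coords, order=1, mode="nearest")
    if fill_value is not None:
        outside = np.zeros(out.shape, dtype=bool)
        for ax, (idx, n) in enumerate(zip(axes_idx, grid.dims)):
            bad = (idx < -0.5) | (idx > n - 0.5)
            if bad.any():
                shape = [1, 1, 1]
                shape[ax] = len(idx)
                outside |= bad.reshape(shape)
        out[outside] = fill_value
    return VoxelGrid(out, (edge_mm,) * 3)


def resample_mask_to_cubic(region: BinaryRegion, edge_mm: float) -> BinaryRegion:
    """Resample a mask to cubic voxels with nearest-neighbour interpolation."""
    if edge_mm <= 0:
        raise GridError(f"edge_mm must be positive, got {edge_mm}")
    extent = np.array(region.mask.shape) * np.array(region.spacing)
    new_dims = np.maximum(1, np.rint(extent / edge_mm).astype(int))
    axes_idx = [
        ((np.arange(n) + 0.5) * edge_mm) / s - 0.5
        for n, s in zip(new_dims, region.spacing)
    ]
    coords = np.stack(np.meshgrid(*axes_idx, indexing="ij"), axis=0)
    out = ndimage.map_coordinates(
        region.mask.astype(np.uint8), coords, order=0, mode="nearest"
    )
    return BinaryRegion(out.astype(bool), (edge_mm,) * 3)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _to_internal_orientation(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple[float, ...]]:
    """Reorient a NIfTI image to the internal L/P/I voxel axis order."""
    if img.affine is None:
        raise GridError("NIfTI image has no affine; cannot determine orientation")
    current = nib.orientations.io_orientation(img.affine)
    target = nib.orientations.axcodes2ornt(INTERNAL_AXCODES)
    transform = nib.orientations.ornt_transform(current, target)
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), transform)
    # spacing follows the axis permutation
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    perm = transform[:, 0].astype(int)
    spacing = tuple(zooms[perm])
    return np.asarray(data, dtype=np.float64), spacing


def _internal_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """Affine mapping internal (L, P, I) voxel indices to RAS mm."""
    aff = np.diag([-spacing[0], -spacing[1], -spacing[2], 1.0])
    return aff


def read_nifti(path: str) -> VoxelGrid:
    """Read a NIfTI-1 volume and reorient it to the internal axis frame."""
    img = nib.load(path)
    data, spacing = _to_internal_orientation(img)
    return VoxelGrid(data, spacing)  # type: ignore[arg-type]


def write_nifti(grid: VoxelGrid, path: str) -> None:
    img = nib.Nifti1Image(grid.values.astype(np.float32), _internal_affine(grid.spacing))
    nib.save(img, path)


def read_mask(path: str) -> BinaryRegion:
    img = nib.load(path)
    data, spacing = _to_internal_orientation(img)
    return BinaryRegion(data > 0.5, spacing)  # type: ignore[arg-type]


def write_mask(region: BinaryRegion, path: str) -> None:
    img = nib.Nifti1Image(
        region.mask.astype(np.uint8), _internal_affine(region.spacing)
    )
    nib.save(img, path)
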