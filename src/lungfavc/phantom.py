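"""Synthetic thorax CT phantom with exact ground truth.

The phantom emulates a low-resolution tidal-breathing thorax scan: a
90-slice volume of 4.42 mm cubic voxels containing a soft-tissue body,
an air shell outside the body, two air-filled lung ellipsoids (right
larger than left, the left carrying a medial cardiac notch), a trachea /
main-bronchus Y-tube in the mediastinum, and tissue-density vessels
radiating from each hilum.  Lung voxel intensities invert the density
model used for measurement,

    I_vox = I_air + (I_tissue - I_air) * rho_t * (1 - FAVC),

so that the measurement chain applied to a noise-free phantom recovers
the specified FAVC field exactly.  The image is then degraded by
Gaussian blur (emulating the time-averaging of the tidal cycle plus
scanner resolution) and additive Gaussian noise.  Ground truth (masks,
FAVC field, volumes) is computed on the clean field before degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .favc import DEFAULT_RHO_T
from .image_model import BinaryRegion, CalibrationPair, GridError, Landmarks, VoxelGrid

__all__ = [
    "Ellipsoid",
    "Cylinder",
    "FAVCFieldSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre in voxel coordinates, semi-axes in mm."""

    center_vox: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def contains(self, coords_mm: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
        c = (np.asarray(self.center_vox) + 0.5) * np.asarray(spacing)
        r = np.asarray(self.semi_axes_mm)
        d = (coords_mm - c) / r
        return (d * d).sum(axis=-1) <= 1.0

    def fractional_radius(
        self, coords_mm: np.ndarray, spacing: tuple[float, float, float]
    ) -> np.ndarray:
        c = (np.asarray(self.center_vox) + 0.5) * np.asarray(spacing)
        d = (coords_mm - c) / np.asarray(self.semi_axes_mm)
        return np.sqrt((d * d).sum(axis=-1))


@dataclass(frozen=True)
class Cylinder:
    """Capsule (cylinder with hemispherical caps) between two voxel points."""

    start_vox: tuple[float, float, float]
    end_vox: tuple[float, float, float]
    radius_mm: float

    def contains(self, coords_mm: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
        sp = np.asarray(spacing)
        a = (np.asarray(self.start_vox) + 0.5) * sp
        b = (np.asarray(self.end_vox) + 0.5) * sp
        ab = b - a
        denom = float(ab @ ab)
        rel = coords_mm - a
        t = np.clip((rel @ ab) / denom if denom > 0 else 0.0, 0.0, 1.0)
        nearest = a + t[..., None] * ab
        dist2 = ((coords_mm - nearest) ** 2).sum(axis=-1)
        return dist2 <= self.radius_mm**2


@dataclass(frozen=True)
class FAVCFieldSpec:
    """Specification of the within-lung FAVC field.

    ``kind`` is one of ``"constant"`` (value ``a``), ``"linear"`` (gradient
    from ``a`` to ``b`` along ``axis`` across the grid extent) or
    ``"radial"`` (gradient from ``a`` at the lung centre to ``b`` at the
    lung surface, in normalised ellipsoid radius).
    """

    kind: str = "constant"
    a: float = 0.68
    b: float = 0.68
    axis: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "radial"):
            raise GridError(f"unknown FAVC field kind {self.kind!r}")
        for v in (self.a, self.b):
            if not (0.0 <= v <= 1.0):
                raise GridError(f"FAVC field values must lie in [0, 1], got {v}")


def _default_vessels_right() -> tuple[Cylinder, ...]:
    # three vessels radiating laterally from near the right hilum, sized to
    # occupy roughly fractional radii 0.1-0.35 of the lung (shells 2-3);
    # their origins sit ~2 voxels off the hilum so the seed voxel stays air
    return (
        Cylinder((23.0, 32.0, 36.5), (19.0, 32.0, 34.0), 4.0),
        Cylinder((23.5, 30.5, 39.5), (20.0, 28.0, 43.0), 3.5),
        Cylinder((23.5, 34.0, 39.0), (21.0, 37.0, 41.0), 3.5),
    )


def _default_vessels_left() -> tuple[Cylinder, ...]:
    return (
        Cylinder((40.0, 32.0, 36.5), (44.0, 32.0, 34.0), 4.0),
        Cylinder((39.5, 30.5, 39.5), (43.0, 28.0, 43.0), 3.5),
        Cylinder((39.5, 34.0, 39.0), (42.0, 37.0, 41.0), 3.5),
    )


@dataclass
class PhantomSpec:
    """Full parameterisation of the synthetic thorax.

    Defaults reproduce the study geometry: 64 x 64 x 90 grid of 4.42 mm
    cubic voxels; right lung space volume ~1.5 l, left ~1.2 l after the
    cardiac notch; constant FAVC 0.68; 8 mm FWHM blur; no noise.
    """

    dims: tuple[int, int, int] = (64, 64, 90)
    spacing: tuple[float, float, float] = (4.42, 4.42, 4.42)
    right_lung: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((16.0, 32.0, 45.0), (45.0, 58.0, 138.0))
    )
    left_lung: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((47.0, 32.0, 45.0), (42.0, 55.0, 130.0))
    )
    heart_notch: Ellipsoid | None = field(
        default_factory=lambda: Ellipsoid((36.0, 26.0, 52.0), (30.0, 30.0, 55.0))
    )
    body: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((31.5, 32.0, 45.0), (134.0, 125.0, 260.0))
    )
    hilum_right: tuple[int, int, int] = (24, 32, 38)
    hilum_left: tuple[int, int, int] = (39, 32, 38)
    trachea_seed: tuple[int, int, int] = (31, 32, 10)
    trachea: Cylinder = field(
        default_factory=lambda: Cylinder((31.5, 32.0, 4.0), (31.5, 32.0, 30.0), 8.0)
    )
    bronchi: tuple[Cylinder, ...] = field(
        default_factory=lambda: (
            # main bronchi stop short of the lung surface: airway walls keep
            # the tube air disconnected from the lung air
            Cylinder((31.5, 32.0, 30.0), (28.8, 32.0, 32.9), 6.0),
            Cylinder((31.5, 32.0, 30.0), (34.2, 32.0, 32.9), 6.0),
        )
    )
    vessels_right: tuple[Cylinder, ...] = field(default_factory=_default_vessels_right)
    vessels_left: tuple[Cylinder, ...] = field(default_factory=_default_vessels_left)
    favc_field: FAVCFieldSpec = field(default_factory=FAVCFieldSpec)
    blur_fwhm_mm: float = 8.0
    noise_sd: float = 0.0
    calibration: CalibrationPair = field(default_factory=CalibrationPair)
    rho_t: float = DEFAULT_RHO_T
    #: density of the body soft tissue surrounding the lungs; perfused
    #: muscle/mediastinum is ~1.05 g/ml, the same constant as lung tissue,
    #: which makes the background FAVC exactly zero
    body_density: float = DEFAULT_RHO_T
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GridError("noise sd must be >= 0")
        if self.blur_fwhm_mm < 0:
            raise GridError("blur FWHM must be >= 0")


@dataclass
class PhantomTruth:
    """Exact ground truth computed on the clean, pre-degradation field."""

    right_envelope: BinaryRegion
    left_envelope: BinaryRegion
    trachea_mask: BinaryRegion
    favc_map: np.ndarray
    right_air_ml: float
    left_air_ml: float
    right_space_ml: float
    left_space_ml: float
    landmarks: Landmarks

    def to_json_dict(self) -> dict:
        return {
            "right_air_ml": self.right_air_ml,
            "left_air_ml": self.left_air_ml,
            "right_space_ml": self.right_space_ml,
            "left_space_ml": self.left_space_ml,
            "landmarks": {
                "trachea_seed": list(self.landmarks.trachea_seed),
                "hilum_right": list(self.landmarks.hilum_right),
                "hilum_left": list(self.landmarks.hilum_left),
            },
        }


def _voxel_center_coords(dims, spacing) -> np.ndarray:
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(dims, spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)


def _favc_values(spec: PhantomSpec, coords_mm: np.ndarray, lung: Ellipsoid) -> np.ndarray:
    f = spec.favc_field
    if f.kind == "constant":
        return np.full(coords_mm.shape[:-1], f.a)
    if f.kind == "linear":
        ax = f.axis
        extent = spec.dims[ax] * spec.spacing[ax]
        frac = coords_mm[..., ax] / extent
        return f.a + (f.b - f.a) * frac
    # radial: normalised ellipsoid radius, clipped at the surface
    r = np.clip(lung.fractional_radius(coords_mm, spec.spacing), 0.0, 1.0)
    return f.a + (f.b - f.a) * r


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Render the phantom image and its ground truth.

    Output is bit-for-bit reproducible for a fixed ``spec`` (including
    its ``seed``).
    """
    coords = _voxel_center_coords(spec.dims, spec.spacing)
    sp = spec.spacing

    right = spec.right_lung.contains(coords, sp)
    left = spec.left_lung.contains(coords, sp)
    if spec.heart_notch is not None:
        left &= ~spec.heart_notch.contains(coords, sp)
    if (right & left).any():
        raise GridError("right and left lung ellipsoids overlap")

    airway = spec.trachea.contains(coords, sp)
    for b in spec.bronchi:
        airway |= b.contains(coords, sp)
    right &= ~airway
    left &= ~airway

    vess_r = np.zeros(spec.dims, dtype=bool)
    for v in spec.vessels_right:
        vess_r |= v.contains(coords, sp)
    vess_r &= right
    vess_l = np.zeros(spec.dims, dtype=bool)
    for v in spec.vessels_left:
        vess_l |= v.contains(coords, sp)
    vess_l &= left

    for name, lm, lung in (
        ("hilum_right", spec.hilum_right, right),
        ("hilum_left", spec.hilum_left, left),
    ):
        if not lung[tuple(lm)]:
            raise GridError(f"landmark {name}={lm} is not inside its lung envelope")
    if not airway[tuple(spec.trachea_seed)]:
        raise GridError(f"trachea seed {spec.trachea_seed} is not inside the airway")

    body = spec.body.contains(coords, sp)

    # true FAVC field: lung parenchyma follows the field spec, vessels are
    # solid tissue (FAVC 0), airway lumen is pure air, background 0
    favc = np.zeros(spec.dims)
    favc[right] = _favc_values(spec, coords, spec.right_lung)[right]
    favc[left] = _favc_values(spec, coords, spec.left_lung)[left]
    favc[vess_r | vess_l] = 0.0
    favc[airway] = 1.0

    calib = spec.calibration
    span = calib.i_tissue - calib.i_air
    intensity = np.full(spec.dims, calib.i_air)        # exterior air
    intensity[body] = calib.i_air + span * spec.body_density  # body soft tissue
    in_lung = right | left
    intensity[in_lung] = calib.i_air + span * spec.rho_t * (1.0 - favc[in_lung])
    intensity[airway] = calib.i_air

    v_ml = float(np.prod(sp)) / 1000.0
    truth = PhantomTruth(
        right_envelope=BinaryRegion(right, sp),
        left_envelope=BinaryRegion(left, sp),
        trachea_mask=BinaryRegion(airway, sp),
        favc_map=favc,
        right_air_ml=float(favc[right].sum()) * v_ml,
        left_air_ml=float(favc[left].sum()) * v_ml,
        right_space_ml=float(right.sum()) * v_ml,
        left_space_ml=float(left.sum()) * v_ml,
        landmarks=Landmarks(spec.trachea_seed, spec.hilum_right, spec.hilum_left),
    )

    if spec.blur_fwhm_mm > 0:
        sigma_vox = [spec.blur_fwhm_mm * FWHM_TO_SIGMA / s for s in sp]
        intensity = ndimage.gaussian_filter(intensity, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.dims)

    return VoxelGrid(intensity, sp), truth
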