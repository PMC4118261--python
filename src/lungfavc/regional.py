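"""Cohort mean FAVC image with edge correction, and 1D orthogonal profiles.

After each subject's lung has been radially registered to a common
template shape, the registered FAVC images are averaged voxel by voxel.
The outermost voxel layers of the mean image are systematically reduced
by the partial volume effect, so a layer-based correction is applied:
the envelope outline is eroded three times to define three one-voxel
layers, and each of the two outer layers is multiplied by the factor that
equalises its mean FAVC with that of the third layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .favc import FAVCMap
from .image_model import BinaryRegion, GridError, boundary_layers

__all__ = ["MeanVolumeImage", "mean_image", "edge_correction", "axis_profile"]

AXIS_NAMES = {
    "lateral-medial": 0,
    "anterior-posterior": 1,
    "superior-inferior": 2,
}


@dataclass
class MeanVolumeImage:
    """Voxelwise mean FAVC over a cohort, on the template envelope."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    n_subjects: int
    correction_factors: tuple[float, float] | None = None

    def as_favc_map(self, rho_t: float = 1.05) -> FAVCMap:
        return FAVCMap(self.values, self.spacing, rho_t)


def mean_image(registered_maps: list[FAVCMap]) -> MeanVolumeImage:
    """Unweighted voxelwise arithmetic mean of registered FAVC maps."""
    if not registered_maps:
        raise GridError("need at least one registered map")
    shape = registered_maps[0].values.shape
    spacing = registered_maps[0].spacing
    for m in registered_maps[1:]:
        if m.values.shape != shape or not np.allclose(m.spacing, spacing):
            raise GridError("registered maps are not on a common template grid")
    stack = np.stack([m.values for m in registered_maps])
    return MeanVolumeImage(stack.mean(axis=0), spacing, len(registered_maps))


def edge_correction(
    mean_img: MeanVolumeImage,
    template_envelope: BinaryRegion,
    n_layers: int = 3,
    connectivity: int = 26,
) -> MeanVolumeImage:
    """Equalise the mean FAVC of the outer envelope layers.

    Layers 1..n are peeled off the envelope outline; every voxel in
    layers 1..n-1 is multiplied by mean(layer n)/mean(layer k), so that
    afterwards all n layer means equal that of the innermost peeled
    layer.  The core (deeper than layer n) is untouched.  If layer n is
    empty (envelope too thin to support the erosions) the correction is
    skipped with a warning — thin regions such as the lung base then stay
    under-corrected.
    """
    if template_envelope.mask.shape != mean_img.values.shape:
        raise GridError("envelope and mean image are on different grids")
    layers = boundary_layers(template_envelope, n_layers, connectivity)
    if layers[-1].count == 0:
        warnings.warn(
            f"envelope too thin for {n_layers} erosion layers; "
            "edge correction skipped", stacklevel=2,
        )
        return replace(mean_img, correction_factors=None)
    ref = float(mean_img.values[layers[-1].mask].mean())
    out = mean_img.values.copy()
    factors = []
    for layer in layers[:-1]:
        m = float(mean_img.values[layer.mask].mean())
        if m <= 0 or not np.isfinite(m):
            raise GridError(f"cannot correct layer with mean FAVC {m}")
        factor = ref / m
        out[layer.mask] *= factor
        factors.append(factor)
    return MeanVolumeImage(
        out, mean_img.spacing, mean_img.n_subjects, tuple(factors)
    )


def axis_profile(
    favc_map: FAVCMap | MeanVolumeImage,
    envelope: BinaryRegion,
    axis: str,
    lateral_sign: int = -1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1D profile of mean FAVC through the lung along an anatomical axis.

    For each slice plane perpendicular to the axis that intersects the
    envelope, the mean FAVC over envelope voxels in that plane is
    computed.  The abscissa is the fractional position of the slice
    across the envelope's bounding extent on that axis, oriented in the
    named direction; ``axis`` is one of ``"lateral-medial"``,
    ``"anterior-posterior"`` or ``"superior-inferior"``.  The
    lateral-medial direction depends on the side: ``lateral_sign`` is -1
    for the right lung (lateral at small x) and +1 for the left.

    Returns ``(position_fraction, mean_favc, n_voxels)`` arrays.
    """
    if axis not in AXIS_NAMES:
        raise GridError(
            f"unknown axis {axis!r}; expected one of {sorted(AXIS_NAMES)}"
        )
    if envelope.count == 0:
        raise GridError("empty envelope")
    ax = AXIS_NAMES[axis]
    mask = envelope.mask
    vals = favc_map.values
    idx = np.any(mask, axis=tuple(i for i in range(3) if i != ax))
    lo, hi = int(np.argmax(idx)), int(len(idx) - 1 - np.argmax(idx[::-1]))
    extent = hi - lo + 1

    positions, means, counts = [], [], []
    for i in range(lo, hi + 1):
        sl_mask = np.take(mask, i, axis=ax)
        n = int(sl_mask.sum())
        if n == 0:
            continue
        positions.append((i - lo + 0.5) / extent)
        means.append(float(np.take(vals, i, axis=ax)[sl_mask].mean()))
        counts.append(n)
    pos = np.asarray(positions)
    means_a = np.asarray(means)
    counts_a = np.asarray(counts)

    # orient: lateral->medial runs against +x for the left lung; the other
    # two named directions coincide with the +y and +z axes
    if ax == 0 and lateral_sign > 0:
        pos = 1.0 - pos[::-1]
        means_a = means_a[::-1]
        counts_a = counts_a[::-1]
    return pos, means_a, counts_a
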