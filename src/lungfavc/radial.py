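"""Radial geometry of the lung: transform centre, fractional radius,
concentric shell decomposition and shape-to-template radial registration.

Two different centres are used, following the method:

* **Shell analysis** uses the hilum itself as the centre, because airways
  and vessels branch out approximately radially from it, so equal
  fractional-radius shells approximate airway generation ordering.
* **Registration and mean-image formation** use a point in the centre of
  the lung, displaced from the hilum halfway to the lateral lung edge
  along x — the hilum itself is on or near the lung edge, so nearly half
  the radial paths from it would have zero length inside the lung.

A voxel's *fractional radius* f about a centre O is |OV| / |OE|, where E
is the outermost point at which the ray from O through V leaves the lung
envelope.  The registration maps a subject lung onto a template lung by
matching direction cosines and fractional radius, copying (never
rescaling) the subject's FAVC values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .favc import FAVCMap
from .image_model import BinaryRegion, GridError

__all__ = [
    "TransformCenter",
    "ShellProfile",
    "transform_center",
    "fractional_radius",
    "shell_decomposition",
    "cp_ratio",
    "radial_register",
]

#: Ray-marching step as a fraction of the voxel edge.
RAY_STEP_VOXELS = 0.25


@dataclass(frozen=True)
class TransformCenter:
    """Centre of the radial transform for one lung.

    ``o`` is a continuous voxel-space coordinate (voxel centres at integer
    coordinates + 0.5 are *not* used here: ``o`` is expressed in voxel
    index units, where the centre of voxel ``i`` is at ``i`` itself).
    """

    o: tuple[float, float, float]
    hilum: tuple[int, int, int]
    p_x: float


def transform_center(
    envelope: BinaryRegion,
    hilum: tuple[int, int, int],
    lateral_sign: int,
    literal: bool = False,
) -> TransformCenter:
    """Place the transform centre between the hilum and the lateral edge.

    ``lateral_sign`` is -1 for the right lung and +1 for the left under
    the x-toward-subject-left convention.  ``p_x`` is the x index of the
    outermost envelope voxel in the lateral direction at the hilum's
    (y, z).  The centre is the hilum displaced halfway toward that edge
    along x; y and z copy the hilum.  With ``literal=True`` the
    historical formula ``o_x = h_x + p_x / 2`` is applied verbatim
    (geometrically meaningful only when the hilum is near x = 0).
    """
    if lateral_sign not in (-1, 1):
        raise GridError(f"lateral_sign must be +1 or -1, got {lateral_sign}")
    hx, hy, hz = (int(c) for c in hilum)
    row = envelope.mask[:, hy, hz]
    xs = np.flatnonzero(row)
    if xs.size == 0:
        raise GridError(
            f"no envelope voxel on the lateral ray at y={hy}, z={hz}"
        )
    p_x = float(xs.max() if lateral_sign > 0 else xs.min())
    if literal:
        ox = hx + p_x / 2.0
    else:
        ox = hx + (p_x - hx) / 2.0
    return TransformCenter((ox, float(hy), float(hz)), (hx, hy, hz), p_x)


# ---------------------------------------------------------------------------
# Ray marching
# ---------------------------------------------------------------------------

def _ray_exit_lengths(
    mask: np.ndarray,
    origin: np.ndarray,
    directions: np.ndarray,
    t_max: float,
    step: float = RAY_STEP_VOXELS,
) -> np.ndarray:
    """Outermost envelope-crossing distance (in voxel units) per ray.

    Marches each unit-direction ray from ``origin`` in steps of ``step``
    voxels up to ``t_max`` and returns the largest sampled distance still
    inside ``mask`` (NaN for rays that never sample inside).
    """
    n_steps = max(1, int(np.ceil(t_max / step)))
    ts = (np.arange(n_steps, dtype=np.float64) + 1.0) * step
    exits = np.full(directions.shape[0], np.nan)
    chunk = max(1, int(4e6 // n_steps))
    for lo in range(0, directions.shape[0], chunk):
        d = directions[lo:lo + chunk]
        pts = origin[None, None, :] + d[:, None, :] * ts[None, :, None]
        inside = ndimage.map_coordinates(
            mask.astype(np.uint8), pts.reshape(-1, 3).T, order=0, cval=0
        ).reshape(d.shape[0], n_steps).astype(bool)
        any_in = inside.any(axis=1)
        # index of last inside sample per ray
        last = n_steps - 1 - np.argmax(inside[:, ::-1], axis=1)
        block = np.full(d.shape[0], np.nan)
        block[any_in] = ts[last[any_in]]
        exits[lo:lo + chunk] = block
    return exits


def _fractional_radii(
    mask: np.ndarray, center: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Fractional radius of each point (voxel index coords) about center."""
    delta = points.astype(np.float64) - center[None, :]
    r = np.linalg.norm(delta, axis=1)
    f = np.zeros(len(points))
    nz = r > 0
    dirs = delta[nz] / r[nz, None]
    # the exit search must span the whole envelope, not just the queried
    # points: bound it by the farthest mask bounding-box corner
    bbox = [(int(a.min()), int(a.max())) for a in np.nonzero(mask)]
    corners = np.array(np.meshgrid(*[(lo, hi) for lo, hi in bbox],
                                   indexing="ij")).reshape(3, -1).T
    t_max = float(np.linalg.norm(corners - center[None, :], axis=1).max()) + 2.0
    exits = _ray_exit_lengths(mask, center, dirs, t_max)
    with np.errstate(invalid="ignore", divide="ignore"):
        f[nz] = r[nz] / exits
    f[nz & np.isnan(f)] = np.inf
    return f


def fractional_radius(
    envelope: BinaryRegion,
    center: TransformCenter | tuple[float, float, float],
    voxel: tuple[float, float, float],
) -> float:
    """Fractional radial distance of one voxel about the transform centre.

    Returns 0.0 when the voxel coincides with the centre.
    """
    o = np.asarray(center.o if isinstance(center, TransformCenter) else center,
                   dtype=np.float64)
    if not envelope.mask[tuple(int(round(c)) for c in o)]:
        raise GridError(f"transform centre {tuple(o)} is outside the envelope")
    p = np.asarray(voxel, dtype=np.float64)
    return float(_fractional_radii(envelope.mask, o, p[None, :])[0])


# ---------------------------------------------------------------------------
# Shell decomposition and c/p ratio
# ---------------------------------------------------------------------------

@dataclass
class ShellProfile:
    """Concentric-shell air volumes and mean FAVC about a centre.

    Shell ``i`` (1-based) collects envelope voxels with fractional radius
    in [(i-1)/n, i/n); the outermost shell also takes the occasional
    f >= 1 discretization stragglers.  The shells partition the envelope.
    """

    volumes_ml: np.ndarray
    mean_favc: np.ndarray
    counts: np.ndarray

    @property
    def n_shells(self) -> int:
        return len(self.volumes_ml)

    @property
    def total_air_ml(self) -> float:
        return float(self.volumes_ml.sum())


def shell_decomposition(
    favc_map: FAVCMap,
    envelope: BinaryRegion,
    hilum: tuple[int, int, int],
    n_shells: int = 10,
) -> ShellProfile:
    """Divide the lung into ``n_shells`` concentric fractional-radius
    shells about the hilum and integrate air volume per shell.

    The hilum itself is the centre here (not the mid-lung registration
    centre): shells then approximate airway generation ordering.
    """
    if n_shells < 2:
        raise GridError(f"n_shells must be >= 2, got {n_shells}")
    if envelope.count == 0:
        raise GridError("empty envelope")
    if envelope.mask.shape != favc_map.values.shape:
        raise GridError("envelope and FAVC map are on different grids")
    center = np.asarray(hilum, dtype=np.float64)
    pts = np.argwhere(envelope.mask)
    f = _fractional_radii(envelope.mask, center, pts)
    shell_idx = np.minimum((f * n_shells).astype(int), n_shells - 1)

    vals = favc_map.values[tuple(pts.T)]
    v_ml = favc_map.voxel_volume_ml
    counts = np.bincount(shell_idx, minlength=n_shells)
    sums = np.bincount(shell_idx, weights=vals, minlength=n_shells)
    volumes = sums * v_ml
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0) + 1
        warnings.warn(f"empty shells: {list(empty)}", stacklevel=2)
    return ShellProfile(volumes, means, counts)


def cp_ratio(profile: ShellProfile) -> float:
    """Central-to-peripheral ratio: air in the inner half of the shells
    divided by air in the outer half (shells 1-5 over 6-10 for n=10)."""
    half = profile.n_shells // 2
    peripheral = float(profile.volumes_ml[half:].sum())
    if peripheral <= 0:
        raise GridError("zero peripheral air volume; c/p undefined")
    return float(profile.volumes_ml[:half].sum()) / peripheral


# ---------------------------------------------------------------------------
# Radial registration
# ---------------------------------------------------------------------------

def radial_register(
    subject_favc: FAVCMap,
    subject_envelope: BinaryRegion,
    subject_center: TransformCenter,
    template_envelope: BinaryRegion,
    template_center: TransformCenter,
) -> tuple[FAVCMap, np.ndarray]:
    """Elastically map a subject FAVC image onto a template lung shape.

    For every voxel V_t of the template envelope the direction cosines
    and fractional radius f_t about the template centre are computed; the
    same-direction ray is cast from the subject centre, and among the
    subject voxels sampled along it the one with fractional radius f_s
    nearest to f_t donates its FAVC value (ties broken toward the smaller
    radius).  Values are copied unmodified, so every output value exists
    in the subject map.

    Returns the registered map (defined on the template envelope, zero
    elsewhere) and a boolean flag array marking template voxels whose own
    ray found no subject voxel and that were filled from the
    nearest-direction successful ray.
    """
    t_mask = template_envelope.mask
    s_mask = subject_envelope.mask
    if not t_mask.any() or not s_mask.any():
        raise GridError("empty envelope in registration")
    o_t = np.asarray(template_center.o, dtype=np.float64)
    o_s = np.asarray(subject_center.o, dtype=np.float64)

    pts = np.argwhere(t_mask)
    delta = pts.astype(np.float64) - o_t[None, :]
    r_t = np.linalg.norm(delta, axis=1)
    out_vals = np.zeros(len(pts))
    flags_pts = np.zeros(len(pts), dtype=bool)

    # template fractional radii
    f_t = _fractional_radii(t_mask, o_t, pts)

    nz = r_t > 0
    dirs = np.zeros_like(delta)
    dirs[nz] = delta[nz] / r_t[nz, None]

    # centre voxel (zero radius): f_t = 0 -> handled with a downward ray
    dirs[~nz] = np.array([0.0, 0.0, 1.0])

    # march subject rays
    s_pts = np.argwhere(s_mask)
    t_max = float(np.linalg.norm(s_pts - o_s[None, :], axis=1).max()) + 2.0
    n_steps = max(1, int(np.ceil(t_max / RAY_STEP_VOXELS)))
    ts = (np.arange(n_steps) + 1.0) * RAY_STEP_VOXELS

    s_u8 = s_mask.astype(np.uint8)
    chunk = max(1, int(4e6 // n_steps))
    for lo in range(0, len(pts), chunk):
        d = dirs[lo:lo + chunk]
        ft_blk = f_t[lo:lo + chunk]
        sample = o_s[None, None, :] + d[:, None, :] * ts[None, :, None]
        flat = sample.reshape(-1, 3)
        inside = ndimage.map_coordinates(
            s_u8, flat.T, order=0, cval=0
        ).reshape(d.shape[0], n_steps).astype(bool)
        any_in = inside.any(axis=1)
        last = n_steps - 1 - np.argmax(inside[:, ::-1], axis=1)
        t_exit = np.where(any_in, ts[last], np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_s = ts[None, :] / t_exit[:, None]
        cost = np.abs(f_s - ft_blk[:, None])
        cost[~inside] = np.inf
        # tie-break toward smaller radius: argmin returns first minimum,
        # and ts is ascending
        best = np.argmin(cost, axis=1)
        chosen = sample[np.arange(d.shape[0]), best]
        vox = np.rint(chosen).astype(int)
        for ax in range(3):
            vox[:, ax] = np.clip(vox[:, ax], 0, s_mask.shape[ax] - 1)
        vals = subject_favc.values[tuple(vox.T)]
        out_vals[lo:lo + chunk] = np.where(any_in, vals, np.nan)
        flags_pts[lo:lo + chunk] = ~any_in

    # fill failed rays from the nearest-direction successful ray
    if flags_pts.any():
        ok = ~flags_pts & nz
        if not ok.any():
            raise GridError("no successful rays during registration")
        d_ok = dirs[ok]
        v_ok = out_vals[ok]
        for i in np.flatnonzero(flags_pts):
            dots = d_ok @ dirs[i]
            out_vals[i] = v_ok[np.argmax(dots)]

    out = np.zeros(t_mask.shape)
    out[tuple(pts.T)] = out_vals
    registered = FAVCMap(out, template_envelope.spacing, subject_favc.rho_t)
    flags = np.zeros(t_mask.shape, dtype=bool)
    flags[tuple(pts.T)] = flags_pts
    return registered, flags
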