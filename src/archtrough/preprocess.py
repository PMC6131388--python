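"""Intensity normalization, Frankfort reorientation and confound removal.

The mandible cannot be segmented reliably while the midface, cervical
vertebrae and temporal bone are present: their gray values disturb the
bimodal bone/soft-tissue histogram.  These operations zero the offending
regions using a handful of operator landmarks, leaving a volume in which
slice-wise Otsu thresholding is well posed.  All removals only ever set
voxels to zero, so they commute and never create intensity.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import PipelineConfig
from .io_formats import Image2D, Volume3D
from .segmentation import (
    DegenerateHistogramError,
    EmptyMaskWarning,
    otsu_threshold,
    scale_region,
)

__all__ = [
    "normalize_intensity",
    "reorient_to_frankfort",
    "frankfort_point_map",
    "project",
    "remove_superior_halfplane",
    "remove_cervical_vertebrae",
    "remove_condyle_caps",
]

log = logging.getLogger(__name__)

_AXIS = {"X": 0, "Y": 1, "Z": 2}


def normalize_intensity(vol: Volume3D) -> Volume3D:
    """Affinely map intensities so the output spans exactly [0, 1]."""
    data = np.asarray(vol.data, float)
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        raise DegenerateHistogramError("constant volume cannot be normalized")
    return vol.copy_with((data - lo) / (hi - lo))


def _frankfort_angle(orbit, meatus) -> tuple[float, np.ndarray]:
    """Inclination of the orbit-meatus line in the sagittal (Y, Z) plane
    and the rotation pivot (midpoint), both in world mm."""
    o = np.asarray(orbit, float)[-2:]
    m = np.asarray(meatus, float)[-2:]
    if np.allclose(o, m):
        raise ValueError("orbit and meatus points coincide; no plane defined")
    dy, dz = o - m
    return float(np.arctan2(dz, dy)), 0.5 * (o + m)


def frankfort_point_map(orbit, meatus):
    """The world-point transform applied by :func:`reorient_to_frankfort`.

    Returns a callable mapping 3-D world points; X is unchanged, (Y, Z)
    rotate about the orbit/meatus midpoint so the pair becomes level.
    """
    alpha, c = _frankfort_angle(orbit, meatus)
    ca, sa = np.cos(-alpha), np.sin(-alpha)
    rot = np.array([[ca, -sa], [sa, ca]])

    def apply(p):
        p = np.asarray(p, float)
        out = p.copy()
        out[-2:] = c + rot @ (p[-2:] - c)
        return out

    return apply


def reorient_to_frankfort(vol: Volume3D, orbit, meatus) -> Volume3D:
    """Rotate the volume in the sagittal plane so the Frankfort line is level.

    ``orbit`` and ``meatus`` are points in world mm, given either as (y, z)
    picked on the sagittal projection or as full (x, y, z) landmarks.  The
    rotation pivots on their midpoint; resampling is trilinear with zero
    fill outside the grid.
    """
    alpha, c = _frankfort_angle(orbit, meatus)
    if abs(alpha) < 1e-12:
        return vol.copy_with(vol.data.copy())
    # output(idx) = input(S^-1 (Rot(alpha)(world - c) + c - origin)); the
    # inverse point map in index coordinates feeds affine_transform.
    ca, sa = np.cos(alpha), np.sin(alpha)
    rot_inv = np.array([[ca, -sa], [sa, ca]])
    s_yz = np.diag(vol.spacing[1:])
    s_inv = np.diag([1.0 / vol.spacing[1], 1.0 / vol.spacing[2]])
    a_yz = s_inv @ rot_inv @ s_yz
    o_yz = np.asarray(vol.origin[1:], float)
    b_yz = s_inv @ (rot_inv @ (o_yz - c) + c - o_yz)
    matrix = np.eye(3)
    matrix[1:, 1:] = a_yz
    offset = np.array([0.0, b_yz[0], b_yz[1]])
    data = ndimage.affine_transform(
        np.asarray(vol.data, float), matrix, offset=offset, order=1, cval=0.0
    )
    return vol.copy_with(data)


def project(vol: Volume3D, axis: str, mode: str = "max") -> Image2D:
    """Maximum- or mean-intensity projection along one anatomical axis.

    The image keeps the two remaining axes in (X, Y, Z) order with their
    spacing and origin, e.g. ``axis="Z"`` gives an axial image over (X, Y).
    """
    if axis not in _AXIS:
        raise ValueError(f"axis must be one of {sorted(_AXIS)}, got {axis!r}")
    if mode not in ("max", "mean"):
        raise ValueError(f"mode must be 'max' or 'mean', got {mode!r}")
    ax = _AXIS[axis]
    data = np.asarray(vol.data, float)
    img = data.max(axis=ax) if mode == "max" else data.mean(axis=ax)
    keep = [i for i in range(3) if i != ax]
    return Image2D(
        img,
        spacing=tuple(vol.spacing[i] for i in keep),
        origin=tuple(vol.origin[i] for i in keep),
        axes=tuple("XYZ"[i] for i in keep),
    )


def remove_superior_halfplane(vol: Volume3D, view_axis: str, p1, p2) -> Volume3D:
    """Zero everything superior to the line through two projection points.

    ``view_axis`` names the projection direction: ``"Y"`` for a coronal
    view (points in the X-Z plane), ``"X"`` for a sagittal view (points in
    the Y-Z plane).  The infinite line through ``p1`` and ``p2`` (world mm)
    splits the plane; every voxel whose projected coordinate lies strictly
    on the +Z side is set to zero, through the full extent of the viewing
    axis.
    """
    if view_axis not in ("X", "Y"):
        raise ValueError("view_axis must be 'X' (sagittal) or 'Y' (coronal)")
    h_axis = 1 if view_axis == "X" else 0  # in-plane horizontal world axis
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if p1.shape[-1] == 3:  # full 3-D landmarks: take the in-plane components
        p1 = p1[[h_axis, 2]]
        p2 = p2[[h_axis, 2]]
    (h1, z1), (h2, z2) = p1, p2
    if np.isclose(h1, h2):
        if np.isclose(z1, z2):
            raise ValueError("halfplane points coincide")
        raise ValueError("vertical line: the superior side is undefined")
    slope = (z2 - z1) / (h2 - h1)
    h = vol.axis_coords(h_axis)
    z_line = z1 + slope * (h - h1)
    z = vol.axis_coords(2)
    above = z[None, :] > z_line[:, None]  # (h, z)
    data = np.array(vol.data, float, copy=True)
    if view_axis == "X":
        data[:, above] = 0.0
    else:
        data[np.broadcast_to(above[:, None, :], data.shape)] = 0.0
    return vol.copy_with(data)


def remove_cervical_vertebrae(
    vol: Volume3D, occlusal_z: float, cfg: PipelineConfig | None = None
) -> Volume3D:
    """Detect and zero the cervical vertebrae posterior to the mandible.

    The axial MIP over the tooth band ``[occlusal_z - tooth_length,
    occlusal_z]`` is Otsu-binarized; the largest 8-connected component is
    taken as the mandibular arch, and every other component whose centroid
    lies posterior (-Y) to the arch centroid is labelled vertebra.  The
    union of vertebra components, magnified by ``vertebra_magnification``
    (see :func:`~archtrough.segmentation.scale_region`), is zeroed
    through all Z.
    """
    cfg = cfg or PipelineConfig()
    zc = vol.axis_coords(2)
    band = (zc >= occlusal_z - cfg.tooth_length_mm - 1e-9) & (zc <= occlusal_z + 1e-9)
    if not band.any():
        raise ValueError("tooth band does not intersect the volume")
    mip = np.asarray(vol.data, float)[:, :, band].max(axis=2)
    try:
        t = otsu_threshold(mip.ravel())
    except DegenerateHistogramError:
        warnings.warn("no foreground in tooth band; volume unchanged", EmptyMaskWarning)
        return vol.copy_with(vol.data.copy())
    fg = mip > t
    if not fg.any():
        warnings.warn("no foreground in tooth band; volume unchanged", EmptyMaskWarning)
        return vol.copy_with(vol.data.copy())
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    arch_label = int(np.argmax(counts))
    yc = vol.axis_coords(1)
    arch_y = yc[np.nonzero(labels == arch_label)[1]].mean()
    vertebra = np.zeros(fg.shape, bool)
    n_removed = 0
    for lab in range(1, labels.max() + 1):
        if lab == arch_label:
            continue
        comp = labels == lab
        if yc[np.nonzero(comp)[1]].mean() < arch_y:  # posterior to the arch
            vertebra |= comp
            n_removed += 1
    if not vertebra.any():
        return vol.copy_with(vol.data.copy())
    region = scale_region(vertebra, cfg.vertebra_magnification,
                          spacing=vol.spacing[:2])
    log.info(
        "removing %d vertebra component(s); footprint %d px magnified to %d px",
        n_removed, int(vertebra.sum()), int(region.sum()),
    )
    data = np.array(vol.data, float, copy=True)
    data[region, :] = 0.0
    return vol.copy_with(data)


def remove_condyle_caps(
    vol: Volume3D, condyle_a, condyle_b, cfg: PipelineConfig | None = None
) -> tuple[Volume3D, float]:
    """Zero the temporal bone above each condyle and return the stop plane.

    For each point an ellipse (anteroposterior x superoinferior axes from
    the config, default 15 mm x 21 mm) centred on the point in the sagittal
    Y-Z plane is zeroed through all X.  ``stop_z`` is the most inferior Z
    of the removed union - the superior stopping plane for binarization.
    """
    cfg = cfg or PipelineConfig()
    ry = cfg.condyle_ellipse_mm[0] / 2.0
    rz = cfg.condyle_ellipse_mm[1] / 2.0
    yc = vol.axis_coords(1)
    zc = vol.axis_coords(2)
    data = np.array(vol.data, float, copy=True)
    stop_z = np.inf
    lo, hi = vol.world_bounds()
    for p in (condyle_a, condyle_b):
        p = np.asarray(p, float)
        py, pz = p[-2:]
        if not (lo[1] - 1e-9 <= py <= hi[1] + 1e-9 and lo[2] - 1e-9 <= pz <= hi[2] + 1e-9):
            raise ValueError(f"condyle point ({py}, {pz}) lies outside the volume")
        inside = ((yc[:, None] - py) / ry) ** 2 + ((zc[None, :] - pz) / rz) ** 2 <= 1.0
        data[:, inside] = 0.0
        stop_z = min(stop_z, pz - rz)
    return vol.copy_with(data), float(stop_z)
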