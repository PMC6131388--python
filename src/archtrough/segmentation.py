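"""Otsu thresholding and cumulative slice-by-slice binarization.

Cone-beam CT gray values are not calibrated, so a single global threshold is
unreliable.  The mandible is instead binarized slice by slice from inferior
to superior, with each slice's Otsu histogram confined to a mask derived
from the union of the previous ``k`` binary slices, magnified slightly so
that anatomy may drift between slices.  Structures that continue smoothly
through the stack (the mandible) are followed; structures appearing abruptly
are suppressed by the mask.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import PipelineConfig
from .io_formats import BinaryVolume3D, Image2D, Volume3D

__all__ = [
    "DegenerateHistogramError",
    "EmptyMaskWarning",
    "otsu_threshold",
    "binarize_slice",
    "cumulative_binarize",
    "largest_component",
    "scale_region",
]

log = logging.getLogger(__name__)

OTSU_BINS = 256


class DegenerateHistogramError(ValueError):
    """Fewer than two distinct intensities: no threshold separates anything."""


class EmptyMaskWarning(UserWarning):
    """A binarization mask was empty or degenerate; slice left as background."""


def otsu_threshold(values: np.ndarray, bins: int = OTSU_BINS) -> float:
    """Bin-edge threshold maximizing between-class variance on [0, 1].

    The histogram has ``bins`` equal bins on [0, 1]; every interior bin edge
    is a candidate split (lower class = bins below the edge).  Ties are
    broken toward the lower edge.
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0 or np.all(v == v.flat[0]):
        raise DegenerateHistogramError("need at least 2 distinct intensity values")
    counts, edges = np.histogram(v, bins=bins, range=(0.0, 1.0))
    counts = counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise DegenerateHistogramError("no values fall inside [0, 1]")
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]                    # class sizes below edge i+1
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = m0[-1] + counts[-1] * centers[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateHistogramError("all mass in a single histogram bin")
    sigma_b = np.full(w0.shape, -np.inf)
    sigma_b[valid] = w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[best + 1])


def scale_region(mask: np.ndarray, factor: float,
                 spacing: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Magnify a 2-D binary region to ``factor`` times its original size.

    The region is expanded outward by the distance that scales its
    equivalent radius ``sqrt(area / pi)`` by ``factor``; for a disk this
    is exactly similarity scaling about the centre.  Unlike a similarity
    transform about the centroid, the expansion *contains* the original
    region for arbitrary (e.g. U-shaped) geometry, which the slice-to-slice
    mask propagation relies on: a scaled U-band about its centroid would
    displace the limbs by more than their own width and stop covering the
    anatomy it is meant to track.
    """
    mask = np.asarray(mask, bool)
    if not mask.any() or factor == 1.0:
        return mask.copy()
    if factor < 1.0:
        raise ValueError("magnification factor must be >= 1")
    area = float(mask.sum()) * spacing[0] * spacing[1]
    grow = (factor - 1.0) * np.sqrt(area / np.pi)
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return mask | (dist <= grow)


def binarize_slice(slice_img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Otsu-binarize one 2-D slice, optionally confined to a mask.

    The threshold is computed from the masked pixels only; foreground is
    ``pixel > threshold`` (and inside the mask).  An empty mask or a
    degenerate masked histogram yields an all-background slice with an
    :class:`EmptyMaskWarning`.
    """
    slice_img = np.asarray(slice_img, float)
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != slice_img.shape:
            raise ValueError("mask shape must match slice shape")
        if not mask.any():
            warnings.warn("empty binarization mask; slice set to background", EmptyMaskWarning)
            return np.zeros(slice_img.shape, bool)
        pixels = slice_img[mask]
    else:
        pixels = slice_img.ravel()
    try:
        t = otsu_threshold(pixels)
    except DegenerateHistogramError:
        warnings.warn("degenerate slice histogram; slice set to background", EmptyMaskWarning)
        return np.zeros(slice_img.shape, bool)
    fg = slice_img > t
    if mask is not None:
        fg &= mask
    return fg


def cumulative_binarize(
    vol: Volume3D,
    z_start: float,
    z_stop: float,
    cfg: PipelineConfig | None = None,
) -> BinaryVolume3D:
    """Binarize axial slices from ``z_start`` up to ``z_stop`` (world mm).

    The first ``k_prev_slices`` slices are binarized unmasked.  After that
    the union of the previous ``k`` binary slices, magnified by
    ``mask_magnification`` (see :func:`scale_region`), masks the current
    slice's histogram and its foreground.  If the union is empty the slice falls
    back to unmasked Otsu.  Slices outside the range stay background.
    """
    cfg = cfg or PipelineConfig()
    if z_start >= z_stop:
        raise ValueError(f"empty z-range: z_start={z_start} must be < z_stop={z_stop}")
    zc = vol.axis_coords(2)
    ks = np.nonzero((zc >= z_start - 1e-9) & (zc <= z_stop + 1e-9))[0]
    if ks.size == 0:
        raise ValueError("z-range contains no slices of the volume")

    out = np.zeros(vol.shape, bool)
    prev: deque[np.ndarray] = deque(maxlen=cfg.k_prev_slices)
    for k in ks:
        sl = vol.data[:, :, k]
        if len(prev) < cfg.k_prev_slices:
            fg = binarize_slice(sl)
        else:
            summed = np.sum(prev, axis=0)
            support = summed > 0
            if not support.any():
                fg = binarize_slice(sl)  # fallback: no prior anatomy to follow
            else:
                mask = scale_region(support, cfg.mask_magnification,
                                    spacing=vol.spacing[:2])
                fg = binarize_slice(sl, mask)
        out[:, :, k] = fg
        prev.append(fg)
    return BinaryVolume3D(out, vol.spacing, vol.origin)


def largest_component(img: np.ndarray | Image2D) -> np.ndarray | Image2D:
    """Keep only the largest 8-connected component of a 2-D binary image.

    Area ties are broken toward the component whose label comes first in
    raster order.  An empty image is returned unchanged.
    """
    wrap = isinstance(img, Image2D)
    data = np.asarray(img.data if wrap else img, bool)
    if data.ndim != 2:
        raise ValueError("largest_component expects a 2-D binary image")
    if not data.any():
        out = data.copy()
    else:
        labels = measure.label(data, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        out = labels == int(np.argmax(counts))
    if wrap:
        return Image2D(out, img.spacing, img.origin, img.axes)
    return out
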