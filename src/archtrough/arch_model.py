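"""Per-subject axial arch images and the cohort average arch shape.

Each subject contributes one binary axial MIP of the segmented mandible
(dental arch plus posterior mandible).  Subjects are aligned purely by
translation onto the midpoint of the bilateral canine distal contact
points - no rotation, scaling or non-rigid warping - and averaged into a
per-pixel foreground-frequency map.  Binarizing the frequency map at the
threshold whose area best matches the mean individual arch area yields the
cohort's average arch shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage
from skimage import measure, morphology

from .config import PipelineConfig
from .io_formats import BinaryVolume3D, Image2D
from .segmentation import largest_component

__all__ = [
    "ArchImage",
    "AverageArch",
    "DisconnectedMaskError",
    "SkeletonBranchError",
    "build_arch_image",
    "superimpose_arches",
    "area_matched_threshold",
    "arch_centerline",
]

log = logging.getLogger(__name__)


class DisconnectedMaskError(ValueError):
    """The mask is not a single connected band."""


class SkeletonBranchError(ValueError):
    """The pruned skeleton is not a single dominant path."""


@dataclass
class ArchImage:
    """Binary axial arch mask of one subject.

    ``reference`` is the canine-midpoint coordinate in image mm, the
    superimposition anchor.  ``canines`` optionally keeps the two distal
    contact points themselves (axial mm) for downstream arc-length
    bookkeeping.
    """

    mask: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]
    reference: np.ndarray
    canines: np.ndarray | None = None  # (2, 2) right, left

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.reference = np.asarray(self.reference, float).reshape(2)
        if self.canines is not None:
            self.canines = np.asarray(self.canines, float).reshape(2, 2)
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.mask.shape) - 1) * np.asarray(self.spacing)
        if not (np.all(self.reference >= lo - 1e-9) and np.all(self.reference <= hi + 1e-9)):
            raise ValueError("reference point lies outside the image bounds")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.spacing[0] * self.spacing[1]

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.mask.shape[axis])


@dataclass
class AverageArch:
    """Foreground-frequency map of the aligned cohort plus its binarization.

    The frame is centred on the common canine midpoint: the world origin
    (0, 0) of this image is the superimposition anchor.
    """

    frequency: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]
    n_subjects: int
    threshold: float | None = None
    mask: np.ndarray | None = None
    mean_individual_area_mm2: float | None = None
    canines: np.ndarray | None = None  # cohort-mean canine points, (2, 2)

    @property
    def average_area_mm2(self) -> float | None:
        if self.mask is None:
            return None
        return float(self.mask.sum()) * self.spacing[0] * self.spacing[1]

    def as_arch_image(self) -> ArchImage:
        if self.mask is None:
            raise ValueError("average arch has not been thresholded yet")
        return ArchImage(self.mask, self.spacing, self.origin,
                         reference=(0.0, 0.0), canines=self.canines)


def build_arch_image(
    mask: BinaryVolume3D,
    dental_band: tuple[float, float],
    ramus_band: tuple[float, float],
    canines: np.ndarray,
) -> ArchImage:
    """Axial MIP of the segmented mandible over the dental and ramus bands.

    ``dental_band`` and ``ramus_band`` are (z_lo, z_hi) in world mm; the
    projection runs over their union, then only the largest component is
    kept (the temporal bone may survive segmentation).  ``canines`` are the
    two distal contact points (world mm, right then left); the reference is
    their axial midpoint.
    """
    zc = mask.axis_coords(2)
    sel = np.zeros(zc.shape, bool)
    for z_lo, z_hi in (dental_band, ramus_band):
        sel |= (zc >= min(z_lo, z_hi) - 1e-9) & (zc <= max(z_lo, z_hi) + 1e-9)
    if not sel.any():
        raise ValueError("projection bands do not intersect the mask's Z extent")
    proj = mask.data[:, :, sel].any(axis=2)
    if not proj.any():
        raise ValueError("empty arch projection: no foreground in the selected bands")
    proj = largest_component(proj)
    canines = np.asarray(canines, float)[:, :2]
    reference = canines.mean(axis=0)
    return ArchImage(
        proj,
        spacing=(mask.spacing[0], mask.spacing[1]),
        origin=(mask.origin[0], mask.origin[1]),
        reference=reference,
        canines=canines,
    )


def superimpose_arches(arches: list[ArchImage]) -> AverageArch:
    """Translate every arch so its reference lands on a common origin,
    then average the binary masks into a per-pixel frequency map.

    Translation is by whole pixels (the masks stay binary); all arches must
    share the same pixel spacing.
    """
    if not arches:
        raise ValueError("need at least one arch image")
    spacing = arches[0].spacing
    for a in arches[1:]:
        if not np.allclose(a.spacing, spacing):
            raise ValueError(
                "mixed pixel spacing between arch images; resample to a "
                "common spacing before superimposing"
            )
    # integer pixel offset of each arch's pixel (0,0) relative to its
    # (nearest-pixel) reference
    offsets = []
    for a in arches:
        ref_px = np.round((a.reference - np.asarray(a.origin)) / np.asarray(spacing)).astype(int)
        offsets.append(-ref_px)
    offsets = np.asarray(offsets)
    shapes = np.asarray([a.mask.shape for a in arches])
    lo = offsets.min(axis=0)
    hi = (offsets + shapes).max(axis=0)
    canvas = np.zeros(tuple(hi - lo), float)
    for a, off in zip(arches, offsets):
        i0, j0 = off - lo
        canvas[i0:i0 + a.mask.shape[0], j0:j0 + a.mask.shape[1]] += a.mask
    freq = canvas / len(arches)
    origin = tuple(lo * np.asarray(spacing))
    canine_sets = [a.canines for a in arches if a.canines is not None]
    canines = None
    if len(canine_sets) == len(arches):
        canines = np.mean([c - a.reference for c, a in zip(canine_sets, arches)], axis=0)
    return AverageArch(freq, spacing, origin, n_subjects=len(arches), canines=canines)


def area_matched_threshold(
    avg: AverageArch | np.ndarray,
    individual_areas: list[float],
    cfg: PipelineConfig | None = None,
    pixel_area: float | None = None,
) -> tuple[float, np.ndarray]:
    """Pick the frequency threshold whose mask area best matches the mean
    individual arch area.

    Candidates are the grid {step, 2 step, ..., 1.0}.  Ties are broken
    toward the candidate nearest 0.5 (with more subjects the matched
    threshold converges there), then toward the lower candidate.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(avg, AverageArch):
        freq = avg.frequency
        pixel_area = avg.spacing[0] * avg.spacing[1]
    else:
        freq = np.asarray(avg, float)
        if pixel_area is None:
            pixel_area = 1.0
    if freq.size == 0 or not np.any(freq > 0):
        raise ValueError("empty frequency map")
    if not individual_areas:
        raise ValueError("need at least one individual arch area")
    target = float(np.mean(individual_areas))
    step = cfg.threshold_grid_step
    n_cand = int(round(1.0 / step))
    candidates = np.round(np.arange(1, n_cand + 1) * step, 12)
    areas = np.array([
        float(np.count_nonzero(freq >= t - 1e-9)) * pixel_area for t in candidates
    ])
    err = np.abs(areas - target)
    # lexicographic tie-break: |area error|, then |t - 0.5|, then t
    order = np.lexsort((candidates, np.abs(candidates - 0.5), np.round(err, 9)))
    best = order[0]
    t_star = float(candidates[best])
    mask = freq >= t_star - 1e-9
    log.info("area-matched threshold t*=%.2f (mask area %.2f mm^2, target %.2f mm^2)",
             t_star, areas[best], target)
    if isinstance(avg, AverageArch):
        avg.threshold = t_star
        avg.mask = mask
        avg.mean_individual_area_mm2 = target
    return t_star, mask


# --------------------------------------------------------------------------
# centerline extraction
# --------------------------------------------------------------------------

def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    pts = np.argwhere(skel)
    pset = set(map(tuple, pts))
    for i, j in pts:
        g.add_node((i, j))
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                q = (i + di, j + dj)
                if q in pset:
                    g.add_edge((i, j), q, weight=float(np.hypot(di, dj)))
    # drop diagonal edges short-circuited by an orthogonal corner pixel:
    # 8-connected skeletons form 3-cliques at corners that would otherwise
    # masquerade as branch points
    for a, b in list(g.edges):
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 2 and a[0] != b[0] and a[1] != b[1]:
            if ((a[0], b[1]) in pset) or ((b[0], a[1]) in pset):
                g.remove_edge(a, b)
    return g


def _prune_spurs(g: nx.Graph, min_length: float) -> nx.Graph:
    """Iteratively remove endpoint branches shorter than ``min_length``.

    All offending branches of one iteration are removed together: a blunt
    band end sprouts a *pair* of corner branches from one junction, and
    removing them one at a time would dissolve the junction after the
    first, grafting the second corner onto the main path.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        junctions = {n for n in g if g.degree(n) >= 3}
        if not junctions:
            break
        to_remove: set = set()
        for end in [n for n in g if g.degree(n) == 1]:
            path = [end]
            length = 0.0
            cur, prev = end, None
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if cur in junctions or not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["weight"]
                path.append(nxt)
                prev, cur = cur, nxt
                if cur in junctions:
                    break
            if cur in junctions and length < min_length:
                to_remove.update(path[:-1])
        if to_remove:
            g.remove_nodes_from(to_remove)
            changed = True
    return g


def arch_centerline(
    mask: ArchImage | np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Ordered centerline (mm) of a connected arch band.

    The morphological skeleton is pruned of spurs shorter than 5% of the
    total skeleton length; the surviving path is returned ordered from the
    right-posterior end (smaller X) to the left-posterior end.
    """
    if isinstance(mask, ArchImage):
        data, spacing, origin = mask.mask, mask.spacing, mask.origin
    else:
        data = np.asarray(mask, bool)
    if not data.any():
        raise DisconnectedMaskError("empty mask has no centerline")
    n_comp = measure.label(data, connectivity=2).max()
    if n_comp != 1:
        raise DisconnectedMaskError(f"mask has {n_comp} components; expected one band")
    skel = morphology.skeletonize(data)
    g = _skeleton_graph(skel)
    total = sum(d["weight"] for _, _, d in g.edges(data=True))
    # prune spurs shorter than 5% of the skeleton length, and in any case
    # shorter than the band radius: blunt band ends sprout corner
    # ("fishtail") branches up to ~0.7 band widths long that are artifacts
    # of the discrete medial axis, not arch geometry
    radius_px = float(ndimage.distance_transform_edt(data).max())
    g = _prune_spurs(g, max(0.05 * total, 1.6 * radius_px))
    branches = [n for n in g if g.degree(n) > 2]
    if branches:
        raise SkeletonBranchError(
            f"skeleton retains {len(branches)} branch point(s) after pruning; "
            "no single dominant path"
        )
    ends = [n for n in g if g.degree(n) == 1]
    if len(ends) != 2:
        raise SkeletonBranchError(
            f"pruned skeleton has {len(ends)} endpoints; expected an open path"
        )
    path = nx.shortest_path(g, ends[0], ends[1])
    px = np.asarray(path, float)
    # trim end runs that hug the mask boundary: at a blunt band end the
    # discrete skeleton may bend along the cut edge toward a corner
    # (distance-to-boundary near zero) instead of stopping at the medial
    # endpoint (distance ~ half the band width).  An end pixel is dropped
    # while the band is substantially thicker one band-width further along.
    dt = ndimage.distance_transform_edt(data)
    dtv = dt[tuple(np.asarray(path).T)]
    m = max(3, int(round(float(dt.max()))))
    limit = len(px) // 4
    i0 = 0
    while i0 < min(limit, len(px) - m - 1) and dtv[i0] < 0.85 * dtv[i0 + m]:
        i0 += 1
    i1 = len(px)
    while i1 > max(len(px) - limit, i0 + m + 1) and dtv[i1 - 1] < 0.85 * dtv[i1 - 1 - m]:
        i1 -= 1
    px = px[i0:i1]

    def _dir(a, b):
        v = px[b] - px[a]
        n = np.linalg.norm(v)
        return v / n if n else v

    # a second, directional guard: drop end pixels while the local path
    # direction disagrees by more than ~25 degrees with the direction one
    # band-width further in (the skeleton tail curling around a corner)
    j0, j1 = 0, len(px)
    while j1 - j0 > 2 * m + 8 and _dir(j0, j0 + 3) @ _dir(j0 + m, j0 + m + 3) < 0.9:
        j0 += 1
    while j1 - j0 > 2 * m + 8 and _dir(j1 - 4, j1 - 1) @ _dir(j1 - m - 4, j1 - m - 1) < 0.9:
        j1 -= 1
    px = px[j0:j1]
    pts = np.asarray(origin) + px * np.asarray(spacing)
    if pts[0, 0] > pts[-1, 0]:  # order right (smaller X) -> left
        pts = pts[::-1]
    return pts
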