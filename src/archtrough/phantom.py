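"""Synthetic CBCT-like phantoms with known mandible geometry.

The phantom emulates, at the level the pipeline cares about, a skull-like
volume: a U-shaped mandibular band in the axial plane extruded in Z, joined
to straight ascending rami with condylar knobs on top, embedded in a
soft-tissue head outline, with optional cervical-"vertebra" and cranial-slab
confounders, a smooth multiplicative bias field and Gaussian noise.

The axial centerline has three closed-form pieces per side:

* a parabolic dental arch ``u = a (x/b)**2`` (``u`` = depth posterior to the
  anterior apex), whose tangent angle to the midsagittal axis falls from 90
  degrees at the apex to ``atan(b/(2a))`` at the parabola end;
* a circular junction arc of radius ``R`` that turns the tangent outward
  from ``atan(b/(2a))`` up to the ramus angle ``theta`` (C1 at both ends);
* a straight ramus segment at constant tangent angle ``theta``.

On the junction arc the magnitude of ``d2x/du2`` (lateral offset vs.
posterior coordinate) *increases* to its maximum exactly at the arc-to-line
joint, so the curvature-peak definition of the dental-arch-to-ramus
transition has a unique, analytically known answer: the joint location and
slope ``theta``.  A direct tangent-continuous parabola-to-line join would
instead place the curvature maximum at the anterior end of any search
window, leaving the transition undefined; the short arc is also what real
mandibles show between the molar row and the ascending ramus.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import BinaryVolume3D, LandmarkSet, Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "GeometryError",
    "generate_phantom",
    "generate_cohort",
]


class GeometryError(ValueError):
    """The requested phantom geometry is self-intersecting or inconsistent."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Lengths in mm, angles in degrees, intensities in arbitrary units with
    ``bone > soft tissue > background``.
    """

    shape: tuple[int, int, int] = (220, 220, 180)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    #: if None, the X origin is chosen so the grid is symmetric about X=0
    origin: tuple[float, float, float] | None = None

    # axial centerline geometry
    arch_depth_mm: float = 40.0          # parabola depth a (apex to parabola end)
    arch_half_width_mm: float = 30.0     # parabola half-width b at depth a
    ramus_angle_deg: float = 40.0        # tangent of the ramus to the midsagittal axis
    junction_radius_mm: float = 12.0     # radius of the arch-to-ramus junction arc
    ramus_length_mm: float = 20.0
    canine_offset_mm: float = 8.0        # canine depth posterior to the apex

    # band and vertical extents
    band_width_mm: float = 12.0          # buccolingual band width w at the apex
    band_width_slope: float = 0.0        # dw/ds per mm of arc length from the apex
    apex_y_mm: float = 25.0
    occlusal_z_mm: float = 0.0
    body_depth_mm: float = 25.0          # mandible body below the occlusal plane
    ramus_height_mm: float = 40.0        # ascending ramus above the occlusal plane
    condyle_radius_mm: float = 6.0

    # tissue intensities
    bone_intensity: float = 0.8
    soft_tissue_intensity: float = 0.12
    background_intensity: float = 0.0
    include_soft_tissue: bool = True

    # confounders
    include_vertebra: bool = False
    vertebra_radius_mm: float = 8.0
    vertebra_gap_mm: float = 3.0         # clearance behind the posterior band edge
    include_cranium: bool = False
    cranium_gap_mm: float = 4.0          # clearance above the condyle tops

    # corruption
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    #: optional fixed linear bias direction (cx, cy, cz); None draws a smooth
    #: random low-order polynomial from the seed
    bias_coeffs: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.origin is None:
            ox = -(self.shape[0] - 1) * self.spacing[0] / 2.0
            self.origin = (ox, -75.0, -35.0)
        self.origin = tuple(float(o) for o in self.origin)
        if min(self.arch_depth_mm, self.arch_half_width_mm, self.band_width_mm) <= 0:
            raise GeometryError("arch depth, half-width and band width must be > 0")
        if not (0.0 < self.ramus_angle_deg < 90.0):
            raise GeometryError("ramus angle must be in (0, 90) degrees")
        if not self.bone_intensity > self.soft_tissue_intensity > self.background_intensity:
            raise GeometryError("need bone > soft tissue > background intensity")
        phi_p = np.degrees(np.arctan(self.arch_half_width_mm / (2 * self.arch_depth_mm)))
        if self.ramus_angle_deg <= phi_p:
            raise GeometryError(
                f"ramus angle {self.ramus_angle_deg:.1f} deg must exceed the parabola "
                f"end tangent {phi_p:.1f} deg for an outward junction arc"
            )
        # band self-intersection: half-width must stay below the smallest
        # radius of curvature (parabola apex b^2/2a, junction arc R)
        r_min = min(self.arch_half_width_mm**2 / (2 * self.arch_depth_mm),
                    self.junction_radius_mm)
        if self.band_width_mm / 2.0 >= r_min:
            raise GeometryError(
                f"band half-width {self.band_width_mm / 2:.1f} mm >= minimum "
                f"centerline curvature radius {r_min:.1f} mm: band self-intersects"
            )
        if not (0 < self.canine_offset_mm < self.arch_depth_mm):
            raise GeometryError("canine offset must lie within the parabolic arch")


@dataclass
class PhantomGroundTruth:
    """Analytic truth accompanying one generated phantom."""

    centerline: np.ndarray          # (N, 2) axial mm, right-posterior -> left-posterior
    arc_length: np.ndarray          # (N,) cumulative arc length along `centerline`
    half_width: np.ndarray          # (N,) w(s)/2 at each centerline sample
    landmarks: LandmarkSet
    mask: BinaryVolume3D            # true mandible (band + rami + condyles)
    theta_deg: float
    transition_lateral_mm: float    # |X| of the arc-to-ramus joint
    transition_posterior_mm: float  # canine-midpoint Y minus joint Y
    joint_xy: np.ndarray            # (2,) axial position of the left-side joint
    band_area_mm2: float            # analytic integral of w(s) ds
    canine_mid: np.ndarray          # (2,) axial mm


# --------------------------------------------------------------------------
# centerline geometry
# --------------------------------------------------------------------------

def _side_centerline(spec: PhantomSpec, step: float = 0.2):
    """Left-side (x >= 0) centerline samples, apex -> ramus end.

    Returns (points (N,2), arc length from apex (N,), joint position (2,),
    arc length of the arc-to-line joint).
    """
    a = spec.arch_depth_mm
    b = spec.arch_half_width_mm
    theta = np.radians(spec.ramus_angle_deg)
    phi_p = np.arctan(b / (2 * a))
    R = spec.junction_radius_mm
    y0 = spec.apex_y_mm

    # parabola sampled uniformly in x (du/dx bounded, near-uniform arc)
    nx = max(int(np.ceil(b / step)) * 2, 16)
    x = np.linspace(0.0, b, nx)
    par = np.column_stack([x, y0 - a * (x / b) ** 2])

    # junction arc: dA/dphi = R (sin phi, -cos phi)
    E = np.array([b, y0 - a])
    nphi = max(int(np.ceil(R * (theta - phi_p) / step)), 8)
    phi = np.linspace(phi_p, theta, nphi + 1)
    arc = np.column_stack(
        [E[0] + R * (np.cos(phi_p) - np.cos(phi)), E[1] - R * (np.sin(phi) - np.sin(phi_p))]
    )
    joint = arc[-1].copy()

    # straight ramus
    nl = max(int(np.ceil(spec.ramus_length_mm / step)), 4)
    t = np.linspace(0.0, spec.ramus_length_mm, nl + 1)
    line = joint[None, :] + t[:, None] * np.array([np.sin(theta), -np.cos(theta)])[None, :]

    pts = np.vstack([par, arc[1:], line[1:]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_joint = float(s[len(par) + len(arc) - 2])  # index of the arc-to-line joint
    return pts, s, joint, s_joint


def _full_centerline(spec: PhantomSpec, step: float = 0.2):
    """Both sides, ordered right-posterior -> apex -> left-posterior."""
    left, s_side, joint, s_joint = _side_centerline(spec, step)
    right = left[1:][::-1] * np.array([-1.0, 1.0])
    pts = np.vstack([right, left])
    s_apex_dist = np.concatenate([s_side[1:][::-1], s_side])  # |arc dist to apex|
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s, s_apex_dist, joint, s_joint


def _width_at(spec: PhantomSpec, dist_from_apex: np.ndarray) -> np.ndarray:
    return spec.band_width_mm + spec.band_width_slope * dist_from_apex


# --------------------------------------------------------------------------
# rasterisation
# --------------------------------------------------------------------------

def _band_footprints(spec: PhantomSpec, xg: np.ndarray, yg: np.ndarray):
    """Axial footprints (band, ramus-only) on the pixel grid, flat-capped."""
    pts, _, s_apex, joint, s_joint = _full_centerline(spec)
    tree = cKDTree(pts)
    px, py = np.meshgrid(xg, yg, indexing="ij")
    q = np.column_stack([px.ravel(), py.ravel()])
    dist, idx = tree.query(q)
    half_w = _width_at(spec, s_apex[idx]) / 2.0
    inside = dist <= half_w
    # flat caps: drop pixels lying beyond either ramus end along the tangent
    for end_idx, prev_idx in ((0, 1), (len(pts) - 1, len(pts) - 2)):
        outward = pts[end_idx] - pts[prev_idx]
        outward /= np.linalg.norm(outward)
        at_end = idx == end_idx
        beyond = (q[at_end] - pts[end_idx]) @ outward > 0
        sel = np.nonzero(at_end)[0][beyond]
        inside[sel] = False
    ramus = inside & (s_apex[idx] > s_joint)
    shape = (xg.size, yg.size)
    return inside.reshape(shape), ramus.reshape(shape)


def _ellipse_footprint(xg, yg, cx, cy, rx, ry):
    px, py = np.meshgrid(xg, yg, indexing="ij")
    return ((px - cx) / rx) ** 2 + ((py - cy) / ry) ** 2 <= 1.0


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomGroundTruth]:
    """Render one phantom volume and its analytic ground truth."""
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    ox, oy, oz = spec.origin
    xg = ox + sx * np.arange(nx)
    yg = oy + sy * np.arange(ny)
    zg = oz + sz * np.arange(nz)

    band2d, ramus2d = _band_footprints(spec, xg, yg)

    occl = spec.occlusal_z_mm
    z_body = (zg >= occl - spec.body_depth_mm) & (zg <= occl)
    z_ramus = (zg > occl) & (zg <= occl + spec.ramus_height_mm)

    mask = band2d[:, :, None] & z_body[None, None, :]
    mask |= ramus2d[:, :, None] & z_ramus[None, None, :]

    # condylar knobs: spheres inset by one radius from each ramus end;
    # the radius is clamped to the local band half-width so the knob's
    # axial footprint stays inside the arch band
    pts, s_full, s_apex, joint, _ = _full_centerline(spec)
    theta = np.radians(spec.ramus_angle_deg)
    w_end = float(_width_at(spec, s_apex.max()))
    r_k = min(spec.condyle_radius_mm, w_end / 2.0)
    end_left = pts[-1]
    tangent_left = np.array([np.sin(theta), -np.cos(theta)])
    knob_left = end_left - r_k * tangent_left
    knob_z = occl + spec.ramus_height_mm
    for sgn in (+1.0, -1.0):
        cx_, cy_ = sgn * knob_left[0], knob_left[1]
        i0, i1 = np.searchsorted(xg, [cx_ - r_k - sx, cx_ + r_k + sx])
        j0, j1 = np.searchsorted(yg, [cy_ - r_k - sy, cy_ + r_k + sy])
        k0, k1 = np.searchsorted(zg, [knob_z - r_k - sz, knob_z + r_k + sz])
        sub = (
            (xg[i0:i1, None, None] - cx_) ** 2
            + (yg[None, j0:j1, None] - cy_) ** 2
            + (zg[None, None, k0:k1] - knob_z) ** 2
        ) <= r_k**2
        mask[i0:i1, j0:j1, k0:k1] |= sub

    vol = np.full(spec.shape, float(spec.background_intensity))
    condyle_top = knob_z + r_k

    if spec.include_soft_tissue:
        head = _ellipse_footprint(
            xg, yg,
            0.0, (spec.apex_y_mm + end_left[1]) / 2.0,
            end_left[0] + spec.band_width_mm / 2 + 6.0,
            (spec.apex_y_mm - end_left[1]) / 2 + spec.band_width_mm / 2 + 10.0,
        )
        soft3d = head[:, :, None] & (zg <= condyle_top)[None, None, :]
        vol[soft3d] = spec.soft_tissue_intensity
    else:
        head = None

    if spec.include_vertebra:
        vy = end_left[1] - spec.band_width_mm / 2 - spec.vertebra_gap_mm - spec.vertebra_radius_mm
        vert2d = _ellipse_footprint(xg, yg, 0.0, vy, spec.vertebra_radius_mm,
                                    spec.vertebra_radius_mm)
        vol[vert2d[:, :, None] & (zg <= occl)[None, None, :]] = spec.bone_intensity

    if spec.include_cranium:
        slab_lo = condyle_top + spec.cranium_gap_mm
        foot = head if head is not None else np.ones((nx, ny), bool)
        vol[foot[:, :, None] & (zg >= slab_lo)[None, None, :]] = spec.bone_intensity

    vol[mask] = spec.bone_intensity

    rng = np.random.default_rng(spec.seed)
    if spec.bias_amplitude > 0:
        xh = (xg - xg.mean()) / (np.ptp(xg) / 2)
        yh = (yg - yg.mean()) / (np.ptp(yg) / 2)
        zh = (zg - zg.mean()) / (np.ptp(zg) / 2)
        if spec.bias_coeffs is not None:
            cx_, cy_, cz_ = spec.bias_coeffs
            bias = (cx_ * xh[:, None, None] + cy_ * yh[None, :, None]
                    + cz_ * zh[None, None, :])
        else:
            c = rng.uniform(-1, 1, size=6)
            bias = (
                c[0] * xh[:, None, None]
                + c[1] * yh[None, :, None]
                + c[2] * zh[None, None, :]
                + c[3] * xh[:, None, None] * yh[None, :, None]
                + c[4] * xh[:, None, None] * zh[None, None, :]
                + c[5] * yh[None, :, None] * zh[None, None, :]
            )
        peak = np.abs(bias).max()
        if peak > 0:
            bias /= peak
        vol = vol * (1.0 + spec.bias_amplitude * bias)
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)

    # landmarks (world mm) -------------------------------------------------
    c_par = spec.arch_half_width_mm / np.sqrt(spec.arch_depth_mm)
    u_c = spec.canine_offset_mm
    canine_x = c_par * np.sqrt(u_c)
    canine_y = spec.apex_y_mm - u_c
    molar_u = 0.9 * spec.arch_depth_mm
    coronal_z = condyle_top + 2.0
    frank_z = min(condyle_top + 2.0, zg[-1])
    landmarks = LandmarkSet({
        "frankfort_orbit": (0.0, spec.apex_y_mm - 2.0, frank_z),
        "frankfort_meatus": (0.0, end_left[1] - 2.0, frank_z),
        "coronal_right": (-end_left[0], end_left[1], min(coronal_z, zg[-1])),
        "coronal_left": (end_left[0], end_left[1], min(coronal_z, zg[-1])),
        "occlusal_anterior": (0.0, spec.apex_y_mm, occl),
        "occlusal_posterior": (c_par * np.sqrt(molar_u), spec.apex_y_mm - molar_u, occl),
        "condyle_a": (-knob_left[0], knob_left[1], min(condyle_top, zg[-1])),
        "condyle_b": (knob_left[0], knob_left[1], min(condyle_top, zg[-1])),
        "canine_right": (-canine_x, canine_y, occl),
        "canine_left": (canine_x, canine_y, occl),
    })

    half_width = _width_at(spec, s_apex) / 2.0
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    band_area = float(np.sum((half_width[:-1] + half_width[1:]) * seg))  # trapezoid of w(s)

    truth = PhantomGroundTruth(
        centerline=pts,
        arc_length=s_full,
        half_width=half_width,
        landmarks=landmarks,
        mask=BinaryVolume3D(mask, spec.spacing, spec.origin),
        theta_deg=spec.ramus_angle_deg,
        transition_lateral_mm=float(abs(joint[0])),
        transition_posterior_mm=float(canine_y - joint[1]),
        joint_xy=joint,
        band_area_mm2=band_area,
        canine_mid=np.array([0.0, canine_y]),
    )
    volume = Volume3D(vol, spec.spacing, spec.origin)
    return volume, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

#: parameters scaled by a fractional-variability cohort draw
_VARIED = (
    "arch_depth_mm",
    "arch_half_width_mm",
    "ramus_angle_deg",
    "junction_radius_mm",
    "ramus_length_mm",
    "band_width_mm",
    "canine_offset_mm",
)


def _sub_seed(master_seed: int, params: dict) -> int:
    """Deterministic per-phantom seed from the drawn parameters.

    Hashing the parameters (instead of drawing a fresh seed per subject)
    makes a zero-variability cohort bit-identical to n copies of the base
    phantom while still decorrelating noise across distinct subjects.
    """
    key = repr(sorted((k, round(float(v), 9)) for k, v in params.items()))
    return (int(master_seed) ^ zlib.crc32(key.encode())) % (2**31)


def generate_cohort(
    base_spec: PhantomSpec,
    n: int,
    variability: float | dict[str, float] = 0.0,
    seed: int = 0,
) -> list[tuple[Volume3D, PhantomGroundTruth]]:
    """Draw ``n`` phantoms with Gaussian parameter variation around a base.

    ``variability`` is either a fractional standard deviation applied to
    each geometric parameter, or a mapping ``{field: absolute sd}``.
    Draws violating the geometry invariants are rejected and redrawn (at
    most 100 times per subject).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(variability, dict):
        sds = {k: float(v) for k, v in variability.items()}
    else:
        frac = float(variability)
        sds = {k: frac * abs(getattr(base_spec, k)) for k in _VARIED}
    out = []
    for _ in range(n):
        for attempt in range(100):
            params = {k: float(getattr(base_spec, k)) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                      for k, sd in sds.items()}
            try:
                spec = dataclasses.replace(
                    base_spec, seed=_sub_seed(seed, params), **params
                )
                break
            except GeometryError:
                continue
        else:
            raise GeometryError(
                "could not draw a valid phantom spec in 100 attempts; "
                "reduce the requested variability"
            )
        out.append(generate_phantom(spec))
    return out
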