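"""Focal trough geometry: center and boundary curves, thickness, transition.

The panoramic focal trough is modelled by three piecewise-cubic smoothing
splines fitted to the average arch shape: the center (from the arch
skeleton) and the buccal and lingual boundaries (from the arch contour
along center normals).  Because a panoramic focal trough is bilaterally
symmetric, right and left sides are averaged at matching arc-length
fractions before fitting.

A cubic smoothing spline here minimizes ``p * sum(residual^2) +
(1 - p) * integral(f'')^2`` with ``p`` in (0, 1]; ``p = 1`` interpolates.

The dental-arch-to-ramus transition is the curvature peak of the lateral
offset ``x`` expressed against the posterior coordinate ``u`` (mm posterior
to the canine midpoint): its location is the maximum of ``|d2x/du2|`` and
its slope is ``atan(dx/du)`` there, in degrees from the midsagittal axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import PPoly, make_smoothing_spline
from skimage import measure

from .config import PipelineConfig
from .arch_model import ArchImage
from .io_formats import SplineRecord

__all__ = [
    "FittedCurve1D",
    "FittedCurve",
    "TroughModel",
    "ThicknessProfile",
    "TransitionResult",
    "OneSidedInputError",
    "TroughFitError",
    "NoTransitionError",
    "symmetrize",
    "fit_smoothing_spline",
    "fit_trough",
    "thickness_profile",
    "regional_minima",
    "locate_transition",
]

log = logging.getLogger(__name__)


class OneSidedInputError(ValueError):
    """Symmetrization needs samples on both sides of the midsagittal axis."""


class TroughFitError(ValueError):
    """Boundary extraction failed on too many centerline samples."""


class NoTransitionError(ValueError):
    """The center curve has no curvature peak posterior to the canines."""


# --------------------------------------------------------------------------
# splines
# --------------------------------------------------------------------------

@dataclass
class FittedCurve1D:
    """One fitted coordinate as an explicit piecewise cubic polynomial."""

    breaks: np.ndarray            # (m+1,) knots of the m cubic pieces
    coefficients: np.ndarray      # (4, m), highest power first (PPoly layout)

    def __post_init__(self):
        self.breaks = np.asarray(self.breaks, float)
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape[0] != 4:
            raise ValueError("cubic pieces need exactly 4 coefficients")
        self._pp = PPoly(self.coefficients, self.breaks, extrapolate=True)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.breaks[0]), float(self.breaks[-1])

    def __call__(self, t, nu: int = 0) -> np.ndarray:
        return self._pp(t, nu=nu)

    def to_record(self, name: str) -> SplineRecord:
        return SplineRecord(
            name=name,
            breaks=list(self.breaks),
            coefficients=[list(self.coefficients[:, i]) for i in range(self.coefficients.shape[1])],
        )


def fit_smoothing_spline(params: np.ndarray, values: np.ndarray, p: float) -> FittedCurve1D:
    """Fit a cubic smoothing spline to ordered (parameter, value) samples.

    ``p`` in (0, 1] weights fidelity against the integrated squared second
    derivative; the objective is equivalent to the classic penalized form
    with roughness weight ``lam = (1 - p) / p``, so ``p = 1`` interpolates.
    """
    x = np.asarray(params, float).ravel()
    y = np.asarray(values, float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples to fit a cubic smoothing spline")
    if np.any(np.diff(x) <= 0):
        raise ValueError("parameters must be strictly increasing (no duplicates)")
    if not (0 < p <= 1):
        raise ValueError("smoothing parameter p must be in (0, 1]")
    lam = (1.0 - p) / p
    spl = make_smoothing_spline(x, y, lam=lam)
    pp = PPoly.from_spline(spl)
    keep = np.diff(pp.x) > 0  # drop the zero-width end intervals of the B-spline basis
    breaks = np.concatenate([pp.x[:-1][keep], [pp.x[-1]]])
    coeffs = pp.c[:, keep]
    return FittedCurve1D(breaks, coeffs)


@dataclass
class FittedCurve:
    """A planar curve: two piecewise cubics sharing an arc-length parameter."""

    x: FittedCurve1D
    y: FittedCurve1D

    @property
    def domain(self) -> tuple[float, float]:
        return self.x.domain

    def __call__(self, s, nu: int = 0) -> np.ndarray:
        s = np.asarray(s, float)
        return np.stack([self.x(s, nu=nu), self.y(s, nu=nu)], axis=-1)

    def tangent(self, s) -> np.ndarray:
        d = self(s, nu=1)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def normal(self, s) -> np.ndarray:
        t = self.tangent(s)
        return np.stack([-t[..., 1], t[..., 0]], axis=-1)


# --------------------------------------------------------------------------
# symmetrization
# --------------------------------------------------------------------------

def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    pts = np.asarray(pts, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate polyline with zero length")
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def symmetrize(points: np.ndarray, axis_x: float, n_samples: int | None = None) -> np.ndarray:
    """Average an ordered polyline with its mirror image about ``X = axis_x``.

    Each point at arc-length fraction ``u`` is paired with the reflection of
    the point at fraction ``1 - u``; the mean of the pair replaces both.
    The output polyline is exactly mirror-symmetric and inherits the input
    ordering (right end first).  Input lying entirely on one side of the
    axis is rejected.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("expected an ordered (N, 2) polyline")
    if pts[:, 0].min() >= axis_x or pts[:, 0].max() <= axis_x:
        raise OneSidedInputError(
            "polyline lies entirely on one side of the midsagittal axis; "
            "cannot pair left and right sides"
        )
    if n_samples is None:
        n_samples = max(len(pts), 201)
        if n_samples % 2 == 0:
            n_samples += 1
    rs = _resample_polyline(pts, n_samples)
    mirrored = rs[::-1].copy()
    mirrored[:, 0] = 2.0 * axis_x - mirrored[:, 0]
    avg = 0.5 * (rs + mirrored)
    # re-resample to uniform arc length so the result is a fixed point of
    # this operation (averaging alters local point spacing)
    return _resample_polyline(avg, n_samples)


# --------------------------------------------------------------------------
# trough fitting
# --------------------------------------------------------------------------

def _mask_contours_mm(arch: ArchImage) -> list[np.ndarray]:
    cs = measure.find_contours(arch.mask.astype(float), 0.5)
    out = []
    for c in cs:
        out.append(np.asarray(arch.origin) + c * np.asarray(arch.spacing))
    return out


def _ray_band_crossings(p: np.ndarray, n: np.ndarray, segs_a: np.ndarray, segs_d: np.ndarray):
    """Signed distances t along ``p + t n`` of all contour crossings."""
    denom = n[0] * segs_d[:, 1] - n[1] * segs_d[:, 0]
    rel = segs_a - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * segs_d[:, 1] - rel[:, 1] * segs_d[:, 0]) / denom
        u = (rel[:, 0] * n[1] - rel[:, 1] * n[0]) / denom
    ok = np.isfinite(t) & (u >= 0.0) & (u < 1.0)
    return t[ok]


@dataclass
class TroughModel:
    """The fitted focal trough of one (average) arch shape."""

    center: FittedCurve
    buccal: FittedCurve
    lingual: FittedCurve
    canine_mid: np.ndarray          # (2,) axial mm
    canine_s: tuple[float, float]   # arc-length positions of the two canines
    axis_x: float
    #: measured (symmetrized) contour-crossing offsets along the center
    #: normals, kept for thickness evaluation: (s, buccal t, lingual t)
    offsets: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def s_apex(self) -> float:
        lo, hi = self.center.domain
        return 0.5 * (lo + hi)   # the anterior midline, by mirror symmetry

    def spline_records(self) -> list[SplineRecord]:
        recs = []
        for name, curve in (("center", self.center), ("buccal", self.buccal),
                            ("lingual", self.lingual)):
            recs.append(curve.x.to_record(f"{name}_x"))
            recs.append(curve.y.to_record(f"{name}_y"))
        return recs


def fit_trough(
    arch: ArchImage,
    centerline: np.ndarray,
    canines: np.ndarray,
    cfg: PipelineConfig | None = None,
    n_samples: int = 301,
) -> TroughModel:
    """Fit center, buccal and lingual curves of the focal trough.

    ``centerline`` is the ordered skeleton polyline (mm) of the arch mask;
    ``canines`` the two distal contact points (right, left; axial mm).  The
    centerline is symmetrized about the vertical axis through the canine
    midpoint and spline-fitted per coordinate against arc length; at every
    center sample the local normal is intersected with the mask contour to
    find the outer (buccal) and inner (lingual) boundary points, which are
    symmetrized and fitted the same way.
    """
    cfg = cfg or PipelineConfig()
    canines = np.asarray(canines, float).reshape(2, 2)
    canine_mid = canines.mean(axis=0)
    axis_x = float(canine_mid[0])
    if n_samples % 2 == 0:
        n_samples += 1
    sym = symmetrize(centerline, axis_x, n_samples=n_samples)
    seg = np.linalg.norm(np.diff(sym, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    p = cfg.spline_smoothing
    cx = fit_smoothing_spline(s, sym[:, 0], p)
    cy = fit_smoothing_spline(s, sym[:, 1], p)
    center = FittedCurve(cx, cy)

    pts = center(s)
    normals = center.normal(s)
    contours = _mask_contours_mm(arch)
    if not contours:
        raise TroughFitError("mask has no contour")
    segs_a = np.vstack([c[:-1] for c in contours])
    segs_d = np.vstack([np.diff(c, axis=0) for c in contours])

    # side of the normal facing the arch interior (lingual side); majority
    # vote keeps the assignment consistent for straight bands where the
    # interior reference is ambiguous
    ref = sym.mean(axis=0)
    dots = np.einsum("ij,ij->i", ref[None, :] - pts, normals)
    sgn = 1.0 if dots.sum() >= 0 else -1.0

    t_buccal = np.full(len(s), np.nan)
    t_lingual = np.full(len(s), np.nan)
    for i in range(len(s)):
        t_all = _ray_band_crossings(pts[i], normals[i], segs_a, segs_d)
        pos = t_all[t_all > 1e-9]
        neg = t_all[t_all < -1e-9]
        if pos.size == 0 or neg.size == 0:
            continue
        t_to_ref = pos.min() if sgn > 0 else neg.max()
        t_away = neg.max() if sgn > 0 else pos.min()
        t_lingual[i] = t_to_ref
        t_buccal[i] = t_away
    bad = ~(np.isfinite(t_buccal) & np.isfinite(t_lingual))
    if bad.mean() > 0.05:
        raise TroughFitError(
            f"normal failed to cross both contours at {bad.sum()}/{len(s)} samples"
        )
    if bad.any():  # fill rare gaps by interpolation along s
        good = ~bad
        t_buccal[bad] = np.interp(s[bad], s[good], t_buccal[good])
        t_lingual[bad] = np.interp(s[bad], s[good], t_lingual[good])

    # symmetrize the signed offsets (mirror samples correspond exactly)
    t_buccal = 0.5 * (t_buccal + t_buccal[::-1])
    t_lingual = 0.5 * (t_lingual + t_lingual[::-1])

    # trim the posterior end-taper: where a cohort's rami stop overlapping
    # the average band collapses, and skeleton + normals chase the ragged tip
    thick = np.abs(t_buccal - t_lingual)
    med = float(np.median(thick))
    low = thick < cfg.tail_trim_fraction * med
    n_trim = 0
    while n_trim < len(s) // 4 and (low[n_trim] or low[len(s) - 1 - n_trim]):
        n_trim += 1
    if n_trim:
        ds = (s[-1] - s[0]) / (len(s) - 1)
        n_trim = min(n_trim + int(np.ceil(cfg.tail_trim_margin_mm / ds)), len(s) // 4)
    if n_trim:
        log.info("trimmed %d tapered end sample(s) per side from the trough domain", n_trim)
        sl = slice(n_trim, len(s) - n_trim)
        s, sym = s[sl], sym[sl]
        t_buccal, t_lingual = t_buccal[sl], t_lingual[sl]
        cx = fit_smoothing_spline(s, sym[:, 0], p)
        cy = fit_smoothing_spline(s, sym[:, 1], p)
        center = FittedCurve(cx, cy)
        pts = center(s)
        normals = center.normal(s)

    bpts = pts + t_buccal[:, None] * normals
    lpts = pts + t_lingual[:, None] * normals
    buccal = FittedCurve(fit_smoothing_spline(s, bpts[:, 0], p),
                         fit_smoothing_spline(s, bpts[:, 1], p))
    lingual = FittedCurve(fit_smoothing_spline(s, lpts[:, 0], p),
                          fit_smoothing_spline(s, lpts[:, 1], p))

    # arc positions of the canines on the center curve
    d_r = np.linalg.norm(pts - canines[0], axis=1)
    d_l = np.linalg.norm(pts - canines[1], axis=1)
    canine_s = (float(s[np.argmin(d_r)]), float(s[np.argmin(d_l)]))
    return TroughModel(center, buccal, lingual, canine_mid, canine_s, axis_x,
                       offsets=(s.copy(), t_buccal.copy(), t_lingual.copy()))


# --------------------------------------------------------------------------
# thickness
# --------------------------------------------------------------------------

@dataclass
class ThicknessProfile:
    """Trough thickness against arc length from the anterior midline.

    ``s`` runs from 0 at the anterior midline to the posterior end of one
    side (the model is symmetric); ``canine_s`` marks the canine distal
    contact position on that axis.
    """

    s: np.ndarray
    thickness: np.ndarray
    canine_s: float
    anterior_min: float | None = None
    posterior_min: float | None = None


def thickness_profile(model: TroughModel, cfg: PipelineConfig | None = None) -> ThicknessProfile:
    """Distance between the buccal and lingual boundaries along the center.

    The boundary points were constructed along center normals, so the
    distance between the two fitted boundary curves at a shared arc
    parameter is the normal-wise trough thickness there.
    """
    cfg = cfg or PipelineConfig()
    lo, hi = model.center.domain
    s_apex = model.s_apex
    s = np.arange(s_apex, hi + 1e-9, cfg.thickness_step_mm)
    thick = np.linalg.norm(model.buccal(s) - model.lingual(s), axis=-1)
    if np.any(thick <= 0):
        raise TroughFitError("non-positive trough thickness encountered")
    canine_s = max(model.canine_s) - s_apex
    prof = ThicknessProfile(s - s_apex, thick, canine_s)
    prof.anterior_min, prof.posterior_min = regional_minima(prof)
    return prof


def regional_minima(profile: ThicknessProfile) -> tuple[float, float]:
    """Minimum thickness anterior (midline to canine) and posterior
    (canine to the posterior end) of the canine distal contact point."""
    ant = profile.thickness[profile.s <= profile.canine_s + 1e-9]
    post = profile.thickness[profile.s > profile.canine_s + 1e-9]
    if ant.size == 0 or post.size == 0:
        raise ValueError("empty anterior or posterior region in thickness profile")
    return float(ant.min()), float(post.min())


# --------------------------------------------------------------------------
# transition
# --------------------------------------------------------------------------

@dataclass
class TransitionResult:
    """Dental-arch-to-ramus transition, reported from the canine midpoint."""

    lateral_mm: float
    posterior_mm: float
    slope_deg: float
    per_side: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.lateral_mm < 0 or self.posterior_mm < 0:
            raise ValueError("transition offsets must be >= 0")
        if not (0.0 < self.slope_deg < 90.0):
            raise ValueError("transition slope must be in (0, 90) degrees")


def _side_transition(model: TroughModel, side: str, cfg: PipelineConfig):
    lo, hi = model.center.domain
    s_apex = model.s_apex
    if side == "left":
        s = np.arange(max(model.canine_s), hi, 0.25)
    else:
        s = np.arange(min(model.canine_s), lo, -0.25)
    if s.size < 8:
        raise NoTransitionError("center curve barely extends past the canines")
    pts = model.center(s)
    y_canine = float(model.center(np.array([max(model.canine_s)]))[0, 1])
    u = y_canine - pts[:, 1]          # mm posterior to the canine
    xi = np.abs(pts[:, 0] - model.axis_x)
    keep = u > 1e-6
    u, xi = u[keep], xi[keep]
    if u.size < 8:
        raise NoTransitionError("no usable posterior samples beyond the canine")
    mono = np.concatenate([[True], np.diff(u) > 1e-9])
    u, xi = u[mono], xi[mono]
    if u.size < 8:
        raise NoTransitionError("no usable posterior samples beyond the canine")
    # location: curvature peak of a heavily smoothed fit (second
    # derivatives amplify pixel noise); only interior peaks count, so a
    # rise cut off by the end margin cannot masquerade as the transition
    curve = fit_smoothing_spline(u, xi, cfg.transition_smoothing)
    u_hi = u[-1] - cfg.transition_end_margin_mm
    if u_hi <= u[0]:
        raise NoTransitionError("center curve too short posterior to the canine")
    ug = np.arange(u[0], u_hi, 0.05)
    curv = np.abs(curve(ug, nu=2))
    peaks, _ = signal.find_peaks(curv)
    i = int(peaks[np.argmax(curv[peaks])]) if peaks.size else int(np.argmax(curv))
    peak = float(curv[i])
    if peak < cfg.min_transition_curvature:
        raise NoTransitionError(
            f"no curvature peak: max |d2x/du2| = {peak:.2e} / mm"
        )
    u_star = float(ug[i])
    # slope: the tangent where the curve straightens into the ramus.  The
    # steepest lightly-smoothed tangent just past the peak is read first,
    # then clipped into a narrow band below the steepest heavily-smoothed
    # tangent of the whole post-transition section: the local estimate
    # carries pixel noise, the section-wide one rides over any overshoot
    # of the averaged curve, and each bounds the other.
    slope_curve = fit_smoothing_spline(u, xi, cfg.spline_smoothing)
    uw = np.arange(u_star, min(u_star + cfg.slope_window_mm, u[-1]), 0.05)
    t_local = float(np.abs(slope_curve(uw, nu=1)).max())
    uw2 = np.arange(u_star, min(u_star + cfg.transition_section_mm, u_hi), 0.05)
    t_section = float(np.abs(curve(uw2, nu=1)).max())
    t_final = min(max(t_local, 0.97 * t_section), t_section)
    slope = float(np.degrees(np.arctan(t_final)))
    lateral = float(curve(np.array([u_star]))[0])
    return {"lateral_mm": lateral, "posterior_mm": u_star, "slope_deg": slope}


def locate_transition(model: TroughModel, cfg: PipelineConfig | None = None) -> TransitionResult:
    """Find the arch-to-ramus transition on each side and average them.

    On each half the center is expressed as lateral offset vs. posterior
    coordinate; the transition is the maximum-|second derivative| point
    posterior to the canine, its slope the first derivative's angle there.
    """
    cfg = cfg or PipelineConfig()
    sides = [_side_transition(model, side, cfg) for side in ("right", "left")]
    return TransitionResult(
        lateral_mm=float(np.mean([d["lateral_mm"] for d in sides])),
        posterior_mm=float(np.mean([d["posterior_mm"] for d in sides])),
        slope_deg=float(np.mean([d["slope_deg"] for d in sides])),
        per_side=sides,
    )
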