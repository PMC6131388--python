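"""Pipeline constants.

Every number the procedure depends on lives here with its published default,
so a run can be audited or deliberately re-parameterised from a single YAML
file.  Magnifications are geometric similarity factors applied to binary
regions about their own centroid; the condyle ellipse axes are the
anteroposterior (Y) and superoinferior (Z) extents of the removal ellipse.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    #: similarity factor applied to detected vertebra regions before removal
    vertebra_magnification: float = 1.5
    #: similarity factor applied to the summed previous-slice mask
    mask_magnification: float = 1.2
    #: condyle-cap removal ellipse, (anteroposterior, superoinferior) mm
    condyle_ellipse_mm: tuple[float, float] = (15.0, 21.0)
    #: average tooth length; depth of the dental band below the occlusal plane
    tooth_length_mm: float = 20.0
    #: number of previous binarized slices summed into the propagation mask
    k_prev_slices: int = 3
    #: candidate-grid step of the average-arch threshold search
    threshold_grid_step: float = 0.01
    #: smoothing-spline parameter p in (0, 1] for the trough curves; at
    #: half-millimetre pixels this suppresses skeleton staircase noise
    #: while following the arch at the millimetre scale
    spline_smoothing: float = 0.5
    #: much heavier smoothing used when re-fitting lateral offset vs.
    #: posterior distance for curvature-peak (transition) detection
    transition_smoothing: float = 0.1
    #: arc-length sampling step of the thickness profile, mm
    thickness_step_mm: float = 0.5
    #: curvature magnitude (1/mm) below which no transition is declared
    min_transition_curvature: float = 1e-3
    #: posterior end samples whose local thickness falls below this fraction
    #: of the median are trimmed (cohort averages taper where subjects'
    #: rami stop overlapping), plus a fixed margin
    tail_trim_fraction: float = 0.9
    tail_trim_margin_mm: float = 1.5
    #: the transition slope is the steepest tangent within this arc window
    #: posterior of the curvature peak
    slope_window_mm: float = 2.0
    #: length of the post-transition section consulted when bounding the
    #: slope readout
    transition_section_mm: float = 6.0
    #: curvature-peak search excludes this margin at the posterior end of
    #: the curve, where spline end conditions make second derivatives
    #: unreliable
    transition_end_margin_mm: float = 4.0

    def __post_init__(self):
        self.condyle_ellipse_mm = tuple(float(v) for v in self.condyle_ellipse_mm)
        if self.vertebra_magnification <= 1 or self.mask_magnification <= 1:
            raise ValueError("magnifications must be > 1")
        if any(a <= 0 for a in self.condyle_ellipse_mm):
            raise ValueError("condyle ellipse axes must be > 0")
        if self.k_prev_slices < 1:
            raise ValueError("k_prev_slices must be >= 1")
        if not (0 < self.threshold_grid_step <= 1):
            raise ValueError("threshold_grid_step must be in (0, 1]")
        for p in (self.spline_smoothing, self.transition_smoothing):
            if not (0 < p <= 1):
                raise ValueError("smoothing parameters must be in (0, 1]")
        if self.tooth_length_mm <= 0 or self.thickness_step_mm <= 0:
            raise ValueError("lengths must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condyle_ellipse_mm"] = list(self.condyle_ellipse_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
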