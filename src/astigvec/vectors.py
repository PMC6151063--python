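"""Alpins-Method astigmatism vector mathematics.

Astigmatism is a 180°-periodic quantity: a cylinder of magnitude M at axis
θ is the same correction as M at θ + 180°.  The Alpins decomposition maps
each astigmatism vector onto a doubled-angle plane,

    X = M · cos(2θ),    Y = M · sin(2θ),

where astigmatism vectors add and subtract like ordinary plane vectors.
All surgical quantities are derived there:

* TIA (target-induced astigmatism): the change the surgery intended.
  With an emmetropic target it equals the preoperative astigmatism.
* SIA (surgically-induced astigmatism): the change achieved, computed as
  preop − postop componentwise on the doubled-angle plane.
* DV (difference vector): TIA − SIA, the remaining astigmatic error,
  ideally null.
* CI (correction index): |SIA| / |TIA|; 1 is ideal, > 1 overcorrection,
  < 1 undercorrection.  Undefined when |TIA| = 0.

Left-eye (OS) axes are mirrored about the vertical (θ → 180 − θ) before
any computation so that cyclotorsion-like errors from the two eyes do not
cancel when cohorts are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

__all__ = [
    "CylinderReading",
    "EyeRecord",
    "PolarVector",
    "RectVector",
    "EyeResult",
    "CohortSummary",
    "CISummary",
    "wrap_axis",
    "to_positive_cylinder",
    "mirror_os_axis",
    "polar_to_rect",
    "rect_to_polar",
    "compute_tia",
    "compute_sia",
    "compute_dv",
    "compute_ci",
    "summarize_vectors",
    "summarize_ci",
    "classify_orientation",
    "analyze_eye",
    "analyze_dataset",
]

#: Sanity bound on clinically plausible cylinder magnitude (diopters).
MAX_MAGNITUDE = 30.0


def wrap_axis(axis: float) -> float:
    """Wrap an axis in degrees into the canonical half-open range (0, 180].

    The 0° and 180° meridians are physically identical; following the
    clinical printing convention the 0° meridian is reported as 180.
    """
    a = math.fmod(axis, 180.0)
    if a < 0:
        a += 180.0
    return 180.0 if a == 0.0 else a


@dataclass(frozen=True)
class CylinderReading:
    """A cylinder measurement as a clinician records it.

    ``magnitude`` is signed: a negative sign encodes negative-cylinder
    notation.  ``axis`` is in degrees within [0, 180] (both endpoints are
    accepted on input; they denote the same meridian).
    """

    magnitude: float
    axis: float
    max_magnitude: float = field(default=MAX_MAGNITUDE, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude) or abs(self.magnitude) >= self.max_magnitude:
            raise ValueError(
                f"cylinder magnitude {self.magnitude!r} outside sane range "
                f"(|magnitude| < {self.max_magnitude} D)"
            )
        if not math.isfinite(self.axis) or not (0.0 <= self.axis <= 180.0):
            raise ValueError(f"axis {self.axis!r} not in [0, 180] degrees")


@dataclass(frozen=True)
class EyeRecord:
    """One eye's pre/postoperative cylinder pair.

    ``source_row`` is the 1-based row number in the originating file
    (0 for programmatically built records).
    """

    eye: Literal["OD", "OS"]
    preop: CylinderReading
    postop: CylinderReading
    source_row: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")


@dataclass(frozen=True)
class PolarVector:
    """A normalized positive-cylinder astigmatism vector.

    ``magnitude`` ≥ 0 D; ``axis`` in (0, 180].  A zero-magnitude vector
    carries no axis information and conventionally stores axis 180.
    """

    magnitude: float
    axis: float

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError(f"magnitude must be >= 0, got {self.magnitude!r}")
        if not (0.0 < self.axis <= 180.0):
            raise ValueError(f"axis {self.axis!r} not in (0, 180]")


@dataclass(frozen=True)
class RectVector:
    """Rectangular (X, Y) components on the doubled-angle plane, in diopters."""

    x: float
    y: float

    def __sub__(self, other: "RectVector") -> "RectVector":
        return RectVector(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class EyeResult:
    """Per-eye Alpins quantities: TIA, SIA, DV vectors and scalar CI.

    ``ci`` is ``None`` (undefined) iff the TIA magnitude is zero.
    """

    eye: Literal["OD", "OS"]
    tia: PolarVector
    sia: PolarVector
    dv: PolarVector
    ci: Optional[float]


@dataclass(frozen=True)
class CohortSummary:
    """Doubled-angle X/Y statistics and vector mean for one vector population."""

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    vector_mean: PolarVector
    arith_mean_magnitude: float
    n: int


@dataclass(frozen=True)
class CISummary:
    """Geometric-mean summary of the correction-index population.

    Undefined CIs (zero TIA) and CI == 0 values (log undefined) are
    excluded from the geometric mean and counted in ``n_excluded``.
    """

    geometric_mean: float
    n_defined: int
    n_excluded: int


def to_positive_cylinder(reading: CylinderReading) -> PolarVector:
    """Convert a signed cylinder reading to positive-cylinder notation.

    Negative-cylinder values are converted by taking the absolute
    magnitude and flipping the axis by 90°; e.g. −2.00 × 90 becomes
    +2.00 × 180 and −1.00 × 180 becomes +1.00 × 90.  Already-positive
    readings only have their axis wrapped into (0, 180].
    """
    if reading.magnitude < 0:
        return PolarVector(-reading.magnitude, wrap_axis(reading.axis + 90.0))
    return PolarVector(reading.magnitude, wrap_axis(reading.axis))


def mirror_os_axis(axis: float, eye: str) -> float:
    """Mirror a left-eye (OS) axis about the vertical meridian.

    OD axes pass through unchanged; OS axes map θ → 180 − θ, with a
    result of 0 reported as 180.  The mirror prevents symmetric
    cyclotorsion/healing errors of the two eyes from cancelling in
    cohort averages.
    """
    if eye == "OD":
        return axis
    if eye == "OS":
        return wrap_axis(180.0 - axis)
    raise ValueError(f"eye must be 'OD' or 'OS', got {eye!r}")


def polar_to_rect(v: PolarVector) -> RectVector:
    """Doubled-angle decomposition: x = M cos 2θ, y = M sin 2θ (θ in degrees)."""
    theta = math.radians(2.0 * v.axis)
    return RectVector(v.magnitude * math.cos(theta), v.magnitude * math.sin(theta))


def rect_to_polar(r: RectVector) -> PolarVector:
    """Recover (magnitude, axis) from doubled-angle components.

    magnitude = √(x² + y²); axis = ½·atan2(y, x) wrapped into (0, 180].
    The zero vector maps to magnitude 0 with conventional axis 180.
    """
    magnitude = math.hypot(r.x, r.y)
    if magnitude == 0.0:
        return PolarVector(0.0, 180.0)
    axis = wrap_axis(math.degrees(math.atan2(r.y, r.x)) / 2.0)
    return PolarVector(magnitude, axis)


def compute_tia(preop: PolarVector) -> PolarVector:
    """Target-induced astigmatism under an emmetropic target.

    The input format carries no refractive target, so the target is
    assumed to be emmetropia and the TIA equals the (normalized,
    mirrored) preoperative vector.
    """
    return preop


def compute_sia(preop: PolarVector, postop: PolarVector) -> PolarVector:
    """Surgically-induced astigmatism: preop − postop on the doubled-angle plane.

    The magnitude is √(SIA_X² + SIA_Y²) of the componentwise difference.
    """
    return rect_to_polar(polar_to_rect(preop) - polar_to_rect(postop))


def compute_dv(tia: PolarVector, sia: PolarVector) -> PolarVector:
    """Difference vector DV = TIA − SIA (vectorial, doubled-angle plane)."""
    return rect_to_polar(polar_to_rect(tia) - polar_to_rect(sia))


def compute_ci(sia: PolarVector, tia: PolarVector) -> Optional[float]:
    """Correction index CI = |SIA| / |TIA|, or ``None`` when |TIA| = 0.

    CI > 1 signals overcorrection, CI < 1 undercorrection, 1 an optimal
    outcome.  Undefined CI is a value, not an error; callers must handle
    ``None``.
    """
    if tia.magnitude == 0.0:
        return None
    return sia.magnitude / tia.magnitude


def summarize_vectors(vectors: Sequence[PolarVector]) -> CohortSummary:
    """Cohort summary of a vector population on the doubled-angle plane.

    X/Y means are arithmetic; SDs use the sample (n − 1) denominator and
    are 0 for n = 1.  The vector mean is the polar vector recovered from
    (mean_x, mean_y); ``arith_mean_magnitude`` averages raw magnitudes.
    """
    vectors = list(vectors)
    n = len(vectors)
    if n == 0:
        raise ValueError("cannot summarize an empty vector collection")
    rects = [polar_to_rect(v) for v in vectors]
    mean_x = math.fsum(r.x for r in rects) / n
    mean_y = math.fsum(r.y for r in rects) / n
    if n == 1:
        sd_x = sd_y = 0.0
    else:
        sd_x = math.sqrt(math.fsum((r.x - mean_x) ** 2 for r in rects) / (n - 1))
        sd_y = math.sqrt(math.fsum((r.y - mean_y) ** 2 for r in rects) / (n - 1))
    return CohortSummary(
        mean_x=mean_x,
        mean_y=mean_y,
        sd_x=sd_x,
        sd_y=sd_y,
        vector_mean=rect_to_polar(RectVector(mean_x, mean_y)),
        arith_mean_magnitude=math.fsum(v.magnitude for v in vectors) / n,
        n=n,
    )


def summarize_ci(cis: Iterable[Optional[float]]) -> CISummary:
    """Geometric-mean summary of correction indices.

    ``None`` (undefined, zero-TIA eyes) and CI == 0 values are excluded
    (the logarithm of zero is undefined) and counted.  Raises if nothing
    remains to average.
    """
    cis = list(cis)
    if not cis:
        raise ValueError("cannot summarize an empty CI collection")
    included = [c for c in cis if c is not None and c > 0.0]
    n_excluded = len(cis) - len(included)
    if not included:
        raise ValueError(
            "no defined, strictly positive correction indices to average "
            f"({n_excluded} excluded)"
        )
    log_mean = math.fsum(math.log(c) for c in included) / len(included)
    return CISummary(
        geometric_mean=math.exp(log_mean),
        n_defined=len(included),
        n_excluded=n_excluded,
    )


def classify_orientation(
    axis: float, boundary: Literal["oblique", "shaded"] = "oblique"
) -> str:
    """Label an axis as 'ATR', 'WTR' or 'oblique'.

    Sector bands follow the standard shaded single-angle plot layout:
    against-the-rule spans 0–30° and 150–180°, with-the-rule 60–120°,
    oblique the two unshaded 30–60° and 120–150° bands.  Axes exactly on
    a band boundary (30, 60, 120, 150) default to 'oblique'; pass
    ``boundary='shaded'`` to assign them to the adjacent shaded band
    instead.  Every axis in (0, 180] receives exactly one label.
    """
    if not (0.0 < axis <= 180.0):
        raise ValueError(f"axis {axis!r} not in (0, 180]")
    if boundary == "oblique":
        if 0.0 < axis < 30.0 or 150.0 < axis <= 180.0:
            return "ATR"
        if 60.0 < axis < 120.0:
            return "WTR"
        return "oblique"
    if boundary == "shaded":
        if axis <= 30.0 or axis >= 150.0:
            return "ATR"
        if 60.0 <= axis <= 120.0:
            return "WTR"
        return "oblique"
    raise ValueError(f"unknown boundary policy {boundary!r}")


def analyze_eye(record: EyeRecord) -> EyeResult:
    """Run the full per-eye Alpins pipeline.

    Order: convert both readings to positive cylinder, mirror OS axes,
    then TIA (emmetropic target), SIA, DV and CI.
    """
    preop = to_positive_cylinder(record.preop)
    postop = to_positive_cylinder(record.postop)
    preop = PolarVector(preop.magnitude, mirror_os_axis(preop.axis, record.eye))
    postop = PolarVector(postop.magnitude, mirror_os_axis(postop.axis, record.eye))
    tia = compute_tia(preop)
    sia = compute_sia(preop, postop)
    dv = compute_dv(tia, sia)
    ci = compute_ci(sia, tia)
    return EyeResult(eye=record.eye, tia=tia, sia=sia, dv=dv, ci=ci)


def analyze_dataset(records: Iterable[EyeRecord]) -> list[EyeResult]:
    """Analyze every record of a dataset, preserving order."""
    return [analyze_eye(r) for r in records]
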