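"""Synthetic pre/postoperative astigmatism cohorts with known ground truth.

Emulates the three demonstration cohorts used to exercise the analysis —
with-the-rule (axes near 90°), against-the-rule (near 0°/180°) and
oblique (near 45°) — 25 eyes each by default, with a configurable
ground-truth correction ratio (the CI the surgery achieves) and axis
noise.

Each eye is built backwards from the ground truth: a preoperative vector
is drawn, the achieved treatment (SIA) is set to ``correction_ratio`` ×
the intended treatment in magnitude, applied at the intended axis
perturbed by Gaussian noise, and the postoperative vector is obtained by
subtracting the treatment on the doubled-angle plane.  Analyzing such a
cohort with zero axis noise (and clinical rounding disabled) recovers
the correction ratio exactly, eye for eye.

Magnitudes are rounded to 0.25 D steps and axes to whole degrees by
default, mimicking clinical refraction granularity; rounding happens
after outcome construction, so exact-recovery tests disable it via
``round_clinical=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats

from .data_io import Dataset, write_dataset
from .vectors import (
    CylinderReading,
    EyeRecord,
    PolarVector,
    mirror_os_axis,
    polar_to_rect,
    rect_to_polar,
    wrap_axis,
)

__all__ = ["CohortParams", "generate_cohort", "emit_demo_files", "DEMO_SEEDS"]

#: Default axis centers per astigmatism type (degrees).
AXIS_CENTERS = {"WTR": 90.0, "ATR": 180.0, "oblique": 45.0}

#: Fixed seeds for the three demonstration files.
DEMO_SEEDS = {"WTR": 101, "ATR": 202, "oblique": 303}

#: Smallest clinically meaningful cylinder magnitude (diopters).
_MIN_MAG = 0.25


@dataclass(frozen=True)
class CohortParams:
    """Ground-truth parameters of one synthetic cohort.

    ``correction_ratio`` is the ground-truth correction index;
    ``postop_axis_noise_sd`` perturbs the axis at which the treatment is
    applied (degrees); ``os_fraction`` is the probability an eye is a
    left eye.  ``cylinder_convention`` selects the sign convention the
    file is emitted in ('negative' mirrors common clinical practice).
    """

    astig_type: Literal["WTR", "ATR", "oblique"] = "WTR"
    n_eyes: int = 25
    preop_mag_mean: float = 1.50
    preop_mag_sd: float = 0.75
    axis_center: float | None = None
    axis_spread_sd: float = 4.0
    correction_ratio: float = 0.95
    postop_axis_noise_sd: float = 2.0
    os_fraction: float = 0.5
    seed: int = 0
    round_clinical: bool = True
    cylinder_convention: Literal["positive", "negative"] = "negative"

    def validate(self) -> None:
        if self.astig_type not in AXIS_CENTERS:
            raise ValueError(f"astig_type must be one of {sorted(AXIS_CENTERS)}")
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if self.preop_mag_mean <= 0:
            raise ValueError("preop_mag_mean must be > 0")
        if self.correction_ratio < 0:
            raise ValueError("correction_ratio must be >= 0")
        if min(self.preop_mag_sd, self.axis_spread_sd, self.postop_axis_noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.os_fraction <= 1.0):
            raise ValueError("os_fraction must be in [0, 1]")

    @property
    def center(self) -> float:
        return AXIS_CENTERS[self.astig_type] if self.axis_center is None else self.axis_center


def _round_quarter(x: float) -> float:
    return round(x * 4.0) / 4.0


def _round_axis(axis: float) -> float:
    return wrap_axis(float(round(axis)))


def _draw_magnitude(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Preoperative magnitude from a normal truncated below at 0.25 D."""
    if sd == 0.0:
        return max(mean, _MIN_MAG)
    a = (_MIN_MAG - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _emit_reading(v: PolarVector, convention: str, rounded: bool) -> CylinderReading:
    mag, axis = v.magnitude, v.axis
    if rounded:
        mag = _round_quarter(mag)
        axis = _round_axis(axis)
    if convention == "negative" and mag > 0.0:
        return CylinderReading(-mag, wrap_axis(axis + 90.0))
    return CylinderReading(mag, axis)


def generate_cohort(params: CohortParams) -> Dataset:
    """Generate one cohort, fully reproducible from ``params.seed``.

    Axes are drawn in the analysis frame (after the OS mirror), then
    un-mirrored for left eyes on emission, so that the analyzed TIA axes
    center on ``axis_center`` regardless of eye laterality.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    records: list[EyeRecord] = []
    for i in range(params.n_eyes):
        eye = "OS" if rng.random() < params.os_fraction else "OD"
        mag = _draw_magnitude(rng, params.preop_mag_mean, params.preop_mag_sd)
        axis = wrap_axis(params.center + rng.normal(0.0, params.axis_spread_sd))
        preop = PolarVector(mag, axis)

        treat_axis = wrap_axis(axis + rng.normal(0.0, params.postop_axis_noise_sd))
        sia = PolarVector(params.correction_ratio * mag, treat_axis)
        postop = rect_to_polar(polar_to_rect(preop) - polar_to_rect(sia))

        if eye == "OS":  # emit in the eye's own frame; the mirror is involutive
            preop = PolarVector(preop.magnitude, mirror_os_axis(preop.axis, "OS"))
            postop = PolarVector(postop.magnitude, mirror_os_axis(postop.axis, "OS"))

        records.append(
            EyeRecord(
                eye=eye,  # type: ignore[arg-type]
                preop=_emit_reading(preop, params.cylinder_convention, params.round_clinical),
                postop=_emit_reading(postop, params.cylinder_convention, params.round_clinical),
                source_row=i + 1,
            )
        )
    return Dataset(records=records, n_discarded=0, source_path=None)


def emit_demo_files(outdir, dialect: str = "xlsx") -> list[Path]:
    """Write the three 25-eye demonstration cohorts (WTR, ATR, Oblique).

    Uses fixed, documented seeds so repeated runs produce identical
    files.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".xlsx" if dialect == "xlsx" else ".csv"
    names = {"WTR": "WTR", "ATR": "ATR", "oblique": "Oblique"}
    paths = []
    for astig_type, stem in names.items():
        params = CohortParams(astig_type=astig_type, seed=DEMO_SEEDS[astig_type])  # type: ignore[arg-type]
        dataset = generate_cohort(params)
        paths.append(write_dataset(dataset, outdir / f"{stem}{suffix}", dialect=dialect))
    return paths
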