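"""Standard single-angle polar plots for astigmatism vector analysis.

Each of the four graphs (TIA, SIA, DV, CI) is drawn on an upper
semicircular polar canvas with 0° on the right and 180° on the left,
the convention clinicians read corneal axes in.  Shaded sectors mark the
orientation bands: blue for against-the-rule (0–30° and 150–180°), red
for with-the-rule (60–120°), unshaded white for oblique (30–60° and
120–150°).  Each eye is a black radial line ending in a blue circle
marker; a red diamond marks the vector mean on the TIA/SIA/DV graphs
(omitted on the CI graph, per reporting standards).  A call-out box
carries the doubled-angle X/Y means ± SDs and the vector mean (or the
geometric-mean CI).

Styling is deliberately fixed — no color/font options are exposed — so
figures from different studies remain directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe; no-op if a GUI backend is active

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.figure import Figure

from .vectors import CISummary, CohortSummary, EyeResult, summarize_ci, summarize_vectors

__all__ = ["PlotSpec", "build_plot_spec", "render_single_angle_plot", "export_figures"]

GRAPH_KINDS = ("TIA", "SIA", "DV", "CI")

_ATR_COLOR = "#9ecae9"   # blue sectors: against-the-rule
_WTR_COLOR = "#f2a9a9"   # red sector: with-the-rule
_SECTOR_ALPHA = 0.55
_SHADED_SECTORS = (((0.0, 30.0), _ATR_COLOR), ((150.0, 180.0), _ATR_COLOR),
                   ((60.0, 120.0), _WTR_COLOR))

_TITLES = {
    "TIA": "Target-Induced Astigmatism (TIA)",
    "SIA": "Surgically-Induced Astigmatism (SIA)",
    "DV": "Difference Vector (DV)",
    "CI": "Correction Index (CI)",
}


@dataclass(frozen=True)
class PlotSpec:
    """Everything needed to render one graph, independent of the renderer.

    ``points`` are (radius, axis°) pairs — diopters for TIA/SIA/DV,
    index units for CI (each CI plotted at its eye's TIA axis).
    """

    kind: str
    points: tuple[tuple[float, float], ...]
    summary: Union[CohortSummary, CISummary]
    radial_max: float
    title: str

    def __post_init__(self) -> None:
        if self.kind not in GRAPH_KINDS:
            raise ValueError(f"kind must be one of {GRAPH_KINDS}, got {self.kind!r}")
        if self.radial_max <= 0:
            raise ValueError("radial_max must be > 0")
        if any(r > self.radial_max for r, _ in self.points):
            raise ValueError("a point exceeds radial_max (would be clipped)")
        if self.kind == "CI" and not isinstance(self.summary, CISummary):
            raise ValueError("CI plot requires a CISummary")


def _radial_limit(max_radius: float, kind: str) -> float:
    """Smallest tick-friendly limit covering all points.

    Diopter graphs use the 0.5 D ladder (0.5, 1.0, 1.5, …); the CI graph
    uses 0.5 then doubling (0.5, 1.0, 2.0, 4.0, …) since CI is a ratio.
    """
    if kind == "CI":
        limit = 0.5
        while limit < max_radius:
            limit *= 2.0
        return limit
    return max(0.5, math.ceil(max_radius / 0.5 - 1e-12) * 0.5)


def build_plot_spec(results: Sequence[EyeResult], kind: str) -> PlotSpec:
    """Extract one graph's point population and summary from eye results.

    For TIA/SIA/DV the points are the per-eye vectors and the summary is
    a :class:`CohortSummary`.  For CI the points are (CI, TIA axis) for
    every eye with a defined CI (zero-TIA eyes are excluded) and the
    summary is a :class:`CISummary`.
    """
    if kind not in GRAPH_KINDS:
        raise ValueError(f"kind must be one of {GRAPH_KINDS}, got {kind!r}")
    results = list(results)
    if not results:
        raise ValueError("cannot build a plot from zero eye results")
    if kind == "CI":
        points = tuple(
            (r.ci, r.tia.axis) for r in results if r.ci is not None
        )
        summary: Union[CohortSummary, CISummary] = summarize_ci([r.ci for r in results])
    else:
        vectors = [getattr(r, kind.lower()) for r in results]
        points = tuple((v.magnitude, v.axis) for v in vectors)
        summary = summarize_vectors(vectors)
    max_radius = max((r for r, _ in points), default=0.0)
    return PlotSpec(
        kind=kind,
        points=points,
        summary=summary,
        radial_max=_radial_limit(max_radius, kind),
        title=f"{_TITLES[kind]}  (n = {len(points)})",
    )


def _draw_sectors(ax, rmax: float) -> None:
    theta = np.linspace(0.0, math.pi, 361)
    for (lo, hi), color in _SHADED_SECTORS:
        band = (theta >= math.radians(lo)) & (theta <= math.radians(hi))
        ax.fill_between(theta[band], 0.0, rmax, color=color,
                        alpha=_SECTOR_ALPHA, linewidth=0, zorder=0)


def _callout_text(spec: PlotSpec) -> str:
    s = spec.summary
    if isinstance(s, CISummary):
        lines = [f"geometric mean CI = {s.geometric_mean:.2f}",
                 f"n = {s.n_defined}"]
        if s.n_excluded:
            lines.append(f"excluded (CI undefined/0): {s.n_excluded}")
        return "\n".join(lines)
    vm = s.vector_mean
    return "\n".join([
        f"X = {s.mean_x:+.2f} ± {s.sd_x:.2f} D",
        f"Y = {s.mean_y:+.2f} ± {s.sd_y:.2f} D",
        f"vector mean = {vm.magnitude:.2f} D @ {vm.axis:.0f}°",
    ])


def render_single_angle_plot(spec: PlotSpec) -> Figure:
    """Render one graph on a 0–180° semicircular polar canvas.

    Deterministic for a fixed spec: two renders produce byte-identical
    raster buffers at the same dpi.
    """
    fig = plt.figure(figsize=(7.0, 4.6))
    ax = fig.add_subplot(projection="polar")
    ax.set_thetamin(0.0)
    ax.set_thetamax(180.0)
    ax.set_rlim(0.0, spec.radial_max)
    ax.set_thetagrids(range(0, 181, 30))
    _draw_sectors(ax, spec.radial_max)

    for radius, axis in spec.points:
        theta = math.radians(axis)
        ax.plot([theta, theta], [0.0, radius], color="black", linewidth=0.9, zorder=2)
        ax.plot([theta], [radius], marker="o", markersize=5, color="tab:blue",
                markeredgecolor="black", markeredgewidth=0.4, linestyle="none", zorder=3)

    if isinstance(spec.summary, CohortSummary):  # no vector-mean diamond on CI graphs
        vm = spec.summary.vector_mean
        ax.plot([math.radians(vm.axis)], [vm.magnitude], marker="D", markersize=9,
                color="red", linestyle="none", zorder=4)

    ax.set_title(spec.title, pad=18)
    unit = "correction index" if spec.kind == "CI" else "diopters (D)"
    fig.text(0.5, 0.04, f"radial scale: {unit}, max {spec.radial_max:g}",
             ha="center", fontsize=9)
    fig.text(0.985, 0.82, _callout_text(spec), ha="right", va="top", fontsize=8,
             bbox=dict(boxstyle="round", facecolor="white", edgecolor="0.4"))
    return fig


def export_figures(
    figures: dict[str, Figure],
    source_path,
    out_dir=None,
    dpi: int = 300,
) -> list[Path]:
    """Save figures as TIFF images into a folder named after the data file.

    By default the folder is a sibling of the data file sharing its stem
    (``/d/cohort.xlsx`` → ``/d/cohort/{TIA,SIA,DV,CI}.tif``); pass
    ``out_dir`` to override.  Existing files are overwritten.
    """
    if not figures:
        raise ValueError("no figures to export")
    source_path = Path(source_path)
    target = Path(out_dir) if out_dir is not None else source_path.with_suffix("")
    target.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, fig in figures.items():
        out = target / f"{kind}.tif"
        fig.savefig(out, dpi=dpi, format="tiff")
        written.append(out)
    return written
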