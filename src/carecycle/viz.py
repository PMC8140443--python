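"""Circular (radar) maps of the care continuum on a natural-log scale.

Each stratum's adjusted odds ratios are drawn as a closed polygon over the
cycle's elements: axes are equally spaced, the first element sits at
12 o'clock and the cycle proceeds clockwise, and the radial coordinate is
ln(OR) so that the OR = 1 reference ring is the zero circle, identical in
every panel.  Significant elements (95 % CI excluding 1.00) are marked with
an asterisk on the axis label.  Degenerate estimates are drawn as gaps in
the polygon rather than at radius zero, which would fabricate a null
effect.

SVG output is deterministic: identical estimates produce byte-identical
files (fixed hash salt, no timestamp metadata), and every polygon carries a
stable ``gid`` so emitted coordinates can be checked against the layout
geometry.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib
import numpy as np

matplotlib.use("Agg")  # headless, deterministic
import matplotlib.pyplot as plt  # noqa: E402

from .estimation import ContinuumEstimates
from .spec import ContinuumSpec, default_msk_spec

__all__ = [
    "RadarLayout",
    "FigureRequest",
    "VisualizationError",
    "to_polar_layout",
    "render_radar",
    "polygon_svg_vertices",
]

# Okabe-Ito colorblind-safe palette
PALETTE = ["#0072B2", "#D55E00", "#009E73", "#CC79A7", "#E69F00", "#56B4E9"]


class VisualizationError(ValueError):
    pass


@dataclass(frozen=True)
class RadarLayout:
    """Geometry of the cyclical map: axis angles and the ln-OR radial scale."""

    element_ids: tuple[str, ...]
    element_labels: tuple[str, ...]
    angles_deg: tuple[float, ...]  # first element at 90 deg (12 o'clock), clockwise
    r_max: float                   # symmetric radial range [-r_max, r_max], in ln(OR)
    tick_ors: tuple[float, ...]    # OR values of the radial rings

    @property
    def angles_rad(self) -> tuple[float, ...]:
        return tuple(math.radians(a) for a in self.angles_deg)


@dataclass
class FigureRequest:
    """What to draw: which strata of which estimates, to which file."""

    estimates: ContinuumEstimates
    out_path: str
    strata: Optional[Sequence[str]] = None  # default: all non-reference strata
    format: str = "svg"                     # svg | png
    annotate_values: bool = False
    ci_whiskers: bool = False
    palette: Sequence[str] = field(default_factory=lambda: list(PALETTE))
    panel_size: float = 3.6                 # inches per panel


def to_polar_layout(spec: ContinuumSpec, estimates: ContinuumEstimates) -> RadarLayout:
    """Compute the radar layout shared by every panel of one figure.

    Axes are spaced 360/n degrees apart starting at 12 o'clock; the radial
    range is symmetric about ln(OR) = 0 and padded out to the nearest
    power-of-two OR ring covering every finite estimate.
    """
    element_ids = list(spec.element_ids)
    n = len(element_ids)
    if n == 0:
        raise VisualizationError("spec has no elements")
    lors = [
        math.log(r.odds_ratio)
        for r in estimates.results
        if not r.is_reference and not r.degenerate and np.isfinite(r.odds_ratio)
        and r.odds_ratio > 0
    ]
    if not lors:
        raise VisualizationError("all estimates are degenerate; nothing to lay out")
    biggest = max(abs(v) for v in lors)
    k = max(1, math.ceil(biggest / math.log(2) - 1e-12))
    r_max = k * math.log(2)
    ticks = tuple(float(2.0 ** j) for j in range(-k, k + 1))
    angles = tuple(90.0 - i * 360.0 / n for i in range(n))
    labels = tuple(spec.element(e).label for e in element_ids)
    return RadarLayout(tuple(element_ids), labels, angles, r_max, ticks)


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", text.lower()).strip("-")


def _format_or(v: float) -> str:
    return f"{v:g}"


def axis_labels(est: ContinuumEstimates, stratum: str, layout: RadarLayout) -> list[str]:
    """Element axis labels for one panel; significant elements get a '*' suffix."""
    labels = []
    for eid, base in zip(layout.element_ids, layout.element_labels):
        r = est.result(stratum, eid)
        labels.append(base + ("*" if r.significant else ""))
    return labels


def render_radar(
    request: FigureRequest,
    layout: Optional[RadarLayout] = None,
    spec: Optional[ContinuumSpec] = None,
) -> tuple[str, dict[str, list[dict]]]:
    """Render one multi-panel figure (one panel per requested stratum).

    Returns the written path and, per stratum, the polygon vertex geometry —
    element id, angle, radius, and the (x, y) position in the output file's
    coordinate system — for downstream checks.
    """
    est = request.estimates
    spec = spec if spec is not None else default_msk_spec()
    if layout is None:
        layout = to_polar_layout(spec, est)
    strata = list(request.strata) if request.strata is not None else [
        s for s in est.strata if s != est.reference_stratum
    ]
    unknown = [s for s in strata if s not in est.strata]
    if unknown:
        raise VisualizationError(f"unknown strata requested: {unknown}")
    fmt = request.format.lower()
    if fmt not in ("svg", "png"):
        raise VisualizationError(f"unsupported format {request.format!r}")

    n_panels = len(strata)
    ncols = min(2, n_panels)
    nrows = math.ceil(n_panels / ncols)
    with plt.rc_context({"svg.hashsalt": "carecycle", "font.family": "DejaVu Sans"}):
        fig = plt.figure(
            figsize=(request.panel_size * ncols, request.panel_size * nrows + 0.6),
            dpi=72 if fmt == "svg" else 150,
        )
        axes = []
        any_degenerate = False
        for i, stratum in enumerate(strata):
            ax = fig.add_subplot(nrows, ncols, i + 1, projection="polar")
            axes.append(ax)
            color = request.palette[i % len(request.palette)]
            rs = []
            for eid in layout.element_ids:
                r = est.result(stratum, eid)
                ok = not r.degenerate and np.isfinite(r.odds_ratio) and r.odds_ratio > 0
                rs.append(math.log(r.odds_ratio) if ok else math.nan)
                any_degenerate |= not ok

            thetas = list(layout.angles_rad)
            # close the cycle (NaN vertices break the polygon into gap segments)
            theta_c = thetas + [thetas[0]]
            rs_c = rs + [rs[0]]
            line, = ax.plot(theta_c, rs_c, marker="o", markersize=3.5,
                            linewidth=1.6, color=color, zorder=3)
            line.set_gid(f"continuum-polygon-{_slug(stratum)}")
            ring = np.linspace(0, 2 * np.pi, 181)
            ax.plot(ring, np.zeros_like(ring), linestyle="--", linewidth=1.0,
                    color="#555555", zorder=2)  # OR = 1 reference ring

            if request.ci_whiskers:
                for theta, eid in zip(thetas, layout.element_ids):
                    r = est.result(stratum, eid)
                    if r.degenerate or not np.isfinite(r.ci_low) or r.ci_low <= 0:
                        continue
                    lo = max(math.log(r.ci_low), -layout.r_max)
                    hi = min(math.log(r.ci_high), layout.r_max)
                    ax.plot([theta, theta], [lo, hi], color=color, linewidth=0.9,
                            alpha=0.6, zorder=2)
            if request.annotate_values:
                for theta, rv, eid in zip(thetas, rs, layout.element_ids):
                    if math.isnan(rv):
                        continue
                    r = est.result(stratum, eid)
                    ax.annotate(f"{r.odds_ratio:.2f}", (theta, rv), fontsize=6,
                                xytext=(2, 2), textcoords="offset points")

            ax.set_ylim(-layout.r_max, layout.r_max)
            tick_r = [math.log(t) for t in layout.tick_ors]
            ax.set_yticks(tick_r)
            ax.set_yticklabels([_format_or(t) for t in layout.tick_ors], fontsize=6)
            ax.set_xticks(list(layout.angles_rad))
            ax.set_xticklabels(axis_labels(est, stratum, layout), fontsize=7)
            ax.set_title(stratum, fontsize=9)
            ax.grid(True, linewidth=0.4, alpha=0.5)

        note = (
            f"Reference stratum: {est.reference_stratum}; adjusted for "
            f"{', '.join(est.covariates)}; alpha = {est.alpha:g}; radial scale: ln(OR)."
        )
        if any_degenerate:
            note += " Gaps mark degenerate (inestimable) elements."
        fig.text(0.01, 0.01, note, fontsize=6)
        fig.tight_layout(rect=(0, 0.03, 1, 1))

        fig.canvas.draw()
        geometry: dict[str, list[dict]] = {}
        height_units = fig.get_figheight() * fig.dpi
        for ax, stratum in zip(axes, strata):
            verts = []
            for theta, eid in zip(layout.angles_rad, layout.element_ids):
                r = est.result(stratum, eid)
                if r.degenerate or not np.isfinite(r.odds_ratio) or r.odds_ratio <= 0:
                    continue
                rv = math.log(r.odds_ratio)
                x_disp, y_disp = ax.transData.transform((theta, rv))
                verts.append({
                    "element": eid, "theta_rad": theta, "r": rv,
                    "x": float(x_disp), "y": float(height_units - y_disp),
                })
            geometry[stratum] = verts

        out_path = str(request.out_path)
        if not out_path.lower().endswith(f".{fmt}"):
            out_path = f"{out_path}.{fmt}"
        os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)
        metadata = {"Date": None} if fmt == "svg" else None
        fig.savefig(out_path, format=fmt, metadata=metadata)
        plt.close(fig)
    return out_path, geometry


def polygon_svg_vertices(svg_path: str, stratum: str) -> list[tuple[float, float]]:
    """Parse a rendered SVG and return the (x, y) vertices of one stratum's polygon.

    Used to verify that emitted vector coordinates match the layout geometry.
    """
    from xml.etree import ElementTree

    ns = {"svg": "http://www.w3.org/2000/svg"}
    tree = ElementTree.parse(svg_path)
    gid = f"continuum-polygon-{_slug(stratum)}"
    group = None
    for g in tree.iter("{http://www.w3.org/2000/svg}g"):
        if g.get("id") == gid:
            group = g
            break
    if group is None:
        raise VisualizationError(f"no polygon with gid {gid!r} in {svg_path}")
    path = group.find(".//svg:path", ns)
    if path is None:
        raise VisualizationError(f"polygon group {gid!r} holds no path")
    d = path.get("d", "")
    coords = [float(v) for v in re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", d)]
    return list(zip(coords[0::2], coords[1::2]))
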