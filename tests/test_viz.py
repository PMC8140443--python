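"""Radar layout geometry and deterministic figure rendering."""

import math

import numpy as np
import pytest

import carecycle as cc
from carecycle.estimation import ContinuumEstimates, ORResult
from carecycle.viz import (
    FigureRequest,
    VisualizationError,
    axis_labels,
    polygon_svg_vertices,
    render_radar,
    to_polar_layout,
)


def _manual_estimates(spec, or_by_element, reference="REF", stratum="S1",
                      ci=None, significant=None):
    results = []
    for eid in spec.element_ids:
        results.append(ORResult(reference, eid, 1.0, float("nan"), float("nan"),
                                float("nan"), False, 10, is_reference=True))
        or_ = or_by_element[eid]
        lo, hi = ci.get(eid, (or_ * 0.8, or_ * 1.25)) if ci else (or_ * 0.8, or_ * 1.25)
        sig = significant.get(eid, lo > 1.0 or hi < 1.0) if significant else (lo > 1.0 or hi < 1.0)
        results.append(ORResult(stratum, eid, or_, lo, hi, 0.5, sig, 10))
    return ContinuumEstimates("manual", reference, results)


def test_layout_axes_equally_spaced_clockwise_from_noon(spec, sim_estimates):
    layout = to_polar_layout(spec, sim_estimates)
    assert len(layout.angles_deg) == 8
    assert layout.angles_deg[0] == 90.0  # first element at 12 o'clock
    diffs = np.diff(layout.angles_deg)
    assert np.allclose(diffs, -45.0)  # clockwise, 360/8 apart


def test_layout_radial_transform_is_natural_log(spec):
    est = _manual_estimates(spec, {e: 1.0 for e in spec.element_ids[:-1]}
                            | {"amputation": 2.74})
    layout = to_polar_layout(spec, est)
    assert math.log(1.0) == 0.0  # OR = 1 sits on the zero ring
    assert math.log(2.74) == pytest.approx(1.0080, abs=5e-4)
    assert layout.r_max >= math.log(2.74)
    assert 1.0 in layout.tick_ors  # the reference ring is always a tick


def test_layout_range_symmetric_and_ticks_cover_estimates(spec, sim_estimates):
    layout = to_polar_layout(spec, sim_estimates)
    finite = [math.log(r.odds_ratio) for r in sim_estimates.results
              if not r.is_reference and not r.degenerate]
    assert layout.r_max >= max(abs(v) for v in finite)
    ticks = sorted(math.log(t) for t in layout.tick_ors)
    assert ticks[0] == pytest.approx(-layout.r_max)
    assert ticks[-1] == pytest.approx(layout.r_max)


def test_all_degenerate_estimates_rejected(spec):
    nan = float("nan")
    results = [ORResult("S1", eid, nan, nan, nan, nan, False, 0, degenerate=True)
               for eid in spec.element_ids]
    est = ContinuumEstimates("broken", "REF", results)
    with pytest.raises(VisualizationError, match="degenerate"):
        to_polar_layout(spec, est)


def test_significance_asterisks_follow_ci(spec):
    ci = {"amputation": (1.10, 2.00), "sepsis": (0.69, 1.52)}
    est = _manual_estimates(spec, {e: 1.4 for e in spec.element_ids}, ci=ci)
    layout = to_polar_layout(spec, est)
    labels = dict(zip(layout.element_ids, axis_labels(est, "S1", layout)))
    assert labels["amputation"].endswith("*")      # CI excludes 1.00
    assert not labels["sepsis"].endswith("*")      # CI covers 1.00


def test_panels_equal_non_reference_strata(sim_estimates, tmp_path):
    path, geometry = render_radar(
        FigureRequest(sim_estimates, str(tmp_path / "fig"), format="svg"))
    assert len(geometry) == 4  # 5 strata, one is the reference


def test_same_estimates_byte_identical_svg(sim_estimates, tmp_path):
    blobs = []
    for sub in ("x", "y"):
        path, _ = render_radar(
            FigureRequest(sim_estimates, str(tmp_path / sub / "fig"), format="svg"))
        blobs.append(open(path, "rb").read())
    assert blobs[0] == blobs[1]


def test_svg_vertices_match_layout_geometry(sim_estimates, tmp_path):
    path, geometry = render_radar(
        FigureRequest(sim_estimates, str(tmp_path / "fig"), format="svg"))
    for stratum, expected in geometry.items():
        got = polygon_svg_vertices(path, stratum)
        assert len(got) >= len(expected)
        for e, (x, y) in zip(expected, got):
            assert math.hypot(e["x"] - x, e["y"] - y) < 0.5  # px


def test_unit_or_polygon_sits_on_reference_ring(spec, tmp_path):
    est = _manual_estimates(spec, {e: 1.0 for e in spec.element_ids})
    path, geometry = render_radar(
        FigureRequest(est, str(tmp_path / "fig"), strata=["S1"], format="svg"))
    assert all(v["r"] == 0.0 for v in geometry["S1"])
    xs = [v["x"] for v in geometry["S1"]]
    ys = [v["y"] for v in geometry["S1"]]
    cx, cy = np.mean(xs), np.mean(ys)
    radii = [math.hypot(x - cx, y - cy) for x, y in zip(xs, ys)]
    assert np.ptp(radii) < 0.5  # all vertices on one circle: the OR=1 ring


def test_unknown_stratum_rejected(sim_estimates, tmp_path):
    with pytest.raises(VisualizationError, match="unknown"):
        render_radar(FigureRequest(sim_estimates, str(tmp_path / "f"),
                                   strata=["nope"]))


def test_png_output(sim_estimates, tmp_path):
    path, _ = render_radar(
        FigureRequest(sim_estimates, str(tmp_path / "fig"), format="png"))
    assert path.endswith(".png")
    assert open(path, "rb").read(8).startswith(b"\x89PNG")
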