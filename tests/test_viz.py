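"""Rendering contracts: decodable output, half-integer separator coordinates,
PTM tick placement, greyscale monotonicity, and SVG determinism."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from pepcover import (
    ConfigurationError,
    DataError,
    PlotConfig,
    TargetEntry,
    ptm_positions_table,
    render_comparison,
    render_coverage_plot,
    render_peptide_lanes,
)

TARGET = TargetEntry("T", "ACDEFGHIKL")  # length 10


def _quant(rows, metric="psm"):
    return pd.DataFrame(
        [{"target_id": "T", "position": p, "metric": metric, "value": v}
         for p, v in rows])


def _regions(rows):
    return pd.DataFrame(
        [{"target_id": "T", "label": lab, "start": s, "end": e, "category": cat}
         for lab, s, e, cat in rows])


def _canvas_array(fig):
    fig.canvas.draw()
    return np.asarray(fig.canvas.buffer_rgba()).copy()


def test_single_peptide_heatmap_decodes_with_one_gray_level(tmp_path):
    """Positions 3..8 at value 1, greyscale: the written file is a valid image
    and the heatmap band holds exactly one distinct non-background color."""
    out = tmp_path / "cov.png"
    quant = _quant([(p, 1.0) for p in range(3, 9)])
    result = render_coverage_plot(quant, [TARGET], config=PlotConfig(output=str(out)))
    assert out.exists()
    img = Image.open(out)
    assert img.format == "PNG" and img.size[0] > 0

    # sample strictly inside the data area of the live canvas
    ax = result.axes[0]
    buf = _canvas_array(result.figure)
    bbox = ax.get_window_extent()
    h = buf.shape[0]
    x0, x1 = int(bbox.x0) + 3, int(bbox.x1) - 3
    y0, y1 = h - int(bbox.y1) + 3, h - int(bbox.y0) - 3
    inner = buf[y0:y1, x0:x1, :3].reshape(-1, 3)
    nonwhite = inner[(inner != 255).any(axis=1)]
    colors, counts = np.unique(nonwhite, axis=0, return_counts=True)
    dominant = colors[counts >= max(1, int(0.01 * len(nonwhite)))]
    assert len(dominant) == 1
    assert np.all(dominant[0] == dominant[0][0])  # a gray: R == G == B


def test_region_separators_sit_at_half_integer_coordinates():
    quant = _quant([(p, 1.0) for p in range(3, 9)])
    regions = _regions([("VH", 1, 5, "domain"), ("CDR1", 7, 9, "cdr")])
    result = render_coverage_plot(quant, [TARGET], regions=regions)
    seps = sorted(
        line.get_xdata()[0]
        for line in result.axes[0].lines if line.get_gid() == "region-sep"
    )
    assert seps == [0.5, 5.5]
    spans = [p for p in result.axes[0].patches if p.get_gid() == "region-span"]
    assert len(spans) == 1
    assert spans[0].get_x() == 6.5
    assert spans[0].get_x() + spans[0].get_width() == 9.5


def test_strict_mode_rejects_unconfigured_region_colors():
    quant = _quant([(3, 1.0)])
    regions = _regions([("CDR1", 7, 9, "cdr")])
    with pytest.raises(ConfigurationError, match="CDR1"):
        render_coverage_plot(quant, [TARGET], regions=regions,
                             config=PlotConfig(strict_colors=True))
    ok = render_coverage_plot(quant, [TARGET], regions=regions,
                              config=PlotConfig(strict_colors=True,
                                                region_colors={"CDR1": "#ffaa00"}))
    assert any(p.get_gid() == "region-span" for p in ok.axes[0].patches)


def test_plot_config_invariants():
    with pytest.raises(ConfigurationError):
        PlotConfig(dpi=0)
    with pytest.raises(ConfigurationError):
        PlotConfig(color_scale=["#ffffff"])  # a ramp needs >= 2 anchors


def test_ptm_tick_lands_on_its_residue_x_coordinate():
    quant = _quant([(p, 1.0) for p in range(3, 9)])
    ptm_pos = pd.DataFrame([{"target_id": "T", "position": 4,
                             "ptm_label": "Phospho", "display_color": "#ff0000"}])
    result = render_coverage_plot(quant, [TARGET], ptm_positions=ptm_pos)
    ticks = [line for line in result.axes[0].lines
             if (line.get_gid() or "").startswith("ptm-tick")]
    assert len(ticks) == 1
    assert list(ticks[0].get_xdata()) == [4]


def test_stacked_ticks_at_one_position_use_distinct_heights():
    quant = _quant([(p, 1.0) for p in range(3, 9)])
    ptm_pos = pd.DataFrame([
        {"target_id": "T", "position": 4, "ptm_label": "B-mod", "display_color": None},
        {"target_id": "T", "position": 4, "ptm_label": "A-mod", "display_color": None},
    ])
    result = render_coverage_plot(quant, [TARGET], ptm_positions=ptm_pos)
    ys = {line.get_gid(): list(line.get_ydata()) for line in result.axes[0].lines
          if (line.get_gid() or "").startswith("ptm-tick")}
    assert len(ys) == 2
    (y_a,), (y_b,) = ys["ptm-tick:A-mod"], ys["ptm-tick:B-mod"]
    assert y_a != y_b and y_a > y_b  # label-sorted: A-mod drawn first, closest to the band


def test_normalization_mode_immaterial_for_identical_facets():
    quant = pd.concat([
        _quant([(p, v) for p, v in [(2, 1.0), (3, 2.0)]]).assign(donor="D1"),
        _quant([(p, v) for p, v in [(2, 1.0), (3, 2.0)]]).assign(donor="D2"),
    ], ignore_index=True)
    buffers = []
    for mode in ("global", "per_facet"):
        result = render_coverage_plot(
            quant, [TARGET], config=PlotConfig(scale_normalization=mode))
        buffers.append(_canvas_array(result.figure))
    assert np.array_equal(*buffers)


def test_greyscale_luminance_decreases_with_value():
    quant = _quant([(2, 1.0), (5, 2.0), (8, 3.0)])
    result = render_coverage_plot(quant, [TARGET])
    ax = result.axes[0]
    buf = _canvas_array(result.figure)
    h = buf.shape[0]

    def luminance(pos):
        x, y = ax.transData.transform((pos, 0.0))
        return buf[h - int(round(y)), int(round(x)), :3].mean()

    assert luminance(2) > luminance(5) > luminance(8)


def test_svg_output_is_deterministic(tmp_path):
    quant = _quant([(p, 1.0) for p in range(3, 9)])
    contents = []
    for name in ("a.svg", "b.svg"):
        out = tmp_path / name
        render_coverage_plot(quant, [TARGET], config=PlotConfig(output=str(out)))
        contents.append(out.read_bytes())
    assert contents[0] == contents[1]


def test_sidecar_matrix_covers_full_target(tmp_path):
    out = tmp_path / "cov.png"
    quant = _quant([(3, 2.0)])
    result = render_coverage_plot(quant, [TARGET], config=PlotConfig(output=str(out)))
    side = tmp_path / "cov.matrix.tsv"
    assert side in result.written and side.exists()
    matrix = pd.read_csv(side, sep="\t")
    assert list(matrix["position"]) == list(range(1, 11))
    assert matrix.loc[matrix["position"] == 3, "value"].iloc[0] == 2.0
    assert matrix["value"].sum() == 2.0


def test_empty_quant_errors_unless_allowed(tmp_path):
    empty = _quant([])
    with pytest.raises(DataError):
        render_coverage_plot(empty, [TARGET])
    out = tmp_path / "empty.png"
    result = render_coverage_plot(empty, [TARGET],
                                  config=PlotConfig(allow_empty=True, output=str(out)))
    assert out.exists() and result.matrix.empty


def test_comparison_panels_share_x_extent():
    psm = _quant([(p, 1.0) for p in range(3, 9)], metric="psm")
    intensity = _quant([(p, 500.0) for p in range(3, 9)], metric="intensity")
    area = _quant([(p, 900.0) for p in range(3, 9)], metric="area")

    two = render_comparison([psm, intensity], [TARGET])
    assert len(two.axes) == 2
    assert len({ax.get_xlim() for ax in two.axes}) == 1

    three = render_comparison([psm, intensity, area], [TARGET])
    assert len(three.axes) == 3
    assert len({ax.get_xlim() for ax in three.axes}) == 1

    single = render_comparison([psm], [TARGET])
    assert len(single.axes) == 1

    other = psm.assign(target_id="OTHER")
    with pytest.raises(ConfigurationError):
        render_comparison([psm, other], [TargetEntry("OTHER", "ACDEFGHIKL"), TARGET])


def test_peptide_lanes_pack_overlaps_into_separate_lanes():
    matches = pd.DataFrame([
        {"record_id": "a", "target_id": "T", "start": 1, "end": 6},
        {"record_id": "b", "target_id": "T", "start": 4, "end": 9},
        {"record_id": "c", "target_id": "T", "start": 7, "end": 10},
    ])
    result = render_peptide_lanes(matches, [TARGET])
    lanes = [p for p in result.axes[0].patches if p.get_gid() == "peptide-lane"]
    assert len(lanes) == 3
    y_centers = sorted({round(p.get_y() + p.get_height() / 2, 2) for p in lanes})
    assert len(y_centers) == 2  # a/b overlap -> two lanes; c reuses lane 0


def test_projected_ptm_positions_follow_match_offsets():
    matches = pd.DataFrame([
        {"record_id": "a", "target_id": "T", "start": 3, "end": 8}])
    ptms = pd.DataFrame([
        {"record_id": "a", "ptm_label": "Phospho", "ptm_position": 2,
         "multi_ptm": False, "display_color": "#f00"},
        {"record_id": "a", "ptm_label": "Acetyl", "ptm_position": "NTERM",
         "multi_ptm": False, "display_color": "#0f0"},
    ])
    table = ptm_positions_table(matches, ptms)
    got = dict(zip(table["ptm_label"], table["position"]))
    assert got == {"Phospho": 4, "Acetyl": 3}
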