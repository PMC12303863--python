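"""Linearized coverage heatmaps.

The visual contract: one heatmap row per group (e.g. donor), the x-axis
spanning the full target length with uncovered positions blank; targets (e.g.
heavy/light chain) side by side with widths proportional to their lengths;
domain boundaries drawn as vertical separators at half-integer coordinates
with labels; CDR / mutation regions overlaid in their configured colors; and
PTM tick marks in a band above the heatmap at the modified residues'
x-coordinates. PSM counts default to a white-to-black greyscale ramp,
intensity and peak area to a white-to-blue ramp.

Heatmap tiles are centered on integer residue positions with unit width
(tile ``i`` spans ``i-0.5 .. i+0.5``); region boundaries sit at half-integer
edges, so quantification and annotation tracks align unambiguously. A sidecar
TSV of the exact plotted matrix accompanies every written figure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .errors import ConfigurationError, CrossReferenceError, DataError
from .mapping import TargetEntry
from .quantify import group_columns

#: default fill colors by region category (domains get separators, not fills)
_CATEGORY_FILLS = {"cdr": "#fdbf6f", "mutation": "#e31a1c", "other": "#cab2d6"}

_TICK_PALETTE = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#a65628", "#f781bf", "#17becf", "#666666", "#bcbd22",
)

_WHITE_TO_BLUE = LinearSegmentedColormap.from_list("white_to_blue", ["#ffffff", "#08519c"])


@dataclass(frozen=True)
class PlotConfig:
    """Rendering options for coverage heatmaps.

    ``color_scale='auto'`` picks the conventional ramp per metric (psm ->
    greyscale, intensity/area -> white-to-blue); a list of >= 2 colors defines
    a custom ramp. ``scale_normalization='global'`` shares one color scale
    across all facets (the default, so conditions remain comparable);
    ``'per_facet'`` rescales each target panel independently.
    """

    color_scale: object = "auto"  # auto | greyscale | white_to_blue | [colors]
    scale_normalization: str = "global"  # global | per_facet
    region_colors: dict = field(default_factory=dict)
    ptm_tick_colors: dict = field(default_factory=dict)
    show_domain_labels: bool = True
    show_axis_ticks: bool = True
    strict_colors: bool = False
    allow_empty: bool = False
    output: str | None = None
    fmt: str | None = None  # png | svg | pdf; inferred from output suffix
    dpi: int = 150
    window: tuple[int, int] | None = None
    figsize: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ConfigurationError("dpi must be positive")
        if isinstance(self.color_scale, (list, tuple)) and len(self.color_scale) < 2:
            raise ConfigurationError("a custom color ramp needs at least 2 anchors")
        if self.scale_normalization not in ("global", "per_facet"):
            raise ConfigurationError(
                f"unknown scale_normalization {self.scale_normalization!r}"
            )


@dataclass
class CoverageFigure:
    """A rendered figure plus its written artifacts."""

    figure: object
    axes: list
    written: list[Path]
    matrix: pd.DataFrame  # the exact plotted values, long format


def _colormap(config: PlotConfig, metric: str):
    scale = config.color_scale
    if isinstance(scale, (list, tuple)):
        return LinearSegmentedColormap.from_list("custom", list(scale))
    if scale == "auto":
        scale = "greyscale" if metric == "psm" else "white_to_blue"
    if scale == "greyscale":
        return plt.get_cmap("Greys")
    if scale == "white_to_blue":
        return _WHITE_TO_BLUE
    raise ConfigurationError(f"unknown color scale {scale!r}")


def _group_rows(quant: pd.DataFrame) -> tuple[list[str], list[tuple]]:
    gcols = group_columns(quant)
    if not gcols:
        return [], [()]
    groups = sorted(set(map(tuple, quant[gcols].itertuples(index=False, name=None))))
    return gcols, groups


def _matrices(quant: pd.DataFrame, targets: list[TargetEntry],
              gcols: list[str], groups: list[tuple]) -> dict[str, np.ndarray]:
    index = {g: i for i, g in enumerate(groups)}
    mats = {t.target_id: np.zeros((len(groups), len(t))) for t in targets}
    for _, row in quant.iterrows():
        tid = row["target_id"]
        if tid not in mats:
            raise CrossReferenceError(f"quantification references unknown target {tid!r}")
        key = tuple(row[c] for c in gcols)
        pos = int(row["position"])
        if not (1 <= pos <= mats[tid].shape[1]):
            raise DataError(f"position {pos} outside target {tid!r}")
        mats[tid][index[key], pos - 1] = float(row["value"])
    return mats


def _matrix_long(mats: dict[str, np.ndarray], gcols: list[str],
                 groups: list[tuple]) -> pd.DataFrame:
    rows = []
    for tid, mat in mats.items():
        for gi, group in enumerate(groups):
            for pos in range(1, mat.shape[1] + 1):
                row = {"target_id": tid, **dict(zip(gcols, group)),
                       "position": pos, "value": mat[gi, pos - 1]}
                rows.append(row)
    return pd.DataFrame(rows, columns=["target_id"] + gcols + ["position", "value"])


def _draw_panel(ax, mat: np.ndarray, target: TargetEntry, cmap, vmax: float,
                regions: pd.DataFrame | None, ptms: pd.DataFrame | None,
                groups: list[tuple], config: PlotConfig, show_groups: bool) -> None:
    n_groups, length = mat.shape
    ax.imshow(mat, origin="upper", aspect="auto", interpolation="nearest",
              extent=(0.5, length + 0.5, n_groups - 0.5, -0.5),
              cmap=cmap, vmin=0.0, vmax=vmax)
    y_top = -0.5

    if regions is not None and len(regions):
        here = regions[regions["target_id"] == target.target_id]
        for _, reg in here.iterrows():
            lo, hi = reg["start"] - 0.5, reg["end"] + 0.5
            if reg["category"] == "domain":
                for x in (lo, hi):
                    ax.axvline(x, color="0.15", linewidth=0.8, gid="region-sep")
                if config.show_domain_labels:
                    ax.annotate(reg["label"], ((lo + hi) / 2, n_groups - 0.5),
                                xytext=(0, -12), textcoords="offset points",
                                ha="center", va="top", fontsize=7, annotation_clip=False)
            else:
                color = config.region_colors.get(reg["label"])
                if color is None:
                    if config.strict_colors:
                        raise ConfigurationError(
                            f"no color configured for region label {reg['label']!r}"
                        )
                    color = _CATEGORY_FILLS.get(reg["category"], "#cab2d6")
                ax.axvspan(reg["start"] - 0.5, reg["end"] + 0.5, color=color,
                           alpha=0.35, gid="region-span", linewidth=0)

    if ptms is not None and len(ptms):
        here = ptms[ptms["target_id"] == target.target_id]
        y_top = _draw_ptm_ticks(ax, here, config)

    title = target.target_id if target.chain is None else f"{target.target_id} {target.chain}"
    ax.set_title(title, fontsize=8)
    ax.set_ylim(n_groups - 0.5, y_top - 0.4)
    if config.window:
        lo, hi = config.window
        ax.set_xlim(lo - 0.5, hi + 0.5)
    else:
        ax.set_xlim(0.5, length + 0.5)
    if show_groups and groups != [()]:
        ax.set_yticks(range(n_groups))
        ax.set_yticklabels([" / ".join(map(str, g)) for g in groups], fontsize=7)
    else:
        ax.set_yticks([])
    if not config.show_axis_ticks:
        ax.set_xticks([])
    ax.tick_params(axis="x", labelsize=7)


def _draw_ptm_ticks(ax, ptms: pd.DataFrame, config: PlotConfig) -> float:
    """Draw the PTM band above the heatmap; overlapping ticks at one position
    stack vertically in label-sorted order. Returns the topmost y used."""
    base, step = -0.9, 0.35
    palette = itertools.cycle(_TICK_PALETTE)
    labels = sorted(ptms["ptm_label"].unique())
    colors = {lab: config.ptm_tick_colors.get(lab) or next(palette) for lab in labels}
    depth: dict[int, int] = {}
    xs: dict[str, list[float]] = {lab: [] for lab in labels}
    ys: dict[str, list[float]] = {lab: [] for lab in labels}
    for _, row in ptms.sort_values("ptm_label", kind="stable").iterrows():
        pos = int(row["position"])
        k = depth.get(pos, 0)
        depth[pos] = k + 1
        xs[row["ptm_label"]].append(pos)
        ys[row["ptm_label"]].append(base - step * k)
    y_top = base
    for lab in labels:
        if not xs[lab]:
            continue
        y_top = min(y_top, min(ys[lab]))
        ax.plot(xs[lab], ys[lab], linestyle="", marker="|", markersize=7,
                markeredgewidth=1.6, color=colors[lab], clip_on=False,
                gid=f"ptm-tick:{lab}")
    return y_top


def _save(fig, config: PlotConfig) -> list[Path]:
    if config.output is None:
        return []
    path = Path(config.output)
    fmt = config.fmt or (path.suffix.lstrip(".") or "png")
    if not path.suffix:
        path = path.with_suffix(f".{fmt}")
    metadata = {"Date": None} if fmt == "svg" else None
    with matplotlib.rc_context({"svg.hashsalt": "pepcover"}):
        fig.savefig(path, format=fmt, dpi=config.dpi, metadata=metadata,
                    bbox_inches="tight")
    return [path]


def _sidecar(matrix: pd.DataFrame, written: list[Path]) -> None:
    for path in list(written):
        side = path.with_suffix(".matrix.tsv")
        matrix.to_csv(side, sep="\t", index=False)
        written.append(side)


def ptm_positions_table(matches: pd.DataFrame, ptms: pd.DataFrame) -> pd.DataFrame:
    """Project peptide-local PTM positions onto target coordinates.

    Joins PTM records to match records on ``record_id``; an integer PTM
    position ``p`` lands at target residue ``start + p - 1``; the symbolic
    terminal positions NTERM/CTERM land on the first/last matched residue.
    Returns distinct (target_id, position, ptm_label) rows plus the PTM's
    display color, ready for :func:`render_coverage_plot`.
    """
    if len(ptms) == 0 or len(matches) == 0:
        return pd.DataFrame(columns=["target_id", "position", "ptm_label", "display_color"])
    joined = ptms.merge(matches[["record_id", "target_id", "start", "end"]],
                        on="record_id", how="inner")

    def _target_pos(row):
        p = row["ptm_position"]
        if p == "NTERM":
            return row["start"]
        if p == "CTERM":
            return row["end"]
        return row["start"] + int(p) - 1

    joined["position"] = joined.apply(_target_pos, axis=1)
    out = joined[["target_id", "position", "ptm_label", "display_color"]]
    return out.drop_duplicates(ignore_index=True)


def ptm_tick_colors(ptms: pd.DataFrame) -> dict:
    """Label -> display color mapping from a PTM record table."""
    if len(ptms) == 0 or "display_color" not in ptms.columns:
        return {}
    pairs = ptms[["ptm_label", "display_color"]].dropna().drop_duplicates()
    return dict(zip(pairs["ptm_label"], pairs["display_color"]))


def render_coverage_plot(quant: pd.DataFrame, targets: list[TargetEntry],
                         regions: pd.DataFrame | None = None,
                         ptm_positions: pd.DataFrame | None = None,
                         config: PlotConfig | None = None) -> CoverageFigure:
    """Render one coverage heatmap (rows = groups, columns = residues).

    ``ptm_positions`` is a table of (target_id, position, ptm_label) rows to
    mark in the tick band. Raises on empty quantification unless
    ``config.allow_empty`` is set, in which case an empty-axes figure is
    produced.
    """
    config = config or PlotConfig()
    if quant is None or len(quant) == 0:
        if not config.allow_empty:
            raise DataError("empty quantification table; pass allow_empty to render anyway")
        fig, ax = plt.subplots(figsize=config.figsize or (6, 2))
        ax.set_axis_off()
        written = _save(fig, config)
        return CoverageFigure(fig, [ax], written, pd.DataFrame())

    metric = str(quant["metric"].iloc[0])
    gcols, groups = _group_rows(quant)
    mats = _matrices(quant, targets, gcols, groups)
    fig, axes = _facet_axes(targets, len(groups), config, n_rows=1)
    _render_row(axes[0], mats, targets, metric, regions, ptm_positions, groups,
                gcols, config)
    matrix = _matrix_long(mats, gcols, groups)
    written = _save(fig, config)
    _sidecar(matrix, written)
    return CoverageFigure(fig, list(axes[0]), written, matrix)


def _facet_axes(targets: list[TargetEntry], n_groups: int, config: PlotConfig,
                n_rows: int):
    widths = [len(t) for t in targets]
    figsize = config.figsize or (
        max(4.0, sum(widths) / 45.0), n_rows * max(1.6, 0.35 * n_groups + 1.2),
    )
    fig, axes = plt.subplots(
        n_rows, len(targets), figsize=figsize, squeeze=False,
        gridspec_kw={"width_ratios": widths},
    )
    return fig, axes


def _render_row(axes_row, mats, targets, metric, regions, ptm_positions, groups,
                gcols, config: PlotConfig) -> None:
    cmap = _colormap(config, metric)
    global_vmax = max((m.max() for m in mats.values()), default=0.0) or 1.0
    for ax, target in zip(axes_row, targets):
        mat = mats[target.target_id]
        vmax = global_vmax if config.scale_normalization == "global" \
            else (mat.max() or 1.0)
        _draw_panel(ax, mat, target, cmap, vmax, regions, ptm_positions,
                    groups, config, show_groups=(ax is axes_row[0]))


def render_comparison(quants: list[pd.DataFrame], targets: list[TargetEntry],
                      regions: pd.DataFrame | None = None,
                      ptm_positions: pd.DataFrame | None = None,
                      config: PlotConfig | None = None) -> CoverageFigure:
    """Stack one panel row per metric (e.g. PSM above, intensity below) with a
    shared x-extent and aligned region separators.

    All quantification tables must reference the same targets and groups; each
    panel row uses its own metric's color scale.
    """
    config = config or PlotConfig()
    if not quants:
        raise ConfigurationError("render_comparison needs at least one quantification table")
    if len(quants) == 1:
        return render_coverage_plot(quants[0], targets, regions, ptm_positions, config)

    ref_targets = set(quants[0]["target_id"])
    ref_groups = _group_rows(quants[0])
    for q in quants[1:]:
        if set(q["target_id"]) != ref_targets:
            raise ConfigurationError("comparison panels reference mismatched targets")
        if _group_rows(q) != ref_groups:
            raise ConfigurationError("comparison panels have mismatched groups")

    gcols, groups = ref_groups
    fig, axes = _facet_axes(targets, len(groups), config, n_rows=len(quants))
    frames = []
    for i, q in enumerate(quants):
        metric = str(q["metric"].iloc[0])
        mats = _matrices(q, targets, gcols, groups)
        _render_row(axes[i], mats, targets, metric, regions,
                    ptm_positions if i == 0 else None, groups, gcols, config)
        long = _matrix_long(mats, gcols, groups)
        long.insert(len(long.columns) - 1, "metric", metric)
        frames.append(long)
    matrix = pd.concat(frames, ignore_index=True)
    written = _save(fig, config)
    _sidecar(matrix, written)
    return CoverageFigure(fig, [ax for row in axes for ax in row], written, matrix)


def render_peptide_lanes(matches: pd.DataFrame, targets: list[TargetEntry],
                         regions: pd.DataFrame | None = None,
                         config: PlotConfig | None = None) -> CoverageFigure:
    """Non-collapsed display: every match occurrence as its own horizontal
    segment, lanes packed greedily by first fit."""
    config = config or PlotConfig()
    if len(matches) == 0 and not config.allow_empty:
        raise DataError("empty match table; pass allow_empty to render anyway")
    fig, axes = _facet_axes(targets, 4, config, n_rows=1)
    for ax, target in zip(axes[0], targets):
        here = matches[matches["target_id"] == target.target_id]
        lanes: list[int] = []  # last occupied end per lane
        segs = []
        for _, m in here.sort_values(["start", "end"]).iterrows():
            lane = next((i for i, last in enumerate(lanes) if last < m["start"]), None)
            if lane is None:
                lane = len(lanes)
                lanes.append(0)
            lanes[lane] = int(m["end"])
            segs.append((lane, int(m["start"]), int(m["end"])))
        for lane, start, end in segs:
            rect = matplotlib.patches.Rectangle(
                (start - 0.5, lane - 0.4), end - start + 1, 0.8,
                color="#377eb8", gid="peptide-lane")
            ax.add_patch(rect)
        if regions is not None and len(regions):
            for _, reg in regions[regions["target_id"] == target.target_id].iterrows():
                if reg["category"] == "domain":
                    for x in (reg["start"] - 0.5, reg["end"] + 0.5):
                        ax.axvline(x, color="0.15", linewidth=0.8, gid="region-sep")
        ax.set_xlim(0.5, len(target) + 0.5)
        ax.set_ylim(-0.6, max(len(lanes), 1) - 0.4)
        title = target.target_id if target.chain is None else f"{target.target_id} {target.chain}"
        ax.set_title(title, fontsize=8)
    written = _save(fig, config)
    return CoverageFigure(fig, list(axes[0]), written, matches.copy())
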