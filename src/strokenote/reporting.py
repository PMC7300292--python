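"""Report rendering: the documentation surface of the pipeline.

Renders the session timeline/heatmap panels for music (note intensity over
time with an mf guide line, notes over time with a C4 guide line, and a
note-vs-time heatmap colored by intensity with a pppp–ffff colorbar), the
art tracking graph (tool and color lanes with erasure spans, a canvas
stroke render and a pressure trace), alpha-composited superpositions of
several artworks, and flat metric tables (one row per session).

SVG output is deterministic: the same input and style configuration yield
byte-identical files, so renders can be diffed and regression-tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.lines import Line2D

from strokenote.art import ArtMetrics
from strokenote.events import ArtSession, MusicSession
from strokenote.music import DYNAMICS_BANDS, MF_INTENSITY, MusicMetrics
from strokenote.stats import SuperposedSession

C4_PITCH = 60

#: display RGB for the 10 palette tokens (style config defaults)
PALETTE_RGB = {
    "white": "#f2f2f2",
    "yellow": "#f5d90a",
    "orange": "#f28c28",
    "pink": "#f49ac2",
    "skin": "#e8b88a",
    "red": "#d62828",
    "violet": "#7d3fbf",
    "green": "#2a9d3f",
    "blue": "#2a5fd6",
    "black": "#1a1a1a",
}

MUSIC_PANELS = ("intensity_timeline", "notes_timeline", "note_intensity_heatmap")


@dataclass
class ReportSpec:
    """Which panels to draw and where the guide lines sit."""

    panels: tuple[str, ...] = MUSIC_PANELS
    guides: dict = field(
        default_factory=lambda: {"mf_intensity": MF_INTENSITY, "middle_C": C4_PITCH}
    )
    colormap: str = "inferno"  # perceptually uniform; colder = softer
    figsize: tuple[float, float] = (8.0, 2.2)
    palette_rgb: dict = field(default_factory=lambda: dict(PALETTE_RGB))

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("a report needs at least one panel")


def _deterministic_save(fig, path: Path) -> None:
    with plt.rc_context({"svg.hashsalt": "strokenote"}):
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)


def _note_stream(obj: Union[MusicSession, SuperposedSession]):
    if isinstance(obj, SuperposedSession):
        return [n for _, n in obj.events], obj.duration
    return list(obj.notes), obj.duration


def render_music_report(
    obj: Union[MusicSession, SuperposedSession],
    spec: Optional[ReportSpec] = None,
    path: Union[str, Path] = "music_report.svg",
) -> Path:
    """Render the configured music panels into one stacked figure."""
    spec = spec or ReportSpec()
    unknown = set(spec.panels) - set(MUSIC_PANELS)
    if unknown:
        raise ValueError(f"unknown panel token(s): {sorted(unknown)}")
    path = Path(path)
    notes, duration = _note_stream(obj)
    n_panels = len(spec.panels)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(spec.figsize[0], spec.figsize[1] * n_panels),
        squeeze=False, constrained_layout=True,
    )
    xmax = max(duration, 1e-3)
    cmap = plt.get_cmap(spec.colormap)
    for ax, panel in zip(axes[:, 0], spec.panels):
        ax.set_xlim(0, xmax)
        ax.set_ylim(0, 127)
        ax.set_xlabel("time (s)")
        if panel == "intensity_timeline":
            segs = [[(n.onset, n.intensity), (n.offset, n.intensity)] for n in notes]
            ax.add_collection(LineCollection(segs, colors="#404040", linewidths=1.5))
            mf = spec.guides.get("mf_intensity", MF_INTENSITY)
            ax.axhline(mf, color="green", lw=1.0)
            ax.set_ylabel("intensity (MIDI)")
        elif panel == "notes_timeline":
            segs = [[(n.onset, n.pitch), (n.offset, n.pitch)] for n in notes]
            ax.add_collection(LineCollection(segs, colors="#404040", linewidths=1.5))
            c4 = spec.guides.get("middle_C", C4_PITCH)
            ax.axhline(c4, color="orange", lw=1.0)
            ax.set_ylabel("note (MIDI)")
        else:  # note_intensity_heatmap
            segs = [[(n.onset, n.pitch), (n.offset, n.pitch)] for n in notes]
            colors = [cmap(n.intensity / 127.0) for n in notes]
            ax.add_collection(LineCollection(segs, colors=colors, linewidths=2.5,
                                             gid="note-span"))
            ax.set_ylabel("note (MIDI)")
            sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, 127))
            cbar = fig.colorbar(sm, ax=ax, ticks=[i * 16 + 8 for i in range(8)])
            cbar.ax.set_yticklabels(DYNAMICS_BANDS)
    _deterministic_save(fig, path)
    return path


def _draw_canvas(ax, session: ArtSession, palette_rgb: dict, alpha: float = 1.0) -> None:
    ax.set_xlim(0, session.canvas_width)
    ax.set_ylim(session.canvas_height, 0)  # screen frame: y down
    ax.set_aspect("equal")
    ax.set_facecolor("#fbf7ef")
    for st in session.strokes:
        xs = [s.x for s in st.samples]
        ys = [s.y for s in st.samples]
        if st.is_eraser:
            ax.plot(xs, ys, color="#999999", lw=3.0, ls=":", alpha=alpha, gid="stroke")
        else:
            ax.plot(xs, ys, color=palette_rgb.get(st.color, "#000000"),
                    lw=2.0, alpha=alpha, gid="stroke")


def render_art_report(
    session: ArtSession,
    spec: Optional[ReportSpec] = None,
    path: Union[str, Path] = "art_report.svg",
) -> Path:
    """Render the art tracking graph: canvas, tool/color lanes, pressure."""
    spec = spec or ReportSpec(panels=("art_tracking_graph",))
    path = Path(path)
    fig = plt.figure(figsize=(9, 7), constrained_layout=True)
    gs = fig.add_gridspec(3, 2, height_ratios=[3, 1, 1])
    ax_canvas = fig.add_subplot(gs[0, :])
    ax_tool = fig.add_subplot(gs[1, :])
    ax_press = fig.add_subplot(gs[2, :])

    _draw_canvas(ax_canvas, session, spec.palette_rgb)
    ax_canvas.set_title("canvas")

    xmax = max(session.duration, 1e-3)
    tools = list(session.toolset)
    for st in session.strokes:
        lane = tools.index(st.tool)
        color = ("#cc2222" if st.is_eraser
                 else spec.palette_rgb.get(st.color, "#404040"))
        ax_tool.broken_barh([(st.start, max(st.end - st.start, xmax * 1e-3))],
                            (lane - 0.4, 0.8), facecolors=color,
                            gid="erasure-span" if st.is_eraser else "tool-span")
    ax_tool.set_xlim(0, xmax)
    ax_tool.set_yticks(range(len(tools)))
    ax_tool.set_yticklabels(tools, fontsize=7)
    ax_tool.set_ylim(-0.6, len(tools) - 0.4)
    ax_tool.set_ylabel("tool / color")

    for st in session.strokes:
        ax_press.plot([s.t for s in st.samples], [s.pressure for s in st.samples],
                      color="#404040", lw=1.0)
    ax_press.set_xlim(0, xmax)
    ax_press.set_ylim(0, 1)
    ax_press.set_ylabel("pressure")
    ax_press.set_xlabel("time (s)")
    _deterministic_save(fig, path)
    return path


def render_superposition_art(
    sessions: Sequence[ArtSession],
    opacity_pct: float = 50.0,
    path: Union[str, Path] = "superposition.svg",
    spec: Optional[ReportSpec] = None,
) -> Path:
    """Overlay per-session stroke renders at the given opacity (default 50%)."""
    if not sessions:
        raise ValueError("need at least one session to superimpose")
    if not 0 < opacity_pct <= 100:
        raise ValueError("opacity must be in (0, 100]")
    spec = spec or ReportSpec(panels=("superposition_render",))
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4.5), constrained_layout=True)
    for session in sessions:
        _draw_canvas(ax, session, spec.palette_rgb, alpha=opacity_pct / 100.0)
    w = max(s.canvas_width for s in sessions)
    h = max(s.canvas_height for s in sessions)
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)
    _deterministic_save(fig, path)
    return path


def metrics_table(
    metrics: Sequence[Union[MusicMetrics, ArtMetrics]],
    path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Flatten a homogeneous metrics list into a one-row-per-session table.

    Percentages are rounded to 1 decimal (table convention); written as CSV
    or JSON depending on the path suffix.
    """
    if not metrics:
        raise ValueError("empty metrics list")
    if len({m.modality for m in metrics}) != 1:
        raise ValueError("mixed modalities in one table")
    rows = [m.to_flat_dict() for m in metrics]
    df = pd.DataFrame(rows)
    for col in df.columns:
        if "pct" in col and pd.api.types.is_numeric_dtype(df[col]):
            df[col] = df[col].round(1)
    if path is not None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(df.to_json(orient="records", indent=1), encoding="utf-8")
        else:
            df.to_csv(path, index=False)
    return df
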