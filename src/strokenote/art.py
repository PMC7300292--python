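"""Art-modality metrics for a drawn session.

Covers the time budget (net drawing vs idle), erasure share, color/tool
preference profiles with switching rates and their (tool, color) cross-
section, stroke kinematics (arc length, velocity, net direction, amplitude,
rotation sense, pressure), and page-canvas use on a configurable grid
(cell occupancy, boundary/center dwell, horizontal/vertical page crossings).

Canvas coordinates follow the tablet convention: origin top-left,
y increasing downward.  Rotation sense (clockwise/counter-clockwise) is
reported as seen on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Optional, Sequence

from strokenote.events import ArtSession, Stroke
from strokenote.states import interval_union_length

#: compass labels for the 8 direction sectors of 45°, screen "up" = N
DIRECTION_BINS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")

#: |shoelace area| below this fraction of the bounding-box area → no rotation
ROTATION_AREA_FRAC = 0.01

DEFAULT_GRID = (3, 3)


@dataclass
class ArtMetrics:
    """The flat per-session art parameter record (one table row)."""

    total_duration_min: float
    net_drawing_time_s: float
    pct_net_drawing_time: float
    idle_time_s: float
    erasure_pct_of_drawing_time: Optional[float]
    color_use_pct: dict[str, float]
    tool_use_pct: dict[str, float]
    color_switches_per_min: float
    tool_switches_per_min: float
    pct_colors_used: float
    pct_tools_used: float
    color_by_tool_crosstab: dict[tuple[str, str], float]
    stroke_count: int
    total_stroke_length: float
    mean_stroke_length: float
    mean_drawing_velocity: float
    mean_pressure: Optional[float]
    pressure_max: Optional[float]
    rotation_counts: dict[str, int]
    direction_histogram: dict[str, int]
    canvas_cell_occupancy: float
    pct_time_on_boundary: float
    pct_time_in_center: float
    horizontal_crossings: int
    vertical_crossings: int

    modality = "art"

    def to_flat_dict(self) -> dict[str, Any]:
        """Flatten into scalar columns for tables and group comparison."""
        out: dict[str, Any] = {
            k: v for k, v in self.__dict__.items() if not isinstance(v, dict)
        }
        for color, v in sorted(self.color_use_pct.items()):
            out[f"color_pct_{color}"] = v
        for tool, v in sorted(self.tool_use_pct.items()):
            out[f"tool_pct_{tool}"] = v
        for sense in ("cw", "ccw", "none"):
            out[f"rotation_{sense}"] = self.rotation_counts.get(sense, 0)
        for name in DIRECTION_BINS:
            out[f"direction_{name}"] = self.direction_histogram.get(name, 0)
        for (tool, color), v in sorted(self.color_by_tool_crosstab.items()):
            out[f"crosstab_{tool}_{color}"] = v
        return out


@dataclass(frozen=True)
class StrokeFeatures:
    """Kinematic summary of one stroke."""

    length: float
    duration: float
    velocity: float
    direction: Optional[float]  # radians, screen-up = +pi/2; None if no net motion
    amplitude: float  # bounding-box diagonal
    rotation: str  # "cw" | "ccw" | "none"


def time_budget(session: ArtSession) -> tuple[float, float, float]:
    """(net drawing time incl. eraser strokes, % of session, idle time)."""
    net = interval_union_length(
        (st.start, st.end) for st in session.strokes if st.end > st.start
    )
    pct = 100.0 * net / session.duration if session.duration > 0 else 0.0
    return net, pct, session.duration - net


def stroke_features(stroke: Stroke) -> StrokeFeatures:
    """Arc length, velocity, net direction, amplitude and rotation sense.

    A one-sample stroke has zero length, velocity and amplitude and no
    rotation.  Rotation is the sign of the shoelace signed area of the
    closed polyline; near-straight strokes (area below 1% of the bounding
    box) count as "none".
    """
    pts = [(s.x, s.y) for s in stroke.samples]
    if len(pts) < 2:
        return StrokeFeatures(0.0, 0.0, 0.0, None, 0.0, "none")
    length = sum(math.dist(a, b) for a, b in zip(pts, pts[1:]))
    duration = stroke.end - stroke.start
    velocity = length / duration if duration > 0 else 0.0
    dx = pts[-1][0] - pts[0][0]
    dy = pts[-1][1] - pts[0][1]
    # direction in a y-up math frame so compass N points up on screen
    direction = math.atan2(-dy, dx) if (dx, dy) != (0.0, 0.0) else None
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    bbox_w, bbox_h = max(xs) - min(xs), max(ys) - min(ys)
    amplitude = math.hypot(bbox_w, bbox_h)
    # shoelace on raw screen coords: positive area = clockwise as seen on
    # screen (y points down)
    area = 0.5 * sum(
        a[0] * b[1] - b[0] * a[1] for a, b in zip(pts, pts[1:] + pts[:1])
    )
    bbox_area = bbox_w * bbox_h
    if bbox_area <= 0 or abs(area) < ROTATION_AREA_FRAC * bbox_area:
        rotation = "none"
    else:
        rotation = "cw" if area > 0 else "ccw"
    return StrokeFeatures(length, duration, velocity, direction, amplitude, rotation)


def _direction_bin(angle: float) -> str:
    return DIRECTION_BINS[round(angle / (math.pi / 4)) % 8]


def color_tool_usage(session: ArtSession) -> dict[str, Any]:
    """Color/tool preference profiles, switching rates and cross-section.

    Per-color and per-tool shares are % of net drawing time (eraser time
    included in the denominator, so color shares plus the eraser share
    partition drawing time).  A switch is a pair of consecutive strokes
    differing in color (eraser strokes skipped, their color token being
    meaningless) resp. tool; rates are per minute of session time.
    """
    net, _, _ = time_budget(session)
    color_time: dict[str, float] = {}
    tool_time: dict[str, float] = {}
    crosstab: dict[tuple[str, str], float] = {}
    for st in session.strokes:
        span = st.end - st.start
        tool_time[st.tool] = tool_time.get(st.tool, 0.0) + span
        if not st.is_eraser:
            color_time[st.color] = color_time.get(st.color, 0.0) + span
            key = (st.tool, st.color)
            crosstab[key] = crosstab.get(key, 0.0) + span
    color_pct = {c: (100.0 * v / net if net > 0 else 0.0) for c, v in color_time.items()}
    tool_pct = {t: (100.0 * v / net if net > 0 else 0.0) for t, v in tool_time.items()}

    colors_seq = [st.color for st in session.strokes if not st.is_eraser]
    tools_seq = [st.tool for st in session.strokes]
    color_switches = sum(1 for a, b in zip(colors_seq, colors_seq[1:]) if a != b)
    tool_switches = sum(1 for a, b in zip(tools_seq, tools_seq[1:]) if a != b)
    mins = session.duration / 60.0
    return {
        "color_use_pct": color_pct,
        "tool_use_pct": tool_pct,
        "color_switches": color_switches,
        "tool_switches": tool_switches,
        "color_switches_per_min": color_switches / mins if mins > 0 else 0.0,
        "tool_switches_per_min": tool_switches / mins if mins > 0 else 0.0,
        "pct_colors_used": 100.0 * len(set(colors_seq)) / len(session.palette),
        "pct_tools_used": 100.0 * len(set(tools_seq)) / len(session.toolset),
        "color_by_tool_crosstab": crosstab,
    }


def erasure_pct(session: ArtSession) -> Optional[float]:
    """Eraser-stroke time as % of net drawing time (None if nothing drawn)."""
    net, _, _ = time_budget(session)
    if net <= 0:
        return None
    eraser = sum(st.end - st.start for st in session.strokes if st.is_eraser)
    return 100.0 * eraser / net


def _sample_dwell_weights(stroke: Stroke) -> list[float]:
    """Per-sample dwell time: half of each adjacent inter-sample gap."""
    ts = [s.t for s in stroke.samples]
    n = len(ts)
    if n == 1:
        return [0.0]
    w = [0.0] * n
    for i in range(n - 1):
        dt = ts[i + 1] - ts[i]
        w[i] += dt / 2.0
        w[i + 1] += dt / 2.0
    return w


def stroke_aggregate(session: ArtSession) -> dict[str, Any]:
    """Counts, lengths, velocity, pressure statistics and per-stroke
    rotation/direction histograms.

    Mean drawing velocity is total arc length over net drawing time; mean
    pressure is dwell-time-weighted over all samples (falling back to a
    plain sample mean for zero-extent strokes).
    """
    feats = [stroke_features(st) for st in session.strokes]
    total_len = sum(f.length for f in feats)
    count = len(feats)
    net, _, _ = time_budget(session)
    rotation_counts = {"cw": 0, "ccw": 0, "none": 0}
    direction_hist = {name: 0 for name in DIRECTION_BINS}
    for f in feats:
        rotation_counts[f.rotation] += 1
        if f.direction is not None:
            direction_hist[_direction_bin(f.direction)] += 1
    p_num = p_den = 0.0
    p_all: list[float] = []
    p_max: Optional[float] = None
    for st in session.strokes:
        for s, w in zip(st.samples, _sample_dwell_weights(st)):
            p_num += w * s.pressure
            p_den += w
            p_all.append(s.pressure)
            p_max = s.pressure if p_max is None else max(p_max, s.pressure)
    if p_den > 0:
        mean_pressure: Optional[float] = p_num / p_den
    elif p_all:
        mean_pressure = sum(p_all) / len(p_all)
    else:
        mean_pressure = None
    return {
        "stroke_count": count,
        "total_stroke_length": total_len,
        "mean_stroke_length": total_len / count if count else 0.0,
        "mean_drawing_velocity": total_len / net if net > 0 else 0.0,
        "mean_pressure": mean_pressure,
        "pressure_max": p_max,
        "rotation_counts": rotation_counts,
        "direction_histogram": direction_hist,
    }


def _cell_index(v: float, extent: float, n: int) -> int:
    return min(int(v / extent * n), n - 1) if extent > 0 else 0


def canvas_usage(
    session: ArtSession, grid_rows: int = 3, grid_cols: int = 3
) -> dict[str, Any]:
    """Page-canvas use on a ``grid_rows × grid_cols`` grid (default 3×3).

    Occupancy is the % of cells holding ≥ 1 sample.  Boundary cells form
    the outer ring, center cells the middle cell(s); their shares are % of
    drawing time by sample dwell.  Horizontal (vertical) crossings count
    column (row) boundary passages along each stroke, summing |Δindex| over
    consecutive samples so re-sampling a straight segment cannot
    double-count.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise ValueError("grid must be at least 2×2")
    if session.canvas_width <= 0 or session.canvas_height <= 0:
        raise ValueError("degenerate canvas")
    w, h = session.canvas_width, session.canvas_height

    def center_indices(n: int) -> set[int]:
        return {n // 2} if n % 2 else {n // 2 - 1, n // 2}

    center_rows, center_cols = center_indices(grid_rows), center_indices(grid_cols)
    touched: set[tuple[int, int]] = set()
    dwell_boundary = dwell_center = dwell_total = 0.0
    h_cross = v_cross = 0
    for st in session.strokes:
        cells = [
            (_cell_index(s.y, h, grid_rows), _cell_index(s.x, w, grid_cols))
            for s in st.samples
        ]
        touched.update(cells)
        for (r1, c1), (r2, c2) in zip(cells, cells[1:]):
            h_cross += abs(c2 - c1)
            v_cross += abs(r2 - r1)
        for (r, c), dw in zip(cells, _sample_dwell_weights(st)):
            dwell_total += dw
            if r in (0, grid_rows - 1) or c in (0, grid_cols - 1):
                dwell_boundary += dw
            if r in center_rows and c in center_cols:
                dwell_center += dw
    n_cells = grid_rows * grid_cols
    return {
        "canvas_cell_occupancy": 100.0 * len(touched) / n_cells,
        "pct_time_on_boundary": 100.0 * dwell_boundary / dwell_total if dwell_total else 0.0,
        "pct_time_in_center": 100.0 * dwell_center / dwell_total if dwell_total else 0.0,
        "horizontal_crossings": h_cross,
        "vertical_crossings": v_cross,
    }


def art_metrics(
    session: ArtSession, grid: tuple[int, int] = DEFAULT_GRID
) -> ArtMetrics:
    """Populate the full :class:`ArtMetrics` record (pure function)."""
    session.validate()
    net, pct_net, idle = time_budget(session)
    usage = color_tool_usage(session)
    agg = stroke_aggregate(session)
    canvas = canvas_usage(session, *grid)
    return ArtMetrics(
        total_duration_min=session.duration / 60.0,
        net_drawing_time_s=net,
        pct_net_drawing_time=pct_net,
        idle_time_s=idle,
        erasure_pct_of_drawing_time=erasure_pct(session),
        color_use_pct=usage["color_use_pct"],
        tool_use_pct=usage["tool_use_pct"],
        color_switches_per_min=usage["color_switches_per_min"],
        tool_switches_per_min=usage["tool_switches_per_min"],
        pct_colors_used=usage["pct_colors_used"],
        pct_tools_used=usage["pct_tools_used"],
        color_by_tool_crosstab=usage["color_by_tool_crosstab"],
        stroke_count=agg["stroke_count"],
        total_stroke_length=agg["total_stroke_length"],
        mean_stroke_length=agg["mean_stroke_length"],
        mean_drawing_velocity=agg["mean_drawing_velocity"],
        mean_pressure=agg["mean_pressure"],
        pressure_max=agg["pressure_max"],
        rotation_counts=agg["rotation_counts"],
        direction_histogram=agg["direction_histogram"],
        canvas_cell_occupancy=canvas["canvas_cell_occupancy"],
        pct_time_on_boundary=canvas["pct_time_on_boundary"],
        pct_time_in_center=canvas["pct_time_in_center"],
        horizontal_crossings=canvas["horizontal_crossings"],
        vertical_crossings=canvas["vertical_crossings"],
    )
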