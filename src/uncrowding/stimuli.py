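"""Vernier/flanker stimulus construction and rasterization.

Coordinate frame: origin at the vernier center, x rightward, y upward,
units arcmin. Vernier offsets are given in arcsec. The vernier is two
vertical 40' lines separated by a 4' gap (total height 84'); the bottom
line carries the horizontal offset. Flanker configurations nest:
Lines < Rectangles < Cubes, each obtained by adding segments.

Rasters are 4-channel binary occupancy grids (vertical, horizontal,
diag45, diag135) drawn with a deterministic nearest-pixel (midpoint) line
rule: pixels are sampled along the major axis and the end pixel farther
from the stimulus center is left open, so a segment of L arcmin occupies
round(L * px_per_arcmin) pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from uncrowding.params import GeometrySpec

CHANNELS = ("vertical", "horizontal", "diag45", "diag135")
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

FLANKER_CONFIGS = (
    "Lines",
    "Rectangles",
    "Cubes",
    "Triangles",
    "CentralRectangle",
    "ScrambledCubes",
)

MAX_OFFSET_ARCSEC = 1600.0

# scrambled strokes stay clear of the target and template-readout zone,
# i.e. within the flanker region proper
_VERNIER_ZONE_ARCMIN = 35.0


def classify_orientation(dx: float, dy: float) -> str:
    """Nearest orientation channel for a direction vector.

    Exactly vertical/horizontal/diagonal segments map to their own channel;
    intermediate angles (e.g. the triangle obliques) are binned to the
    nearest of 0, 45, 90, 135 degrees.
    """
    if dx == 0 and dy == 0:
        raise ValueError("zero-length segment has no orientation")
    angle = math.degrees(math.atan2(dy, dx)) % 180.0
    # bins centered at 0 (horizontal), 45, 90 (vertical), 135
    centers = {"horizontal": 0.0, "diag45": 45.0, "vertical": 90.0, "diag135": 135.0}
    best, bestd = None, 1e9
    for name, c in centers.items():
        d = min(abs(angle - c), 180.0 - abs(angle - c))
        if d < bestd:
            best, bestd = name, d
    return best


@dataclass(frozen=True)
class LineSegment:
    """A straight stroke in arcmin coordinates with an orientation channel."""

    x1: float
    y1: float
    x2: float
    y2: float
    orientation_class: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("segment length must be > 0")
        auto = classify_orientation(self.x2 - self.x1, self.y2 - self.y1)
        if self.orientation_class == "":
            object.__setattr__(self, "orientation_class", auto)
        elif self.orientation_class not in CHANNELS:
            raise ValueError(f"unknown orientation_class {self.orientation_class!r}")
        elif self.orientation_class != auto:
            raise ValueError(
                f"orientation_class {self.orientation_class!r} inconsistent with "
                f"segment angle (expected {auto!r})"
            )

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    def mirrored(self) -> "LineSegment":
        """Reflection about the vertical midline x = 0."""
        return LineSegment(-self.x1, self.y1, -self.x2, self.y2)

    def translated(self, dx: float, dy: float) -> "LineSegment":
        return LineSegment(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy)


@dataclass(frozen=True)
class StimulusFrame:
    """One display frame: a set of segments plus vernier bookkeeping."""

    segments: tuple[LineSegment, ...]
    label: str = ""
    vernier_offset: float = 0.0  # arcsec, signed; positive = bottom line right
    contains_vernier: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.contains_vernier and self.vernier_offset != 0.0:
            raise ValueError("vernier_offset must be 0 when contains_vernier is False")

    @property
    def is_blank(self) -> bool:
        return len(self.segments) == 0


BLANK = StimulusFrame(segments=(), label="blank")


@dataclass(frozen=True)
class FrameSequence:
    """Ordered frames with durations (ms); encodes one condition's timeline."""

    frames: tuple[StimulusFrame, ...]
    durations_ms: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        object.__setattr__(self, "durations_ms", tuple(int(d) for d in self.durations_ms))
        if len(self.frames) != len(self.durations_ms):
            raise ValueError("frames and durations_ms must have equal length")
        if any(d <= 0 for d in self.durations_ms):
            raise ValueError("durations must be positive")

    @property
    def total_duration_ms(self) -> int:
        return sum(self.durations_ms)

    @property
    def vernier_onset_ms(self) -> int | None:
        """Time at which the first vernier-bearing frame begins, or None."""
        t = 0
        for frame, dur in zip(self.frames, self.durations_ms):
            if frame.contains_vernier:
                return t
            t += dur
        return None


# ---------------------------------------------------------------------------
# vernier and flankers


def make_vernier(
    offset_arcsec: float, geometry: GeometrySpec | None = None
) -> list[LineSegment]:
    """Two vertical lines; the bottom one is displaced by the signed offset.

    Positive offsets displace the bottom line rightward. Offsets beyond
    1,600'' (the staircase cap) are rejected.
    """
    if abs(offset_arcsec) > MAX_OFFSET_ARCSEC:
        raise ValueError(
            f"|offset| = {abs(offset_arcsec)}'' exceeds the {MAX_OFFSET_ARCSEC}'' bound"
        )
    g = geometry or GeometrySpec()
    half_gap = g.vernier_gap / 2.0
    dx = offset_arcsec / 60.0  # arcsec -> arcmin
    top = LineSegment(0.0, half_gap, 0.0, half_gap + g.vernier_line_len)
    bottom = LineSegment(dx, -half_gap - g.vernier_line_len, dx, -half_gap)
    return [top, bottom]


def _right_lines(g: GeometrySpec) -> list[LineSegment]:
    x = g.line_separation / 2.0
    h = g.flanker_line_len / 2.0
    return [LineSegment(x, -h, x, h)]


def _right_rectangle(g: GeometrySpec) -> list[LineSegment]:
    xi = g.line_separation / 2.0
    xo = xi + g.rect_width
    h = g.flanker_line_len / 2.0
    return _right_lines(g) + [
        LineSegment(xo, -h, xo, h),
        LineSegment(xi, h, xo, h),
        LineSegment(xi, -h, xo, -h),
    ]


def _right_cube(g: GeometrySpec) -> list[LineSegment]:
    xi = g.line_separation / 2.0
    xo = xi + g.rect_width
    h = g.flanker_line_len / 2.0
    d = g.cube_oblique_len * math.cos(math.radians(g.cube_oblique_angle))
    # obliques from top-left, top-right and bottom-right front corners toward
    # the upper right; back-face edges join the oblique endpoints
    segs = _right_rectangle(g) + [
        LineSegment(xi, h, xi + d, h + d),
        LineSegment(xo, h, xo + d, h + d),
        LineSegment(xo, -h, xo + d, -h + d),
        LineSegment(xi + d, h + d, xo + d, h + d),
        LineSegment(xo + d, -h + d, xo + d, h + d),
    ]
    return segs


def _right_triangle(g: GeometrySpec) -> list[LineSegment]:
    xi = g.line_separation / 2.0
    h = g.triangle_inner / 2.0
    reach = math.sqrt(g.triangle_oblique**2 - h**2)
    apex_x = xi + reach  # lands near the cube front face's far edge (~140')
    return [
        LineSegment(xi, -h, xi, h),
        LineSegment(xi, h, apex_x, 0.0),
        LineSegment(xi, -h, apex_x, 0.0),
    ]


def _central_rectangle(g: GeometrySpec) -> list[LineSegment]:
    w = g.central_rect_w / 2.0
    h = g.central_rect_h / 2.0
    return [
        LineSegment(-w, -h, -w, h),
        LineSegment(w, -h, w, h),
        LineSegment(-w, h, w, h),
        LineSegment(-w, -h, w, -h),
    ]


def _cube_bbox(g: GeometrySpec) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of the right-side cube."""
    xi = g.line_separation / 2.0
    xo = xi + g.rect_width
    h = g.flanker_line_len / 2.0
    d = g.cube_oblique_len * math.cos(math.radians(g.cube_oblique_angle))
    return (xi, xo + d, -h, h + d)


# scrambled segments keep at least this clearance from one another so the
# scatter stays a set of disconnected strokes rather than a tangled network
_SCRAMBLE_CLEARANCE_ARCMIN = 5.0

# and from the outer part of the original cube outline, so the innermost
# strokes stay disconnected from where the cube's boundary was drawn
_WIREFRAME_CLEARANCE_ARCMIN = 6.0
_WIREFRAME_ZONE_X_ARCMIN = 58.0
_OBLIQUE_STUB_ARCMIN = 26.0


def _segment_points(x1, y1, x2, y2, step=2.0):
    n = max(2, int(math.hypot(x2 - x1, y2 - y1) / step) + 1)
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack([x1 + t * (x2 - x1), y1 + t * (y2 - y1)])


def _min_separation(cand_pts, placed_pts) -> float:
    if placed_pts is None:
        return math.inf
    d = cand_pts[:, None, :] - placed_pts[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).min())


def _scrambled_side(
    g: GeometrySpec, rng: np.random.Generator, side: int
) -> list[LineSegment]:
    """Reposition the cube's segments uniformly inside its bounding box.

    Each segment keeps its length and orientation; positions are redrawn if
    any endpoint would fall within the central vernier zone (|x| < 15') or
    within 4' of an already placed segment, so the scrambled strokes form
    isolated, unconnectable pieces.
    """
    xmin, xmax, ymin, ymax = _cube_bbox(g)
    cube_segs = _right_cube(g)
    # the scatter stays clear of the outer part of the original front-face
    # outline and of the oblique stubs at the front corners, so the strokes
    # are disconnected from where the cube's boundary was drawn (full
    # avoidance is infeasible, the long strokes must cross the inner
    # outline rows somewhere)
    front_pts = np.vstack(
        [_segment_points(s.x1, s.y1, s.x2, s.y2) for s in _right_rectangle(g)]
    )
    front_pts = front_pts[np.abs(front_pts[:, 0]) >= _WIREFRAME_ZONE_X_ARCMIN]
    stub_pts = []
    for s in cube_segs:
        if s.orientation_class in ("diag45", "diag135"):
            pts = _segment_points(s.x1, s.y1, s.x2, s.y2)
            d = np.hypot(pts[:, 0] - s.x1, pts[:, 1] - s.y1)
            stub_pts.append(pts[d <= _OBLIQUE_STUB_ARCMIN])
    wire_pts = np.vstack([front_pts] + stub_pts)
    if side < 0:
        wire_pts = wire_pts * np.array([-1.0, 1.0])
    # longest strokes are hardest to place, so they go first
    order = sorted(cube_segs, key=lambda s: -s.length)
    for _restart in range(100):
        out: list[LineSegment] = []
        placed_pts = None
        ok = True
        for seg in order:
            dx, dy = seg.x2 - seg.x1, seg.y2 - seg.y1
            for _ in range(200):
                x1 = rng.uniform(xmin, xmax - abs(dx)) + (0 if dx >= 0 else abs(dx))
                y1 = rng.uniform(ymin, ymax - abs(dy)) + (0 if dy >= 0 else abs(dy))
                x2, y2 = x1 + dx, y1 + dy
                cand = (x1, y1, x2, y2)
                if side < 0:
                    cand = (-x1, y1, -x2, y2)
                if min(abs(cand[0]), abs(cand[2])) < _VERNIER_ZONE_ARCMIN:
                    continue
                pts = _segment_points(*cand)
                if _min_separation(pts, placed_pts) < _SCRAMBLE_CLEARANCE_ARCMIN:
                    continue
                if _min_separation(pts, wire_pts) < _WIREFRAME_CLEARANCE_ARCMIN:
                    continue
                out.append(LineSegment(*cand))
                placed_pts = pts if placed_pts is None else np.vstack([placed_pts, pts])
                break
            else:
                ok = False
                break
        if ok:
            return out
    raise RuntimeError("could not place scrambled segments")  # pragma: no cover


def make_flankers(
    config: str,
    geometry: GeometrySpec | None = None,
    seed: int | None = None,
) -> list[LineSegment]:
    """Build the segment list for a named flanker configuration.

    Segments are mirror-symmetric about x = 0 for all configurations except
    ScrambledCubes, whose per-side scramble is only confined to the mirrored
    bounding boxes. ScrambledCubes requires ``seed`` for reproducibility.
    """
    g = geometry or GeometrySpec()
    if config not in FLANKER_CONFIGS:
        raise ValueError(f"unknown flanker configuration {config!r}")
    if config == "CentralRectangle":
        return _central_rectangle(g)
    if config == "ScrambledCubes":
        if seed is None:
            raise ValueError("ScrambledCubes requires a seed")
        rng = np.random.default_rng(seed)
        return _scrambled_side(g, rng, +1) + _scrambled_side(g, rng, -1)
    builders = {
        "Lines": _right_lines,
        "Rectangles": _right_rectangle,
        "Cubes": _right_cube,
        "Triangles": _right_triangle,
    }
    right = builders[config](g)
    return right + [s.mirrored() for s in right]


# ---------------------------------------------------------------------------
# rasterization


def _pixel_grid(px_per_arcmin: float, canvas_x, canvas_y):
    x0, x1 = canvas_x
    y0, y1 = canvas_y
    w = int(round((x1 - x0) * px_per_arcmin)) + 1
    h = int(round((y1 - y0) * px_per_arcmin)) + 1
    return h, w


def _to_px(x: float, y: float, px_per_arcmin: float, canvas_x, canvas_y):
    """Continuous pixel coordinates (col, row); row 0 is the canvas top."""
    col = (x - canvas_x[0]) * px_per_arcmin
    row = (canvas_y[1] - y) * px_per_arcmin
    return col, row


def _draw_segment(seg: LineSegment, px_per_arcmin: float, canvas_x, canvas_y):
    """Pixel (row, col) list under the half-open nearest-pixel rule.

    The stroke runs from the endpoint nearer the stimulus center outward and
    the final (outer) pixel is left open, so lengths in pixels equal lengths
    in arcmin times the resolution. Rounding is half-to-even, which commutes
    with reflection about the canvas midline.
    """
    p1 = (seg.x1, seg.y1)
    p2 = (seg.x2, seg.y2)
    n1 = abs(seg.x1) + abs(seg.y1)
    n2 = abs(seg.x2) + abs(seg.y2)
    if (n1, seg.y1, seg.x1) > (n2, seg.y2, seg.x2):
        p1, p2 = p2, p1
    c1, r1 = _to_px(*p1, px_per_arcmin, canvas_x, canvas_y)
    c2, r2 = _to_px(*p2, px_per_arcmin, canvas_x, canvas_y)
    dc, dr = c2 - c1, r2 - r1
    n = int(round(max(abs(dc), abs(dr))))
    if n == 0:
        n = 1
    # march whole pixels along the major axis from the inner end; the minor
    # coordinate is the nearest pixel center (round half to even, which
    # commutes with reflection about the canvas midline)
    i = np.arange(n)
    if abs(dc) >= abs(dr):
        cols = int(np.rint(c1)) + i * int(np.sign(dc) or 1)
        rows = np.rint(r1 + (cols - c1) * (dr / dc if dc else 0.0)).astype(int)
    else:
        rows = int(np.rint(r1)) + i * int(np.sign(dr) or 1)
        cols = np.rint(c1 + (rows - r1) * (dc / dr)).astype(int)
    return rows, cols


def rasterize(
    frame: StimulusFrame,
    px_per_arcmin: float = 0.5,
    canvas_x: tuple[float, float] = (-200.0, 200.0),
    canvas_y: tuple[float, float] = (-100.0, 100.0),
) -> np.ndarray:
    """Binary occupancy raster, shape (4, H, W), one orientation per channel.

    Raises if any segment endpoint falls outside the canvas.
    """
    if px_per_arcmin <= 0:
        raise ValueError("px_per_arcmin must be positive")
    h, w = _pixel_grid(px_per_arcmin, canvas_x, canvas_y)
    raster = np.zeros((len(CHANNELS), h, w), dtype=np.uint8)
    for seg in frame.segments:
        for x, y in ((seg.x1, seg.y1), (seg.x2, seg.y2)):
            if not (canvas_x[0] <= x <= canvas_x[1] and canvas_y[0] <= y <= canvas_y[1]):
                raise ValueError(
                    f"segment ({seg.x1},{seg.y1})-({seg.x2},{seg.y2}) exceeds canvas"
                )
        rows, cols = _draw_segment(seg, px_per_arcmin, canvas_x, canvas_y)
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        raster[CHANNEL_INDEX[seg.orientation_class], rows[ok], cols[ok]] = 1
    return raster


# ---------------------------------------------------------------------------
# condition timelines

EXP1_FLANKERS = ("Lines", "Rectangles", "Cubes", "unflanked")
EXP1_DURATIONS = (20, 160)
EXP2_FLANKERS = ("Lines", "Cubes")
EXP2_MODES = ("preview", "postview", "baseline")
EXP3_ISIS = (20, 120, 260, 600, 1000, 1500, 2000)
EXP4_INTERMEDIATES = (
    "Cubes",
    "Rectangles",
    "Triangles",
    "CentralRectangle",
    "ScrambledCubes",
    "Lines",
)


def _frame(
    segments, label, offset_arcsec=0.0, contains_vernier=False
) -> StimulusFrame:
    return StimulusFrame(
        segments=tuple(segments),
        label=label,
        vernier_offset=offset_arcsec if contains_vernier else 0.0,
        contains_vernier=contains_vernier,
    )


def _vernier_frame(flanker: str | None, offset_arcsec, g, seed) -> StimulusFrame:
    segs = make_vernier(offset_arcsec, g)
    label = "vernier"
    if flanker is not None:
        segs = segs + make_flankers(flanker, g, seed=seed)
        label = f"vernier+{flanker}"
    return _frame(segs, label, offset_arcsec, contains_vernier=True)


def _flanker_frame(flanker: str, g, seed) -> StimulusFrame:
    return _frame(make_flankers(flanker, g, seed=seed), flanker)


def build_sequence(
    experiment: int,
    condition: str,
    offset_arcsec: float = 240.0,
    geometry: GeometrySpec | None = None,
    seed: int | None = None,
) -> FrameSequence:
    """Frame timeline for one experimental condition.

    Condition labels:

    * Experiment 1 -- ``"<flanker>-<duration>"`` with flanker in
      {Lines, Rectangles, Cubes, unflanked} and duration in {20, 160} ms.
    * Experiment 2 -- ``"<flanker>-<mode>"`` with flanker in {Lines, Cubes}
      and mode in {preview, postview, baseline}; pre/postview insert a
      120-ms blank and a 20-ms flanker-only display.
    * Experiment 3 -- ``"isi-<ms>"`` (Cubes preview with the given ISI) or
      ``"baseline"`` (Cubes + vernier, 20 ms).
    * Experiment 4 -- ``"<intermediate>"`` or ``"baseline"``; the full
      timeline is Cubes 20 ms, blank 120 ms, intermediate 20 ms, blank
      120 ms, Cubes + vernier 20 ms.
    """
    g = geometry or GeometrySpec()

    def bad():
        raise ValueError(f"invalid condition {condition!r} for experiment {experiment}")

    if experiment == 1:
        parts = condition.rsplit("-", 1)
        if len(parts) != 2:
            bad()
        flank, dur = parts[0], parts[1]
        if flank not in EXP1_FLANKERS or not dur.isdigit() or int(dur) not in EXP1_DURATIONS:
            bad()
        fl = None if flank == "unflanked" else flank
        frames = [_vernier_frame(fl, offset_arcsec, g, seed)]
        durs = [int(dur)]
    elif experiment == 2:
        parts = condition.rsplit("-", 1)
        if len(parts) != 2 or parts[0] not in EXP2_FLANKERS or parts[1] not in EXP2_MODES:
            bad()
        flank, mode = parts
        target = _vernier_frame(flank, offset_arcsec, g, seed)
        if mode == "baseline":
            frames, durs = [target], [20]
        elif mode == "preview":
            frames = [_flanker_frame(flank, g, seed), BLANK, target]
            durs = [20, 120, 20]
        else:
            frames = [target, BLANK, _flanker_frame(flank, g, seed)]
            durs = [20, 120, 20]
    elif experiment == 3:
        if condition == "baseline":
            frames = [_vernier_frame("Cubes", offset_arcsec, g, seed)]
            durs = [20]
        elif condition.startswith("isi-") and condition[4:].isdigit() and int(condition[4:]) in EXP3_ISIS:
            isi = int(condition[4:])
            frames = [
                _flanker_frame("Cubes", g, seed),
                BLANK,
                _vernier_frame("Cubes", offset_arcsec, g, seed),
            ]
            durs = [20, isi, 20]
        else:
            bad()
    elif experiment == 4:
        if condition == "baseline":
            frames = [_vernier_frame("Cubes", offset_arcsec, g, seed)]
            durs = [20]
        elif condition in EXP4_INTERMEDIATES:
            frames = [
                _flanker_frame("Cubes", g, seed),
                BLANK,
                _flanker_frame(condition, g, seed),
                BLANK,
                _vernier_frame("Cubes", offset_arcsec, g, seed),
            ]
            durs = [20, 120, 20, 120, 20]
        else:
            bad()
    else:
        raise ValueError(f"experiment must be 1-4, got {experiment}")
    return FrameSequence(frames=tuple(frames), durations_ms=tuple(durs),
                         label=f"exp{experiment}:{condition}")


def condition_inventory(experiment: int) -> list[str]:
    """All condition labels run for an experiment."""
    if experiment == 1:
        conds = [f"{f}-{d}" for f in ("Lines", "Rectangles", "Cubes") for d in EXP1_DURATIONS]
        return conds + ["unflanked-20"]
    if experiment == 2:
        return [f"{f}-{m}" for f in EXP2_FLANKERS for m in EXP2_MODES]
    if experiment == 3:
        return [f"isi-{i}" for i in EXP3_ISIS] + ["baseline"]
    if experiment == 4:
        return list(EXP4_INTERMEDIATES) + ["baseline"]
    raise ValueError(f"experiment must be 1-4, got {experiment}")


def segments_to_table(frames: list[StimulusFrame]):
    """Segment table across frames (columns: frame_idx, x1, y1, x2, y2, orientation_class)."""
    import pandas as pd

    rows = []
    for i, fr in enumerate(frames):
        for s in fr.segments:
            rows.append((i, s.x1, s.y1, s.x2, s.y2, s.orientation_class))
    return pd.DataFrame(rows, columns=["frame_idx", "x1", "y1", "x2", "y2", "orientation_class"])
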