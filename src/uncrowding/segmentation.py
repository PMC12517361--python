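"""Top-down selection signals, spreading along contours, and layer transfer.

A selection signal is a sustained top-down input at a fixed retinotopic
location (one per flanker side). Every step it marks contour-bearing pixels
inside its radius; from the marked support, the selection mask grows by
breadth-first rings over living contours (8-connected, tolerating single
pixel gaps). Growth is fast on strongly driven contours and slower on
persisting (decaying) ones, which is what makes segmentation time consuming:
briefly shown flankers are only partially selected before their contours
fade below the spreading threshold.

Selected Layer-0 activity is transferred to Layer 1 at the same pixel
locations, which removes it from the evidence readout (uncrowding). The mask
itself decays with ``tau_selection_ms`` so that a selection built during a
preview is lost after long blank intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from uncrowding.field import OrientationField, step_field
from uncrowding.params import GeometrySpec, ModelParams

_RING = np.ones((3, 3), dtype=bool)  # 8-connectivity

# mask values below this no longer support further spreading; with the
# default selection decay this means a selected location stops recruiting
# neighbours roughly 50 ms after it was last reached
MASK_SUPPORT_THRESHOLD = 0.6

# bottom-up input at pixels whose mask exceeds this is routed to Layer 1
ROUTING_THRESHOLD = 0.25


@dataclass(frozen=True)
class SelectionSignal:
    """A circular top-down selection seed, arcmin coordinates."""

    center_x: float
    center_y: float
    radius: float
    onset_ms: int = 0
    side: str = "right"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("selection signal radius must be > 0")


@dataclass
class SegmentationState:
    """Orientation field plus the selection mask and planted signals.

    ``seeded_at_ms`` records when a signal first marked contour pixels;
    spreading begins on the following step.
    """

    field: OrientationField
    selected_mask: np.ndarray  # (H, W) float in [0, 1]
    signals: list[SelectionSignal] = dc_field(default_factory=list)
    seeded_at_ms: int | None = None

    def copy(self) -> "SegmentationState":
        return SegmentationState(
            self.field.copy(),
            self.selected_mask.copy(),
            list(self.signals),
            self.seeded_at_ms,
        )


def init_state(
    raster_shape: tuple[int, int],
    signals: list[SelectionSignal] | None = None,
) -> SegmentationState:
    from uncrowding.field import init_field

    h, w = raster_shape
    return SegmentationState(
        field=init_field(raster_shape),
        selected_mask=np.zeros((h, w)),
        signals=list(signals or []),
    )


# fixed per-configuration seed abscissa (arcmin); the location is chosen once
# per configuration so that it sits on the flanker structure
def _seed_center_x(config: str, g: GeometrySpec) -> float:
    half_sep = g.line_separation / 2.0
    if config == "Lines":
        return half_sep
    if config in ("Rectangles", "Cubes", "ScrambledCubes"):
        return half_sep + g.rect_width  # outer front edge
    if config == "Triangles":
        import math

        return half_sep + math.sqrt(g.triangle_oblique**2 - (g.triangle_inner / 2) ** 2)
    if config == "CentralRectangle":
        return g.central_rect_w / 2.0
    raise ValueError(f"unknown flanker configuration {config!r}")


def place_selection_signals(
    config: str | None,
    params: ModelParams,
    rng: np.random.Generator,
    geometry: GeometrySpec | None = None,
    onset_ms: int = 0,
) -> list[SelectionSignal]:
    """One jittered signal per flanker side; none for an unflanked vernier."""
    if config is None or config == "unflanked":
        return []
    g = geometry or GeometrySpec()
    x_c = _seed_center_x(config, g)
    sigma = params.seed_jitter_arcmin
    out = []
    for side, sx in (("right", +1.0), ("left", -1.0)):
        if sigma > 0:
            # bounded scatter: the top-down signal aims at a fixed location
            # and gross mislocations do not occur
            while True:
                jx, jy = rng.normal(0.0, sigma, size=2)
                if abs(jx) <= 1.5 * sigma and abs(jy) <= 1.5 * sigma:
                    break
        else:
            jx, jy = 0.0, 0.0
        radius = (
            params.seed_radius_lines_arcmin
            if config in ("Lines", "CentralRectangle")
            else params.seed_radius_arcmin
        )
        out.append(
            SelectionSignal(
                center_x=sx * x_c + jx,
                center_y=jy,
                radius=radius,
                onset_ms=onset_ms,
                side=side,
            )
        )
    return out


def _signal_disk(
    sig: SelectionSignal, shape: tuple[int, int], params: ModelParams
) -> np.ndarray:
    """Boolean pixel disk of a signal on the model canvas."""
    h, w = shape
    s = params.px_per_arcmin
    col_c = (sig.center_x - params.canvas_x_arcmin[0]) * s
    row_c = (params.canvas_y_arcmin[1] - sig.center_y) * s
    rows, cols = np.ogrid[:h, :w]
    return (rows - row_c) ** 2 + (cols - col_c) ** 2 <= (sig.radius * s) ** 2


def _alive(field: OrientationField, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """(alive mask, per-pixel max activity) over both layers and all channels."""
    act = field.activity.max(axis=(0, 1))
    return act > params.spread_threshold, act


def ring_candidates(
    support: np.ndarray, alive: np.ndarray
) -> np.ndarray:
    """Pixels reachable in one BFS ring: 8-neighbours of the support that
    carry living contour activity. Spreading therefore crosses only
    connected contours; the rasterized wireframes are 8-connected by
    construction, so a break in the drawing stops the spread."""
    d1 = ndimage.binary_dilation(support, structure=_RING) & ~support
    return d1 & alive


def seed_and_spread(
    state: SegmentationState,
    params: ModelParams,
    input_raster: np.ndarray | None = None,
) -> SegmentationState:
    """Apply one step of mask decay, seeding, and budgeted BFS growth.

    Ring budget per step: up to ``spread_fast_px`` rings of 8-connected
    growth, of which only the first ``spread_slow_px`` may advance across
    weak persisting traces; the remainder advance solely across strongly
    driven contours (activity at least ``spread_fast_threshold``). Selection
    therefore sweeps quickly over a stimulus that is on screen and crawls
    along decaying afterimages.
    """
    m = state.selected_mask
    alive, act = _alive(state.field, params)
    # decay everywhere; the sustained signals re-mark their disks below.
    # Growth expands only from mask laid down on earlier steps, so a pixel
    # seeded this step supports spreading from the next step on.
    m = m * np.exp(-params.dt_ms / params.tau_selection_ms)
    support = m > MASK_SUPPORT_THRESHOLD
    # the sustained signal only grabs strongly active contours; weak decaying
    # traces under the disk are not re-marked
    grabbable = act > params.seed_threshold
    for sig in state.signals:
        if state.field.time_ms > sig.onset_ms:
            disk = _signal_disk(sig, m.shape, params)
            hit = disk & grabbable
            if hit.any():
                m = np.where(hit, 1.0, m)
                if state.seeded_at_ms is None:
                    state.seeded_at_ms = state.field.time_ms
    if support.any():
        # a pixel counts as strongly driven if the current stimulus draws a
        # contour there, or its trace is still essentially at ceiling
        fresh = act >= params.spread_fast_threshold
        if input_raster is not None:
            fresh = fresh | (input_raster.max(axis=0) > 0)
        # fast phase: rings across strongly driven contours, launched only
        # from support on or next to driven contours (a re-presented or
        # abutting object re-activates the selected trace and is swept
        # immediately; a decaying trace only sustains the slow crawl below)
        b_support = support & ndimage.binary_dilation(fresh, structure=_RING)
        for _ in range(params.spread_fast_px - params.spread_slow_px):
            if not b_support.any():
                break
            cand = ring_candidates(b_support, alive) & fresh
            if not cand.any():
                break
            b_support = b_support | cand
            support = support | cand
            m = np.where(cand, 1.0, m)
        # slow phase: rings across any living contour
        for _ in range(params.spread_slow_px):
            cand = ring_candidates(support, alive)
            if not cand.any():
                break
            support = support | cand
            m = np.where(cand, 1.0, m)
    state.selected_mask = m
    return state


def transfer_contours(state: SegmentationState, params: ModelParams) -> SegmentationState:
    """Move selected Layer-0 activity to Layer 1 at the same pixel locations.

    The transferred amount is rho * mask * a0 per channel, capped so Layer-1
    activity stays within [0, 1]; the per-pixel two-layer sum is conserved
    exactly at the instant of transfer.
    """
    a = state.field.activity
    s = state.selected_mask[None, :, :]
    delta = np.minimum(params.transfer_rate * s * a[0], 1.0 - a[1])
    a[0] -= delta
    a[1] += delta
    return state


def step_segmentation(
    state: SegmentationState,
    input_raster: np.ndarray | None,
    params: ModelParams,
) -> SegmentationState:
    """One full 20-ms model step: drive/decay, then spread, then transfer.

    Bottom-up drive at pixels held by the selection mask (above the routing
    threshold) is routed into Layer 1: once a contour location is selected,
    re-presented input at that location joins the shifted representation
    instead of refilling Layer 0. Unselected drive enters Layer 0 as usual.
    """
    routed = None
    if input_raster is None:
        state.field = step_field(state.field, None, params)
    else:
        routed = (state.selected_mask > ROUTING_THRESHOLD)[None, :, :]
        state.field = step_field(state.field, input_raster * ~routed, params)
    state = seed_and_spread(state, params, input_raster)
    state = transfer_contours(state, params)
    if routed is not None:
        # routed drive joins Layer 1 after transfer so that transfer keeps
        # the headroom opened by this step's decay
        a = state.field.activity
        a[1] = np.minimum(1.0, a[1] + input_raster * routed)
    return state
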