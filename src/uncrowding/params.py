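"""Geometry and model parameter containers.

All spatial quantities are in arcmin unless the name says otherwise; vernier
offsets are in arcsec (1' = 60''). Time is in milliseconds and the simulation
advances in fixed 20-ms steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class GeometrySpec:
    """Printed stimulus dimensions, arcmin.

    The vernier is two vertical lines of ``vernier_line_len`` separated by
    ``vernier_gap``; its total height (2*40' + 4' = 84') equals the flanker
    line length. The two flanking lines sit ``line_separation`` apart,
    i.e. at x = +/- line_separation/2. Rectangles share the flanker height
    and are ``rect_width`` wide; Cubes add 45-degree obliques of
    ``cube_oblique_len`` plus back-face edges. Triangles have an 84' inner
    vertical side and 124.3' obliques; the Central-Rectangle is a single
    46' x 84' outline at the origin.
    """

    vernier_line_len: float = 40.0
    vernier_gap: float = 4.0
    flanker_line_len: float = 84.0
    line_separation: float = 46.0
    rect_width: float = 117.0
    cube_oblique_len: float = 53.0
    cube_oblique_angle: float = 45.0
    triangle_inner: float = 84.0
    triangle_oblique: float = 124.3
    central_rect_w: float = 46.0
    central_rect_h: float = 84.0
    eccentricity_deg: float = 9.0  # metadata only; the canvas is stimulus-centered

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "eccentricity_deg" and not v > 0:
                raise ValueError(f"GeometrySpec.{f.name} must be > 0, got {v}")
        total = 2 * self.vernier_line_len + self.vernier_gap
        if abs(total - self.flanker_line_len) > 1e-9:
            raise ValueError(
                "vernier total height (2*line + gap = "
                f"{total}') must equal flanker_line_len ({self.flanker_line_len}')"
            )

    def with_overrides(self, **kwargs: float) -> "GeometrySpec":
        return replace(self, **kwargs)


# the denominator constant of the evidence contrast score; a printed model
# constant, deliberately not exposed as a parameter
EVIDENCE_OFFSET_CONST = 100.0


@dataclass(frozen=True)
class ModelParams:
    """Tunable model and rendering parameters.

    dt_ms
        Simulation step; every frame duration must be a multiple of it.
    tau_contour_ms
        Leak time constant of contour activity. 180 ms keeps contours above
        50% through a 120-ms blank but below 4% after 600 ms.
    tau_selection_ms
        Decay constant of the selection mask where contour activity no
        longer refreshes it.
    spread_fast_px / spread_slow_px
        Rings of 8-connected BFS growth of the selection mask per step on
        strongly driven contours (peak frontier activity above
        ``spread_fast_threshold``) and on weaker persisting contours.
        Selection spreads quickly while a stimulus is on screen and slowly
        along decaying traces, which is what makes segmentation of briefly
        presented flankers incomplete.
    spread_threshold
        Minimum activity for a pixel to count as a living contour for
        seeding and spreading.
    transfer_rate
        Fraction of selected Layer-0 activity moved to Layer 1 per step.
    seed_radius_arcmin / seed_radius_lines_arcmin / seed_jitter_arcmin
        Radius of the top-down selection signals (the signal aimed at the
        small Lines / Central-Rectangle structures is larger, covering the
        lines and the vernier zone between them) and the placement jitter
        (Gaussian SD, truncated at 1.5 sigma).
    evidence_window_ms
        Readout window relative to vernier onset, endpoints inclusive.
    ref_offset_arcmin
        Fixed right offset used for model stimuli (4' = 2 px at default
        resolution).
    template_dilation_px
        Dilation of the rasterized vernier when building templates; large
        enough that templates also cover the nearby flanking lines.
    """

    dt_ms: int = 20
    tau_contour_ms: float = 180.0
    tau_selection_ms: float = 100.0
    spread_fast_px: int = 40
    spread_slow_px: int = 7
    spread_fast_threshold: float = 0.95
    spread_threshold: float = 0.5
    seed_threshold: float = 0.45
    transfer_rate: float = 0.9
    seed_radius_arcmin: float = 30.0
    seed_radius_lines_arcmin: float = 45.0
    seed_jitter_arcmin: float = 8.0
    evidence_window_ms: tuple[int, int] = (20, 100)
    ref_offset_arcmin: float = 4.0
    template_dilation_px: int = 15
    px_per_arcmin: float = 0.5
    canvas_x_arcmin: tuple[float, float] = (-200.0, 200.0)
    canvas_y_arcmin: tuple[float, float] = (-100.0, 100.0)

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if not (0.0 < self.transfer_rate <= 1.0):
            raise ValueError("transfer_rate must be in (0, 1]")
        if self.tau_contour_ms <= 0 or self.tau_selection_ms <= 0:
            raise ValueError("decay constants must be positive")
        if self.spread_fast_px < 1 or self.spread_slow_px < 1:
            raise ValueError("spread speeds must be at least 1 px per step")
        lo, hi = self.evidence_window_ms
        if lo % self.dt_ms or hi % self.dt_ms:
            raise ValueError("evidence window bounds must be multiples of dt_ms")
        if hi < lo:
            raise ValueError("evidence window must be ordered (lo, hi)")
        if self.px_per_arcmin <= 0:
            raise ValueError("px_per_arcmin must be positive")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    @property
    def raster_shape(self) -> tuple[int, int]:
        """(H, W) of the default canvas at the default resolution."""
        x0, x1 = self.canvas_x_arcmin
        y0, y1 = self.canvas_y_arcmin
        w = int(round((x1 - x0) * self.px_per_arcmin)) + 1
        h = int(round((y1 - y0) * self.px_per_arcmin)) + 1
        return (h, w)
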