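"""Left/right vernier templates, the contrast score, and windowed evidence.

The two templates are built from the vernier rasterized at the reference
offsets -delta_ref and +delta_ref (vertical channel only) and extended
horizontally toward their respective sides by ``template_dilation_px``, so
that each template also covers the flanking line on its side. Template
scores S_L and S_R sum Layer-0 vertical-channel activity under the masks;
the per-step contrast is

    C = (S_R - S_L) / (100 + S_R + S_L)

and model evidence is the sum of C over a readout window after vernier
onset (default 20-100 ms inclusive, i.e. five 20-ms steps). Flankers that
remain in Layer 0 inflate the denominator symmetrically and shrink |C|
(crowding); moving them to Layer 1 restores |C| (uncrowding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from uncrowding.field import OrientationField
from uncrowding.params import EVIDENCE_OFFSET_CONST, ModelParams
from uncrowding.stimuli import CHANNEL_INDEX, StimulusFrame, make_vernier, rasterize


@dataclass(frozen=True)
class TemplatePair:
    """Binary masks for the left- and right-shifted vernier templates."""

    mask_L: np.ndarray
    mask_R: np.ndarray

    def __post_init__(self) -> None:
        if self.mask_L.shape != self.mask_R.shape:
            raise ValueError("template masks must share one raster geometry")


@dataclass(frozen=True)
class EvidenceTrace:
    """Per-step contrast values plus the summed evidence over the window."""

    times_ms: tuple[int, ...]
    s_l: tuple[float, ...]
    s_r: tuple[float, ...]
    c_t: tuple[float, ...]
    evidence: float


def _one_sided_dilation(mask: np.ndarray, d: int, direction: int) -> np.ndarray:
    """Extend a binary mask ``d`` pixels leftward (-1) or rightward (+1)."""
    out = mask.astype(bool).copy()
    for k in range(1, d + 1):
        shifted = np.zeros_like(out)
        if direction > 0:
            shifted[:, k:] = mask[:, :-k]
        else:
            shifted[:, :-k] = mask[:, k:]
        out |= shifted.astype(bool)
    return out


def build_templates(params: ModelParams, geometry=None) -> TemplatePair:
    """Templates from the vernier rasterized at -/+ the reference offset.

    Each template is extended toward its own side so that it covers the
    nearby flanking-line column; the pair is exactly mirror symmetric.
    Raises if the reference offset is below one pixel at the working
    resolution.
    """
    if params.ref_offset_arcmin * params.px_per_arcmin < 1.0:
        raise ValueError(
            "reference offset is sub-pixel at this resolution; increase "
            "ref_offset_arcmin or px_per_arcmin"
        )
    off = params.ref_offset_arcmin * 60.0
    d = params.template_dilation_px
    v = CHANNEL_INDEX["vertical"]
    masks = {}
    for sign, direction in ((-1.0, -1), (+1.0, +1)):
        frame = StimulusFrame(
            segments=tuple(make_vernier(sign * off, geometry)),
            label="template",
            vernier_offset=sign * off,
            contains_vernier=True,
        )
        r = rasterize(
            frame, params.px_per_arcmin, params.canvas_x_arcmin, params.canvas_y_arcmin
        )[v]
        masks[direction] = _one_sided_dilation(r > 0, d, direction)
    return TemplatePair(mask_L=masks[-1], mask_R=masks[+1])


def template_scores(
    field: OrientationField, templates: TemplatePair
) -> tuple[float, float]:
    """(S_L, S_R): summed Layer-0 vertical-channel activity under each mask."""
    v = CHANNEL_INDEX["vertical"]
    layer0 = field.activity[0, v]
    if layer0.shape != templates.mask_L.shape:
        raise ValueError(
            f"field raster {layer0.shape} does not match template geometry "
            f"{templates.mask_L.shape}"
        )
    return float(layer0[templates.mask_L].sum()), float(layer0[templates.mask_R].sum())


def contrast(s_l: float, s_r: float) -> float:
    """C = (S_R - S_L) / (100 + S_R + S_L); always strictly inside (-1, 1)."""
    if s_l < 0 or s_r < 0:
        raise ValueError("template scores must be nonnegative")
    return (s_r - s_l) / (EVIDENCE_OFFSET_CONST + s_r + s_l)


def model_evidence(
    times_ms,
    c_t,
    vernier_onset_ms: int,
    window_ms: tuple[int, int] = (20, 100),
) -> float:
    """Sum of contrast values with onset + lo <= t <= onset + hi (inclusive)."""
    times = list(times_ms)
    values = list(c_t)
    if len(times) != len(values):
        raise ValueError("times and contrast values differ in length")
    lo, hi = window_ms
    if not times or max(times) < vernier_onset_ms + hi:
        raise ValueError(
            f"trace ends before the readout window (needs t = {vernier_onset_ms + hi} ms)"
        )
    return float(
        sum(
            v
            for t, v in zip(times, values)
            if vernier_onset_ms + lo <= t <= vernier_onset_ms + hi
        )
    )
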