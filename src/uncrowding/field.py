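"""Time-stepped orientation-channel contour activity.

Two segmentation layers hold per-pixel, per-channel activity in [0, 1].
Layer 0 receives bottom-up drive from the stimulus raster; Layer 1 is fed
only by the selection/transfer process. Both leak toward zero with time
constant ``tau_contour_ms``, chosen so contours persist above half strength
through a 120-ms blank but fade almost completely within ~600 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from uncrowding.params import ModelParams

N_LAYERS = 2


@dataclass
class OrientationField:
    """Activity a[layer, channel, y, x] in [0, 1] plus the simulation clock."""

    activity: np.ndarray  # (2, 4, H, W) float
    time_ms: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.activity.shape[2:]

    def copy(self) -> "OrientationField":
        return OrientationField(self.activity.copy(), self.time_ms)


def init_field(raster_shape: tuple[int, int], n_channels: int = 4) -> OrientationField:
    """Zero-activity field with the simulation clock at 0."""
    h, w = raster_shape
    if h <= 0 or w <= 0:
        raise ValueError("raster shape must be positive")
    return OrientationField(np.zeros((N_LAYERS, n_channels, h, w)), time_ms=0)


def step_field(
    field: OrientationField,
    input_raster: np.ndarray | None,
    params: ModelParams,
) -> OrientationField:
    """Advance one dt: exponential leak on both layers, drive into Layer 0.

    a <- min(1, a * exp(-dt/tau) + input); a blank input (None) models an
    interstimulus interval. Layer 1 decays identically but gets no drive.
    """
    decay = np.exp(-params.dt_ms / params.tau_contour_ms)
    act = field.activity * decay
    if input_raster is not None:
        if input_raster.shape != field.activity.shape[1:]:
            raise ValueError(
                f"input raster shape {input_raster.shape} does not match "
                f"field shape {field.activity.shape[1:]}"
            )
        act[0] = np.minimum(1.0, act[0] + input_raster)
    return OrientationField(act, field.time_ms + params.dt_ms)


def total_activity(field: OrientationField, layer: int) -> float:
    """Summed activity of one layer over channels and pixels."""
    if layer not in (0, 1):
        raise ValueError("layer must be 0 or 1")
    return float(field.activity[layer].sum())
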