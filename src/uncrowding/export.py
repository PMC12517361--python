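"""PNG and CSV exporters for stimuli, fields, and run outputs.

Layer snapshots use the conventional colour code: red for vertical
contours, green for horizontal, blue for the two diagonal channels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from uncrowding.field import OrientationField
from uncrowding.stimuli import CHANNEL_INDEX, StimulusFrame, rasterize


def raster_to_rgb(raster: np.ndarray) -> np.ndarray:
    """(4, H, W) occupancy/activity -> (H, W, 3) uint8 image."""
    r = raster[CHANNEL_INDEX["vertical"]]
    g = raster[CHANNEL_INDEX["horizontal"]]
    b = np.maximum(raster[CHANNEL_INDEX["diag45"]], raster[CHANNEL_INDEX["diag135"]])
    rgb = np.stack([r, g, b], axis=-1)
    return (np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8)


def save_frame_png(
    frame: StimulusFrame,
    path: str | Path,
    px_per_arcmin: float = 0.5,
    canvas_x=(-200.0, 200.0),
    canvas_y=(-100.0, 100.0),
) -> None:
    raster = rasterize(frame, px_per_arcmin, canvas_x, canvas_y)
    Image.fromarray(raster_to_rgb(raster.astype(float))).save(Path(path))


def save_layer_png(field: OrientationField, layer: int, path: str | Path) -> None:
    Image.fromarray(raster_to_rgb(field.activity[layer])).save(Path(path))


def trace_to_frame(trace) -> pd.DataFrame:
    """EvidenceTrace -> tidy per-step table (t_ms, S_L, S_R, C)."""
    return pd.DataFrame(
        {"t_ms": trace.times_ms, "S_L": trace.s_l, "S_R": trace.s_r, "C": trace.c_t}
    )


def segmentation_summary_row(state) -> dict:
    """Per-step summary of a segmentation state for CSV logging."""
    a = state.field.activity
    return {
        "t_ms": state.field.time_ms,
        "layer0_total": float(a[0].sum()),
        "layer1_total": float(a[1].sum()),
        "mask_area": int((state.selected_mask > 0.25).sum()),
    }


def results_to_frame(results) -> pd.DataFrame:
    """ConditionResult list -> tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "experiment": r.experiment,
                "condition": r.condition,
                "n": r.n_trials,
                "mean_evidence": r.mean_evidence,
                "sd_evidence": r.sd_evidence,
                "seed": r.seed,
            }
            for r in results
        ]
    )


def pattern_report_to_frame(report) -> pd.DataFrame:
    return pd.DataFrame(report)


def evidence_panel(results, path: str | Path, title: str = "") -> None:
    """Bar panel of mean evidence per condition with the y-axis reversed,
    so that lower bars mean better predicted performance reads like a
    threshold plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    labels = [r.condition for r in results]
    means = [r.mean_evidence for r in results]
    errs = [r.sd_evidence / max(1, r.n_trials) ** 0.5 for r in results]
    ax.bar(labels, means, yerr=errs, color="steelblue")
    ax.invert_yaxis()
    ax.set_ylabel("model evidence (axis reversed)")
    if title:
        ax.set_title(title)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
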