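"""Condition inventories, Monte-Carlo model runs, and qualitative patterns.

Each trial builds the condition's frame timeline, plants jittered selection
signals, advances the two-layer segmentation model in 20-ms steps, and sums
template contrast over the readout window. Trial-to-trial variability comes
solely from the seed-placement jitter and (for Scrambled Cubes) the shuffle;
there is no neural noise.

``check_patterns`` evaluates the qualitative predictions (which condition
should beat which) as z-scores of mean-evidence differences in pooled-SE
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from uncrowding.evidence import (
    TemplatePair,
    EvidenceTrace,
    build_templates,
    contrast,
    model_evidence,
    template_scores,
)
from uncrowding.field import init_field
from uncrowding.params import GeometrySpec, ModelParams
from uncrowding.segmentation import (
    SegmentationState,
    place_selection_signals,
    step_segmentation,
)
from uncrowding.stimuli import FrameSequence, build_sequence, condition_inventory, rasterize


@dataclass(frozen=True)
class ConditionResult:
    """Aggregate model evidence for one (experiment, condition)."""

    experiment: int
    condition: str
    n_trials: int
    mean_evidence: float
    sd_evidence: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sd_evidence < 0:
            raise ValueError("sd_evidence must be >= 0")


@dataclass(frozen=True)
class PatternAssertion:
    """Machine-readable qualitative claim about two conditions.

    relation: 'greater' (lhs beats rhs by at least ``tolerance`` pooled-SE
    units), 'approx_equal' (|z| below tolerance), or 'less_or_similar'
    (z at most +tolerance; lhs may be arbitrarily lower).
    """

    lhs: str
    rhs: str
    relation: str
    tolerance: float = 2.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.relation not in ("greater", "approx_equal", "less_or_similar"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


# flanker configuration whose centroid receives the selection signals,
# i.e. the configuration of the first flanker-bearing frame of the trial
_SEED_CONFIG = {
    1: lambda cond: None if cond.startswith("unflanked") else cond.rsplit("-", 1)[0],
    2: lambda cond: cond.rsplit("-", 1)[0],
    3: lambda cond: "Cubes",
    4: lambda cond: "Cubes",
}


def _frame_schedule(seq: FrameSequence):
    """(start_ms, end_ms, frame) triples."""
    out, t = [], 0
    for frame, dur in zip(seq.frames, seq.durations_ms):
        out.append((t, t + dur, frame))
        t += dur
    return out


def run_trial(
    experiment: int,
    condition: str,
    params: ModelParams,
    rng: np.random.Generator,
    geometry: GeometrySpec | None = None,
    templates: TemplatePair | None = None,
    return_trace: bool = False,
):
    """One model trial; returns the evidence (and optionally the full trace)."""
    g = geometry or GeometrySpec()
    scramble_seed = int(rng.integers(0, 2**31 - 1))
    seq = build_sequence(
        experiment,
        condition,
        offset_arcsec=params.ref_offset_arcmin * 60.0,
        geometry=g,
        seed=scramble_seed,
    )
    signals = place_selection_signals(
        _SEED_CONFIG[experiment](condition), params, rng, geometry=g, onset_ms=0
    )
    if templates is None:
        templates = build_templates(params, g)
    rasters = [
        None
        if frame.is_blank
        else rasterize(frame, params.px_per_arcmin, params.canvas_x_arcmin, params.canvas_y_arcmin)
        for frame in seq.frames
    ]
    schedule = [
        (t0, t1, rasters[i]) for i, (t0, t1, _) in enumerate(_frame_schedule(seq))
    ]
    onset = seq.vernier_onset_ms
    if onset is None:
        raise ValueError(f"condition {condition!r} contains no vernier")
    t_end = max(seq.total_duration_ms, onset + params.evidence_window_ms[1])
    state = SegmentationState(
        field=init_field(params.raster_shape),
        selected_mask=np.zeros(params.raster_shape),
        signals=signals,
    )
    times, s_ls, s_rs, cs = [], [], [], []
    n_steps = t_end // params.dt_ms
    for i in range(n_steps):
        t0 = i * params.dt_ms
        raster = None
        for a, b, r in schedule:
            if a <= t0 < b:
                raster = r
                break
        state = step_segmentation(state, raster, params)
        s_l, s_r = template_scores(state.field, templates)
        times.append(state.field.time_ms)
        s_ls.append(s_l)
        s_rs.append(s_r)
        cs.append(contrast(s_l, s_r))
    evidence = model_evidence(times, cs, onset, params.evidence_window_ms)
    if return_trace:
        trace = EvidenceTrace(
            times_ms=tuple(times),
            s_l=tuple(s_ls),
            s_r=tuple(s_rs),
            c_t=tuple(cs),
            evidence=evidence,
        )
        return evidence, trace, state
    return evidence


def run_condition(
    experiment: int,
    condition: str,
    n_trials: int,
    seed: int,
    params: ModelParams | None = None,
    geometry: GeometrySpec | None = None,
) -> ConditionResult:
    """Monte-Carlo evidence for one condition; reproducible given the seed."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or ModelParams()
    g = geometry or GeometrySpec()
    templates = build_templates(params, g)
    root = np.random.default_rng(seed)
    evidences = [
        run_trial(experiment, condition, params, child, g, templates)
        for child in root.spawn(n_trials)
    ]
    arr = np.asarray(evidences, dtype=float)
    sd = float(arr.std(ddof=1)) if n_trials > 1 else 0.0
    return ConditionResult(
        experiment=experiment,
        condition=condition,
        n_trials=n_trials,
        mean_evidence=float(arr.mean()),
        sd_evidence=sd,
        seed=seed,
    )


def run_experiment(
    experiment: int,
    n_trials: int = 100,
    seed: int = 0,
    params: ModelParams | None = None,
    geometry: GeometrySpec | None = None,
) -> list[ConditionResult]:
    """Run the full condition inventory of one experiment.

    All conditions share one seed derived from the master seed, so trial k
    of every condition sees identical signal jitter (common random numbers)
    and between-condition comparisons carry no placement variance.
    """
    cond_seed = (seed * 1000 + experiment) % (2**31 - 1)
    return [
        run_condition(experiment, cond, n_trials, cond_seed, params, geometry)
        for cond in condition_inventory(experiment)
    ]


def _zscore(lhs: ConditionResult, rhs: ConditionResult) -> float:
    diff = lhs.mean_evidence - rhs.mean_evidence
    se = math.sqrt(
        lhs.sd_evidence**2 / lhs.n_trials + rhs.sd_evidence**2 / rhs.n_trials
    )
    if se == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / se


def check_patterns(
    results: list[ConditionResult],
    assertions: list[PatternAssertion],
):
    """Evaluate qualitative assertions; returns a list of report dicts.

    Each report carries the z-score of the condition difference and whether
    the stated relation holds at the assertion's tolerance.
    """
    by_cond = {r.condition: r for r in results}
    report = []
    for a in assertions:
        for name in (a.lhs, a.rhs):
            if name not in by_cond:
                raise KeyError(f"pattern assertion references missing condition {name!r}")
        z = _zscore(by_cond[a.lhs], by_cond[a.rhs])
        if a.relation == "greater":
            ok = z >= a.tolerance
        elif a.relation == "approx_equal":
            ok = abs(z) < a.tolerance
        else:  # less_or_similar
            ok = z <= a.tolerance
        report.append(
            {
                "label": a.label or f"{a.lhs} {a.relation} {a.rhs}",
                "lhs": a.lhs,
                "rhs": a.rhs,
                "relation": a.relation,
                "z": z,
                "tolerance": a.tolerance,
                "passed": bool(ok),
            }
        )
    return report


def default_pattern_suite(experiment: int) -> list[PatternAssertion]:
    """The qualitative model predictions for one experiment.

    'greater' uses z >= 3, 'approx_equal' |z| < 2, following the reading of
    the model-evidence panels: short flanked displays are uniformly crowded;
    long displays and flanker previews release Cubes/Rectangles but not
    Lines; the preview advantage survives only short gaps; intermediate
    frames gate the effect by their groupability.
    """
    G, A, L = "greater", "approx_equal", "less_or_similar"
    if experiment == 1:
        return [
            PatternAssertion("unflanked-20", "Lines-20", G, 3.0, "unflanked beats Lines"),
            PatternAssertion("unflanked-20", "Rectangles-20", G, 3.0, "unflanked beats Rectangles"),
            PatternAssertion("unflanked-20", "Cubes-20", G, 3.0, "unflanked beats Cubes"),
            PatternAssertion("Cubes-160", "Cubes-20", G, 3.0, "Cubes uncrowd at 160 ms"),
            PatternAssertion("Rectangles-160", "Rectangles-20", G, 3.0, "Rectangles uncrowd at 160 ms"),
            PatternAssertion("Lines-160", "Lines-20", A, 2.0, "Lines stay crowded"),
            PatternAssertion("Cubes-160", "Rectangles-160", A, 2.0, "Cubes track Rectangles"),
        ]
    if experiment == 2:
        return [
            PatternAssertion("Cubes-preview", "Cubes-baseline", G, 3.0, "Cubes preview uncrowds"),
            PatternAssertion("Lines-preview", "Lines-baseline", A, 2.0, "Lines preview does not"),
            PatternAssertion("Cubes-postview", "Cubes-baseline", A, 2.0, "Cubes postview inert"),
            PatternAssertion("Lines-postview", "Lines-baseline", A, 2.0, "Lines postview inert"),
        ]
    if experiment == 3:
        out = [
            PatternAssertion("isi-20", "baseline", G, 3.0, "advantage at 20-ms ISI"),
            PatternAssertion("isi-120", "baseline", G, 3.0, "advantage at 120-ms ISI"),
        ]
        for isi in (260, 600, 1000, 1500, 2000):
            out.append(
                PatternAssertion(
                    f"isi-{isi}", "baseline", A, 2.0, f"no advantage at {isi}-ms ISI"
                )
            )
        return out
    if experiment == 4:
        return [
            PatternAssertion("Cubes", "baseline", G, 3.0, "Cubes propagate the preview"),
            PatternAssertion("Rectangles", "baseline", G, 3.0, "Rectangles propagate"),
            PatternAssertion("Triangles", "baseline", G, 3.0, "Triangles propagate"),
            PatternAssertion("Lines", "baseline", A, 2.0, "Lines interrupt"),
            PatternAssertion("ScrambledCubes", "baseline", A, 2.0, "Scrambled Cubes interrupt"),
            PatternAssertion("CentralRectangle", "Lines", L, 2.0, "Central-Rectangle at or below Lines"),
        ]
    raise ValueError(f"experiment must be 1-4, got {experiment}")
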