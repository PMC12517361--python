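# uncrowding

A recurrent-segmentation model of visual crowding and uncrowding, with the
full psychophysical toolchain around it: exact vernier/flanker stimulus
generation, a two-layer selection/segmentation network advanced in 20-ms
steps, template-based evidence readout, a PEST adaptive staircase, and
cumulative-Gaussian threshold fitting with simulated observers.

It is written for researchers in visual psychophysics and computational
neuroscience who want a compact, testable implementation of the idea that
crowding is gated by time-consuming grouping: flankers that can be selected
and segmented away from a vernier target release it from crowding, and a
brief flanker preview can start that process ahead of the target.

## The model in brief

Stimulus contours live in two retinotopic layers of orientation-tuned
activity a ∈ [0,1] with leak time constant τ = 180 ms per 20-ms step.
Top-down selection signals at fixed flanker locations mark contours in
their radius and spread along connected contours — fast (40 px/step) over
currently driven contours, slowly (7 px/step) along decaying traces —
and transfer selected contours from Layer 0 to Layer 1. Offset evidence is
read from Layer 0 by left/right vernier templates:

    C_t = (S_R − S_L) / (100 + S_R + S_L),   evidence = Σ C_t  (20–100 ms after onset)

Flankers left in Layer 0 inflate the denominator and crowd the target;
segmented flankers leave the readout and release it. Thresholds follow from
a monotone link μ_log = α − β·evidence driving a simulated 2AFC observer
through PEST staircases (800″ start, 1,600″ cap, 80-trial blocks) and a
post-hoc cumulative-Gaussian fit on log offset (75% criterion).

## Worked example

```python
import uncrowding as u

results = u.run_experiment(2, n_trials=100, seed=1)   # preview/postview study
for r in results:
    print(f"{r.condition:16s} evidence {r.mean_evidence:+.3f} +- {r.sd_evidence:.3f}")
```

prints

```
Lines-preview    evidence +0.028 +- 0.014
Lines-postview   evidence +0.027 +- 0.023
Lines-baseline   evidence +0.027 +- 0.023
Cubes-preview    evidence +0.532 +- 0.007
Cubes-postview   evidence +0.377 +- 0.000
Cubes-baseline   evidence +0.377 +- 0.000
```

A 20-ms preview of the Cubes, 120 ms before the flanked vernier, raises
model evidence from 0.377 to 0.532 (uncrowding: the preview gives selection
time to shift the cubes to the other layer before the target appears).
Lines previews do not help — their selection signal inevitably covers the
target zone, so the vernier is dragged along into the segmented layer — and
postviews are inert. Feeding the condition evidence through the simulated
observer turns this into thresholds:

```python
fit = u.evidence_to_threshold(0.532, np.random.default_rng(7))   # preview
# fit.threshold_arcsec -> 192.5
fit = u.evidence_to_threshold(0.377, np.random.default_rng(7))   # baseline
# fit.threshold_arcsec -> 300.7
```

The qualitative predictions for all four experiments (duration effects,
preview/postview, gap duration, intermediate frames) are encoded as
`default_pattern_suite(experiment)` and checked with
`check_patterns(results, suite)`.

## Command line

```
uncrowding render --out out/              # PNG + CSV of every configuration
uncrowding run --experiment 1 --trials 100 --seed 1 --out out/
uncrowding patterns --experiment all --trials 100 --seed 1 --out out/
uncrowding thresholds --experiment 2 --seed 1 --out out/
uncrowding calibrate --out out/           # coarse grid over spread speeds
```

All outputs are functions of the config and seeds only; a saved YAML config
(`load_config`/`save_config`) reproduces a run exactly.

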