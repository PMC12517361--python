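"""Run configuration: YAML round-trip with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from uncrowding.params import GeometrySpec, ModelParams

# the printed denominator constant of the contrast score is part of the
# model definition, not a tunable
_FORBIDDEN_KEYS = {"evidence_offset_const"}


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs: geometry, model, and run plan."""

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    params: ModelParams = field(default_factory=ModelParams)
    experiments: tuple[int, ...] = (1, 2, 3, 4)
    n_trials: int = 100
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.params).items()
            },
            "experiments": list(self.experiments),
            "n_trials": self.n_trials,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


def _check_keys(given: dict, allowed: set[str], context: str) -> None:
    for key in given:
        if key in _FORBIDDEN_KEYS:
            raise ValueError(f"{context}: '{key}' is a fixed model constant and cannot be overridden")
        if key not in allowed:
            raise ValueError(f"{context}: unknown key '{key}'")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; absent keys fall back to defaults.

    Unknown keys raise, naming the offending key, so silent mis-calibration
    through typos is impossible.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    top_allowed = {"geometry", "params", "experiments", "n_trials", "seed", "out_dir"}
    _check_keys(raw, top_allowed, str(path))

    geo_kwargs = raw.get("geometry") or {}
    _check_keys(geo_kwargs, {f.name for f in dataclasses.fields(GeometrySpec)}, "geometry")
    par_kwargs = dict(raw.get("params") or {})
    _check_keys(par_kwargs, {f.name for f in dataclasses.fields(ModelParams)}, "params")
    for key in ("evidence_window_ms", "canvas_x_arcmin", "canvas_y_arcmin"):
        if key in par_kwargs:
            par_kwargs[key] = tuple(par_kwargs[key])

    return RunConfig(
        geometry=GeometrySpec(**geo_kwargs),
        params=ModelParams(**par_kwargs),
        experiments=tuple(raw.get("experiments", (1, 2, 3, 4))),
        n_trials=int(raw.get("n_trials", 100)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "results")),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
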