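"""Run configuration: defaults, YAML loading, flag overrides, round-trip.

A :class:`RunConfig` carries every tunable default of the toolkit (optimizer
options, motion source, generator parameters, master seed).  Values come
from, in increasing precedence: built-in defaults, a YAML config file,
command-line flags.  Unknown keys are rejected; the effective config is
echoed into every output directory so runs are self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "parse_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration value."""


@dataclass
class RunConfig:
    """All toolkit defaults in one serializable record."""

    # master seed for every random draw in a run
    seed: int = 0
    # generator
    n_frames: int = 30
    n_sequences: int = 8
    scenario: str = "all"
    background_depth_mm: float = 60.0
    tissue_coverage: float = 0.20
    tool_coverage: float = 0.12
    tissue_max_disp_px: float = 14.0
    tissue_controls: int = 5
    camera_translation_mm: float = 0.8
    camera_rotation_deg: float = 0.5
    # optimizer
    max_iters: int = 30
    residual: str = "2d"  # "2d" | "3d"
    motion: str = "none"  # "none" | "gt" | "flowcheck" | "file:PATH"
    refine: str = "none"  # "none" | "weighted" | "vanilla"
    flowcheck_sigma_px: float = 1.0
    iou_threshold: float = 0.5
    # bench noise (study conditions)
    flow_noise_px: float = 0.2
    depth_noise_frac: float = 0.02
    # output
    out: str = "runs"
    verbosity: str = "info"

    def validate(self) -> "RunConfig":
        if self.residual not in ("2d", "3d"):
            raise ConfigError(f"residual: expected '2d' or '3d', got {self.residual!r}")
        if self.refine not in ("none", "weighted", "vanilla"):
            raise ConfigError(f"refine: unknown mode {self.refine!r}")
        ok_motion = self.motion in ("none", "gt", "flowcheck") or self.motion.startswith(
            "file:"
        )
        if not ok_motion:
            raise ConfigError(f"motion: unknown source {self.motion!r}")
        if self.max_iters < 1:
            raise ConfigError("max_iters: must be >= 1")
        if self.n_frames < 2:
            raise ConfigError("n_frames: must be >= 2")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, out_dir: str | Path) -> None:
        """Write the effective config into an output directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def parse_config(
    file: str | Path | None = None, flags: dict | None = None
) -> RunConfig:
    """Build a validated config from an optional YAML file plus flag overrides.

    Flags (a dict of field name to value; None entries are ignored) take
    precedence over file values.  Unknown keys in either source raise
    :class:`ConfigError` naming the offending field.
    """
    values: dict = {}
    if file is not None:
        with open(file) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        for key, val in data.items():
            if key not in _FIELDS:
                raise ConfigError(f"unknown config key {key!r}")
            values[key] = val
    if flags:
        for key, val in flags.items():
            if val is None:
                continue
            if key not in _FIELDS:
                raise ConfigError(f"unknown config key {key!r}")
            values[key] = val
    for key, val in values.items():
        expected = _FIELDS[key].type
        # YAML ints are acceptable where floats are declared
        if expected == "float" and isinstance(val, int):
            values[key] = float(val)
    return RunConfig(**values).validate()
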