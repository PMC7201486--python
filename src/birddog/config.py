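"""Run configuration: scoring parameters with YAML loading and overrides."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import FormatError


@dataclass
class ScoringConfig:
    """Tunable parameters of the per-trial scoring pipeline.

    confidence_threshold
        Keypoints with confidence strictly below this are masked and
        linearly interpolated (strict ``<``: exactly 0.5 is kept).
    d_prime_floor
        Floor applied to D' before log(1/D') so a perfectly stationary
        (synthetic) trial does not produce log(1/0).  Body-lengths/frame.
    dt_mode
        'annotated' uses annotated start/fall frames; 'heuristic' detects
        lift-off and floor contact from the keypoints themselves.
    lift_margin_bl / floor_margin_bl
        Heuristic margins, in body lengths, for "limb clearly off the
        floor" and "limb back on the floor".
    extension_angle_max
        Heuristic: maximum limb-floor angle (degrees) still counted as a
        fully extended posture.
    task_cap_s
        Task abort time; duration time is capped here (seconds).
    """

    confidence_threshold: float = 0.5
    d_prime_floor: float = 1e-6
    dt_mode: str = "annotated"
    lift_margin_bl: float = 0.1
    floor_margin_bl: float = 0.02
    extension_angle_max: float = 30.0
    task_cap_s: float = 60.0

    def __post_init__(self) -> None:
        if self.dt_mode not in ("annotated", "heuristic"):
            raise FormatError(f"dt_mode must be 'annotated' or 'heuristic', got {self.dt_mode!r}")
        if not self.task_cap_s > 0:
            raise FormatError("task_cap_s must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_scoring_config(path: str | Path | None = None, **overrides) -> ScoringConfig:
    """Build a :class:`ScoringConfig` from an optional YAML file plus overrides.

    The YAML file is a flat key/value mapping; unknown keys raise
    :class:`FormatError` naming the key.  Explicit keyword overrides win over
    file values.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a flat mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(ScoringConfig)}
    unknown = set(values) - known
    if unknown:
        raise FormatError(f"unknown config key(s): {sorted(unknown)}")
    return ScoringConfig(**values)
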