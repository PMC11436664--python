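"""Run configuration: defaults, TOML loading, reproducibility hash."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .errors import ConfigurationError


@dataclass(frozen=True)
class RunConfig:
    """Every knob that affects a metric evaluation, in one serializable place.

    ``resolution`` is in points per cm**2 (surface sampling density);
    ``unit_scale`` converts source coordinates to cm; ``normal_decimals``
    and ``bin_cells`` control the orientation categories; ``scheme`` names
    the variable-transform set; ``n_scales`` optionally fixes the number of
    box-counting scales.
    """

    resolution: float = 1.0
    unit_scale: float = 1.0
    normal_decimals: int = 2
    bin_cells: int = 320
    richness_mode: str = "unique-vector"
    diversity_mode: str = "sphere-binned"
    scheme: str = "default"
    n_scales: int | None = None
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Read a TOML config file; unknown keys are an error, not a surprise."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
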