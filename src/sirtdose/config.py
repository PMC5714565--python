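"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .calibration import DEFAULT_SENSITIVITY_CPS_PER_MBQ

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Scanner, nuclide and grid defaults for a pipeline run.

    Unknown keys in a config file are rejected rather than ignored, so typos
    cannot silently fall back to defaults.
    """

    sensitivity_cps_per_mbq: float = DEFAULT_SENSITIVITY_CPS_PER_MBQ
    half_life_days: float = 2.67
    lambda_per_day: float = 0.2596
    dvh_bin_width_gy: float = 0.5
    ct_grid_mm: float = 2.5
    kernel_path: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.sensitivity_cps_per_mbq <= 0:
            raise ValueError("sensitivity must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the configuration, for provenance stamping."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)
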