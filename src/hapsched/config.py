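"""Run configuration: schema, defaults, validation, YAML/JSON I/O."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``schedule`` is either a built-in label (A-J) or a path to a schedule
    JSON file; ``calibration`` / ``histogram`` override the packaged
    defaults when set.
    """

    schedule: str = "A"
    calibration: str | None = None
    histogram: str | None = None
    horizon_hours: float = 1512.0
    num_compartments: int = 32
    initial_cells: int = 1_600_000
    fine_step: float = 0.02
    coarse_step: float = 0.25
    n_replicates: int = 1000
    seed: int = 0
    max_population: int = 10_000_000
    output_dir: str = "results"

    def __post_init__(self):
        if self.horizon_hours <= 0:
            raise ValueError("horizon_hours must be positive")
        if self.num_compartments < 1:
            raise ValueError("num_compartments must be >= 1")
        for name in ("calibration", "histogram"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected by name; missing keys take defaults.
    """
    path = Path(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ValueError("config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(payload) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**payload)
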