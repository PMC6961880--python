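"""Run configuration: a single YAML document covering every module.

The resolved configuration is written next to every run's outputs so that
any artifact can be reproduced from the file plus the recorded seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .kinetics import KineticParams
from .rdsolver import SolverConfig, WhealParams
from .stimulus import StimulusSpec
from .units import ScaleSet

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTION_TYPES = {
    "kinetics": KineticParams,
    "stimulus": StimulusSpec,
    "wheal": WhealParams,
    "solver": SolverConfig,
    "scales": ScaleSet,
}


@dataclass
class RunConfig:
    """All parameters of a run.  Defaults are the Set I reference values."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    stimulus: StimulusSpec = field(default_factory=lambda: StimulusSpec(r=1.0))
    wheal: WhealParams = field(default_factory=WhealParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    scales: ScaleSet = field(default_factory=ScaleSet)
    output_dir: str = "."
    seed: int = 0
    c_max: float = 1.0

    def to_dict(self) -> dict:
        d = {k: asdict(getattr(self, k)) for k in _SECTION_TYPES}
        d["output_dir"] = self.output_dir
        d["seed"] = self.seed
        d["c_max"] = self.c_max
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown fields and type errors raise :class:`ConfigurationError`
    naming the offending section and field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        sub = raw.pop(section, {})
        if sub is None:
            sub = {}
        if not isinstance(sub, dict):
            raise ConfigurationError(f"section '{section}' must be a mapping")
        try:
            kwargs[section] = cls(**sub)
        except TypeError as exc:
            raise ConfigurationError(f"section '{section}': {exc}") from exc
        except (ValueError, ConfigurationError) as exc:
            raise ConfigurationError(f"section '{section}': {exc}") from exc
    for key in ("output_dir", "seed", "c_max"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigurationError(f"unknown config fields: {sorted(raw)}")
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
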