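"""Run configuration: YAML round-trip, validation, seed fan-out."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detection import DetectionConfig
from .inpainting import InpaintConfig
from .phantom import ArtifactSpec, PhantomSpec

_SECTIONS = {
    "phantom": PhantomSpec,
    "artifact": ArtifactSpec,
    "detection": DetectionConfig,
    "inpaint": InpaintConfig,
}


def derive_seeds(global_seed: int, n: int) -> list[int]:
    """Fan one global seed out to independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(int(global_seed))
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _build(section: str, overrides: dict):
    cls = _SECTIONS[section]
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"unknown keys in '{section}' config: {sorted(unknown)}")
    fixed = {
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    }
    return cls(**fixed)


@dataclass
class RunConfig:
    """One config object binding all pipeline stages."""

    seed: int = 0
    out: str = "cardiomar_out"
    log_level: str = "INFO"
    phantom: dict = field(default_factory=dict)
    artifact: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    inpaint: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for section in _SECTIONS:
            _build(section, getattr(self, section))
        known_eval = {"surface_tolerance_vox", "blood_pool_hu", "margin_vox"}
        unknown = set(self.evaluation) - known_eval
        if unknown:
            raise ValueError(f"unknown keys in 'evaluation' config: {sorted(unknown)}")

    def build(self, section: str, **extra):
        """Instantiate a stage config with file overrides plus ``extra``."""
        return _build(section, {**getattr(self, section), **extra})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
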