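"""Run configuration: conditions, timings, seeds; YAML round trip.

All randomness in a protocol run flows from one base seed: condition ``c``,
replica ``r`` uses ``seed + 1000*c + r``, which keeps every replica seed
unique as long as there are fewer than 1000 replicas per condition.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigurationError
from .model_system import SurfaceParams

__all__ = ["Condition", "RunConfig", "DEFAULT_CONDITIONS"]

#: the four donor-acceptor distances of the study protocol: the natural
#: short hydrogen bond plus the three constrained lengths
DEFAULT_CONDITIONS = ((2.5, "dimer-SHB"), (3.0, "dimer-3.0A"),
                      (3.5, "dimer-3.5A"), (4.5, "dimer-4.5A"))


@dataclass(frozen=True)
class Condition:
    hb_length: float
    label: str


@dataclass
class RunConfig:
    """Protocol configuration (times in fs, temperature in K)."""

    conditions: list[Condition] = field(
        default_factory=lambda: [Condition(h, l) for h, l in DEFAULT_CONDITIONS])
    replicas: int = 5
    seed: int = 0
    equilibration_fs: float = 3000.0
    excited_fs: float = 1000.0
    ground_sampling_fs: float = 50000.0
    dt_fs: float = 0.5
    temperature: float = 300.0
    substeps: int = 10
    spectrum_frames: int = 25
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    outdir: str = "shbdecay-out"

    def validate(self) -> "RunConfig":
        for name in ("equilibration_fs", "excited_fs", "ground_sampling_fs"):
            dur = getattr(self, name)
            n = dur / self.dt_fs
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(f"dt {self.dt_fs} does not divide {name}={dur}")
        if self.replicas < 1:
            raise ConfigurationError("replicas must be >= 1")
        if self.replicas >= 1000:
            raise ConfigurationError("replica seeds collide for >= 1000 replicas")
        if len({c.label for c in self.conditions}) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        return self

    def replica_seed(self, condition_index: int, replica: int) -> int:
        return self.seed + 1000 * condition_index + replica

    # -- YAML ----------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [{"hb_length": c.hb_length, "label": c.label}
                           for c in self.conditions]
        d["surface"] = asdict(self.surface)
        d["surface"]["masses"] = list(self.surface.masses)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in data:
            data["conditions"] = [
                Condition(float(c["hb_length"]), str(c["label"]))
                for c in data["conditions"]]
        if "surface" in data and isinstance(data["surface"], dict):
            sp = dict(data["surface"])
            if "masses" in sp:
                sp["masses"] = tuple(sp["masses"])
            data["surface"] = SurfaceParams(**sp)
        return cls(**data).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
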