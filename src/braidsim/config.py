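"""Run configuration: one YAML file, one master seed, named substreams."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from braidsim.dataset import ParameterRanges
from braidsim.kinematics import CrimpSpec
from braidsim.solver import SolverSettings
from braidsim.stent import Material, StentParameters

__all__ = ["RomSettings", "RunConfig", "substream_seed"]


def substream_seed(master: int, name: str) -> int:
    """Deterministic named substream seed derived from the master seed."""
    return (int(master) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class RomSettings:
    """Reduced-order-model settings."""

    eps_pod: float | None = None
    L: int | None = 15  #: fixed basis size (None to use eps_pod)
    N_cl: int = 3  #: centerline predictor points
    use_centerline_predictors: bool = False
    n_test: int = 10


@dataclass(frozen=True)
class RunConfig:
    """Serialisable configuration of a full study run."""

    stent: StentParameters = field(default_factory=StentParameters)
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    solver: SolverSettings = field(default_factory=SolverSettings)
    crimp: CrimpSpec = field(default_factory=CrimpSpec)
    rom: RomSettings = field(default_factory=RomSettings)
    N_s: int = 96
    n_test_class: int = 0  #: classifier test-split size (0: 1/3 of data)
    seed: int = 0
    sdf_spacing: float = 0.2
    n_position_steps: int = 20
    scale: str = "desk"  #: "desk" or "full" (geometry fidelity preset)

    def seed_for(self, name: str) -> int:
        return substream_seed(self.seed, name)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "stent" in kwargs:
            stent = dict(kwargs["stent"])
            if "material" in stent and stent["material"] is not None:
                stent["material"] = Material(**stent["material"])
            kwargs["stent"] = StentParameters(**stent)
        if "ranges" in kwargs:
            kwargs["ranges"] = ParameterRanges(
                **{k: tuple(v) for k, v in kwargs["ranges"].items()}
            )
        if "solver" in kwargs:
            kwargs["solver"] = SolverSettings(**kwargs["solver"])
        if "crimp" in kwargs:
            kwargs["crimp"] = CrimpSpec(**kwargs["crimp"])
        if "rom" in kwargs:
            kwargs["rom"] = RomSettings(**kwargs["rom"])
        try:
            return cls(**kwargs)
        except TypeError as err:
            raise ValueError(f"invalid config: {err}")
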