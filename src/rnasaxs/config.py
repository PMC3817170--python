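"""Declarative run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .anneal import AnnealSchedule
from .saxs import FORM_FACTORS, NoiseParams
from .scoring import ScoreWeights


@dataclass
class RunConfig:
    """All knobs of a modeling run; defaults are the package defaults."""

    weights: ScoreWeights = field(default_factory=ScoreWeights)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_points: int = 200
    q_max: float = 0.5
    seed: int = 0
    debye_bin_width: float | None = None
    form_factors: dict = field(default_factory=lambda: dict(FORM_FACTORS))
    dotbracket: str | None = None
    saxs: str | None = None
    library: str | None = None
    output: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "weights" in kwargs:
            kwargs["weights"] = ScoreWeights(**kwargs["weights"])
        if "schedule" in kwargs:
            kwargs["schedule"] = AnnealSchedule(**kwargs["schedule"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseParams(**kwargs["noise"])
        return cls(**kwargs)
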