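"""Run configuration: one serializable record of every hyperparameter.

A :class:`RunConfig` gathers the weighting scheme, embedding and HNSW
parameters, synthetic-benchmark settings, the method variant and evaluation
knobs into a single YAML-round-trippable object, so that each command-line
run can log exactly the configuration it resolved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import yaml

from .embed import EmbeddingParams
from .hnsw import HNSWParams
from .synth import NoiseParams, SynthParams
from .vectorize import WeightingScheme

log = logging.getLogger("eimatch")


@dataclass
class RunConfig:
    scheme: WeightingScheme = field(default_factory=WeightingScheme)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    hnsw: HNSWParams = field(default_factory=HNSWParams)
    synth: SynthParams = field(default_factory=SynthParams)
    variant: str = "embedding-hnsw"
    k: int = 10
    mass_filter_da: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "scheme" in kwargs:
            kwargs["scheme"] = WeightingScheme(**kwargs["scheme"])
        if "embedding" in kwargs:
            kwargs["embedding"] = EmbeddingParams(**kwargs["embedding"])
        if "hnsw" in kwargs:
            kwargs["hnsw"] = HNSWParams(**kwargs["hnsw"])
        if "synth" in kwargs:
            sp = dict(kwargs["synth"])
            if "noise" in sp:
                sp["noise"] = NoiseParams(**sp["noise"])
            if "mz_range" in sp:
                sp["mz_range"] = tuple(sp["mz_range"])
            kwargs["synth"] = SynthParams(**sp)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def log_resolved(self) -> None:
        log.info("resolved config: %s", json.dumps(self.to_dict(), default=str))
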