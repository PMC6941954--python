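"""Run configuration: YAML round trip, hashing and provenance headers."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .embed import EmbeddingSettings
from .pes import SurrogatePES
from .simulate import LangevinSettings, SimulationProtocol

__all__ = ["RunConfig", "load_config", "dump_config", "provenance_header"]


@dataclass
class RunConfig:
    """All module parameter blocks plus the master seed.

    Round-trips losslessly through YAML; its hash (and the seed) is echoed
    into every output header so that a run can be reproduced bit-identically.
    """

    pes: SurrogatePES = field(default_factory=SurrogatePES)
    langevin: LangevinSettings = field(default_factory=LangevinSettings)
    protocol: SimulationProtocol = field(default_factory=SimulationProtocol)
    embedding: EmbeddingSettings = field(default_factory=EmbeddingSettings)
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # one master seed; section seeds follow it unless set explicitly
        object.__setattr__(self, "langevin",
                           _replace_dc(self.langevin, seed=self.seed))
        object.__setattr__(self, "embedding",
                           _replace_dc(self.embedding, seed=self.seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pes"]["x_range"] = list(d["pes"]["x_range"])
        d["pes"]["q_range"] = list(d["pes"]["q_range"])
        return d

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _replace_dc(dc, **kw):
    from dataclasses import replace
    return replace(dc, **kw)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    sections = {"pes": SurrogatePES, "langevin": LangevinSettings,
                "protocol": SimulationProtocol, "embedding": EmbeddingSettings}
    for name, cls in sections.items():
        if name in raw:
            sect = dict(raw[name])
            for key in ("x_range", "q_range"):
                if key in sect:
                    sect[key] = tuple(sect[key])
            kwargs[name] = cls(**sect)
    for scalar in ("seed", "outdir", "log_level"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def provenance_header(config: RunConfig) -> list[str]:
    """Header lines (without leading '#') for every table the CLI writes."""
    return [
        f"protoncage {__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]
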