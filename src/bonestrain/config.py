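"""Run configuration shared by the CLI subcommands.

A :class:`RunConfig` collects every tunable of the scan-to-score pipeline and
the survival analysis; each field is validated by the owning module's
constructor before any computation starts.  Configurations serialise to JSON
so a run can be reproduced from its provenance block alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .bsi import K_BSI_DEFAULT
from .fem import DEFAULT_THICKNESS_MM, MaterialModel
from .load import LoadModel


@dataclass
class RunConfig:
    material: MaterialModel = field(default_factory=MaterialModel)
    load_model: LoadModel = field(default_factory=LoadModel)
    target_edge_factor: float = 3.0        # x pixel spacing
    segmentation_threshold: float = 0.30   # g/cm^2
    band_fraction: float = 0.08
    thickness_mm: float = DEFAULT_THICKNESS_MM
    constraint: str = "fixed"
    k_bsi: float = K_BSI_DEFAULT
    ties: str = "breslow"
    ph_transform: str = "rank"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_edge_factor <= 0:
            raise ValueError("target_edge_factor must be positive")
        if self.segmentation_threshold <= 0:
            raise ValueError("segmentation_threshold must be positive")
        if not 0.0 < self.band_fraction < 0.5:
            raise ValueError("band_fraction must lie in (0, 0.5)")
        if self.constraint not in ("fixed", "roller"):
            raise ValueError("constraint must be 'fixed' or 'roller'")
        if self.ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        if self.k_bsi <= 0:
            raise ValueError("k_bsi must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "material" in d and isinstance(d["material"], dict):
            d["material"] = MaterialModel(**d["material"])
        if "load_model" in d and isinstance(d["load_model"], dict):
            d["load_model"] = LoadModel(**d["load_model"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {"software": "bonestrain", "version": __version__,
                "config": self.to_dict(), "config_hash": self.config_hash(),
                "seed": self.seed}
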