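"""Pipeline configuration with the method's defaults.

All analysis constants live here: restriction enzyme motifs and cut offsets
(Csp6I G^TAC, NlaIII CATG^), the 1-million-cis-read normalization constant,
the 21-fragment-end smoothing window, the 5-kb differential bin size, the
50/500 normalized-read color thresholds, and the 99.9% FACS gate quantile.
Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    first_motif: str = "GTAC"
    first_offset: int = 1
    second_motif: str = "CATG"
    second_offset: int = 4
    normalization_total: float = 1_000_000.0
    rolling_window: int = 21
    bin_size: int = 5_000
    color_lo: float = 50.0
    color_hi: float = 500.0
    gate_quantile: float = 0.999
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rolling_window < 1 or self.rolling_window % 2 == 0:
            raise ValueError("rolling_window must be odd and >= 1")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.color_lo < self.color_hi:
            raise ValueError("color thresholds must satisfy lo < hi")
        if not 0.0 < self.gate_quantile < 1.0:
            raise ValueError("gate_quantile must lie in (0, 1)")
        if self.normalization_total <= 0:
            raise ValueError("normalization_total must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def digest_hash(self) -> str:
        """Stable short hash of the configuration, for provenance headers."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
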