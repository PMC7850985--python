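"""Pipeline configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Screening conjunction used by default, in Table-2 column order.
DEFAULT_CONJUNCTION = [
    "prostate_cancer",
    "prostate_cancer_metastasis",
    "apoptosis",
    "prostate_expression",
]


@dataclass
class PipelineConfig:
    """Every tunable of the prioritization pipeline, with its default.

    The defaults mirror the study conditions: evidence thresholds of 2/2,
    STRING medium confidence 0.4, a 5 % shortlist, and the bait excluded
    from the ranked list (it participates in the network when named).
    """

    min_unique_peptides: int = 2
    min_psms: int = 2
    min_confidence: float = 0.4
    fraction: float = 0.05
    include_bait: bool = False
    bait_symbol: str | None = None
    conjunction: list[str] = field(default_factory=lambda: list(DEFAULT_CONJUNCTION))
    seed: int = 0
    output_dir: str = "netprio_out"

    def __post_init__(self) -> None:
        if self.min_unique_peptides < 1 or self.min_psms < 1:
            raise ConfigurationError("evidence thresholds must be >= 1")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigurationError("min_confidence must be in [0,1]")
        if not 0.0 < self.fraction <= 1.0:
            raise ConfigurationError("fraction must be in (0,1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
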