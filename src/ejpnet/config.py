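"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .stats import LLD_SUBSTITUTES

__all__ = ["PipelineConfig"]


def _default_lld_table() -> dict[str, float]:
    return {f"{phase}_{hormone}": v for (phase, hormone), v in LLD_SUBSTITUTES.items()}


@dataclass
class PipelineConfig:
    """All tunable knobs of the quantification pipeline.

    ``break_seal_px`` is fixed at 1 by the viral-passage rule (breaks
    greater than one pixel fragment the net); overriding it is possible
    but warned about, since it changes what "fragmented" means.
    """

    pixel_size_um: float = 0.325
    scales_px: list[float] = field(default_factory=lambda: [1.0, 2.0])
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.5
    min_component_px: int = 20
    closing_radius_px: int = 15
    break_seal_px: int = 1
    report_round_trip: bool = False
    lld_substitutes: dict[str, float] = field(default_factory=_default_lld_table)
    output_dir: str = "results"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "min_component_px", "closing_radius_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.scales_px):
            raise ValueError("scales_px must be positive")
        if self.break_seal_px != 1:
            warnings.warn(
                "break_seal_px overridden from 1; the one-pixel fragmentation "
                "rule no longer applies",
                stacklevel=2,
            )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable digest used as a provenance column."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
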