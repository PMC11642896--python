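"""Pipeline configuration: every printed constant of the analysis in one
round-trippable object (sampling rates, filter band, CV layout, SMOTE
strategy, explainability settings).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Tuple

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    fs: float = 250.0
    fs_down: float = 25.0
    resp_band_hz: Tuple[float, float] = (0.05, 0.67)
    cv_folds: int = 10
    seed: int = 0
    smote_strategy: Dict[str, int] = field(
        default_factory=lambda: {"Cardiac": 200, "Healthy": 200, "Sport": 200}
    )
    xai_rounds: int = 30
    selection_k: int = 35

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data["resp_band_hz"] = tuple(data["resp_band_hz"])
        return cls(**data)
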