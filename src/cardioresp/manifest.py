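"""Normative feature manifest: 157 named features with domain tags.

Domain counts are fixed — 5 demographic, 102 cardiac, 18 respiratory,
32 causal/information — and every extractor output is validated against
this manifest, so the feature-table schema cannot drift silently. Each
entry also records which input variant the feature consumes (beat-wise
RRi, 250 Hz tachogram, 250 Hz filtered respiration, or the 25 Hz
signal pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

from .hrv import (
    ENTROPY_NAMES,
    FREQUENCY_NAMES,
    POINCARE_NAMES,
    SYMBOLIC_NAMES,
    TIME_NAMES,
)
from .respiratory import RESPIRATORY_NAMES

__all__ = ["ManifestEntry", "FeatureManifest", "default_manifest"]

DEMOGRAPHIC_NAMES = ["Age", "Weight", "Height", "Sex", "BMI"]

COUPLING_NAMES = [
    "GC_RespToRR", "GC_RRToResp", "GC_Ratio", "GC_DirIndex",
    "KGC_RespToRR", "KGC_RRToResp",
    "lsNGC_F_RespToRR", "lsNGC_F_RRToResp",
    "lsNGC_Aff_RespToRR", "lsNGC_Aff_RRToResp",
    "MLGC_MLP_RespToRR", "MLGC_MLP_RRToResp",
    "MLGC_Poly_RespToRR", "MLGC_Poly_RRToResp",
    "TE_RespToRR", "TE_RRToResp", "NTE_RespToRR", "NTE_RRToResp",
    "TE_DirIndex",
    "CondEn_RRGivenResp", "CondEn_RespGivenRR", "JointEn",
    "MI_Lag0", "MI_Max", "MI_MaxLag",
    "CrossSampEn",
    "CorrCoef_Max", "CorrCoef_MaxLag", "CorrCoef_Lag0",
    "Coh_Max", "Coh_MeanHF", "PhaseSync",
]


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    domain: str            # demographic | cardiac | respiratory | causal_information
    input_variant: str     # demographics | rri | tachogram250 | resp250 | pair25
    description: str = ""


@dataclass
class FeatureManifest:
    entries: List[ManifestEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("manifest names must be unique")
        counts = self.domain_counts()
        expected = {
            "demographic": 5,
            "cardiac": 102,
            "respiratory": 18,
            "causal_information": 32,
        }
        if counts != expected:
            raise ValueError(f"domain counts {counts} != required {expected}")

    def domain_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for e in self.entries:
            counts[e.domain] = counts.get(e.domain, 0) + 1
        return counts

    @property
    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    def names_for(self, *domains: str) -> List[str]:
        return [e.name for e in self.entries if e.domain in domains]

    def __len__(self) -> int:
        return len(self.entries)

    def to_records(self) -> List[Dict[str, str]]:
        return [
            {"name": e.name, "domain": e.domain,
             "input_variant": e.input_variant, "description": e.description}
            for e in self.entries
        ]


def default_manifest() -> FeatureManifest:
    entries: List[ManifestEntry] = []
    for n in DEMOGRAPHIC_NAMES:
        entries.append(ManifestEntry(n, "demographic", "demographics"))
    for n in TIME_NAMES:
        entries.append(ManifestEntry(n, "cardiac", "rri", "time domain"))
    for n in FREQUENCY_NAMES:
        entries.append(ManifestEntry(n, "cardiac", "tachogram250", "frequency domain"))
    for n in POINCARE_NAMES:
        entries.append(
            ManifestEntry(n, "cardiac", "rri", "nonlinear: Poincare/asymmetry")
        )
    for n in ENTROPY_NAMES:
        entries.append(ManifestEntry(n, "cardiac", "rri", "nonlinear: entropy/fractal"))
    for n in SYMBOLIC_NAMES:
        entries.append(ManifestEntry(n, "cardiac", "rri", "symbolic dynamics"))
    for n in RESPIRATORY_NAMES:
        entries.append(ManifestEntry(n, "respiratory", "resp250"))
    for n in COUPLING_NAMES:
        entries.append(ManifestEntry(n, "causal_information", "pair25"))
    return FeatureManifest(entries)
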