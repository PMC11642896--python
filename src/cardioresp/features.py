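"""End-to-end feature extraction: Recording -> 157-feature vector.

Orchestrates preprocessing (band-pass, tachogram, decimation) and the four
feature domains, validating the output against the pinned manifest. The
causal/information block consumes the 25 Hz decimated signal pair; the
frequency-domain HRV features consume the 250 Hz tachogram; everything
else works on the beat-wise RRi or the 250 Hz filtered respiration.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .coupling import CouplingConfig, assemble_coupling_features
from .hrv import (
    hrv_entropy_features,
    hrv_frequency_features,
    hrv_poincare_features,
    hrv_time_features,
    symbolic_dynamics_features,
)
from .manifest import FeatureManifest, default_manifest
from .preprocess import bandpass_resp, check_stationarity, downsample, tachogram_from_rri
from .respiratory import detect_breaths, respiratory_features
from .synthetic import Recording

__all__ = ["extract_features", "extract_cohort_features", "paired_signals_25hz"]

_SEX_CODE = {"M": 1.0, "F": 0.0}


def paired_signals_25hz(recording: Recording):
    """Time-aligned (respiration, tachogram) pair decimated to 25 Hz."""
    fs = recording.fs
    resp_f = bandpass_resp(recording.resp, fs)
    tach = tachogram_from_rri(recording.rri, fs_target=fs)
    start = int(round(tach.t0 * fs))
    resp_seg = resp_f[start: start + len(tach.values)]
    n = min(len(resp_seg), len(tach.values))
    resp_seg = resp_seg[:n]
    rr_seg = tach.values[:n]
    good = np.isfinite(rr_seg)
    resp_seg, rr_seg = resp_seg[good], rr_seg[good]
    factor = int(round(fs / 25.0))
    if factor > 1:
        resp25 = downsample(resp_seg, factor)
        rr25 = downsample(rr_seg, factor)
    else:
        resp25, rr25 = resp_seg, rr_seg
    return resp25, rr25


def extract_features(
    recording: Recording,
    manifest: Optional[FeatureManifest] = None,
    coupling_config: Optional[CouplingConfig] = None,
    seed: int = 0,
) -> Dict[str, float]:
    """All 157 manifest features for one recording (NaN = masked)."""
    manifest = manifest or default_manifest()
    rri = recording.rri
    fs = recording.fs

    feats: Dict[str, float] = {}
    demo = recording.demographics
    feats["Age"] = float(demo["age"])
    feats["Weight"] = float(demo["weight_kg"])
    feats["Height"] = float(demo["height_cm"])
    feats["Sex"] = _SEX_CODE.get(str(demo["sex"]).upper(), np.nan)
    feats["BMI"] = float(demo["bmi"])

    feats.update(hrv_time_features(rri))
    feats.update(hrv_poincare_features(rri))
    feats.update(hrv_entropy_features(rri))
    feats.update(symbolic_dynamics_features(rri))

    tach = tachogram_from_rri(rri, fs_target=fs)
    vals = tach.values[np.isfinite(tach.values)]
    feats.update(hrv_frequency_features(vals, fs))

    resp_f = bandpass_resp(recording.resp, fs)
    breaths = detect_breaths(resp_f, fs)
    feats.update(respiratory_features(breaths))

    resp25, rr25 = paired_signals_25hz(recording)
    coupling, _log = assemble_coupling_features(
        resp25, rr25, fs=25.0, seed=seed, config=coupling_config
    )
    feats.update(coupling)

    missing = set(manifest.names) - set(feats)
    extra = set(feats) - set(manifest.names)
    if missing or extra:
        raise RuntimeError(
            f"feature/manifest mismatch: missing={sorted(missing)}, "
            f"extra={sorted(extra)}"
        )
    return {name: float(feats[name]) for name in manifest.names}


def extract_cohort_features(
    recordings: Iterable[Recording],
    manifest: Optional[FeatureManifest] = None,
    coupling_config: Optional[CouplingConfig] = None,
    seed: int = 0,
    check_rri_stationarity: bool = False,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per subject plus the group label."""
    manifest = manifest or default_manifest()
    rows: List[Dict[str, float]] = []
    index: List[str] = []
    groups: List[str] = []
    for i, rec in enumerate(recordings):
        if check_rri_stationarity:
            check_stationarity(rec.rri)
        row = extract_features(
            rec, manifest=manifest, coupling_config=coupling_config,
            seed=seed + i,
        )
        rows.append(row)
        index.append(rec.subject_id)
        groups.append(rec.group_label)
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    table.insert(0, "group", groups)
    return table
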