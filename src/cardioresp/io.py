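"""Plain-text persistence for recordings, cohorts, feature tables and
results: one directory per subject holding a 250 Hz signal CSV
(``time_s,resp``), an RRi text file (one interval in ms per line) and a
metadata JSON; a cohort manifest CSV ties subjects together.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .manifest import FeatureManifest, default_manifest
from .synthetic import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
    "write_manifest",
    "write_results",
]


def write_recording(rec: Recording, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(rec.resp)) / rec.fs
    pd.DataFrame({"time_s": t, "resp": rec.resp}).to_csv(
        d / "signal.csv", index=False, float_format="%.6f"
    )
    np.savetxt(d / "rri.txt", rec.rri, fmt="%.6f")
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group_label,
        "fs": rec.fs,
        "demographics": rec.demographics,
        "generator": {k: float(v) for k, v in rec.meta.items()},
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))
    return d


def read_recording(directory: str | Path) -> Recording:
    d = Path(directory)
    for fname in ("signal.csv", "rri.txt", "metadata.json"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {d}")
    sig = pd.read_csv(d / "signal.csv")
    t = sig["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise ValueError(f"non-monotone time column in {d/'signal.csv'} at row {bad}")
    rri = []
    for lineno, line in enumerate((d / "rri.txt").read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        val = float(line)
        if val <= 0:
            raise ValueError(f"non-positive RR interval at line {lineno} of rri.txt")
        rri.append(val)
    meta = json.loads((d / "metadata.json").read_text())
    return Recording(
        resp=sig["resp"].to_numpy(),
        rri=np.asarray(rri),
        fs=float(meta["fs"]),
        demographics=meta["demographics"],
        group_label=meta["group"],
        subject_id=meta["subject_id"],
        meta=meta.get("generator", {}),
    )


def write_cohort(recordings: Iterable[Recording], directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        write_recording(rec, d / rec.subject_id)
        demo = rec.demographics
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group_label,
                "age": demo["age"],
                "sex": demo["sex"],
                "height_cm": demo["height_cm"],
                "weight_kg": demo["weight_kg"],
                "bmi": demo["bmi"],
            }
        )
    pd.DataFrame(rows).to_csv(d / "cohort.csv", index=False)
    return d


def read_cohort(directory: str | Path) -> List[Recording]:
    d = Path(directory)
    manifest = pd.read_csv(d / "cohort.csv")
    return [read_recording(d / sid) for sid in manifest["subject_id"]]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=True)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_manifest(path: str | Path, manifest: FeatureManifest | None = None) -> None:
    manifest = manifest or default_manifest()
    Path(path).write_text(json.dumps(manifest.to_records(), indent=1))


def write_results(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, indent=1, default=_default))
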