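"""Breath segmentation and the respiratory feature block.

Breaths are segmented on the band-passed respiration waveform as
trough-peak-trough cycles; per-breath quantities (instantaneous rate,
relative tidal volume, inspiration:expiration ratio) are summarized with
simple robust statistics. Tidal volume is relative — indexed by the median
breath amplitude — because impedance-derived respiration has no volume
calibration.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = ["detect_breaths", "respiratory_features", "RESPIRATORY_NAMES"]

RESPIRATORY_NAMES = [
    "RespRate_Mean", "RespRate_SD", "RespRate_CV", "RespRate_Median",
    "RespRate_IQR", "RespRate_Range",
    "RelTV_Mean", "RelTV_SD", "RelTV_CV", "RelTV_IQR", "RelTV_Range",
    "RelTV_Skew",
    "IERatio_Mean", "IERatio_SD", "IERatio_CV", "IERatio_Median",
    "IERatio_IQR", "IERatio_Range",
]

#: shortest admissible breath: 40 breaths/min
_MIN_BREATH_S = 60.0 / 40.0


def detect_breaths(resp: np.ndarray, fs: float) -> pd.DataFrame:
    """Trough-peak-trough breath table from a band-passed waveform.

    Peaks closer than the minimum breath duration or with prominence below
    0.1x the median prominence are rejected. Columns: onset, peak, end
    (sample indices), t_onset/t_peak/t_end (s), insp_s, exp_s, duration_s,
    amplitude (peak minus mean of flanking troughs).
    """
    resp = np.asarray(resp, dtype=float)
    cols = ["onset", "peak", "end", "t_onset", "t_peak", "t_end",
            "insp_s", "exp_s", "duration_s", "amplitude"]
    if np.ptp(resp) == 0.0:
        return pd.DataFrame(columns=cols)
    min_dist = max(1, int(round(_MIN_BREATH_S * fs)))
    peaks, props = signal.find_peaks(resp, distance=min_dist, prominence=0.0)
    if len(peaks) == 0:
        return pd.DataFrame(columns=cols)
    med_prom = np.median(props["prominences"])
    keep = props["prominences"] >= 0.1 * med_prom
    peaks = peaks[keep]
    if len(peaks) == 0:
        return pd.DataFrame(columns=cols)

    # troughs: minimum between consecutive peaks; boundary troughs at ends
    onsets = np.empty(len(peaks), dtype=int)
    ends = np.empty(len(peaks), dtype=int)
    onsets[0] = int(np.argmin(resp[: peaks[0]])) if peaks[0] > 0 else 0
    for i in range(1, len(peaks)):
        seg = resp[peaks[i - 1]: peaks[i]]
        onsets[i] = peaks[i - 1] + int(np.argmin(seg))
        ends[i - 1] = onsets[i]
    tail = resp[peaks[-1]:]
    ends[-1] = peaks[-1] + (int(np.argmin(tail)) if len(tail) > 1 else 0)

    rows = []
    for on, pk, en in zip(onsets, peaks, ends):
        if not (on < pk < en):
            continue
        amp = resp[pk] - 0.5 * (resp[on] + resp[en])
        rows.append(
            dict(
                onset=on, peak=pk, end=en,
                t_onset=on / fs, t_peak=pk / fs, t_end=en / fs,
                insp_s=(pk - on) / fs, exp_s=(en - pk) / fs,
                duration_s=(en - on) / fs, amplitude=amp,
            )
        )
    return pd.DataFrame(rows, columns=cols)


def _stats(x: np.ndarray) -> Dict[str, float]:
    return {
        "Mean": float(np.mean(x)),
        "SD": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
        "CV": float(np.std(x, ddof=1) / np.mean(x))
        if len(x) > 1 and np.mean(x) != 0 else np.nan,
        "Median": float(np.median(x)),
        "IQR": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "Range": float(np.ptp(x)),
    }


def respiratory_features(breaths: pd.DataFrame) -> Dict[str, float]:
    """The 18 respiratory features from a breath table.

    ``RespRate_Mean`` is 60 / mean breath duration (the detected breathing
    rate); its spread statistics are taken over per-breath instantaneous
    rates. Relative tidal volume is per-breath amplitude divided by the
    median amplitude, so its median is 1 by construction.
    """
    out = {k: np.nan for k in RESPIRATORY_NAMES}
    if len(breaths) < 2:
        return out
    dur = breaths["duration_s"].to_numpy()
    inst_rate = 60.0 / dur
    rate_stats = _stats(inst_rate)
    rate_stats["Mean"] = 60.0 / float(np.mean(dur))
    for k in ("Mean", "SD", "CV", "Median", "IQR", "Range"):
        out[f"RespRate_{k}"] = rate_stats[k]

    amp = breaths["amplitude"].to_numpy()
    med = np.median(amp)
    if med > 0:
        rel_tv = amp / med
        tv_stats = _stats(rel_tv)
        for k in ("Mean", "SD", "CV", "IQR", "Range"):
            out[f"RelTV_{k}"] = tv_stats[k]
        out["RelTV_Skew"] = float(stats.skew(rel_tv)) if len(rel_tv) > 2 else np.nan

    ie = breaths["insp_s"].to_numpy() / breaths["exp_s"].to_numpy()
    ie = ie[np.isfinite(ie)]
    if len(ie) >= 2:
        ie_stats = _stats(ie)
        for k in ("Mean", "SD", "CV", "Median", "IQR", "Range"):
            out[f"IERatio_{k}"] = ie_stats[k]
    return out
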