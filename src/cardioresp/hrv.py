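"""Heart-rate-variability battery: time, frequency, Poincare/asymmetry/
fragmentation, entropy/fractal, and symbolic-dynamics features of a
beat-wise RR-interval series.

All functions return ``{name: value}`` dicts; features that cannot be
computed on a given input (too short, degenerate) are returned as NaN so
that downstream tables carry an explicit missing-value mask instead of
raising mid-pipeline.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import signal

__all__ = [
    "hrv_time_features",
    "hrv_frequency_features",
    "hrv_poincare_features",
    "hrv_entropy_features",
    "symbolic_dynamics_features",
    "TIME_NAMES",
    "FREQUENCY_NAMES",
    "POINCARE_NAMES",
    "ENTROPY_NAMES",
    "SYMBOLIC_NAMES",
]

TIME_NAMES = [
    "MeanNN", "SDNN", "RMSSD", "SDSD", "CVNN", "CVSD", "MedianNN", "MadNN",
    "MCVNN", "IQRNN", "Prc5NN", "Prc20NN", "Prc80NN", "Prc95NN", "MinNN",
    "MaxNN", "RangeNN", "pNN50", "pNN20", "pNN10", "MeanHR", "SDHR", "MinHR",
    "MaxHR", "HTI", "TINN", "SDRMSSD", "MeanAbsDiff", "MedianAbsDiff",
    "MaxAbsDiff",
]
FREQUENCY_NAMES = [
    "VLF", "LF", "HF", "VHF", "TotalPower", "VLFRel", "LFRel", "HFRel",
    "VHFRel", "LFn", "HFn", "LnHF", "LFHF", "LFPeak", "HFPeak", "SpecEn",
]
POINCARE_NAMES = [
    "SD1", "SD2", "SD1SD2", "EllipseArea", "CSI", "CVI", "CSIModified",
    "SD1d", "SD1a", "SD2d", "SD2a", "SDNNd", "SDNNa", "C1d", "C1a", "C2d",
    "C2a", "Cd", "Ca", "GI", "SI", "AI", "PI", "PIP", "IALS", "PSS", "PAS",
]
ENTROPY_NAMES = [
    "ApEn", "SampEn", "SampEnScale2", "SampEnScale3", "CoSEn", "FuzzyEn",
    "PermEn", "WPermEn", "ShanEnHist", "DFAalpha1", "DFAalpha2", "HFD",
    "KFD", "PFD", "SFD", "LZC", "HurstRS",
]
SYMBOLIC_NAMES = [
    "SymDyn0V", "SymDyn1V", "SymDyn2LV", "SymDyn2UV", "SymDynShanEn",
    "SymDynForbidden", "Polvar5", "Polvar10", "Polvar20", "Phvar20",
    "Phvar50", "Phvar100",
]


def _nan_dict(names) -> Dict[str, float]:
    return {k: np.nan for k in names}


# ---------------------------------------------------------------- time domain

def hrv_time_features(rri: np.ndarray) -> Dict[str, float]:
    """Standard time-domain statistics of the RR series (ms)."""
    rri = np.asarray(rri, dtype=float)
    out = _nan_dict(TIME_NAMES)
    if rri.size < 1:
        return out
    hr = 60000.0 / rri
    out["MeanNN"] = float(np.mean(rri))
    out["MedianNN"] = float(np.median(rri))
    out["MinNN"] = float(np.min(rri))
    out["MaxNN"] = float(np.max(rri))
    out["RangeNN"] = float(np.ptp(rri))
    out["MeanHR"] = float(np.mean(hr))
    out["MinHR"] = float(np.min(hr))
    out["MaxHR"] = float(np.max(hr))
    out["Prc5NN"] = float(np.percentile(rri, 5))
    out["Prc20NN"] = float(np.percentile(rri, 20))
    out["Prc80NN"] = float(np.percentile(rri, 80))
    out["Prc95NN"] = float(np.percentile(rri, 95))
    out["IQRNN"] = float(np.percentile(rri, 75) - np.percentile(rri, 25))
    mad = float(np.median(np.abs(rri - np.median(rri))) * 1.4826)
    out["MadNN"] = mad
    out["MCVNN"] = mad / out["MedianNN"] if out["MedianNN"] > 0 else np.nan
    if rri.size >= 2:
        sdnn = float(np.std(rri, ddof=1))
        out["SDNN"] = sdnn
        out["SDHR"] = float(np.std(hr, ddof=1))
        out["CVNN"] = sdnn / out["MeanNN"] if out["MeanNN"] > 0 else np.nan
        d = np.diff(rri)
        rmssd = float(np.sqrt(np.mean(d * d)))
        out["RMSSD"] = rmssd
        out["CVSD"] = rmssd / out["MeanNN"] if out["MeanNN"] > 0 else np.nan
        out["SDSD"] = float(np.std(d, ddof=1)) if d.size >= 2 else 0.0
        out["pNN50"] = float(np.mean(np.abs(d) > 50.0) * 100.0)
        out["pNN20"] = float(np.mean(np.abs(d) > 20.0) * 100.0)
        out["pNN10"] = float(np.mean(np.abs(d) > 10.0) * 100.0)
        out["SDRMSSD"] = sdnn / rmssd if rmssd > 0 else np.nan
        out["MeanAbsDiff"] = float(np.mean(np.abs(d)))
        out["MedianAbsDiff"] = float(np.median(np.abs(d)))
        out["MaxAbsDiff"] = float(np.max(np.abs(d)))
    # geometric features on the standard 1/128 s histogram
    binw = 1000.0 / 128.0
    edges = np.arange(np.min(rri) - binw, np.max(rri) + 2 * binw, binw)
    hist, edges = np.histogram(rri, bins=edges)
    peak = hist.max()
    out["HTI"] = float(rri.size / peak) if peak > 0 else np.nan
    out["TINN"] = _tinn(hist, edges)
    return out


def _tinn(hist: np.ndarray, edges: np.ndarray) -> float:
    """Baseline width of the best-fit triangle over the RR histogram."""
    if hist.sum() == 0:
        return np.nan
    centers = (edges[:-1] + edges[1:]) / 2.0
    k = int(np.argmax(hist))
    y = hist.astype(float)
    best, best_err = np.nan, np.inf
    lo_candidates = range(0, k + 1)
    hi_candidates = range(k, len(y))
    for i in lo_candidates:
        for j in hi_candidates:
            if j <= i:
                continue
            tri = np.zeros_like(y)
            up = np.arange(i, k + 1)
            down = np.arange(k, j + 1)
            if k > i:
                tri[up] = y[k] * (up - i) / (k - i)
            else:
                tri[k] = y[k]
            if j > k:
                tri[down] = y[k] * (j - down) / (j - k)
            tri[k] = y[k]
            err = float(np.sum((y - tri) ** 2))
            if err < best_err:
                best_err = err
                best = centers[j] - centers[i]
    return float(best)


# ----------------------------------------------------------- frequency domain

def hrv_frequency_features(
    tachogram: np.ndarray, fs: float, working_fs: float = 4.0
) -> Dict[str, float]:
    """Welch-periodogram band powers of the tachogram (ms^2 units).

    The tachogram is resampled to a 4 Hz working grid; Welch uses 120 s
    segments with 50% overlap. Bands: VLF 0.0033-0.04, LF 0.04-0.15,
    HF 0.15-0.4, VHF 0.4-0.5 Hz. ``LFn + HFn == 1`` by construction.
    """
    x = np.asarray(tachogram, dtype=float)
    out = _nan_dict(FREQUENCY_NAMES)
    if len(x) / fs < 120.0:
        return out
    t = np.arange(len(x)) / fs
    grid = np.arange(0.0, t[-1], 1.0 / working_fs)
    xi = np.interp(grid, t, x)
    nperseg = min(int(120 * working_fs), len(xi))
    f, pxx = signal.welch(
        xi, fs=working_fs, nperseg=nperseg, noverlap=nperseg // 2,
        detrend="linear",
    )

    def band(lo, hi):
        m = (f >= lo) & (f < hi)
        if not np.any(m):
            return 0.0
        return float(np.trapezoid(pxx[m], f[m]))

    vlf, lf, hf, vhf = band(0.0033, 0.04), band(0.04, 0.15), band(0.15, 0.4), band(0.4, 0.5)
    tp = vlf + lf + hf + vhf
    out.update(VLF=vlf, LF=lf, HF=hf, VHF=vhf, TotalPower=tp)
    if tp > 0:
        out.update(VLFRel=vlf / tp, LFRel=lf / tp, HFRel=hf / tp, VHFRel=vhf / tp)
    if lf + hf > 0:
        out["LFn"] = lf / (lf + hf)
        out["HFn"] = hf / (lf + hf)
    out["LnHF"] = float(np.log(hf)) if hf > 0 else np.nan
    out["LFHF"] = lf / hf if hf > 0 else np.nan
    mlf = (f >= 0.04) & (f < 0.15)
    mhf = (f >= 0.15) & (f < 0.4)
    if np.any(mlf):
        out["LFPeak"] = float(f[mlf][np.argmax(pxx[mlf])])
    if np.any(mhf):
        out["HFPeak"] = float(f[mhf][np.argmax(pxx[mhf])])
    mtot = (f >= 0.0033) & (f < 0.5)
    p = pxx[mtot]
    if p.sum() > 0:
        q = p / p.sum()
        q = q[q > 0]
        out["SpecEn"] = float(-np.sum(q * np.log2(q)) / np.log2(len(p)))
    return out


# ------------------------------------------------ Poincare, asymmetry, fragm.

def hrv_poincare_features(rri: np.ndarray) -> Dict[str, float]:
    """Poincare-plot geometry, heart-rate asymmetry, and fragmentation."""
    rri = np.asarray(rri, dtype=float)
    out = _nan_dict(POINCARE_NAMES)
    if rri.size < 3:
        return out
    d = np.diff(rri)
    rmssd2 = float(np.mean(d * d))
    sd1 = float(np.sqrt(rmssd2 / 2.0))
    var_rr = float(np.var(rri))
    sd2 = float(np.sqrt(max(2.0 * var_rr - sd1 * sd1, 0.0)))
    out["SD1"], out["SD2"] = sd1, sd2
    out["SD1SD2"] = sd1 / sd2 if sd2 > 0 else np.nan
    out["EllipseArea"] = float(np.pi * sd1 * sd2)
    out["CSI"] = sd2 / sd1 if sd1 > 0 else np.nan
    out["CVI"] = float(np.log10(16.0 * sd1 * sd2)) if sd1 * sd2 > 0 else np.nan
    out["CSIModified"] = 4.0 * sd2 * sd2 / sd1 if sd1 > 0 else np.nan

    # asymmetry: distances of Poincare points to / along the identity line
    x, y = rri[:-1], rri[1:]
    n = len(x)
    dist = (y - x) / np.sqrt(2.0)        # transverse (deceleration > 0)
    lon = (x + y - 2.0 * np.mean(rri)) / np.sqrt(2.0)
    dec, acc = dist > 0, dist < 0
    denom = max(n - 1, 1)
    sd1d = float(np.sqrt(np.sum(dist[dec] ** 2) / denom))
    sd1a = float(np.sqrt(np.sum(dist[acc] ** 2) / denom))
    on_line = ~dec & ~acc
    sd2d = float(np.sqrt((np.sum(lon[dec] ** 2) + 0.5 * np.sum(lon[on_line] ** 2)) / denom))
    sd2a = float(np.sqrt((np.sum(lon[acc] ** 2) + 0.5 * np.sum(lon[on_line] ** 2)) / denom))
    out.update(SD1d=sd1d, SD1a=sd1a, SD2d=sd2d, SD2a=sd2a)
    out["SDNNd"] = float(np.sqrt(0.5 * (sd1d ** 2 + sd2d ** 2)))
    out["SDNNa"] = float(np.sqrt(0.5 * (sd1a ** 2 + sd2a ** 2)))
    t1 = sd1d ** 2 + sd1a ** 2
    t2 = sd2d ** 2 + sd2a ** 2
    out["C1d"] = sd1d ** 2 / t1 if t1 > 0 else np.nan
    out["C1a"] = sd1a ** 2 / t1 if t1 > 0 else np.nan
    out["C2d"] = sd2d ** 2 / t2 if t2 > 0 else np.nan
    out["C2a"] = sd2a ** 2 / t2 if t2 > 0 else np.nan
    tot = t1 + t2
    out["Cd"] = (sd1d ** 2 + sd2d ** 2) / tot if tot > 0 else np.nan
    out["Ca"] = (sd1a ** 2 + sd2a ** 2) / tot if tot > 0 else np.nan

    abs_d = np.abs(dist)
    s = abs_d.sum()
    out["GI"] = float(abs_d[dec].sum() / s * 100.0) if s > 0 else np.nan
    theta = np.abs(np.arctan2(y, x) - np.pi / 4.0)
    st = theta.sum()
    out["SI"] = float(theta[dec].sum() / st * 100.0) if st > 0 else np.nan
    r2 = x * x + y * y
    area = 0.5 * r2 * theta
    sa = area.sum()
    out["AI"] = float(area[dec].sum() / sa * 100.0) if sa > 0 else np.nan
    off = dec.sum() + acc.sum()
    out["PI"] = float(acc.sum() / off * 100.0) if off > 0 else np.nan

    out.update(_fragmentation(d))
    return out


def _fragmentation(d: np.ndarray) -> Dict[str, float]:
    """Costa-style fragmentation indices from the sign sequence of dRR."""
    if d.size < 3:
        return {"PIP": np.nan, "IALS": np.nan, "PSS": np.nan, "PAS": np.nan}
    s = np.sign(d)
    # inflection: sign change (zeros count as change, as in fragmented rhythm)
    change = s[1:] * s[:-1] <= 0
    pip = float(np.mean(change) * 100.0)
    # segments of constant sign
    seg_lengths = []
    cur = 1
    for i in range(1, len(s)):
        if s[i] == s[i - 1] and s[i] != 0:
            cur += 1
        else:
            seg_lengths.append(cur)
            cur = 1
    seg_lengths.append(cur)
    seg_lengths = np.asarray(seg_lengths, dtype=float)
    ials = float(1.0 / np.mean(seg_lengths))
    pss = float(np.sum(seg_lengths[seg_lengths < 3]) / np.sum(seg_lengths) * 100.0)
    # alternation: runs of strictly alternating signs, length >= 4 intervals
    alt = s[1:] * s[:-1] < 0
    pas_count = 0
    run = 0
    for a in alt:
        if a:
            run += 1
        else:
            if run >= 3:
                pas_count += run + 1
            run = 0
    if run >= 3:
        pas_count += run + 1
    pas = float(pas_count / len(d) * 100.0)
    return {"PIP": pip, "IALS": ials, "PSS": pss, "PAS": pas}


# ------------------------------------------------------- entropy and fractal

def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = len(x) - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def _count_matches(x: np.ndarray, m: int, r: float) -> int:
    """Number of template pairs (i<j) within Chebyshev distance r."""
    emb = _embed(x, m)
    n = len(emb)
    count = 0
    for i in range(n - 1):
        dist = np.max(np.abs(emb[i + 1:] - emb[i]), axis=1)
        count += int(np.sum(dist <= r))
    return count


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if r <= 0 or len(x) < m + 2:
        return np.nan
    b = _count_matches(x, m, r)
    a = _count_matches(x, m + 1, r)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if r <= 0 or len(x) < m + 2:
        return np.nan

    def phi(mm: int) -> float:
        emb = _embed(x, mm)
        n = len(emb)
        tot = 0.0
        for i in range(n):
            dist = np.max(np.abs(emb - emb[i]), axis=1)
            tot += np.log(np.mean(dist <= r))
        return tot / n

    return float(phi(m) - phi(m + 1))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if r <= 0 or len(x) < m + 2:
        return np.nan

    def phi(mm: int) -> float:
        emb = _embed(x, mm)
        emb = emb - emb.mean(axis=1, keepdims=True)
        n = len(emb)
        tot = 0.0
        for i in range(n - 1):
            dist = np.max(np.abs(emb[i + 1:] - emb[i]), axis=1)
            tot += np.sum(np.exp(-(dist ** 2) / (2 * r * r)))
        pairs = n * (n - 1) / 2.0
        return tot / pairs

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return np.nan
    return float(-np.log(p_m1 / p_m))


def permutation_entropy(
    x: np.ndarray, order: int = 3, weighted: bool = False
) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < order + 1:
        return np.nan
    emb = _embed(x, order)
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))
    if weighted:
        w = np.var(emb, axis=1)
        if w.sum() == 0:
            return 0.0
        p = np.bincount(codes, weights=w, minlength=order ** order)
        p = p / p.sum()
    else:
        p = np.bincount(codes, minlength=order ** order).astype(float)
        p = p / p.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)) / np.log2(_factorial(order)))


def _factorial(k: int) -> int:
    out = 1
    for i in range(2, k + 1):
        out *= i
    return out


def dfa_alpha(x: np.ndarray, scales: np.ndarray) -> float:
    """Detrended fluctuation analysis slope over the given window sizes."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - np.mean(x))
    flucts = []
    used = []
    for s in scales:
        s = int(s)
        nwin = len(y) // s
        if nwin < 2:
            continue
        segs = y[: nwin * s].reshape(nwin, s)
        t = np.arange(s)
        tm = t - t.mean()
        denom = float(tm @ tm)
        slopes = (segs @ tm) / denom
        intercepts = segs.mean(axis=1)
        detrended = segs - (intercepts[:, None] + slopes[:, None] * tm)
        flucts.append(np.sqrt(np.mean(detrended ** 2)))
        used.append(s)
    if len(used) < 3:
        return np.nan
    coeffs = np.polyfit(np.log(used), np.log(flucts), 1)
    return float(coeffs[0])


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < kmax * 3:
        return np.nan
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            lm = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / (len(idx) - 1) / k
            lengths.append(lm / k)
        if lengths:
            lk.append(np.mean(lengths))
            ks.append(k)
    coeffs = np.polyfit(np.log(1.0 / np.asarray(ks)), np.log(lk), 1)
    return float(coeffs[0])


def katz_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.nan
    dists = np.sqrt(1.0 + np.diff(x) ** 2)
    L = dists.sum()
    a = L / (len(x) - 1)
    d = np.max(np.sqrt(np.arange(1, len(x)) ** 2 + (x[1:] - x[0]) ** 2))
    if a <= 0 or d <= 0:
        return np.nan
    return float(np.log10(L / a) / np.log10(d / a))


def petrosian_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.nan
    d = np.diff(x)
    nsc = int(np.sum(d[1:] * d[:-1] < 0))
    n = len(x)
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * nsc))))


def sevcik_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3 or np.ptp(x) == 0:
        return np.nan
    xs = (x - x.min()) / np.ptp(x)
    t = np.linspace(0, 1, n)
    L = np.sum(np.sqrt(np.diff(t) ** 2 + np.diff(xs) ** 2))
    return float(1.0 + np.log(L) / np.log(2.0 * (n - 1)))


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalized LZ76 complexity of the median-binarized series."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        return np.nan
    s = (x > np.median(x)).astype(np.int8)
    # Kaspar-Schuster parsing
    i, c, u, v, vmax = 0, 1, 1, 1, 1
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:
                c += 1
                u += vmax
                v = 1
                i = 0
                vmax = 1
            else:
                v = 1
    if v != 1:
        c += 1
    return float(c * np.log2(n) / n)


def hurst_rs(x: np.ndarray) -> float:
    """Hurst exponent via rescaled-range analysis."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 64:
        return np.nan
    sizes = np.unique(np.floor(np.logspace(np.log10(8), np.log10(n // 2), 8)).astype(int))
    rs_vals, used = [], []
    for s in sizes:
        nwin = n // s
        if nwin < 1:
            continue
        vals = []
        for w in range(nwin):
            seg = x[w * s: (w + 1) * s]
            z = np.cumsum(seg - seg.mean())
            r = np.ptp(z)
            sd = seg.std(ddof=1)
            if sd > 0:
                vals.append(r / sd)
        if vals:
            rs_vals.append(np.mean(vals))
            used.append(s)
    if len(used) < 3:
        return np.nan
    coeffs = np.polyfit(np.log(used), np.log(rs_vals), 1)
    return float(coeffs[0])


def hrv_entropy_features(rri: np.ndarray, min_beats: int = 100) -> Dict[str, float]:
    """Entropy/complexity and fractal-scaling features of the RR series."""
    rri = np.asarray(rri, dtype=float)
    out = _nan_dict(ENTROPY_NAMES)
    if rri.size < min_beats:
        return out
    sd = np.std(rri, ddof=1)
    if sd == 0:
        out["LZC"] = 0.0
        return out
    r = 0.2 * sd
    out["ApEn"] = approximate_entropy(rri, 2, r)
    se = sample_entropy(rri, 2, r)
    out["SampEn"] = se
    if np.isfinite(se):
        out["CoSEn"] = float(se + np.log(2.0 * r) - np.log(np.mean(rri)))
    for scale, key in ((2, "SampEnScale2"), (3, "SampEnScale3")):
        ncg = len(rri) // scale
        cg = rri[: ncg * scale].reshape(ncg, scale).mean(axis=1)
        out[key] = sample_entropy(cg, 2, r)
    out["FuzzyEn"] = fuzzy_entropy(rri, 2, r)
    out["PermEn"] = permutation_entropy(rri, 3, weighted=False)
    out["WPermEn"] = permutation_entropy(rri, 3, weighted=True)
    hist, _ = np.histogram(rri, bins=10)
    p = hist / hist.sum()
    p = p[p > 0]
    out["ShanEnHist"] = float(-np.sum(p * np.log2(p)))
    out["DFAalpha1"] = dfa_alpha(rri, np.arange(4, 17))
    out["DFAalpha2"] = dfa_alpha(rri, np.arange(16, 65, 4))
    out["HFD"] = higuchi_fd(rri)
    out["KFD"] = katz_fd(rri)
    out["PFD"] = petrosian_fd(rri)
    out["SFD"] = sevcik_fd(rri)
    out["LZC"] = lempel_ziv_complexity(rri)
    out["HurstRS"] = hurst_rs(rri)
    return out


# ---------------------------------------------------------- symbolic dynamics

def symbolic_dynamics_features(rri: np.ndarray) -> Dict[str, float]:
    """Symbolic-dynamics descriptors of the RR series.

    Quantization into 6 equal-width bins over [mu - 2 sigma, mu + 2 sigma]
    (values outside clipped into the edge bins), 3-symbol words classified
    by their number of variations: 0V (no change), 1V (one change), 2LV
    (two like changes: monotone), 2UV (two unlike changes: peak/trough).
    Complemented with Voss's pattern-probability measures (Polvar / Phvar:
    probability of six consecutive |dRR| below / above a threshold in ms).
    """
    rri = np.asarray(rri, dtype=float)
    out = _nan_dict(SYMBOLIC_NAMES)
    if rri.size < 10:
        return out
    mu, sigma = np.mean(rri), np.std(rri)
    if sigma == 0:
        out.update(SymDyn0V=100.0, SymDyn1V=0.0, SymDyn2LV=0.0, SymDyn2UV=0.0,
                   SymDynShanEn=0.0, SymDynForbidden=float(215 / 216 * 100.0))
        out.update(Polvar5=1.0, Polvar10=1.0, Polvar20=1.0,
                   Phvar20=0.0, Phvar50=0.0, Phvar100=0.0)
        return out
    edges = np.linspace(mu - 2 * sigma, mu + 2 * sigma, 7)
    sym = np.clip(np.digitize(rri, edges) - 1, 0, 5)
    words = np.lib.stride_tricks.sliding_window_view(sym, 3)
    d1 = words[:, 1] - words[:, 0]
    d2 = words[:, 2] - words[:, 1]
    nvar = (d1 != 0).astype(int) + (d2 != 0).astype(int)
    v0 = nvar == 0
    v1 = nvar == 1
    like = (d1 * d2) > 0
    v2l = (nvar == 2) & like
    v2u = (nvar == 2) & ~like
    n = len(words)
    out["SymDyn0V"] = float(v0.mean() * 100.0)
    out["SymDyn1V"] = float(v1.mean() * 100.0)
    out["SymDyn2LV"] = float(v2l.mean() * 100.0)
    out["SymDyn2UV"] = float(v2u.mean() * 100.0)
    codes = words[:, 0] * 36 + words[:, 1] * 6 + words[:, 2]
    counts = np.bincount(codes, minlength=216).astype(float)
    p = counts / n
    pz = p[p > 0]
    out["SymDynShanEn"] = float(-np.sum(pz * np.log2(pz)))
    out["SymDynForbidden"] = float(np.mean(counts == 0) * 100.0)
    d = np.abs(np.diff(rri))
    for thr, lo_key, hi_key in (
        (5.0, "Polvar5", None), (10.0, "Polvar10", None), (20.0, "Polvar20", "Phvar20"),
        (50.0, None, "Phvar50"), (100.0, None, "Phvar100"),
    ):
        low = (d < thr).astype(int)
        if lo_key:
            out[lo_key] = _pattern_prob(low)
        if hi_key:
            out[hi_key] = _pattern_prob(1 - low)
    return out


def _pattern_prob(bits: np.ndarray, word: int = 6) -> float:
    """Probability that ``word`` consecutive symbols are all 1."""
    if len(bits) < word:
        return np.nan
    win = np.lib.stride_tricks.sliding_window_view(bits, word)
    return float(np.mean(win.sum(axis=1) == word))
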