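"""Synthetic coupled cardiorespiratory recordings with known ground truth.

The generator emulates short supine recordings of the kind used for
pediatric health-status classification: an impedance-pneumography-like
respiration waveform (relative tidal volume, arbitrary units, 250 Hz) and a
beat-wise RR-interval sequence whose variability is partly driven by the
respiration — a controllable respiratory-sinus-arrhythmia mechanism.

RR generation model, for beat n at time t_n:

    RR_n = mu_RR + a * v_n + g * r(t_n - lag)        [ms]

where ``v`` is a unit-variance AR(1) process (intrinsic cardiac
variability), ``r`` the standardized respiration waveform sampled at the
(lagged) beat time, and (a, g) are calibrated so that the expected RMSSD
hits the group target and the respiratory share of RR variance equals the
preset ``coupling_strength``. Setting the coupling to zero makes the RR
series independent of respiration, which gives every downstream causality
estimator an exact null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats

from .presets import DEFAULT_PRESETS, GroupPreset, mean_corrected_truncnorm

__all__ = [
    "Recording",
    "CalibrationResult",
    "CalibrationError",
    "generate_respiration",
    "generate_rri",
    "calibrate_preset",
    "generate_recording",
    "generate_cohort",
    "coupling_contrast_presets",
]

_MIN_RR_MS = 250.0  # physiological floor, guards against non-positive RR


class CalibrationError(RuntimeError):
    """Raised when (a, g) cannot reproduce the requested RMSSD/variance share."""

    def __init__(self, message: str, achieved_rmssd: float, achieved_share: float):
        super().__init__(message)
        self.achieved_rmssd = achieved_rmssd
        self.achieved_share = achieved_share


@dataclass
class Recording:
    """One subject's paired respiration waveform and RR-interval sequence."""

    resp: np.ndarray          # relative tidal volume, arbitrary units
    rri: np.ndarray           # RR intervals, ms
    fs: float                 # respiration sampling rate, Hz
    demographics: Dict[str, float]
    group_label: str
    subject_id: str = "S000"
    meta: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.resp = np.asarray(self.resp, dtype=float)
        self.rri = np.asarray(self.rri, dtype=float)
        if self.duration_s < 300.0 - 1.0 / self.fs:
            raise ValueError("recording must be at least 5 min long")
        if np.any(self.rri <= 0):
            raise ValueError("all RR intervals must be positive")
        h, w = self.demographics.get("height_cm"), self.demographics.get("weight_kg")
        if h is not None and w is not None:
            bmi = w / (h / 100.0) ** 2
            if abs(bmi - self.demographics.get("bmi", bmi)) > 1e-6:
                raise ValueError("bmi inconsistent with height/weight")

    @property
    def duration_s(self) -> float:
        return len(self.resp) / self.fs


@dataclass(frozen=True)
class CalibrationResult:
    a: float
    g: float
    achieved_rmssd: float
    achieved_share: float
    converged: bool


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_respiration(
    preset: GroupPreset,
    duration_s: float = 300.0,
    fs: float = 250.0,
    seed=0,
    subject_rate: Optional[float] = None,
) -> np.ndarray:
    """Quasi-periodic zero-mean respiration waveform.

    Breath-by-breath construction: each breath is a raised-cosine
    inspiration (duration fraction ie/(1+ie) of the breath) followed by a
    raised-cosine expiration, with per-breath amplitude jitter. Per-breath
    rates jitter around the subject rate with SD
    ``breath_jitter_frac * resprate_sd``; the jitter location carries a
    harmonic-mean correction so that the *detected* respiratory rate
    (60 / mean breath duration) is unbiased for the subject rate.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rate = float(subject_rate if subject_rate is not None else preset.resprate_mean)
    if not (3.0 <= rate <= 40.0):
        raise ValueError("respiratory rate must lie in [3, 40] breaths/min")
    if fs <= 2.0 * rate / 60.0:
        raise ValueError("fs must exceed twice the breathing frequency")
    rng = _as_rng(seed)

    within_sd = preset.breath_jitter_frac * preset.resprate_sd
    # harmonic-mean correction: detected rate = 60/mean(duration) is the
    # harmonic mean of per-breath rates, low-biased by ~(sd/rate)^2
    loc = rate * (1.0 + (within_sd / rate) ** 2) if within_sd > 0 else rate

    n_total = int(round(duration_s * fs))
    segments = [np.zeros(1)]
    n_samples = 1
    frac_insp = preset.ie_ratio / (1.0 + preset.ie_ratio)
    while n_samples < n_total + int(60.0 / 3.0 * fs):
        if within_sd > 0:
            breath_rate = float(rng.normal(loc, within_sd))
            breath_rate = min(max(breath_rate, 3.0), 40.0)
        else:
            breath_rate = rate
        dur = 60.0 / breath_rate
        amp = 1.0 + preset.amplitude_jitter * float(rng.standard_normal())
        amp = max(amp, 0.2)
        n_insp = max(2, int(round(dur * frac_insp * fs)))
        n_exp = max(2, int(round(dur * (1.0 - frac_insp) * fs)))
        u = np.arange(1, n_insp + 1) / n_insp
        v = np.arange(1, n_exp + 1) / n_exp
        segments.append(amp * (1.0 - np.cos(np.pi * u)) / 2.0)
        segments.append(amp * (1.0 + np.cos(np.pi * v)) / 2.0)
        n_samples += n_insp + n_exp
    wave = np.concatenate(segments)[:n_total]
    return wave - wave.mean()


def _ar1_path(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) sample path with stationary start."""
    e = rng.standard_normal(n)
    if phi == 0.0:
        return e
    innov = np.sqrt(1.0 - phi * phi) * e
    innov[0] = e[0]  # stationary initial draw, variance 1
    return signal.lfilter([1.0], [1.0, -phi], innov)


def generate_rri(
    preset: GroupPreset,
    resp: np.ndarray,
    fs: float = 250.0,
    seed=0,
    scales: Optional[Tuple[float, float]] = None,
    subject_hr: Optional[float] = None,
    subject_rmssd: Optional[float] = None,
) -> np.ndarray:
    """RR-interval sequence (ms) coupled to ``resp`` per the preset.

    ``scales`` are the calibrated (a, g) for the preset's nominal
    ``rmssd_target``; if omitted they are computed (and cached) via
    :func:`calibrate_preset`. A per-subject RMSSD rescales both linearly.
    """
    resp = np.asarray(resp, dtype=float)
    if resp.size == 0:
        raise ValueError("resp must be non-empty")
    rng = _as_rng(seed)
    if scales is None:
        cal = calibrate_preset(preset, seed=12345)
        scales = (cal.a, cal.g)
    a, g = scales
    if a < 0 or g < 0:
        raise CalibrationError("negative calibration scales", np.nan, np.nan)
    hr = float(subject_hr if subject_hr is not None else preset.hr_mean)
    rmssd = float(
        subject_rmssd if subject_rmssd is not None else preset.rmssd_target
    )
    s = rmssd / preset.rmssd_target
    a, g = a * s, g * s
    mu_rr = 60000.0 / hr

    sd = resp.std()
    if sd > 0:
        r = (resp - resp.mean()) / sd
    else:
        if preset.coupling_strength > 0:
            raise ValueError("flat respiration cannot drive a coupled RR series")
        r = np.zeros_like(resp)

    duration_s = len(resp) / fs
    n_max = int(np.ceil(duration_s / (_MIN_RR_MS / 1000.0))) + 2
    lag = preset.coupling_lag
    n_resp = len(resp)
    if preset.intrinsic_mode == "pseudo_resp":
        # intrinsic variability shaped like an independent breath signal:
        # spectrally matched to the coupled term but unaligned with `resp`
        w2 = generate_respiration(preset, duration_s, fs, rng)
        v_wave = (w2 - w2.mean()) / w2.std()
        v = None
    else:
        v_wave = None
        v = _ar1_path(n_max, preset.ar_phi, rng)

    rri: List[float] = []
    t = 0.0
    i = 0
    while t < duration_s and i < n_max:
        idx = int(round((t - lag) * fs))
        idx = min(max(idx, 0), n_resp - 1)
        if v_wave is not None:
            intrinsic = v_wave[min(max(idx, 0), len(v_wave) - 1)]
        else:
            intrinsic = v[i]
        rr = mu_rr + a * intrinsic + g * r[idx]
        rr = max(rr, _MIN_RR_MS)
        rri.append(rr)
        t += rr / 1000.0
        i += 1
    return np.asarray(rri)


def _resp_beat_diffusion(preset: GroupPreset, fs: float, rng) -> float:
    """E[(r(t+mu_RR) - r(t))^2] for standardized respiration, via pilot waves."""
    shift = max(1, int(round(60.0 / preset.hr_mean * fs)))
    acc = []
    for _ in range(3):
        w = generate_respiration(preset, 300.0, fs, rng)
        r = (w - w.mean()) / w.std()
        acc.append(np.mean((r[shift:] - r[:-shift]) ** 2))
    return float(np.mean(acc))


_CAL_CACHE: Dict[tuple, CalibrationResult] = {}


def calibrate_preset(
    preset: GroupPreset,
    n_pilot: int = 200,
    seed: int = 12345,
    fs: float = 250.0,
    rmssd_tol: float = 0.05,
    share_tol: float = 0.05,
) -> CalibrationResult:
    """Solve for the scales (a, g) of the RR model.

    Closed-form initialization from the AR(1) increment variance and the
    respiration beat-to-beat diffusion, followed by Monte-Carlo pilot
    refinement; deterministic for a given seed. Raises
    :class:`CalibrationError` when the pilot cannot reach the RMSSD target
    within ``rmssd_tol`` or the variance share within ``share_tol``.
    """
    key = (preset.cache_key(), n_pilot, seed, fs)
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    if n_pilot < 20:
        raise ValueError("n_pilot too small for a stable pilot estimate")
    rng = np.random.default_rng(seed)
    c = preset.coupling_strength
    phi = preset.ar_phi
    target = preset.rmssd_target

    pseudo = preset.intrinsic_mode == "pseudo_resp"
    D = _resp_beat_diffusion(preset, fs, rng) if (c > 0 or pseudo) else 0.0
    if pseudo:
        denom = D  # both components share the breath-like beat diffusion
    else:
        denom = 2.0 * (1.0 - phi) * (1.0 - c) + D * c
    V = target * target / denom
    a = float(np.sqrt(V * (1.0 - c)))
    g = float(np.sqrt(V * c))

    achieved_rmssd, achieved_share = np.nan, np.nan
    for _ in range(3):
        rmssds, shares = [], []
        for _ in range(max(20, n_pilot // 4)):
            w = generate_respiration(preset, 300.0, fs, rng)
            rri = generate_rri(preset, w, fs, rng, scales=(a, g))
            d = np.diff(rri)
            rmssds.append(np.sqrt(np.mean(d * d)))
            if c > 0:
                r = (w - w.mean()) / w.std()
                # respiratory term variance share at beat times
                tb = np.cumsum(rri) / 1000.0
                idx = np.clip(
                    np.round((tb - preset.coupling_lag) * fs).astype(int),
                    0,
                    len(r) - 1,
                )
                resp_term = g * r[idx]
                shares.append(np.var(resp_term) / max(np.var(rri), 1e-12))
            else:
                shares.append(0.0)
        achieved_rmssd = float(np.mean(rmssds))
        achieved_share = float(np.mean(shares))
        if abs(achieved_rmssd - target) / target <= 0.01:
            break
        corr = target / achieved_rmssd
        a *= corr
        g *= corr

    ok = (
        abs(achieved_rmssd - target) / target <= rmssd_tol
        and abs(achieved_share - c) <= share_tol
    )
    result = CalibrationResult(a, g, achieved_rmssd, achieved_share, ok)
    if not ok:
        raise CalibrationError(
            f"calibration did not converge: RMSSD {achieved_rmssd:.2f} "
            f"(target {target}), share {achieved_share:.3f} (target {c})",
            achieved_rmssd,
            achieved_share,
        )
    _CAL_CACHE[key] = result
    return result


def _draw_demographics(preset: GroupPreset, rng: np.random.Generator) -> Dict:
    d = preset.demographics
    def draw(mean, sd, lo, hi):
        if sd <= 0:
            return float(mean)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))

    age = draw(d.age_mean, d.age_sd, *d.age_range)
    mass = draw(d.mass_mean, d.mass_sd, *d.mass_range)
    height = draw(d.height_mean, d.height_sd, *d.height_range)
    sex = "M" if rng.random() < d.male_fraction else "F"
    bmi = mass / (height / 100.0) ** 2
    return {
        "age": age,
        "sex": sex,
        "height_cm": height,
        "weight_kg": mass,
        "bmi": bmi,
    }


def generate_recording(
    preset: GroupPreset,
    duration_s: float = 300.0,
    fs: float = 250.0,
    seed=0,
    scales: Optional[Tuple[float, float]] = None,
    subject_id: str = "S000",
    between_subject: bool = True,
) -> Recording:
    """One full synthetic subject: respiration, coupled RRi, demographics.

    With ``between_subject=True``, subject-level HR / RMSSD / RespRate are
    drawn from mean-corrected truncated normals matching the group's
    descriptive statistics; otherwise the preset means are used directly.
    """
    rng = _as_rng(seed)
    if between_subject:
        hr = float(
            mean_corrected_truncnorm(
                preset.hr_mean, preset.hr_sd, *preset.hr_range
            ).rvs(random_state=rng)
        )
        rmssd = float(
            mean_corrected_truncnorm(
                preset.rmssd_target, preset.rmssd_sd, *preset.rmssd_range
            ).rvs(random_state=rng)
        )
        lo, hi = preset.resprate_range
        lo, hi = max(lo, 3.0), min(hi, 40.0)
        rate = float(
            mean_corrected_truncnorm(
                preset.resprate_mean, preset.resprate_sd, lo, hi
            ).rvs(random_state=rng)
        )
    else:
        hr, rmssd, rate = preset.hr_mean, preset.rmssd_target, preset.resprate_mean

    resp = generate_respiration(preset, duration_s, fs, rng, subject_rate=rate)
    if scales is None:
        cal = calibrate_preset(preset, seed=12345, fs=fs)
        scales = (cal.a, cal.g)
    rri = generate_rri(
        preset, resp, fs, rng, scales=scales, subject_hr=hr, subject_rmssd=rmssd
    )
    demo = _draw_demographics(preset, rng)
    meta = {
        "subject_hr": hr,
        "subject_rmssd": rmssd,
        "subject_resprate": rate,
        "a": scales[0],
        "g": scales[1],
        "coupling_strength": preset.coupling_strength,
        "coupling_lag": preset.coupling_lag,
        "ar_phi": preset.ar_phi,
    }
    return Recording(
        resp=resp,
        rri=rri,
        fs=fs,
        demographics=demo,
        group_label=preset.group_label,
        subject_id=subject_id,
        meta=meta,
    )


def coupling_contrast_presets(
    levels: Tuple[float, float, float] = (0.2, 0.45, 0.7),
    base: Optional[GroupPreset] = None,
) -> Dict[str, GroupPreset]:
    """Presets for a cohort whose groups differ only in coupling strength.

    All physiological and demographic parameters are shared (taken from
    ``base``, default the Healthy preset); the intrinsic RR variability is
    switched to the spectrally matched ``pseudo_resp`` mode so that the
    group contrast lives purely in the respiration-RR alignment — the
    construction used to probe whether causal/information features add
    information beyond univariate HRV.
    """
    base = (base or DEFAULT_PRESETS["Healthy"]).with_(intrinsic_mode="pseudo_resp")
    names = ("Cardiac", "Healthy", "Sport")
    return {
        name: base.with_(group_label=name, coupling_strength=float(c))
        for name, c in zip(names, levels)
    }


def generate_cohort(
    presets: Optional[Mapping[str, GroupPreset]] = None,
    n_per_group: Sequence[int] | Mapping[str, int] = (29, 62, 44),
    duration_s: float = 300.0,
    fs: float = 250.0,
    seed: int = 0,
) -> List[Recording]:
    """Reproducible group-labelled cohort of synthetic recordings.

    ``n_per_group`` is either a mapping group->count or a sequence aligned
    with the preset mapping's order (default Cardiac, Healthy, Sport).
    """
    presets = dict(presets or DEFAULT_PRESETS)
    if isinstance(n_per_group, Mapping):
        counts = {k: int(n_per_group[k]) for k in presets}
    else:
        counts = dict(zip(presets.keys(), (int(n) for n in n_per_group)))
    if any(v < 1 for v in counts.values()):
        raise ValueError("each group needs at least one subject")

    ss = np.random.SeedSequence(seed)
    group_seeds = ss.spawn(len(presets))
    recordings: List[Recording] = []
    for (name, preset), gss in zip(presets.items(), group_seeds):
        cal = calibrate_preset(preset, seed=12345, fs=fs)
        subj_seeds = gss.spawn(counts[name])
        for j, sss in enumerate(subj_seeds):
            rec = generate_recording(
                preset,
                duration_s=duration_s,
                fs=fs,
                seed=np.random.default_rng(sss),
                scales=(cal.a, cal.g),
                subject_id=f"{name[0]}{j + 1:03d}",
            )
            recordings.append(rec)
    return recordings
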