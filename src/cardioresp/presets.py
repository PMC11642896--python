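"""Group presets for the synthetic cardiorespiratory cohort generator.

Each preset describes one study group (Cardiac, Healthy, Sport) of the
pediatric cohort: heart rate, short-term heart-rate variability (RMSSD),
respiratory rate, breathing morphology, and the strength/lag of the
respiration -> RR-interval coupling (respiratory sinus arrhythmia) that the
generator plants as ground truth.

Defaults for HR, RMSSD and RespRate reproduce the descriptive statistics of
the three study groups (mean, SD and observed range); the coupling strengths
are free separability knobs, not physiological estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

from scipy import optimize, stats

__all__ = [
    "GroupPreset",
    "DemographicsPreset",
    "CARDIAC",
    "HEALTHY",
    "SPORT",
    "DEFAULT_PRESETS",
    "mean_corrected_truncnorm",
]


@dataclass(frozen=True)
class DemographicsPreset:
    """Group-wise demographic distributions (truncated normals + sex ratio)."""

    age_mean: float
    age_sd: float
    age_range: Tuple[float, float]
    mass_mean: float
    mass_sd: float
    mass_range: Tuple[float, float]
    height_mean: float
    height_sd: float
    height_range: Tuple[float, float]
    male_fraction: float


@dataclass(frozen=True)
class GroupPreset:
    """Generator parameters for one study group.

    Parameters
    ----------
    hr_mean, hr_sd : beats/min
        Between-subject mean heart rate and its SD; per-subject values are
        drawn from a truncated normal over ``hr_range`` whose location is
        corrected so the truncated mean equals ``hr_mean``.
    rmssd_target, rmssd_sd : ms
        Between-subject RMSSD target and SD, same drawing scheme.
    resprate_mean, resprate_sd : breaths/min
        Between-subject respiratory rate and SD. Within a recording,
        per-breath rates jitter around the subject rate with
        SD = ``breath_jitter_frac * resprate_sd``.
    ie_ratio : float
        Inspiration:expiration duration ratio (dimensionless).
    coupling_strength : float in [0, 1]
        Fraction of RR variance driven by the (lagged) respiratory signal.
    coupling_lag : s
        Latency of the respiratory influence on RR.
    ar_phi : float
        AR(1) coefficient of the intrinsic (non-respiratory) RR variability.
    intrinsic_mode : {"ar1", "pseudo_resp"}
        Shape of the intrinsic component: a broadband AR(1) process, or an
        independent pseudo-respiratory oscillation (spectrally matched to
        the coupled term, so coupling strength changes only the
        cross-signal alignment, not the univariate RR spectrum).
    """

    group_label: str
    hr_mean: float
    hr_sd: float
    hr_range: Tuple[float, float]
    rmssd_target: float
    rmssd_sd: float
    rmssd_range: Tuple[float, float]
    resprate_mean: float
    resprate_sd: float
    resprate_range: Tuple[float, float]
    ie_ratio: float = 0.7
    coupling_strength: float = 0.5
    coupling_lag: float = 0.4
    ar_phi: float = 0.8
    intrinsic_mode: str = "ar1"
    breath_jitter_frac: float = 0.5
    amplitude_jitter: float = 0.1
    demographics: DemographicsPreset = field(
        default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if self.hr_mean <= 0:
            raise ValueError("hr_mean must be positive")
        if not (3.0 <= self.resprate_mean <= 40.0):
            raise ValueError("resprate_mean must lie in [3, 40] breaths/min")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.rmssd_target <= 0:
            raise ValueError("rmssd_target must be positive")
        if self.ie_ratio <= 0:
            raise ValueError("ie_ratio must be positive")
        if not (0.0 <= self.ar_phi < 1.0):
            raise ValueError("ar_phi must lie in [0, 1)")
        if self.intrinsic_mode not in ("ar1", "pseudo_resp"):
            raise ValueError("intrinsic_mode must be 'ar1' or 'pseudo_resp'")

    def with_(self, **kwargs) -> "GroupPreset":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def cache_key(self) -> tuple:
        """Hashable identity of the fields that affect RR calibration."""
        return (
            self.hr_mean,
            self.rmssd_target,
            self.resprate_mean,
            self.resprate_sd,
            self.ie_ratio,
            self.coupling_strength,
            self.coupling_lag,
            self.ar_phi,
            self.intrinsic_mode,
            self.breath_jitter_frac,
            self.amplitude_jitter,
        )


def mean_corrected_truncnorm(
    mean: float, sd: float, low: float, high: float
) -> stats.rv_continuous:
    """Truncated normal on [low, high] whose *truncated* mean equals ``mean``.

    Plain truncation of N(mean, sd) shifts the expectation whenever the
    bounds are asymmetric around the mean (for a wide right-skewed range the
    bias can exceed 10%); here the location parameter is solved so that the
    expectation of the truncated law is exactly the requested mean.
    """
    if sd <= 0:
        return stats.uniform(loc=mean, scale=0.0)
    if not (low < mean < high):
        raise ValueError("mean must lie strictly inside (low, high)")

    def trunc_mean(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    span = high - low
    loc = optimize.brentq(trunc_mean, low - 2 * span, high + 2 * span, xtol=1e-10)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


_CARDIAC_DEMO = DemographicsPreset(
    age_mean=13.1, age_sd=3.5, age_range=(6.0, 17.0),
    mass_mean=57.1, mass_sd=21.0, mass_range=(23.0, 95.0),
    height_mean=160.4, height_sd=17.2, height_range=(123.0, 184.0),
    male_fraction=20 / 29,
)
_HEALTHY_DEMO = DemographicsPreset(
    age_mean=11.0, age_sd=2.2, age_range=(7.0, 15.0),
    mass_mean=43.5, mass_sd=12.1, mass_range=(21.4, 75.6),
    height_mean=151.2, height_sd=13.1, height_range=(123.0, 183.0),
    male_fraction=33 / 62,
)
_SPORT_DEMO = DemographicsPreset(
    age_mean=13.3, age_sd=1.4, age_range=(10.0, 15.0),
    mass_mean=57.2, mass_sd=13.6, mass_range=(30.0, 81.8),
    height_mean=169.4, height_sd=12.7, height_range=(135.0, 190.0),
    male_fraction=1.0,
)

CARDIAC = GroupPreset(
    group_label="Cardiac",
    hr_mean=72.8, hr_sd=13.3, hr_range=(56.0, 100.5),
    rmssd_target=55.3, rmssd_sd=36.8, rmssd_range=(9.4, 140.7),
    resprate_mean=18.5, resprate_sd=4.6, resprate_range=(7.9, 25.4),
    coupling_strength=0.2,
    demographics=_CARDIAC_DEMO,
)
HEALTHY = GroupPreset(
    group_label="Healthy",
    hr_mean=79.4, hr_sd=10.2, hr_range=(60.7, 100.5),
    rmssd_target=61.8, rmssd_sd=34.4, rmssd_range=(13.0, 162.3),
    resprate_mean=18.8, resprate_sd=3.5, resprate_range=(10.7, 28.5),
    coupling_strength=0.5,
    demographics=_HEALTHY_DEMO,
)
SPORT = GroupPreset(
    group_label="Sport",
    hr_mean=76.9, hr_sd=15.0, hr_range=(46.7, 121.4),
    rmssd_target=68.2, rmssd_sd=46.7, rmssd_range=(5.6, 178.9),
    resprate_mean=17.1, resprate_sd=3.5, resprate_range=(10.2, 25.8),
    coupling_strength=0.7,
    demographics=_SPORT_DEMO,
)

DEFAULT_PRESETS = {"Cardiac": CARDIAC, "Healthy": HEALTHY, "Sport": SPORT}
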