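"""Simulation configuration for the synthetic cohort generator.

The defaults describe a community cohort of middle-aged and older adults:
roughly 30,000 participants aged 45-85 (mean 59.4, SD 9.9 years), about
50.3% female, with an expected all-cause death prevalence of 3.1% over the
follow-up window. Biomarker deficits become more prevalent with age and
share a single latent vulnerability factor that also raises mortality risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

from .errors import ConfigError

#: Default mortality intercept on the log-odds scale. Solving the marginal
#: logistic expectation by quadrature over the default covariate distribution
#: (age, sex, latent vulnerability) for a 3.1% death prevalence gives -4.355;
#: ``calibrate_mortality_intercept`` re-derives it for non-default settings.
DEFAULT_MORTALITY_INTERCEPT = -4.355


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_participants
        Cohort size.
    age_mean, age_sd, age_range
        Truncated-normal age distribution in years.
    prop_female
        Marginal probability of female sex.
    latent_loading_per_item
        Log-odds shift in each item's deficit propensity per SD of the
        shared latent vulnerability factor.
    age_slope_per_item
        Log-odds shift in each item's deficit propensity per decade of age
        (centred at ``age_mean``).
    item_noise_sd
        SD of the item-specific propensity noise for graded (normalized and
        ordinal) deficits; binary deficits get their noise from the
        Bernoulli draw itself.
    mortality_intercept, mortality_age_per_decade, mortality_male,
    mortality_latent
        Logistic death model: logit p = intercept + b_age * (age-mean)/10
        + b_male * 1[male] + b_latent * latent.
    blood_block_missing_rate
        Probability that a participant's entire blood panel is missing
        (no blood sample taken).
    item_missing_rate
        Independent per-cell missingness rate on top of the block rate.
    target_death_prevalence
        Target for intercept calibration.
    random_weights
        If True, draw analytic weights uniform on [0.5, 2] (normalized to
        mean 1) instead of unit weights, to exercise weighted code paths.
    seed
        Root seed; every random stream is an independent named substream.
    """

    n_participants: int = 30_000
    age_mean: float = 59.4
    age_sd: float = 9.9
    age_range: Tuple[float, float] = (45.0, 85.0)
    prop_female: float = 0.503
    latent_loading_per_item: float = 0.5
    age_slope_per_item: float = 0.4
    item_noise_sd: float = 1.0
    mortality_intercept: float = DEFAULT_MORTALITY_INTERCEPT
    mortality_age_per_decade: float = 0.9
    mortality_male: float = 0.45
    mortality_latent: float = 0.8
    blood_block_missing_rate: float = 0.10
    item_missing_rate: float = 0.02
    target_death_prevalence: float = 0.031
    random_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants", "must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range", "lower bound must be below upper")
        if self.age_sd <= 0:
            raise ConfigError("age_sd", "must be positive")
        if not lo <= self.age_mean <= hi:
            raise ConfigError("age_mean", "must lie inside age_range")
        for name in (
            "prop_female",
            "blood_block_missing_rate",
            "item_missing_rate",
            "target_death_prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, "must lie in [0, 1]")
        if not 0.0 <= self.latent_loading_per_item:
            raise ConfigError("latent_loading_per_item", "must be >= 0")
        if self.item_noise_sd < 0:
            raise ConfigError("item_noise_sd", "must be >= 0")

    @property
    def mortality_coefficients(self) -> Tuple[float, float, float, float]:
        """(intercept, per-decade age, male, latent) on the log-odds scale."""
        return (
            self.mortality_intercept,
            self.mortality_age_per_decade,
            self.mortality_male,
            self.mortality_latent,
        )

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)
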