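"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a community cohort of adults aged 45-85: ages are
truncated-normal, sex is Bernoulli, and every participant carries one
standard-normal latent vulnerability factor. Each biomarker's deficit
propensity rises with age and with the latent factor; death follows a
logistic model in age, sex and the latent factor. Because deficits and
mortality share the latent factor, an index aggregating many deficits
predicts death better than any single item — the premise the downstream
model comparison is designed to measure.

Raw biomarker values are produced by inverting each item's coding rule, so
that re-coding a generated table reproduces the simulated deficit process
exactly: binary items draw a value inside the normal range when no deficit
and above it when in deficit; normalized and ordinal items place the graded
severity on the rule's raw scale.

Per-item deficit intercepts are calibrated by deterministic quadrature so
that average deficit prevalence hits per-item targets whose panel means are
0.15 (blood) and 0.27 (examination) — the marginal frailty-index means the
cohort is meant to reproduce.
"""

from __future__ import annotations

import zlib
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .config import SimulationConfig
from .dictionary import CodingRule, DataDictionary, default_data_dictionary
from .errors import CalibrationError, SchemaError

__all__ = [
    "generate_cohort",
    "generate_default_cohort",
    "inject_missingness",
    "calibrate_mortality_intercept",
    "expected_death_prevalence",
    "item_target_means",
    "DEMOGRAPHIC_COLUMNS",
]

DEMOGRAPHIC_COLUMNS = ["age", "sex", "weight", "died"]

#: Per-panel target ranges for average deficit prevalence: items are spread
#: evenly across the range, so the panel mean equals the midpoint.
_PANEL_TARGET_RANGE = {"blood": (0.08, 0.22), "examination": (0.17, 0.37)}

_QUAD_POINTS = 101  # midpoint-quantile nodes per dimension


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent named random substream under one root seed."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


_TRUNCNORM_CACHE: Dict[tuple, tuple] = {}


def _age_truncnorm_args(config: SimulationConfig) -> tuple:
    """scipy truncnorm (a, b, loc, scale) whose REALIZED moments match.

    ``age_mean``/``age_sd`` state the mean and SD of the truncated
    distribution itself, so the underlying location and scale are solved
    numerically (truncation otherwise shifts both moments).
    """
    lo, hi = config.age_range
    key = (lo, hi, config.age_mean, config.age_sd)
    if key in _TRUNCNORM_CACHE:
        return _TRUNCNORM_CACHE[key]

    def gap(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - config.age_mean, np.sqrt(v) - config.age_sd]

    sol = optimize.root(gap, [config.age_mean, config.age_sd])
    loc, scale = sol.x[0], abs(sol.x[1])
    if not sol.success or np.max(np.abs(gap((loc, scale)))) > 1e-6:
        raise CalibrationError(
            f"no truncated normal on {config.age_range} has mean "
            f"{config.age_mean} and SD {config.age_sd}"
        )
    args = ((lo - loc) / scale, (hi - loc) / scale, loc, scale)
    _TRUNCNORM_CACHE[key] = args
    return args


def _draw_ages(config: SimulationConfig, n: int,
               rng: np.random.Generator) -> np.ndarray:
    a, b, loc, scale = _age_truncnorm_args(config)
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n,
                               random_state=rng)


def _age_decade_nodes(config: SimulationConfig, k: int = _QUAD_POINTS) -> np.ndarray:
    """Quantile nodes of (age - age_mean)/10 under the truncated normal."""
    a, b, loc, scale = _age_truncnorm_args(config)
    q = (np.arange(k) + 0.5) / k
    ages = stats.truncnorm.ppf(q, a, b, loc=loc, scale=scale)
    return (ages - config.age_mean) / 10.0


def _gauss_nodes(k: int = _QUAD_POINTS) -> np.ndarray:
    q = (np.arange(k) + 0.5) / k
    return stats.norm.ppf(q)


def _ordinal_raw_scale(rule: CodingRule) -> tuple[float, float]:
    """Raw generation window for an ordinal rule, spanning all its levels."""
    cuts = rule.cut_points  # type: ignore[assignment]
    span = (cuts[-1] - cuts[0]) if cuts[-1] > cuts[0] else 1.0
    return cuts[0] - span, cuts[-1] + span


def _coded_mean_on_grid(rule: CodingRule, eta: np.ndarray) -> float:
    """Expected coded deficit given a grid of propensity values ``eta``."""
    if rule.kind == "binary_range":
        return float(expit(eta).mean())
    severity = expit(eta)
    if rule.kind == "normalized":
        return float(severity.mean())
    # ordinal: place severity on the raw scale and discretize
    r_lo, r_hi = _ordinal_raw_scale(rule)
    raw = r_lo + severity * (r_hi - r_lo)
    idx = np.searchsorted(rule.cut_points, raw, side="right")
    levels = np.asarray(rule.levels, dtype=float)
    return float(levels[idx].mean())


def _solve_item_intercept(rule: CodingRule, target: float,
                          config: SimulationConfig) -> float:
    """Intercept such that the item's expected coded deficit equals target.

    The expectation is taken over the age and Gaussian-propensity grids by
    midpoint quadrature; the map intercept -> expectation is continuous and
    increasing, so a bracketed root always exists for targets in (0, 1).
    """
    if not 0.0 < target < 1.0:
        raise CalibrationError(
            f"{rule.item_name}: target prevalence {target} not in (0, 1)"
        )
    ages = _age_decade_nodes(config)
    gauss_sd = config.latent_loading_per_item
    if rule.kind != "binary_range":
        gauss_sd = float(np.hypot(gauss_sd, config.item_noise_sd))
    shift = (config.age_slope_per_item * ages[:, None]
             + gauss_sd * _gauss_nodes()[None, :])

    def f(alpha: float) -> float:
        return _coded_mean_on_grid(rule, alpha + shift) - target

    return optimize.brentq(f, -30.0, 30.0, xtol=1e-10)


def item_target_means(dictionary: DataDictionary) -> Dict[str, float]:
    """Per-item target coded-deficit means, spread evenly within each panel.

    Blood items span 0.08-0.22 (panel mean 0.15); examination items span
    0.17-0.37 (panel mean 0.27).
    """
    targets: Dict[str, float] = {}
    for panel, (lo, hi) in _PANEL_TARGET_RANGE.items():
        names = dictionary.panel(panel).item_names
        if not names:
            continue
        if len(names) == 1:
            targets[names[0]] = (lo + hi) / 2.0
        else:
            for name, t in zip(names, np.linspace(lo, hi, len(names))):
                targets[name] = float(t)
    return targets


def _draw_raw_item(rule: CodingRule, eta: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw raw biomarker values whose coding realizes the deficit process."""
    n = eta.shape[0]
    if rule.kind == "binary_range":
        deficit = rng.random(n) < expit(eta)
        lo, hi = rule.normal_range  # type: ignore[misc]
        width = hi - lo
        normal_vals = lo + rng.random(n) * width
        # abnormal values sit above the range (monotone raw-risk relation)
        abnormal_vals = hi + width * 1e-6 + rng.random(n) * 0.6 * width
        return np.where(deficit, abnormal_vals, normal_vals)
    severity = expit(eta)  # item noise is already folded into eta
    if rule.kind == "normalized":
        lo, hi = rule.reference_min, rule.reference_max  # type: ignore[assignment]
        if rule.direction == "higher_is_deficit":
            return lo + severity * (hi - lo)
        return hi - severity * (hi - lo)
    r_lo, r_hi = _ordinal_raw_scale(rule)
    return r_lo + severity * (r_hi - r_lo)


def generate_cohort(config: SimulationConfig,
                    dictionary: Optional[DataDictionary] = None) -> pd.DataFrame:
    """Generate a complete (no-missingness) synthetic cohort table.

    Returns a DataFrame indexed by participant id with columns ``age``
    (years), ``sex`` ("female"/"male"), ``weight`` (analytic weight, mean 1),
    ``died`` (0/1), and one raw-valued column per dictionary item. Identical
    (config, dictionary) pairs produce identical tables; each column has its
    own named random substream, so adding an item leaves the others unchanged.
    """
    if dictionary is None:
        dictionary = default_data_dictionary()
    n = config.n_participants
    seed = config.seed

    age = _draw_ages(config, n, _substream(seed, "age"))
    female = _substream(seed, "sex").random(n) < config.prop_female
    latent = _substream(seed, "latent").standard_normal(n)
    if config.random_weights:
        w = _substream(seed, "weights").uniform(0.5, 2.0, size=n)
        weight = w / w.mean()
    else:
        weight = np.ones(n)

    age_dec = (age - config.age_mean) / 10.0
    targets = item_target_means(dictionary)
    columns: Dict[str, np.ndarray] = {}
    for rule in dictionary:
        alpha = _solve_item_intercept(rule, targets[rule.item_name], config)
        eta = alpha + config.age_slope_per_item * age_dec \
            + config.latent_loading_per_item * latent
        rng = _substream(seed, f"item:{rule.item_name}")
        if rule.kind != "binary_range" and config.item_noise_sd > 0:
            eta = eta + config.item_noise_sd * rng.standard_normal(n)
        columns[rule.item_name] = _draw_raw_item(rule, eta, rng)

    eta_death = (config.mortality_intercept
                 + config.mortality_age_per_decade * age_dec
                 + config.mortality_male * (~female)
                 + config.mortality_latent * latent)
    died = (_substream(seed, "mortality").random(n) < expit(eta_death)).astype(int)

    ids = [f"P{i:06d}" for i in range(1, n + 1)]
    table = pd.DataFrame(
        {"age": age,
         "sex": np.where(female, "female", "male"),
         "weight": weight,
         "died": died,
         **columns},
        index=pd.Index(ids, name="participant_id"),
    )
    return table


def inject_missingness(table: pd.DataFrame, config: SimulationConfig,
                       dictionary: Optional[DataDictionary] = None) -> pd.DataFrame:
    """Apply MCAR missingness to the biomarker columns of a cohort table.

    With probability ``blood_block_missing_rate`` a participant's entire
    blood panel is blanked (no blood sample); independently, every remaining
    biomarker cell is blanked with ``item_missing_rate``. Demographics,
    weight and the death indicator are never touched. Seeded from the
    config's root seed (substream "missingness").
    """
    if dictionary is None:
        dictionary = default_data_dictionary()
    missing_cols = [c for c in dictionary.item_names if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"cohort table lacks dictionary items: {missing_cols}")
    out = table.copy()
    rng = _substream(config.seed, "missingness")
    n = len(out)
    blood_cols = dictionary.panel("blood").item_names
    if blood_cols and config.blood_block_missing_rate > 0:
        block = rng.random(n) < config.blood_block_missing_rate
        out.loc[block, blood_cols] = np.nan
    if config.item_missing_rate > 0:
        for col in dictionary.item_names:
            drop = rng.random(n) < config.item_missing_rate
            out.loc[drop, col] = np.nan
    return out


def generate_default_cohort(seed: int = 0, n: Optional[int] = None,
                            with_missingness: bool = True,
                            config: Optional[SimulationConfig] = None,
                            dictionary: Optional[DataDictionary] = None
                            ) -> pd.DataFrame:
    """Convenience: default-configuration cohort, optionally with missingness."""
    if dictionary is None:
        dictionary = default_data_dictionary()
    if config is None:
        config = SimulationConfig(seed=seed)
    else:
        config = config.with_(seed=seed)
    if n is not None:
        config = config.with_(n_participants=n)
    table = generate_cohort(config, dictionary)
    if with_missingness:
        table = inject_missingness(table, config, dictionary)
    return table


def expected_death_prevalence(config: SimulationConfig) -> float:
    """Marginal death probability under the config, by quadrature.

    Integrates the logistic mortality model over the truncated-normal age
    distribution, the sex margin and the standard-normal latent factor.
    """
    ages = _age_decade_nodes(config)
    z = _gauss_nodes()
    eta = (config.mortality_intercept
           + config.mortality_age_per_decade * ages[:, None]
           + config.mortality_latent * z[None, :])
    p_female = expit(eta)
    p_male = expit(eta + config.mortality_male)
    return float(config.prop_female * p_female.mean()
                 + (1 - config.prop_female) * p_male.mean())


def calibrate_mortality_intercept(config: SimulationConfig,
                                  dictionary: Optional[DataDictionary] = None,
                                  n_pilot: int = 50_000) -> SimulationConfig:
    """Adjust the mortality intercept to hit ``target_death_prevalence``.

    Draws a pilot sample of covariates (age, sex, latent factor) from the
    config's seeded substreams and solves, by monotone root-finding, for the
    intercept whose average logistic death probability over the pilot equals
    the target. Averaging the probabilities rather than Bernoulli draws
    makes the pilot criterion smooth and strictly increasing in the
    intercept, so the root is unique.
    """
    if n_pilot < 1000:
        raise ValueError("n_pilot must be at least 1000")
    target = config.target_death_prevalence
    if not 0.0 < target < 1.0:
        raise CalibrationError(
            f"target death prevalence {target} unattainable on the log-odds scale"
        )
    rng = _substream(config.seed, "calibration-pilot")
    age = _draw_ages(config, n_pilot, rng)
    male = rng.random(n_pilot) >= config.prop_female
    latent = rng.standard_normal(n_pilot)
    base = (config.mortality_age_per_decade * (age - config.age_mean) / 10.0
            + config.mortality_male * male
            + config.mortality_latent * latent)

    def f(b0: float) -> float:
        return float(expit(b0 + base).mean()) - target

    lo_b, hi_b = -40.0, 20.0
    if not f(lo_b) < 0 < f(hi_b):
        raise CalibrationError(
            f"intercept search range [{lo_b}, {hi_b}] does not bracket the target"
        )
    b0 = optimize.brentq(f, lo_b, hi_b, xtol=1e-10)
    return config.with_(mortality_intercept=float(b0))
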