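"""Synthetic cohort generation and choice simulation.

Generates older-adult participants with known ground-truth discounting
parameters (hyperbolic k, quasi-hyperbolic beta/delta), gender-structured
memory instrument responses, covariates (age, IQ, yearly income with
missing-at-random entries), and simulates their per-trial intertemporal
choices under a logistic choice rule on the subjective-value difference.

Ground-truth columns are prefixed ``true_``. All randomness flows from one
root seed through named substreams, so adding participants or stages does not
perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.special import expit

from . import memory as mem
from .design import build_choice_design

# substream ids under the root seed
_STREAM_COHORT = 0
_STREAM_CHOICES = 1
_STREAM_DESIGN = 2

#: floor/ceiling for ln(k): k=1e-4/month is indistinguishable from patience on
#: this task; k=10/month collapses subjective value below 0.04 at 3 months.
K_MIN, K_MAX = 1e-4, 10.0


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Defaults emulate the analysed study sample: 58 older adults (30 women,
    ages 60-89 around mean 72.6), IQ-screen scores around 16, gendered income
    (men ~29.4k, women ~15.8k euros/year) with income missing for ~6
    participants, memory scores with women above men (FNPA-PF .33 vs .57,
    IGD-C1 1.62 vs 1.74, IGD-C2 1.66 vs 1.77), and discounting parameters
    centred near k≈0.14/month, beta≈0.65, delta≈0.975.
    """

    n_participants: int = 58
    female_fraction: float = 30 / 58
    n_inattentive: int = 0  # responders with ~zero choice sensitivity
    seed: int = 0

    # covariates
    age_mean: float = 72.6
    age_sd: float = 6.4
    age_range: tuple = (60.0, 89.0)
    iq_mean: float = 16.1
    iq_sd: float = 4.6
    income_mean_male: float = 29409.0
    income_mean_female: float = 15833.0
    income_cv: float = 0.55  # coefficient of variation of lognormal income
    income_missing_rate: float = 6 / 58

    # memory scores: male means; female = male + gap
    fnpa_pf_mean_male: float = 0.33
    igd_c1_mean_male: float = 1.62
    igd_c2_mean_male: float = 1.66
    memory_gender_gap: object = (0.24, 0.12, 0.11)  # scalar or (PF, C1, C2)
    fnpa_pf_sd: float = 0.20
    igd_c1_sd: float = 0.25
    igd_c2_sd: float = 0.20
    memory_latent_corr: float = 0.5  # correlation of the three score latents
    c2_skip_mean: int = 10  # items eligible to be skipped as inapplicable
    c2_skip_rate: float = 0.2

    # discounting truth
    lnk_mean: float = -2.0
    lnk_sd: float = 1.5
    beta_mean: float = 0.65
    beta_sd: float = 0.20
    delta_mean: float = 0.975
    delta_sd: float = 0.015
    choice_temperature: float = 5.0  # logistic sensitivity, 1/euro
    effect_gender_memory_on_lnk: float = 0.0  # gender x centred IGD-C2 slope on ln k

    def gaps(self) -> np.ndarray:
        g = self.memory_gender_gap
        if np.isscalar(g):
            return np.full(3, float(g))
        g = np.asarray(g, dtype=float)
        if g.shape != (3,):
            raise ConfigError("memory_gender_gap must be a scalar or length-3")
        return g

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        for name in ("female_fraction", "income_missing_rate", "c2_skip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.n_inattentive <= self.n_participants:
            raise ConfigError("n_inattentive must be in [0, n_participants]")
        for name in ("age_sd", "iq_sd", "fnpa_pf_sd", "igd_c1_sd", "igd_c2_sd",
                     "lnk_sd", "beta_sd", "delta_sd", "income_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.beta_mean <= 1.0:
            raise ConfigError("beta_mean must be in [0, 1]")
        if not 0.0 <= self.delta_mean <= 1.0:
            raise ConfigError("delta_mean must be in [0, 1]")
        if not np.isfinite(self.choice_temperature) and self.choice_temperature != np.inf:
            raise ConfigError("choice_temperature must be finite or +inf")
        if self.choice_temperature < 0:
            raise ConfigError("choice_temperature must be >= 0")
        if not -1.0 <= self.memory_latent_corr <= 1.0:
            raise ConfigError("memory_latent_corr must be in [-1, 1]")
        self.gaps()

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if not np.isscalar(d["memory_gender_gap"]):
            d["memory_gender_gap"] = list(np.asarray(d["memory_gender_gap"], float))
        if not np.isscalar(d["age_range"]):
            d["age_range"] = list(np.asarray(d["age_range"], float))
        return d


@dataclass
class ParticipantTruth:
    """Generative truth for one participant."""

    k_true: float
    beta_true: float
    delta_true: float
    choice_temperature: float
    gender: str
    memory_latents: tuple = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        if not 0.0 <= self.beta_true <= 1.0:
            raise ValueError("beta_true must be in [0, 1]")
        if not 0.0 <= self.delta_true <= 1.0:
            raise ValueError("delta_true must be in [0, 1]")
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        if self.choice_temperature < 0:
            raise ValueError("choice_temperature must be >= 0")


def _distribute(total: int, n_bins: int, cap: int) -> np.ndarray:
    """Greedy split of `total` into `n_bins` integers each <= cap."""
    out = np.zeros(n_bins, dtype=int)
    remaining = int(total)
    for i in range(n_bins):
        take = min(cap, remaining)
        out[i] = take
        remaining -= take
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the cohort table: covariates, raw memory responses, realized
    scores, and ground-truth discounting parameters."""
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    n = config.n_participants

    n_female = int(round(n * config.female_fraction))
    genders = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(genders)
    is_female = (genders == "female").astype(float)

    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), *config.age_range
    ).round(0)
    iq = np.clip(rng.normal(config.iq_mean, config.iq_sd, n), 0, 32).round(0)

    income_mean = np.where(
        is_female == 1.0, config.income_mean_female, config.income_mean_male
    )
    sigma2 = np.log(1.0 + config.income_cv**2)
    income = rng.lognormal(
        mean=np.log(income_mean) - sigma2 / 2.0, sigma=np.sqrt(sigma2)
    ).round(0)
    missing = rng.random(n) < config.income_missing_rate
    income = np.where(missing, np.nan, income)

    # correlated latents driving the three memory scores
    rho = config.memory_latent_corr
    shared = rng.normal(size=n)
    latents = rho * shared[:, None] + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(
        size=(n, 3)
    )
    gaps = config.gaps()

    # FNPA: target PF -> hit/false-alarm counts
    pf_target = np.clip(
        config.fnpa_pf_mean_male
        + gaps[0] * is_female
        + config.fnpa_pf_sd * latents[:, 0],
        -1.0,
        1.0,
    )
    lo = np.maximum(0.0, pf_target)
    hi = np.minimum(1.0, 1.0 + pf_target)
    hit_rate = np.clip((1.0 + pf_target) / 2.0 + rng.normal(0, 0.05, n), lo, hi)
    hits = np.rint(20 * hit_rate).astype(int)
    fa = np.clip(hits - np.rint(20 * pf_target).astype(int), 0, 20)
    hits = np.clip(hits, 0, 20)

    # IGD-C1: target score -> event counts and rating sums
    c1_target = np.clip(
        config.igd_c1_mean_male
        + gaps[1] * is_female
        + config.igd_c1_sd * latents[:, 1],
        0.0,
        2.0,
    )
    ev_total = np.rint(20 * np.clip(c1_target / 2.0, 0, 1)).astype(int)
    rat_total = np.rint(36 * np.clip(c1_target - ev_total / 20.0, 0, 1)).astype(int)
    c1_events = np.vstack([_distribute(t, 4, 5) for t in ev_total])
    c1_ratings = np.vstack([_distribute(t, 4, 9) for t in rat_total])

    # IGD-C2: target score -> answered / yes / confidence
    c2_target = np.clip(
        config.igd_c2_mean_male
        + gaps[2] * is_female
        + config.igd_c2_sd * latents[:, 2],
        0.0,
        2.0,
    )
    answered = 64 - rng.binomial(config.c2_skip_mean, config.c2_skip_rate, n)
    yes = np.rint(answered * np.clip(c2_target / 2.0, 0, 1)).astype(int)
    conf = np.rint(
        3 * yes * np.clip(c2_target - yes / answered, 0, 1)
    ).astype(int)

    # realized scores (from the raw responses, through the scoring formulas)
    fnpa_scores = np.array([mem.fnpa_pf(h, f) for h, f in zip(hits, fa)])
    c1_scores = np.array(
        [mem.igd_c1(e, r) for e, r in zip(c1_events, c1_ratings)]
    )
    c2_scores = np.array(
        [mem.igd_c2(a, y, c) for a, y, c in zip(answered, yes, conf)]
    )

    # discounting truth; the configured gender x IGD-C2 interaction enters ln k
    ln_k = (
        config.lnk_mean
        + config.effect_gender_memory_on_lnk
        * is_female
        * (c2_scores - c2_scores.mean())
        + config.lnk_sd * rng.normal(size=n)
    )
    ln_k = np.clip(ln_k, np.log(K_MIN), np.log(K_MAX))
    beta = np.clip(rng.normal(config.beta_mean, config.beta_sd, n), 0.0, 1.0)
    delta = np.clip(rng.normal(config.delta_mean, config.delta_sd, n), 0.0, 1.0)

    temperature = np.full(n, float(config.choice_temperature))
    if config.n_inattentive > 0:
        idx = rng.choice(n, size=config.n_inattentive, replace=False)
        temperature[idx] = 1e-6

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "gender": genders,
            "age": age,
            "iq": iq,
            "income": income,
            "fnpa_hits": hits,
            "fnpa_fa": fa,
            **{f"c1_events_e{j + 1}": c1_events[:, j] for j in range(4)},
            **{f"c1_ratings_e{j + 1}": c1_ratings[:, j] for j in range(4)},
            "c2_answered": answered,
            "c2_yes": yes,
            "c2_conf": conf,
            "fnpa_pf": fnpa_scores,
            "igd_c1": c1_scores,
            "igd_c2": c2_scores,
            "true_k": np.exp(ln_k),
            "true_ln_k": ln_k,
            "true_beta": beta,
            "true_delta": delta,
            "true_temperature": temperature,
            **{f"true_mem_latent_{j + 1}": latents[:, j] for j in range(3)},
        }
    )
    return table


def subjective_value(amount, delay, beta, delta):
    """Subjective value A * beta * delta^T for T>0, A at T=0 ("tomorrow")."""
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    discount = np.where(delay > 0, beta * np.power(delta, delay), 1.0)
    return amount * discount


def simulate_choices(truth, design: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Fill the ``choice`` column of a design by a logistic choice rule.

    P(later) = logistic(temperature * (SV_later - SV_sooner)), with subjective
    values computed for both options (the sooner option is itself delayed in
    blocks 5-6). temperature=inf gives deterministic choices with equal-SV
    ties resolved 50/50; temperature=0 gives pure Bernoulli(1/2) noise.
    """
    if design["sooner_amount"].isna().any() or design["later_delay"].isna().any():
        raise ValueError("malformed design: unset amounts or delays")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    beta = truth.beta_true if hasattr(truth, "beta_true") else truth["true_beta"]
    delta = truth.delta_true if hasattr(truth, "delta_true") else truth["true_delta"]
    temp = (
        truth.choice_temperature
        if hasattr(truth, "choice_temperature")
        else truth["true_temperature"]
    )
    sv_sooner = subjective_value(
        design["sooner_amount"].to_numpy(), design["sooner_delay"].to_numpy(), beta, delta
    )
    sv_later = subjective_value(
        design["later_amount"].to_numpy(), design["later_delay"].to_numpy(), beta, delta
    )
    diff = sv_later - sv_sooner
    if np.isinf(temp):
        p_later = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    else:
        p_later = expit(temp * diff)
    out = design.copy()
    out["choice"] = np.where(rng.random(len(design)) < p_later, "later", "sooner")
    return out


def simulate_trials(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Build a design and simulate choices for every participant in a cohort.

    Each participant gets independent, named substreams for design
    randomization and choice noise derived from the root seed.
    """
    all_trials = []
    for i, row in enumerate(cohort.itertuples(index=False)):
        design = build_choice_design(
            row.participant_id, np.random.default_rng([seed, _STREAM_DESIGN, i])
        )
        truth = ParticipantTruth(
            k_true=row.true_k,
            beta_true=row.true_beta,
            delta_true=row.true_delta,
            choice_temperature=row.true_temperature,
            gender=row.gender,
        )
        trials = simulate_choices(
            truth, design, np.random.default_rng([seed, _STREAM_CHOICES, i])
        )
        all_trials.append(trials)
    return pd.concat(all_trials, ignore_index=True)
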