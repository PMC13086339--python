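"""Synthetic feeding-trial datasets with known ground truth.

Emulates the study design: 6 sea cages of 8 adult seabass each (total length
~ Normal(57.3, 3.2) cm), three chronic diet levels (60/75/90% of the
recommended ration, two cages each), 8 feeding trials per cage across a
4-month late-summer-to-autumn window with water temperature cooling from
27.6 to 21.8 degC, a boat-traffic stress proxy strongly correlated with
temperature (target Pearson r = 0.83), and a per-trial delivered ration drawn
uniformly from 10-80% of the planned ration. Pellet outcomes are drawn i.i.d.
within a trial from the 9-way categorical distribution of the score model,
with fish and replicate random effects drawn from their dispersions.

Ground-truth coefficients default to the posterior medians of the fitted
stress-variant model (see ``REFERENCE_MEDIANS``), so that simulated data mimic
the statistical structure the analysis expects.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from feedshare import likelihood
from feedshare.data_model import (
    FISH_PER_CAGE,
    Dataset,
    FishRecord,
    PelletEvent,
    TrialRecord,
    ValidationError,
    standardize,
    validate_dataset,
)
from feedshare.likelihood import ModelParams

#: Ground truth is parameterized exactly like a fitted model.
TrueParams = ModelParams

#: Posterior medians of the stress-variant fit (reference values used as the
#: default simulation truth).
REFERENCE_MEDIANS = {
    "beta0": 0.266,
    "sigma_fish": 0.431,
    "sigma_replicate": 0.183,
    "beta_L2": 0.101,
    "beta_S": -0.104,
    "beta_R": -0.050,
    "diet_offset_75": -0.072,
    "diet_offset_90": -0.136,
}


def default_true_params() -> TrueParams:
    """Stress-variant truth at the reference posterior medians (no effects drawn)."""
    m = REFERENCE_MEDIANS
    return ModelParams(
        beta0=m["beta0"],
        diet_offsets={60: 0.0, 75: m["diet_offset_75"], 90: m["diet_offset_90"]},
        beta_L2=m["beta_L2"],
        beta_S=m["beta_S"],
        beta_R=m["beta_R"],
        sigma_fish=m["sigma_fish"],
        sigma_replicate=m["sigma_replicate"],
    )


@dataclass
class DesignConfig:
    """Experimental-design knobs of the generator (defaults = study design)."""

    n_cages: int = 6
    fish_per_cage: int = 8
    replicates_per_cage: int = 8
    length_mean_cm: float = 57.3
    length_sd_cm: float = 3.2
    temp_range_C: tuple[float, float] = (21.8, 27.6)
    boat_temp_correlation_target: float = 0.83
    mean_boat_count: float = 15.0
    diet_levels: tuple[int, ...] = (60, 75, 90)
    ration_fraction_range: tuple[float, float] = (0.10, 0.80)
    planned_pellets_base: int = 40
    start_date: str = "2024-08-01"
    season_days: int = 92  # early August -> early November
    temp_noise_sd_C: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fish_per_cage != FISH_PER_CAGE:
            raise ValidationError("the outcome model is fixed at 8 fish per cage")
        if self.n_cages % len(self.diet_levels) != 0:
            raise ValidationError("n_cages must divide evenly across diet levels")
        lo, hi = self.temp_range_C
        if not lo < hi:
            raise ValidationError("temp_range_C must be a non-degenerate (low, high) pair")
        lo, hi = self.ration_fraction_range
        if not 0 <= lo <= hi:
            raise ValidationError("ration_fraction_range must satisfy 0 <= low <= high")
        if self.length_sd_cm < 0 or self.length_mean_cm <= 0:
            raise ValidationError("length distribution parameters invalid")
        if self.planned_pellets_base <= 0:
            raise ValidationError("planned_pellets_base must be positive")
        if not 0 <= self.boat_temp_correlation_target < 1:
            raise ValidationError("boat_temp_correlation_target must be in [0, 1)")


def generate_fish(config: DesignConfig, rng: np.random.Generator) -> list[FishRecord]:
    """Draw cage rosters with lengths ~ Normal(mean, sd), truncated at 0."""
    records = []
    n = 0
    for c in range(config.n_cages):
        cage_id = f"C{c + 1}"
        for i in range(1, config.fish_per_cage + 1):
            n += 1
            length = -1.0
            while length <= 0:
                length = config.length_mean_cm + config.length_sd_cm * rng.standard_normal()
                if config.length_sd_cm == 0:
                    length = config.length_mean_cm
                    break
            records.append(
                FishRecord.from_length(f"F{n:02d}", cage_id, i, float(length))
            )
    return records


def _boat_slope_for_target(target_r: float, mean_count: float) -> float:
    """Log-linear Poisson slope b giving corr(z, Y) ~= target for z ~ N(0,1).

    With rate exp(a + b z) and a = log(mean) - b^2/2 (so E[Y] = mean):
    corr = b * mean / sqrt(mean + mean^2 (exp(b^2) - 1)). The correlation is
    unimodal in b; solve on the rising branch.
    """
    if target_r == 0:
        return 0.0

    def corr(b: float) -> float:
        return b * mean_count / np.sqrt(mean_count + mean_count**2 * np.expm1(b**2))

    grid = np.linspace(1e-6, 3.0, 400)
    vals = np.array([corr(b) for b in grid])
    peak = int(np.argmax(vals))
    if target_r > vals[peak]:
        raise ValidationError(
            f"correlation target {target_r} unachievable for mean boat count "
            f"{mean_count} (max {vals[peak]:.3f}); raise mean_boat_count"
        )
    return brentq(lambda b: corr(b) - target_r, grid[0], grid[peak])


def generate_environment(
    config: DesignConfig, rng: np.random.Generator
) -> list[TrialRecord]:
    """One trial per (cage, replicate): seasonal temperature, correlated boat
    counts, and a delivered ration uniform on the configured fraction range.

    Temperature follows a half-cosine cooling trajectory from the range
    maximum (trial day 0) to the minimum (last trial day), with small
    observation noise; replicate days are common across cages with a per-cage
    jitter of a couple of days. Boat counts are Poisson with log-rate affine
    in standardized temperature, the slope solved so the model correlation
    matches ``boat_temp_correlation_target``.
    """
    t_lo, t_hi = config.temp_range_C
    n_rep = config.replicates_per_cage
    start = datetime.date.fromisoformat(config.start_date)

    days = np.empty((config.n_cages, n_rep))
    for c in range(config.n_cages):
        base = np.linspace(0, config.season_days, n_rep)
        jitter = rng.integers(-2, 3, size=n_rep) if n_rep > 1 else np.zeros(1)
        days[c] = np.clip(base + jitter, 0, config.season_days)

    frac = 1 - days / config.season_days  # 1 at start (warm), 0 at end (cool)
    temp = t_lo + (t_hi - t_lo) * (1 - np.cos(np.pi * frac)) / 2
    temp = temp + config.temp_noise_sd_C * rng.standard_normal(temp.shape)
    temp = np.clip(temp, t_lo, t_hi)

    # standardize temperature over all trials for the boat-count rate
    z = (temp - temp.mean()) / max(temp.std(), 1e-12)
    b = _boat_slope_for_target(config.boat_temp_correlation_target, config.mean_boat_count)
    a = np.log(config.mean_boat_count) - 0.5 * b**2
    boats = rng.poisson(np.exp(a + b * z))

    lo_f, hi_f = config.ration_fraction_range
    cages_per_diet = config.n_cages // len(config.diet_levels)
    trials = []
    for c in range(config.n_cages):
        cage_id = f"C{c + 1}"
        diet = config.diet_levels[c // cages_per_diet]
        for j in range(1, n_rep + 1):
            fraction = rng.uniform(lo_f, hi_f)
            planned = config.planned_pellets_base
            trials.append(
                TrialRecord(
                    cage_id=cage_id,
                    replicate_index=j,
                    date=(start + datetime.timedelta(days=int(days[c, j - 1]))).isoformat(),
                    temperature_C=round(float(temp[c, j - 1]), 2),
                    boat_count=int(boats[c, j - 1]),
                    diet_level=diet,
                    planned_pellets=planned,
                    delivered_pellets=int(round(planned * fraction)),
                )
            )
    return trials


def simulate_events(
    fish: list[FishRecord],
    trials: list[TrialRecord],
    true_params: TrueParams,
    rng: np.random.Generator,
    variant: likelihood.Variant = "stress",
) -> list[PelletEvent]:
    """Draw each trial's pellet outcomes i.i.d. from the score model.

    Covariates are standardized with the generated dataset's own constants,
    exactly as the analysis will see them.
    """
    ds = standardize(Dataset(fish=list(fish), trials=list(trials), events=[]))
    design = likelihood.build_design(ds)
    probs = likelihood.softmax_probs(design, true_params, variant)
    events = []
    for t, trial in enumerate(
        sorted(trials, key=lambda tr: design.trial_keys.index((tr.cage_id, tr.replicate_index)))
    ):
        outcomes = rng.choice(likelihood.N_CATEGORIES, size=trial.delivered_pellets, p=probs[t])
        for k, o in enumerate(outcomes, start=1):
            events.append(
                PelletEvent(
                    cage_id=trial.cage_id,
                    replicate_index=trial.replicate_index,
                    pellet_index=k,
                    outcome=int(o) + 1,
                )
            )
    return events


def generate_dataset(
    config: DesignConfig | None = None,
    true_params: TrueParams | None = None,
    variant: likelihood.Variant = "stress",
) -> tuple[Dataset, TrueParams]:
    """Generate a complete validated dataset plus the ground truth used.

    If ``true_params`` omits fish/replicate effects, they are drawn
    Normal(0, sigma) from the configured dispersions. Reproducible under
    ``config.rng_seed``.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(config.rng_seed)
    truth = dataclasses.replace(true_params) if true_params else default_true_params()

    fish = generate_fish(config, rng)
    trials = generate_environment(config, rng)
    if not truth.fish_effects:
        truth.fish_effects = {
            (f.cage_id, f.fish_index): float(truth.sigma_fish * rng.standard_normal())
            for f in fish
        }
    if not truth.replicate_effects:
        truth.replicate_effects = {
            (t.cage_id, t.replicate_index): float(
                truth.sigma_replicate * rng.standard_normal()
            )
            for t in trials
        }
    events = simulate_events(fish, trials, truth, rng, variant)
    ds = standardize(Dataset(fish=fish, trials=trials, events=events))
    validate_dataset(ds, max_delivery_ratio=2.0)
    return ds, truth
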