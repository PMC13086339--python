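"""The per-pellet ingestion model: scores, softmax probabilities, log-likelihood.

For fish i = 1..8 in cage c during replicate trial j, the linear score is

    sco[i,j,c] = beta0_D + betaL2 * L2[i] (+ betaT * T + betaT2 * T^2)
                 (+ betaS * S) + betaR * R + Fish[i,c] + Replicate[j,c]

with all continuous covariates standardized. Temperature and the boat-count
stress proxy are collinear in the study design, so a fitted model carries one
of the two: the "stress" variant uses S, the "temperature" variant uses T and
T^2. The ninth score — the pellet sinking unconsumed — is pinned to the
negative sum of the eight fish scores, which fixes the softmax gauge: raising
every fish's score genuinely lowers the waste probability instead of being a
no-op reparameterization. Outcome probabilities are the softmax of the nine
scores (positive exponent: a larger score means a greater willingness to
consume), and the observed consumer identities of a trial's pellets are a
draw from the resulting categorical/multinomial distribution.

This module is the single source of truth for the likelihood; the synthetic
generator simulates from it and the sampler differentiates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy.special import log_softmax, softmax

from feedshare.data_model import FISH_PER_CAGE, Dataset, ValidationError

Variant = Literal["stress", "temperature"]

N_CATEGORIES = FISH_PER_CAGE + 1


@dataclass
class ModelParams:
    """All coefficients and random effects of the score model.

    ``diet_offsets`` maps diet level (percent) to its intercept offset; the
    reference diet (60%) is pinned at offset 0 so ``beta0`` is the general
    intercept. ``fish_effects`` is keyed by ``(cage_id, fish_index)`` and
    ``replicate_effects`` by ``(cage_id, replicate_index)``.
    """

    beta0: float = 0.0
    diet_offsets: dict[int, float] = field(default_factory=lambda: {60: 0.0, 75: 0.0, 90: 0.0})
    beta_L2: float = 0.0
    beta_T: float = 0.0
    beta_T2: float = 0.0
    beta_S: float = 0.0
    beta_R: float = 0.0
    sigma_fish: float = 1.0
    sigma_replicate: float = 1.0
    fish_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    replicate_effects: dict[tuple[str, int], float] = field(default_factory=dict)

    def fish_effect(self, cage_id: str, fish_index: int) -> float:
        return self.fish_effects.get((cage_id, fish_index), 0.0)

    def replicate_effect(self, cage_id: str, replicate_index: int) -> float:
        return self.replicate_effects.get((cage_id, replicate_index), 0.0)


def fish_score(
    covariates: Mapping[str, float],
    params: ModelParams,
    fish_effect: float = 0.0,
    replicate_effect: float = 0.0,
    variant: Variant = "stress",
) -> float:
    """Linear score of one fish for one trial.

    ``covariates`` must carry the standardized values ``L2_std``, ``R_std``,
    plus ``S_std`` (stress variant) or ``T_std`` (temperature variant), and
    the trial's ``diet_level``. The temperature term is parabolic: the square
    of the standardized temperature enters with its own slope.
    """
    diet = covariates["diet_level"]
    try:
        offset = params.diet_offsets[diet]
    except KeyError:
        raise ValidationError(f"unknown diet level {diet!r}")
    score = params.beta0 + offset + params.beta_L2 * covariates["L2_std"]
    if variant == "temperature":
        t = covariates["T_std"]
        score += params.beta_T * t + params.beta_T2 * t * t
    elif variant == "stress":
        score += params.beta_S * covariates["S_std"]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    score += params.beta_R * covariates["R_std"]
    return score + fish_effect + replicate_effect


def complete_scores(fish_scores: Iterable[float]) -> np.ndarray:
    """Append the not-consumed score: the negative sum of the 8 fish scores.

    Returns the full 9-vector, which sums to zero by construction.
    """
    s = np.asarray(list(fish_scores), dtype=float)
    if s.shape != (FISH_PER_CAGE,):
        raise ValidationError(f"expected 8 fish scores, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValidationError("fish scores must be finite")
    return np.concatenate([s, [-s.sum()]])


def consumption_probs(score_vector: np.ndarray) -> np.ndarray:
    """Softmax of the 9 scores (positive exponent, max-subtracted).

    ``probs[k] = exp(scores[k]) / sum_m exp(scores[m])``.
    """
    s = np.asarray(score_vector, dtype=float)
    if s.shape != (N_CATEGORIES,):
        raise ValidationError(f"expected a 9-entry score vector, got shape {s.shape}")
    return softmax(s)


# ---------------------------------------------------------------------------
# vectorized design + likelihood


@dataclass
class Design:
    """Array view of a standardized dataset, in a fixed trial order.

    Trials are ordered by (cage order of first appearance, replicate index);
    pellets by (trial order, pellet index). ``counts[t, k]`` is the number of
    the trial's pellets with outcome k+1.
    """

    cage_ids: list[str]
    fish_ids: np.ndarray  # (n_cages, 8) of str
    trial_keys: list[tuple[str, int]]
    cage_of_trial: np.ndarray  # (n_trials,) int
    diet_of_trial: np.ndarray  # (n_trials,) diet level in percent
    L2_std: np.ndarray  # (n_cages, 8)
    T_std: np.ndarray  # (n_trials,)
    S_std: np.ndarray  # (n_trials,)
    R_std: np.ndarray  # (n_trials,)
    delivered: np.ndarray  # (n_trials,) int
    counts: np.ndarray  # (n_trials, 9) int
    pellet_trial: np.ndarray  # (n_pellets,) int
    pellet_outcome: np.ndarray  # (n_pellets,) int in 0..8 (0-based category)

    @property
    def n_trials(self) -> int:
        return len(self.trial_keys)

    @property
    def n_cages(self) -> int:
        return len(self.cage_ids)

    @property
    def n_pellets(self) -> int:
        return int(self.pellet_trial.shape[0])


def build_design(ds: Dataset) -> Design:
    """Assemble the array design from a standardized dataset."""
    if ds.standardization is None:
        raise ValidationError("dataset must be standardized first (data_model.standardize)")
    std = ds.standardization
    cage_ids = ds.cage_ids()
    cage_pos = {c: i for i, c in enumerate(cage_ids)}

    L2_std = np.zeros((len(cage_ids), FISH_PER_CAGE))
    fish_ids = np.empty((len(cage_ids), FISH_PER_CAGE), dtype=object)
    for f in ds.fish:
        z = std.transform("L2", f.structural_surface_cm2)
        L2_std[cage_pos[f.cage_id], f.fish_index - 1] = z
        fish_ids[cage_pos[f.cage_id], f.fish_index - 1] = f.fish_id

    trials = sorted(ds.trials, key=lambda t: (cage_pos[t.cage_id], t.replicate_index))
    trial_keys = [(t.cage_id, t.replicate_index) for t in trials]
    trial_pos = {k: i for i, k in enumerate(trial_keys)}
    cage_of_trial = np.array([cage_pos[t.cage_id] for t in trials], dtype=int)
    diet_of_trial = np.array([t.diet_level for t in trials], dtype=int)
    T_std = std.transform("T", [t.temperature_C for t in trials])
    S_std = std.transform("S", [t.boat_count for t in trials])
    R_std = std.transform("R", [t.delivered_pellets for t in trials])
    delivered = np.array([t.delivered_pellets for t in trials], dtype=int)

    counts = np.zeros((len(trials), N_CATEGORIES), dtype=int)
    order = sorted(
        range(len(ds.events)),
        key=lambda i: (
            trial_pos.get((ds.events[i].cage_id, ds.events[i].replicate_index), -1),
            ds.events[i].pellet_index,
        ),
    )
    pellet_trial = np.empty(len(ds.events), dtype=int)
    pellet_outcome = np.empty(len(ds.events), dtype=int)
    for j, i in enumerate(order):
        e = ds.events[i]
        key = (e.cage_id, e.replicate_index)
        if key not in trial_pos:
            raise ValidationError(f"event references unknown trial {key}")
        t = trial_pos[key]
        pellet_trial[j] = t
        pellet_outcome[j] = e.outcome - 1
        counts[t, e.outcome - 1] += 1
    return Design(
        cage_ids=cage_ids,
        fish_ids=fish_ids,
        trial_keys=trial_keys,
        cage_of_trial=cage_of_trial,
        diet_of_trial=diet_of_trial,
        L2_std=L2_std,
        T_std=T_std,
        S_std=S_std,
        R_std=R_std,
        delivered=delivered,
        counts=counts,
        pellet_trial=pellet_trial,
        pellet_outcome=pellet_outcome,
    )


def score_matrix(design: Design, params: ModelParams, variant: Variant = "stress") -> np.ndarray:
    """Per-trial 9-score matrix (n_trials, 9) under ``params``."""
    base = np.full(design.n_trials, params.beta0, dtype=float)
    base += np.array([params.diet_offsets[d] for d in design.diet_of_trial])
    if variant == "temperature":
        base += params.beta_T * design.T_std + params.beta_T2 * design.T_std**2
    elif variant == "stress":
        base += params.beta_S * design.S_std
    else:
        raise ValueError(f"unknown variant {variant!r}")
    base += params.beta_R * design.R_std

    fish_eff = np.zeros((design.n_cages, FISH_PER_CAGE))
    for (cage_id, idx), v in params.fish_effects.items():
        fish_eff[design.cage_ids.index(cage_id), idx - 1] = v
    rep_eff = np.array(
        [params.replicate_effects.get(k, 0.0) for k in design.trial_keys], dtype=float
    )

    per_fish = params.beta_L2 * design.L2_std + fish_eff  # (n_cages, 8)
    fish_scores = base[:, None] + per_fish[design.cage_of_trial] + rep_eff[:, None]
    return np.concatenate([fish_scores, -fish_scores.sum(axis=1, keepdims=True)], axis=1)


def softmax_probs(design: Design, params: ModelParams, variant: Variant = "stress") -> np.ndarray:
    """Per-trial 9-category outcome probabilities (n_trials, 9)."""
    return softmax(score_matrix(design, params, variant), axis=1)


def pellet_loglik(design: Design, params: ModelParams, variant: Variant = "stress") -> np.ndarray:
    """Log-probability of each pellet's observed outcome, in design order."""
    logp = log_softmax(score_matrix(design, params, variant), axis=1)
    return logp[design.pellet_trial, design.pellet_outcome]


def dataset_loglik(
    ds: Dataset, params: ModelParams, variant: Variant = "stress"
) -> tuple[float, np.ndarray]:
    """Total observation log-likelihood plus the per-pellet vector.

    Each pellet contributes ``log prob(outcome)``; trials with zero pellets
    contribute nothing. The per-pellet vector (ordered by trial, then pellet
    index) is what leave-one-out cross-validation consumes.
    """
    design = build_design(ds)
    ll = pellet_loglik(design, params, variant)
    return float(ll.sum()), ll
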