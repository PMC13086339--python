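import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.special import gammaln

from feedshare.data_model import NOT_CONSUMED, ValidationError
from feedshare.likelihood import (
    ModelParams,
    build_design,
    complete_scores,
    consumption_probs,
    dataset_loglik,
    fish_score,
)
from tests.conftest import tiny_dataset

ZERO_COVS = {"L2_std": 0.0, "T_std": 0.0, "S_std": 0.0, "R_std": 0.0, "diet_level": 60}


class TestFishScore:
    def test_null_params_give_zero(self):
        assert fish_score(ZERO_COVS, ModelParams()) == 0.0

    def test_intercept_only(self):
        p = ModelParams(beta0=0.266)
        assert fish_score(ZERO_COVS, p) == pytest.approx(0.266)

    def test_stress_slope(self):
        p = ModelParams(beta_S=-0.104)
        covs = dict(ZERO_COVS, S_std=1.0)
        assert fish_score(covs, p, variant="stress") == pytest.approx(-0.104)

    def test_variant_gates_collinear_terms(self):
        # the stress variant must ignore temperature slopes and vice versa
        p = ModelParams(beta_S=-0.5, beta_T=0.7, beta_T2=0.3)
        covs = dict(ZERO_COVS, S_std=1.0, T_std=1.0)
        assert fish_score(covs, p, variant="stress") == pytest.approx(-0.5)
        assert fish_score(covs, p, variant="temperature") == pytest.approx(1.0)

    def test_unknown_diet_level_rejected(self):
        with pytest.raises(ValidationError):
            fish_score(dict(ZERO_COVS, diet_level=50), ModelParams())


class TestCompleteScores:
    @pytest.mark.parametrize(
        "scores, ninth",
        [
            ([0.0] * 8, 0.0),
            ([1.0] * 8, -8.0),
            ([0.5, -0.5, 0, 0, 0, 0, 0, 0], 0.0),
        ],
    )
    def test_ninth_entry(self, scores, ninth):
        full = complete_scores(scores)
        assert full[8] == pytest.approx(ninth)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            complete_scores([np.nan] + [0.0] * 7)

    @settings(derandomize=True, max_examples=100)
    @given(hnp.arrays(float, 8, elements=st.floats(-20, 20)))
    def test_sum_to_zero_invariant(self, scores):
        assert complete_scores(scores).sum() == pytest.approx(0.0, abs=1e-12)


class TestConsumptionProbs:
    def test_symmetric_null_gives_one_ninth(self):
        p = consumption_probs(np.zeros(9))
        assert np.allclose(p, 1 / 9)

    @pytest.mark.parametrize("s", [-2.0, 0.0, 0.7, 3.0])
    def test_equal_scores_give_eighth_conditional_share(self, s):
        # 12.5% of the consumed pellets per fish whenever fish are exchangeable
        p = consumption_probs(complete_scores([s] * 8))
        conditional = p[:8] / p[:8].sum()
        assert np.allclose(conditional, 0.125)

    def test_log_two_example(self):
        p = consumption_probs(complete_scores([math.log(2)] + [0.0] * 7))
        assert p[0] == pytest.approx(2 / (2 + 7 + 0.5))

    @settings(derandomize=True, max_examples=100)
    @given(hnp.arrays(float, 9, elements=st.floats(-300, 300)))
    def test_normalization(self, scores):
        p = consumption_probs(scores)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)

    def test_gauge_constant_shift_lowers_waste(self):
        # adding c > 0 to all fish scores strictly lowers prob(not consumed):
        # the pinned ninth score is what makes the overall level identifiable
        waste = [
            consumption_probs(complete_scores([0.3] * 8 + np.full(8, c)))[8]
            for c in [-1.0, 0.0, 0.5, 1.0]
        ]
        assert all(a > b for a, b in zip(waste, waste[1:]))

    def test_monotonicity_in_single_score(self):
        base = consumption_probs(complete_scores([0.1, -0.2, 0, 0, 0.4, 0, 0, 0]))
        bumped = consumption_probs(complete_scores([0.6, -0.2, 0, 0, 0.4, 0, 0, 0]))
        assert bumped[0] > base[0]
        assert np.all(bumped[1:] < base[1:])


def _oracle_loglik(ds, params, variant):
    """Straight-loop reference: recompute scores, softmax and log-probs per
    pellet with plain Python floats, no shared vectorized code."""
    std = ds.standardization
    total = 0.0
    for e in ds.events:
        trial = ds.trial(e.cage_id, e.replicate_index)
        scores = []
        for f in ds.fish_in_cage(e.cage_id):
            s = params.beta0 + params.diet_offsets[trial.diet_level]
            s += params.beta_L2 * float(std.transform("L2", f.structural_surface_cm2))
            if variant == "stress":
                s += params.beta_S * float(std.transform("S", trial.boat_count))
            else:
                t = float(std.transform("T", trial.temperature_C))
                s += params.beta_T * t + params.beta_T2 * t * t
            s += params.beta_R * float(std.transform("R", trial.delivered_pellets))
            s += params.fish_effects.get((f.cage_id, f.fish_index), 0.0)
            s += params.replicate_effects.get((trial.cage_id, trial.replicate_index), 0.0)
            scores.append(s)
        scores.append(-sum(scores))
        denom = sum(math.exp(v) for v in scores)
        total += math.log(math.exp(scores[e.outcome - 1]) / denom)
    return total


class TestDatasetLoglik:
    def test_symmetric_null_gives_log_one_ninth_per_pellet(self):
        rng = np.random.default_rng(3)
        ds = tiny_dataset(rng, n_trials=2, pellets_per_trial=1)
        total, per = dataset_loglik(ds, ModelParams())
        assert np.allclose(per, math.log(1 / 9))
        assert total == pytest.approx(per.size * math.log(1 / 9))

    def test_additivity_on_duplicated_events(self):
        import dataclasses

        rng = np.random.default_rng(4)
        ds = tiny_dataset(rng, n_trials=3, pellets_per_trial=3)
        params = ModelParams(beta0=0.3, beta_L2=0.1, beta_S=-0.1, sigma_fish=0.4)
        total, per = dataset_loglik(ds, params)
        doubled = dataclasses.replace(
            ds,
            events=ds.events
            + [
                dataclasses.replace(e, pellet_index=e.pellet_index + 100)
                for e in ds.events
            ],
        )
        total2, _ = dataset_loglik(doubled, params)
        assert total2 == pytest.approx(2 * total, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("variant", ["stress", "temperature"])
    def test_matches_straight_loop_oracle(self, seed, variant):
        rng = np.random.default_rng(seed)
        ds = tiny_dataset(rng, n_cages=1, n_trials=3, pellets_per_trial=2)
        params = ModelParams(
            beta0=float(rng.normal(0, 0.5)),
            diet_offsets={60: 0.0, 75: float(rng.normal()), 90: float(rng.normal())},
            beta_L2=float(rng.normal(0, 0.3)),
            beta_T=float(rng.normal(0, 0.3)),
            beta_T2=float(rng.normal(0, 0.2)),
            beta_S=float(rng.normal(0, 0.3)),
            beta_R=float(rng.normal(0, 0.3)),
            fish_effects={("C1", i): float(rng.normal(0, 0.4)) for i in range(1, 9)},
            replicate_effects={("C1", j): float(rng.normal(0, 0.2)) for j in range(1, 4)},
        )
        total, per = dataset_loglik(ds, params, variant)
        assert total == pytest.approx(_oracle_loglik(ds, params, variant), abs=1e-10)
        assert per.shape == (9,)

    def test_equals_multinomial_logpmf_up_to_coefficient(self):
        from scipy.stats import multinomial

        rng = np.random.default_rng(11)
        ds = tiny_dataset(rng, n_trials=2, pellets_per_trial=6)
        params = ModelParams(beta0=0.2, beta_S=-0.3)
        total, _ = dataset_loglik(ds, params)
        design = build_design(ds)
        from feedshare.likelihood import softmax_probs

        probs = softmax_probs(design, params)
        expected = 0.0
        for t in range(design.n_trials):
            n = design.counts[t]
            logpmf = multinomial.logpmf(n, n.sum(), probs[t])
            coefficient = gammaln(n.sum() + 1) - gammaln(n + 1).sum()
            expected += logpmf - coefficient
        assert total == pytest.approx(expected, abs=1e-9)
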