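import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedshare.data_model import (
    Dataset,
    FishRecord,
    PelletEvent,
    Standardization,
    TrialRecord,
    ValidationError,
    standardize,
)
from feedshare.likelihood import complete_scores, consumption_probs
from feedshare.reporting import (
    CloneCurve,
    clone_curve,
    clone_probability,
    fish_effect_table,
    meal_shares,
    predicted_counts,
    variance_partition,
)
from tests.test_inference import _draws_from_array


class TestVariancePartition:
    def test_reference_dispersions_give_headline_share(self):
        assert variance_partition(0.431, 0.183) == pytest.approx(0.702, abs=5e-4)

    def test_equal_dispersions_split_evenly(self):
        for x in [0.01, 1.0, 7.3]:
            assert variance_partition(x, x) == 0.5

    def test_vanishing_replicate_dispersion_limit(self):
        assert variance_partition(0.4, 1e-12) == pytest.approx(1.0)

    def test_squared_alternative(self):
        assert variance_partition(0.431, 0.183, squared=True) == pytest.approx(0.847, abs=5e-4)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            variance_partition(0.0, 0.2)
        with pytest.raises(ValidationError):
            variance_partition(0.2, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_complementarity(self, a, b):
        assert variance_partition(a, b) + variance_partition(b, a) == pytest.approx(1.0)


def _one_cage_dataset(consumers: list[int], delivered: int) -> Dataset:
    """One cage, two trials; the first trial's outcomes are ``consumers``."""
    fish = [FishRecord.from_length(f"F{i:02d}", "C1", i, 50.0 + i) for i in range(1, 9)]
    trials = [
        TrialRecord("C1", 1, "2024-08-01", 26.0, 10, 60, 40, delivered),
        TrialRecord("C1", 2, "2024-09-01", 23.0, 5, 60, 40, delivered + 8),
    ]
    events = [
        PelletEvent("C1", 1, k + 1, o) for k, o in enumerate(consumers)
    ] + [PelletEvent("C1", 2, k + 1, (k % 8) + 1) for k in range(delivered + 8)]
    return standardize(Dataset(fish=fish, trials=trials, events=events))


class TestMealShares:
    def test_even_distribution_gives_one_eighth_shares(self):
        # 16 pellets, two per fish -> every share 12.5%
        ds = _one_cage_dataset([i % 8 + 1 for i in range(16)], 16)
        shares = meal_shares(ds)
        t1 = shares.per_trial[shares.per_trial.replicate_index == 1]
        assert np.allclose(t1.share_pct, 12.5)

    def test_monopolizing_fish(self):
        ds = _one_cage_dataset([1] * 12, 12)
        shares = meal_shares(ds)
        t1 = shares.per_trial[shares.per_trial.replicate_index == 1]
        assert sorted(t1.share_pct, reverse=True) == [100.0] + [0.0] * 7
        assert (shares.waste.waste_pct == 0.0).all()

    def test_shares_plus_waste_conserve_percentage(self, default_dataset):
        ds, _ = default_dataset
        shares = meal_shares(ds)
        per_trial_sum = shares.per_trial.groupby(["cage_id", "replicate_index"]).agg(
            total=("share_pct", "sum"), consumed=("consumed", "sum"), delivered=("delivered", "first")
        )
        waste_share = 100 * (1 - per_trial_sum.consumed / per_trial_sum.delivered)
        assert np.allclose(per_trial_sum.total + waste_share, 100.0)

    def test_zero_pellet_trial_excluded(self):
        ds = _one_cage_dataset([i % 8 + 1 for i in range(16)], 16)
        trials = list(ds.trials) + [
            TrialRecord("C1", 3, "2024-10-01", 22.0, 2, 60, 40, 0)
        ]
        ds2 = dataclasses.replace(ds, trials=trials)
        shares = meal_shares(ds2)
        assert set(shares.per_trial.replicate_index) == {1, 2}

    def test_per_fish_sorted_by_decreasing_median_within_diet(self, default_dataset):
        ds, _ = default_dataset
        per_fish = meal_shares(ds).per_fish
        for _, grp in per_fish.groupby("diet_level"):
            assert (grp.median_share.diff().dropna() <= 1e-12).all()


class TestFishEffectTable:
    def test_all_zero_draws_give_zero_medians(self, fitted):
        _, _, draws = fitted
        zeroed = dataclasses.replace(
            draws, fish_effect_draws=np.zeros_like(draws.fish_effect_draws)
        )
        table = fish_effect_table(zeroed)
        assert (table["median"] == 0).all() and len(table) == 48

    def test_ordering_follows_meal_shares(self, fitted):
        ds, _, draws = fitted
        table = fish_effect_table(draws, ds)
        expected = meal_shares(ds).per_fish.fish_id.tolist()
        assert table.fish_id.tolist() == expected


class TestPredictedCounts:
    def test_symmetric_null_predicts_uniform_ninth(self, fitted):
        ds, _, draws = fitted
        null = dataclasses.replace(
            draws,
            posterior={k: np.zeros_like(v) for k, v in draws.posterior.items()},
            fish_effect_draws=np.zeros_like(draws.fish_effect_draws),
            replicate_effect_draws=np.zeros_like(draws.replicate_effect_draws),
        )
        # cut to a few draws for speed
        null = dataclasses.replace(
            null,
            posterior={k: v[:, :5] for k, v in null.posterior.items()},
            fish_effect_draws=null.fish_effect_draws[:, :5],
            replicate_effect_draws=null.replicate_effect_draws[:, :5],
            log_lik=null.log_lik[:, :5],
        )
        pred = predicted_counts(null, ds)
        assert np.allclose(pred.predicted, pred.delivered / 9)

    def test_conservation_per_trial(self, fitted):
        ds, _, draws = fitted
        small = dataclasses.replace(
            draws,
            posterior={k: v[:, :20] for k, v in draws.posterior.items()},
            fish_effect_draws=draws.fish_effect_draws[:, :20],
            replicate_effect_draws=draws.replicate_effect_draws[:, :20],
            log_lik=draws.log_lik[:, :20],
        )
        pred = predicted_counts(small, ds)
        by_trial = pred.groupby(["cage_id", "replicate_index"]).agg(
            total=("predicted", "sum"), delivered=("delivered", "first")
        )
        assert np.allclose(by_trial.total, by_trial.delivered, atol=1e-9)

    def test_calibrated_on_truth_simulated_data(self, fitted):
        # regression of observed on predicted counts has slope near 1
        ds, _, draws = fitted
        pred = predicted_counts(draws, ds)
        fish_rows = pred[pred.fish_id != "NC"]
        slope = np.polyfit(fish_rows.predicted, fish_rows.observed, 1)[0]
        assert 0.8 < slope < 1.2


class TestCloneCurve:
    def _std(self):
        return Standardization(
            means={"L2": 70.0, "T": 24.5, "S": 12.0, "R": 18.0},
            sds={"L2": 8.0, "T": 1.8, "S": 6.0, "R": 8.0},
        )

    def test_zero_coefficients_give_uniform_probability(self):
        draws = _draws_from_array(np.zeros((2, 50)))
        curve = clone_curve(draws, "S", np.linspace(0, 30, 7), self._std())
        assert np.allclose(curve.table["median"], 1 / 9)

    def test_closed_form_matches_generic_softmax(self):
        for s in np.linspace(-3, 3, 13):
            generic = consumption_probs(complete_scores([s] * 8))[0]
            assert clone_probability(s) == pytest.approx(generic, abs=1e-12)

    def test_large_score_limit_is_one_eighth(self):
        assert clone_probability(40.0) == pytest.approx(1 / 8)

    def test_monotone_decreasing_under_negative_stress_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 100))
        draws = _draws_from_array(x)
        draws.posterior["beta_S"] = -np.abs(x)  # every draw has beta_S < 0
        curve = clone_curve(draws, "S", np.linspace(0, 30, 9), self._std())
        assert (np.diff(curve.table["median"]) < 0).all()
        assert (np.diff(curve.table.q05) < 0).all()

    def test_variable_absent_from_variant_rejected(self):
        draws = _draws_from_array(np.zeros((1, 10)))
        with pytest.raises(ValidationError, match="not part of"):
            clone_curve(draws, "T", np.linspace(20, 28, 5), self._std())
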