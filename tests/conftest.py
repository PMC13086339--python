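import numpy as np
import pytest

from feedshare import fit, generate_dataset
from feedshare.data_model import (
    Dataset,
    FishRecord,
    PelletEvent,
    TrialRecord,
    standardize,
)
from feedshare.synthetic import DesignConfig


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study at the default design and reference truth."""
    ds, truth = generate_dataset(DesignConfig(rng_seed=0))
    return ds, truth


@pytest.fixture(scope="session")
def fitted(default_dataset):
    """A stress-variant fit of the default synthetic study (reduced chains
    for speed; the full estimation protocol is exercised separately)."""
    ds, truth = default_dataset
    draws = fit(ds, "stress", chains=2, draws=600, warmup=600, seed=7)
    return ds, truth, draws


def tiny_dataset(
    rng: np.random.Generator,
    n_cages: int = 1,
    n_trials: int = 2,
    pellets_per_trial: int = 4,
) -> Dataset:
    """A small hand-assembled dataset with randomized covariates/outcomes."""
    fish = []
    for c in range(n_cages):
        cage = f"C{c + 1}"
        for i in range(1, 9):
            fish.append(
                FishRecord.from_length(
                    f"F{c * 8 + i:02d}", cage, i, float(rng.uniform(50, 65))
                )
            )
    trials, events = [], []
    diets = [60, 75, 90]
    for c in range(n_cages):
        cage = f"C{c + 1}"
        for j in range(1, n_trials + 1):
            delivered = pellets_per_trial + j - 1  # varied so R can be standardized
            trials.append(
                TrialRecord(
                    cage_id=cage,
                    replicate_index=j,
                    date=f"2024-08-{j:02d}",
                    temperature_C=float(rng.uniform(21.8, 27.6)),
                    boat_count=int(rng.integers(0, 30)),
                    diet_level=diets[c % 3],
                    planned_pellets=40,
                    delivered_pellets=delivered,
                )
            )
            for k in range(1, delivered + 1):
                events.append(
                    PelletEvent(
                        cage_id=cage,
                        replicate_index=j,
                        pellet_index=k,
                        outcome=int(rng.integers(1, 10)),
                    )
                )
    return standardize(Dataset(fish=fish, trials=trials, events=events))
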