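"""Domain types, CSV table I/O, covariate standardization and dataset validation.

The experimental unit is a feeding trial: one monitored meal in one sea cage
of 8 tagged fish, during which pellets are delivered one at a time and each
pellet is either consumed by exactly one fish (outcome 1..8, the fish's index
within its cage) or sinks uneaten (outcome 9, "not consumed"). A complete
study is 6 cages x 8 fish x 8 replicate trials.

Continuous covariates are referred to throughout by short keys:

=====  =======================================================
key    covariate
=====  =======================================================
L2     structural surface of the fish, (total length x delta)^2, cm^2
T      water temperature during the trial, degC
S      anthropogenic-stress proxy: motorised boats passing the channel
R      ration: number of pellets delivered in the trial
=====  =======================================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Category index of the "pellet not consumed" outcome.
NOT_CONSUMED = 9

#: Fish per cage assumed by the 9-category outcome model.
FISH_PER_CAGE = 8

#: Species-specific shape coefficient delta for European seabass, used to
#: convert total length to structural length.
DEFAULT_SHAPE_COEF = 0.148

#: Continuous covariates subject to standardization.
COVARIATES = ("L2", "T", "S", "R")

#: Chronic feeding treatments, in percent of the recommended daily ration.
DIET_LEVELS = (60, 75, 90)


class ValidationError(ValueError):
    """A dataset or record violates a structural invariant."""


def structural_surface(total_length_cm: float, delta: float = DEFAULT_SHAPE_COEF) -> float:
    """Structural surface (cm^2) of a fish: ``(total_length_cm * delta) ** 2``.

    The squared structural length is the body-size covariate of the ingestion
    model, following the bioenergetic argument that ingestion scales with an
    organism's surface.

    Parameters
    ----------
    total_length_cm
        Total length of the fish in cm; must be non-negative.
    delta
        Species-specific shape coefficient (0.148 for *D. labrax*).
    """
    if total_length_cm < 0:
        raise ValidationError(f"total_length_cm must be >= 0, got {total_length_cm}")
    if delta <= 0:
        raise ValidationError(f"delta must be > 0, got {delta}")
    return (total_length_cm * delta) ** 2


@dataclass(frozen=True)
class FishRecord:
    """One tagged individual with cage membership and body-size covariate."""

    fish_id: str
    cage_id: str
    fish_index: int  # 1..8 within cage
    total_length_cm: float
    structural_surface_cm2: float

    @classmethod
    def from_length(
        cls,
        fish_id: str,
        cage_id: str,
        fish_index: int,
        total_length_cm: float,
        delta: float = DEFAULT_SHAPE_COEF,
    ) -> "FishRecord":
        return cls(
            fish_id=str(fish_id),
            cage_id=str(cage_id),
            fish_index=int(fish_index),
            total_length_cm=float(total_length_cm),
            structural_surface_cm2=structural_surface(total_length_cm, delta),
        )


@dataclass(frozen=True)
class TrialRecord:
    """One feeding trial: a monitored meal in one cage."""

    cage_id: str
    replicate_index: int  # 1..8
    date: str  # ISO 8601
    temperature_C: float
    boat_count: int
    diet_level: int  # one of DIET_LEVELS, percent of recommended ration
    planned_pellets: int
    delivered_pellets: int


@dataclass(frozen=True)
class PelletEvent:
    """The categorical outcome of one delivered pellet."""

    cage_id: str
    replicate_index: int
    pellet_index: int  # >= 1, in delivery order
    outcome: int  # 1..8 = fish_index of the consumer, 9 = not consumed


@dataclass
class Standardization:
    """Per-covariate centring/scaling constants (sample mean and sd, n-1)."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def transform(self, name: str, x):
        """Map raw covariate values to the standardized (z) scale."""
        return (np.asarray(x, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, z):
        """Map standardized values back to the raw scale."""
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]


@dataclass
class Dataset:
    """A validated feeding-trial dataset: fish, trials, pellet events."""

    fish: list[FishRecord]
    trials: list[TrialRecord]
    events: list[PelletEvent]
    standardization: Standardization | None = None

    # -- lookups -----------------------------------------------------------
    def cage_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.fish:
            seen.setdefault(f.cage_id)
        return list(seen)

    def fish_in_cage(self, cage_id: str) -> list[FishRecord]:
        return sorted(
            (f for f in self.fish if f.cage_id == cage_id), key=lambda f: f.fish_index
        )

    def trial(self, cage_id: str, replicate_index: int) -> TrialRecord:
        for t in self.trials:
            if t.cage_id == cage_id and t.replicate_index == replicate_index:
                return t
        raise KeyError(f"no trial ({cage_id}, replicate {replicate_index})")

    def events_for_trial(self, cage_id: str, replicate_index: int) -> list[PelletEvent]:
        return sorted(
            (
                e
                for e in self.events
                if e.cage_id == cage_id and e.replicate_index == replicate_index
            ),
            key=lambda e: e.pellet_index,
        )

    # -- frames ------------------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        fish = pd.DataFrame(
            [
                {
                    "fish_id": f.fish_id,
                    "cage_id": f.cage_id,
                    "fish_index": f.fish_index,
                    "total_length_cm": f.total_length_cm,
                }
                for f in self.fish
            ]
        )
        trials = pd.DataFrame([dataclasses.asdict(t) for t in self.trials])
        events = pd.DataFrame(
            [
                {
                    "cage_id": e.cage_id,
                    "replicate_index": e.replicate_index,
                    "pellet_index": e.pellet_index,
                    "outcome": "NC" if e.outcome == NOT_CONSUMED else str(e.outcome),
                }
                for e in self.events
            ],
            columns=["cage_id", "replicate_index", "pellet_index", "outcome"],
        )
        return fish, trials, events


# ---------------------------------------------------------------------------
# validation


def validate_dataset(ds: Dataset, max_delivery_ratio: float = 2.0) -> None:
    """Check every structural invariant; raise :class:`ValidationError` on the
    first violation, naming the offending record.

    Checks: 8 fish per cage with indices 1..8; positive lengths; the
    structural-surface consistency (surface is the square of a positive
    quantity); diet level constant within a cage and drawn from the known
    treatments; delivered pellets within ``max_delivery_ratio`` of planned;
    referential integrity of events; outcomes within 1..9; and per-trial event
    counts equal to the trial's delivered pellets.
    """
    by_cage: dict[str, list[FishRecord]] = {}
    for f in ds.fish:
        by_cage.setdefault(f.cage_id, []).append(f)
        if f.total_length_cm <= 0:
            raise ValidationError(f"fish {f.fish_id}: total_length_cm must be > 0")
        if f.structural_surface_cm2 <= 0:
            raise ValidationError(f"fish {f.fish_id}: structural_surface_cm2 must be > 0")
    for cage_id, members in by_cage.items():
        if len(members) != FISH_PER_CAGE:
            raise ValidationError(
                f"cage {cage_id}: cage size != 8 (found {len(members)} fish)"
            )
        if sorted(f.fish_index for f in members) != list(range(1, FISH_PER_CAGE + 1)):
            raise ValidationError(f"cage {cage_id}: fish_index values are not 1..8")

    diet_by_cage: dict[str, int] = {}
    trial_keys: set[tuple[str, int]] = set()
    for t in ds.trials:
        key = (t.cage_id, t.replicate_index)
        if key in trial_keys:
            raise ValidationError(f"duplicate trial {key}")
        trial_keys.add(key)
        if t.cage_id not in by_cage:
            raise ValidationError(f"trial {key}: unknown cage {t.cage_id}")
        if t.diet_level not in DIET_LEVELS:
            raise ValidationError(f"trial {key}: diet_level {t.diet_level} not in {DIET_LEVELS}")
        if diet_by_cage.setdefault(t.cage_id, t.diet_level) != t.diet_level:
            raise ValidationError(f"cage {t.cage_id}: diet level not constant across trials")
        if t.planned_pellets <= 0:
            raise ValidationError(f"trial {key}: planned_pellets must be > 0")
        if t.delivered_pellets < 0:
            raise ValidationError(f"trial {key}: delivered_pellets must be >= 0")
        if t.delivered_pellets > max_delivery_ratio * t.planned_pellets:
            raise ValidationError(
                f"trial {key}: delivered_pellets {t.delivered_pellets} exceeds "
                f"{max_delivery_ratio} x planned ({t.planned_pellets})"
            )

    counts: dict[tuple[str, int], int] = {k: 0 for k in trial_keys}
    for i, e in enumerate(ds.events):
        key = (e.cage_id, e.replicate_index)
        if key not in trial_keys:
            raise ValidationError(f"event row {i}: references unknown trial {key}")
        if not 1 <= e.outcome <= NOT_CONSUMED:
            raise ValidationError(
                f"event row {i} (trial {key}, pellet {e.pellet_index}): "
                f"outcome out of range: {e.outcome}"
            )
        counts[key] += 1
    for t in ds.trials:
        n = counts[(t.cage_id, t.replicate_index)]
        if n != t.delivered_pellets:
            raise ValidationError(
                f"trial ({t.cage_id}, {t.replicate_index}): {n} events but "
                f"delivered_pellets = {t.delivered_pellets}"
            )


# ---------------------------------------------------------------------------
# I/O

_FISH_COLS = ["fish_id", "cage_id", "fish_index", "total_length_cm"]
_TRIAL_COLS = [
    "cage_id",
    "replicate_index",
    "date",
    "temperature_C",
    "boat_count",
    "diet_level",
    "planned_pellets",
    "delivered_pellets",
]
_EVENT_COLS = ["cage_id", "replicate_index", "pellet_index", "outcome"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def read_dataset(
    fish_table: str | Path,
    trial_table: str | Path,
    event_table: str | Path,
    delta: float = DEFAULT_SHAPE_COEF,
    validate: bool = True,
) -> Dataset:
    """Read the three study tables (CSV, UTF-8, single header row) into a
    validated :class:`Dataset`, computing each fish's structural surface."""
    fish_df = pd.read_csv(fish_table)
    trial_df = pd.read_csv(trial_table)
    event_df = pd.read_csv(event_table)
    _require_columns(fish_df, _FISH_COLS, "fish table")
    _require_columns(trial_df, _TRIAL_COLS, "trial table")
    _require_columns(event_df, _EVENT_COLS, "event table")

    fish = [
        FishRecord.from_length(
            r.fish_id, r.cage_id, int(r.fish_index), float(r.total_length_cm), delta
        )
        for r in fish_df.itertuples()
    ]
    trials = [
        TrialRecord(
            cage_id=str(r.cage_id),
            replicate_index=int(r.replicate_index),
            date=str(r.date),
            temperature_C=float(r.temperature_C),
            boat_count=int(r.boat_count),
            diet_level=int(r.diet_level),
            planned_pellets=int(r.planned_pellets),
            delivered_pellets=int(r.delivered_pellets),
        )
        for r in trial_df.itertuples()
    ]
    events = []
    for i, r in enumerate(event_df.itertuples()):
        raw = str(r.outcome).strip()
        if raw.upper() == "NC":
            outcome = NOT_CONSUMED
        else:
            try:
                outcome = int(raw)
            except ValueError:
                raise ValidationError(f"event table row {i}: unparseable outcome {raw!r}")
        events.append(
            PelletEvent(
                cage_id=str(r.cage_id),
                replicate_index=int(r.replicate_index),
                pellet_index=int(r.pellet_index),
                outcome=outcome,
            )
        )
    ds = Dataset(fish=fish, trials=trials, events=events)
    if validate:
        validate_dataset(ds)
    return ds


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write fish.csv, trials.csv and events.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fish, trials, events = ds.to_frames()
    paths = {
        "fish": out / "fish.csv",
        "trials": out / "trials.csv",
        "events": out / "events.csv",
    }
    fish.to_csv(paths["fish"], index=False)
    trials.to_csv(paths["trials"], index=False)
    events.to_csv(paths["events"], index=False)
    return paths


# ---------------------------------------------------------------------------
# standardization


def _covariate_values(ds: Dataset, name: str) -> np.ndarray:
    if name == "L2":
        return np.array([f.structural_surface_cm2 for f in ds.fish], dtype=float)
    if name == "T":
        return np.array([t.temperature_C for t in ds.trials], dtype=float)
    if name == "S":
        return np.array([t.boat_count for t in ds.trials], dtype=float)
    if name == "R":
        return np.array([t.delivered_pellets for t in ds.trials], dtype=float)
    raise KeyError(name)


def standardize(ds: Dataset) -> Dataset:
    """Attach a :class:`Standardization` (sample mean/sd, n-1 denominator)
    for each continuous covariate, computed from this dataset.

    The body-size covariate L2 is standardized over the fish table; T, S and R
    over the trial table. Records keep their raw values; standardized values
    are obtained through ``dataset.standardization.transform``. Raises on a
    zero-variance covariate.
    """
    std = Standardization()
    for name in COVARIATES:
        x = _covariate_values(ds, name)
        if x.size < 2:
            raise ValidationError(f"covariate {name}: need >= 2 values to standardize")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValidationError(f"covariate {name}: zero variance, cannot standardize")
        std.means[name] = mean
        std.sds[name] = sd
    return dataclasses.replace(ds, standardization=std)
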