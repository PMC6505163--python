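"""Inner-validation grid search over training epochs and hidden-unit counts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from gpmix.errors import ValidationError
from gpmix.network import NetworkConfig, train_network
from gpmix.traits import TraitSpec


@dataclass(frozen=True)
class TuningGrid:
    """Candidate epochs and unit counts.

    Defaults are the full grid (epochs 1..100, units 10 to 490 in steps of
    20); :meth:`reduced` is a small preset for desk-scale runs and tests.
    """

    epoch_candidates: tuple[int, ...] = tuple(range(1, 101))
    unit_candidates: tuple[int, ...] = tuple(range(10, 500, 20))

    def __post_init__(self) -> None:
        for name, cand in (
            ("epoch_candidates", self.epoch_candidates),
            ("unit_candidates", self.unit_candidates),
        ):
            if not cand:
                raise ValidationError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(cand, cand[1:])):
                raise ValidationError(f"{name} must be strictly increasing")
            if cand[0] < 1:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def reduced(cls) -> "TuningGrid":
        """Small preset for CI and desk-scale experiments."""
        return cls(epoch_candidates=(10, 50, 100), unit_candidates=(10, 50))


@dataclass
class TuningResult:
    """Chosen (units, epochs) and the recorded validation-loss table."""

    units: int
    epochs: int
    val_loss: float
    table: list[tuple[int, int, float]]  # (units, epochs, validation loss)


def split_inner_validation(
    train_records: Sequence | np.ndarray, fraction: float, seed: int
) -> tuple[list, list]:
    """Disjoint, exhaustive seeded split of the outer-training records.

    The validation side holds ``round(fraction * n)`` records (at least 1
    required); the rest are inner-training records.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("validation fraction must be in (0, 1)")
    records = list(train_records)
    n = len(records)
    if n < 2:
        raise ValidationError("inner split needs >= 2 records")
    n_val = int(round(fraction * n))
    if n_val == 0:
        raise ValidationError(
            f"validation set would be empty ({n} records, fraction {fraction})"
        )
    if n_val == n:
        raise ValidationError("validation set would swallow every record")
    order = np.random.default_rng(seed).permutation(n)
    val = [records[i] for i in order[:n_val]]
    inner = [records[i] for i in order[n_val:]]
    return inner, val


def grid_search(
    X_train: np.ndarray,
    targets_train: dict[str, np.ndarray],
    grid: TuningGrid,
    base_config: NetworkConfig,
    specs: list[TraitSpec],
    seed: int,
    validation_fraction: float = 0.20,
) -> TuningResult:
    """Pick (units, epochs) minimizing inner-validation total loss.

    For each unit candidate a single network is trained for the largest
    candidate epoch count while the validation loss is recorded after every
    epoch, which is equivalent to (and far cheaper than) retraining per
    epoch candidate. Ties are broken toward smaller units, then smaller
    epochs. Only outer-training data ever reaches this function.
    """
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[0]
    inner_idx, val_idx = split_inner_validation(np.arange(n), validation_fraction, seed)
    inner_idx = np.array(inner_idx, dtype=int)
    val_idx = np.array(val_idx, dtype=int)
    X_inner, X_val = X_train[inner_idx], X_train[val_idx]
    t_inner = {k: v[inner_idx] for k, v in targets_train.items()}
    t_val = {k: v[val_idx] for k, v in targets_train.items()}

    max_epochs = max(grid.epoch_candidates)
    table: list[tuple[int, int, float]] = []
    best: tuple[int, int, float] | None = None
    for U in grid.unit_candidates:
        config = replace(base_config, units=U, epochs=max_epochs, seed=seed)
        try:
            _, trace = train_network(
                X_inner, t_inner, config, specs, validation=(X_val, t_val)
            )
            val_losses = trace["val"]
        except ValidationError:
            val_losses = [float("inf")] * max_epochs
        for E in grid.epoch_candidates:
            loss = float(val_losses[E - 1])
            table.append((U, E, loss))
            if np.isfinite(loss) and (best is None or loss < best[2]):
                best = (U, E, loss)
    if best is None:
        raise ValidationError("every grid candidate diverged during training")
    return TuningResult(units=best[0], epochs=best[1], val_loss=best[2], table=table)
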