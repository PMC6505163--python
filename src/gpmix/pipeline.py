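"""End-to-end experiment: QC -> GRM -> features -> CV2 -> tuning -> metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gpmix.errors import ValidationError
from gpmix.evaluation import (
    MetricReport,
    aggregate_metrics,
    make_cv2_folds,
    pccc,
    pearson_correlation,
)
from gpmix.features import (
    INTERACTION_MODES,
    assemble_feature_matrix,
    build_design_matrices,
    cholesky_upper,
    compute_grm,
)
from gpmix.markers import MarkerMatrix, impute_markers, marker_qc
from gpmix.network import (
    NetworkConfig,
    encode_targets,
    predict_traits,
    standardize_continuous,
    train_network,
)
from gpmix.phenotypes import PhenotypeTable
from gpmix.traits import TraitSpec, validate_trait_specs
from gpmix.tuning import TuningGrid, grid_search

logger = logging.getLogger(__name__)

MODEL_KINDS = ("MTDLMP", "UDL")


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    trait_specs: list[TraitSpec]
    model_kind: str = "MTDLMP"
    interaction_mode: str = "I"
    n_hidden_layers: int = 1
    grid: TuningGrid = field(default_factory=TuningGrid.reduced)
    n_outer_folds: int = 5
    inner_validation_fraction: float = 0.20
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0
    # marker QC thresholds
    max_marker_missing: float = 0.60
    min_maf: float = 0.05
    max_het: float = 0.10
    max_line_missing: float = 0.50
    apply_qc: bool = True
    standardize_features: bool = False  # input columns of X; off by default

    def __post_init__(self) -> None:
        validate_trait_specs(self.trait_specs)
        self.model_kind = self.model_kind.upper()
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(f"model_kind must be one of {MODEL_KINDS}")
        if self.interaction_mode not in INTERACTION_MODES:
            raise ValidationError(f"interaction_mode must be one of {INTERACTION_MODES}")
        if self.n_hidden_layers not in (1, 2, 3):
            raise ValidationError("n_hidden_layers must be 1, 2 or 3")
        if self.n_outer_folds < 2:
            raise ValidationError("n_outer_folds must be >= 2")
        if not 0.0 < self.inner_validation_fraction < 1.0:
            raise ValidationError("inner_validation_fraction must be in (0, 1)")

    def network_config(self, seed: int) -> NetworkConfig:
        return NetworkConfig(
            n_hidden_layers=self.n_hidden_layers,
            units=self.grid.unit_candidates[0],
            epochs=max(self.grid.epoch_candidates),
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=seed,
        )


def _check_category_coverage(
    phenotypes: PhenotypeTable, specs: list[TraitSpec], fold: int
) -> None:
    for spec in specs:
        if not spec.is_categorical:
            continue
        observed = set(phenotypes.values[spec.name][~np.isnan(phenotypes.values[spec.name])])
        expected = set(float(c) for c in range(1, spec.n_categories + 1))
        missing = sorted(expected - observed)
        if missing:
            raise ValidationError(
                f"trait {spec.name!r}: categories {[int(c) for c in missing]} "
                f"absent from the training set of fold {fold}"
            )


def _fit_and_predict(
    X_train: np.ndarray,
    train_table: PhenotypeTable,
    X_test: np.ndarray,
    config: RunConfig,
    specs: list[TraitSpec],
    seed: int,
) -> tuple[dict[str, np.ndarray], dict[str, tuple[float, float]], dict]:
    """Tune, retrain on the full outer-training set, and predict the test rows."""
    targets = encode_targets(train_table, specs)
    stats: dict[str, tuple[float, float]] = {}
    for spec in specs:
        if spec.kind == "continuous":
            try:
                std, mean, sd = standardize_continuous(targets[spec.name])
            except ValidationError as err:
                raise ValidationError(f"trait {spec.name!r}: {err}") from None
            targets[spec.name] = std
            stats[spec.name] = (mean, sd)
    base = config.network_config(seed)
    result = grid_search(
        X_train,
        targets,
        config.grid,
        base,
        specs,
        seed,
        validation_fraction=config.inner_validation_fraction,
    )
    final_config = replace(base, units=result.units, epochs=result.epochs, seed=seed)
    weights, _ = train_network(X_train, targets, final_config, specs)
    _, decoded = predict_traits(X_test, weights, specs, standardization=stats)
    detail = {
        "units": result.units,
        "epochs": result.epochs,
        "val_loss": result.val_loss,
    }
    return decoded, stats, detail


def run_experiment(
    config: RunConfig, markers: MarkerMatrix, phenotypes: PhenotypeTable
) -> MetricReport:
    """Run the full CV2 evaluation and return the per-fold metric report.

    Fully reproducible given the master seed. The report also carries the
    raw test-set predictions (``report.predictions``) so metrics can be
    recomputed externally.
    """
    specs = config.trait_specs
    if config.apply_qc:
        markers = marker_qc(
            markers,
            config.max_marker_missing,
            config.min_maf,
            config.max_het,
            config.max_line_missing,
        )
    markers = impute_markers(markers)

    known_lines = set(markers.line_ids)
    unknown = [l for l in phenotypes.lines if l not in known_lines]
    if unknown:
        raise ValidationError(
            f"{len(unknown)} phenotyped lines have no marker data after QC "
            f"(first few: {unknown[:5]})"
        )

    grm = compute_grm(markers)
    Q = cholesky_upper(grm)
    env_order = phenotypes.environments
    design = build_design_matrices(phenotypes, markers.line_ids, env_order)
    design = assemble_feature_matrix(design, Q, config.interaction_mode)
    X = design.X
    assert X is not None
    if config.standardize_features:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    seed_rng = np.random.default_rng(config.seed)
    cv_seed = int(seed_rng.integers(2**31))
    fold_seeds = [int(seed_rng.integers(2**31)) for _ in range(config.n_outer_folds)]
    plan = make_cv2_folds(phenotypes, config.n_outer_folds, cv_seed)

    fold_of_record = np.array(
        [plan.fold_of(l, e) for l, e in phenotypes.record_keys], dtype=int
    )
    env_arr = np.array(phenotypes.environment_ids)

    rows: list[dict] = []
    fold_details: list[dict] = []
    pred_rows: list[dict] = []
    for fold in range(1, config.n_outer_folds + 1):
        test_mask = fold_of_record == fold
        train_idx = np.nonzero(~test_mask)[0]
        test_idx = np.nonzero(test_mask)[0]
        train_table = phenotypes.subset(train_idx)
        _check_category_coverage(train_table, specs, fold)
        X_train, X_test = X[train_idx], X[test_idx]

        if config.model_kind == "MTDLMP":
            decoded, stats, detail = _fit_and_predict(
                X_train, train_table, X_test, config, specs, fold_seeds[fold - 1]
            )
            detail = {"model": "MTDLMP", **detail}
        else:
            decoded = {}
            stats = {}
            detail = {"model": "UDL", "per_trait": {}}
            trait_rng = np.random.default_rng(fold_seeds[fold - 1])
            for spec in specs:
                trait_seed = int(trait_rng.integers(2**31))
                d, s, dt = _fit_and_predict(
                    X_train, train_table, X_test, config, [spec], trait_seed
                )
                decoded.update(d)
                stats.update(s)
                detail["per_trait"][spec.name] = dt
        fold_details.append(
            {"fold": fold, "standardization": dict(stats), **detail}
        )

        test_envs = env_arr[test_idx]
        for spec in specs:
            observed_all = phenotypes.values[spec.name][test_idx]
            predicted_all = decoded[spec.name]
            for env in env_order:
                in_env = test_envs == env
                if not in_env.any():
                    continue
                obs = observed_all[in_env]
                pred = predicted_all[in_env]
                ok = ~np.isnan(obs)
                metric = "pearson" if spec.kind == "continuous" else "pccc"
                if spec.kind == "continuous":
                    if ok.sum() >= 3 and np.ptp(obs[ok]) > 0 and np.ptp(pred[ok]) > 0:
                        value = pearson_correlation(obs[ok], pred[ok])
                    else:
                        value = float("nan")
                else:
                    value = pccc(obs[ok].astype(int), pred[ok].astype(int)) if ok.any() else float("nan")
                rows.append(
                    {
                        "trait": spec.name,
                        "environment": env,
                        "fold": fold,
                        "metric": metric,
                        "value": value,
                    }
                )
            for i, rec in enumerate(test_idx):
                pred_rows.append(
                    {
                        "trait": spec.name,
                        "line": phenotypes.line_ids[rec],
                        "environment": phenotypes.environment_ids[rec],
                        "fold": fold,
                        "observed": observed_all[i],
                        "predicted": predicted_all[i],
                    }
                )
        fold_rows = [r for r in rows if r["fold"] == fold]
        logger.info(
            "fold %d/%d: %s | %s",
            fold,
            config.n_outer_folds,
            {k: v for k, v in fold_details[-1].items() if k not in ("standardization",)},
            "; ".join(
                f"{r['trait']}/{r['environment']} {r['metric']}={r['value']:.4f}"
                for r in fold_rows
            ),
        )

    report = aggregate_metrics(pd.DataFrame(rows), fold_details)
    report.predictions = pd.DataFrame(pred_rows)
    report.cv_plan = plan
    return report
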