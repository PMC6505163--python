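"""CV2 fold construction and the per-trait accuracy metrics.

CV2 partitions (line, environment) cells, not lines: a line evaluated in
several environments typically has some cells in training while its
remaining cells are predicted, which mirrors incomplete field trials.
Continuous traits are scored with Pearson's correlation per
trait-environment cell of each test fold; categorical traits with the
fraction of correctly classified cases (PCCC, reported in [0, 1]); the
fold average is the summary value.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from gpmix.errors import ValidationError
from gpmix.phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class CV2Plan:
    """Assignment of (line, environment) records to folds 1..k."""

    k: int
    assignment: dict[tuple[str, str], int]
    seed: int

    def fold_of(self, line: str, env: str) -> int:
        return self.assignment[(line, env)]

    def test_keys(self, fold: int) -> list[tuple[str, str]]:
        return [key for key, f in self.assignment.items() if f == fold]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["line", "environment", "fold"])
            for (line, env), fold in self.assignment.items():
                writer.writerow([line, env, fold])


@dataclass
class MetricReport:
    """Per-fold metric rows plus the fold-averaged summary.

    ``rows`` columns: trait, environment, fold, metric, value (value may be
    NaN when a fold metric is undefined, e.g. a constant vector).
    ``summary`` columns: trait, environment, metric, value, n_folds.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame
    fold_details: list[dict] = field(default_factory=list)
    predictions: pd.DataFrame | None = None
    cv_plan: "CV2Plan | None" = None

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.rename(columns={"metric": "metric_name"})
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary_dict(self) -> dict:
        """JSON-friendly fold-averaged summary."""
        records = []
        for _, row in self.summary.iterrows():
            records.append(
                {
                    "trait": row["trait"],
                    "environment": row["environment"],
                    "metric": row["metric"],
                    "value": None if pd.isna(row["value"]) else float(row["value"]),
                    "n_folds": int(row["n_folds"]),
                }
            )
        return {"summary": records}


def make_cv2_folds(phenotypes: PhenotypeTable, k: int, seed: int) -> CV2Plan:
    """Seeded random partition of phenotype records into k near-equal folds.

    Fold sizes differ by at most one. Because cells (not lines) are
    partitioned, lines generally span training and test within a fold — the
    CV2 property.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    keys = phenotypes.record_keys
    n = len(keys)
    if n < k:
        raise ValidationError(f"{n} records cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(n)
    assignment: dict[tuple[str, str], int] = {}
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        for i in chunk:
            assignment[keys[int(i)]] = fold
    return CV2Plan(k=k, assignment=assignment, seed=seed)


def pearson_correlation(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Sample Pearson product-moment correlation.

    Returns NaN (with a warning) when either vector is constant, so callers
    can exclude the fold from averaging.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValidationError("observed and predicted lengths differ")
    if observed.size < 3:
        raise ValidationError("Pearson correlation needs >= 3 pairs")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        warnings.warn(
            "constant vector: Pearson correlation undefined, recording missing",
            stacklevel=2,
        )
        return float("nan")
    return float(scipy_stats.pearsonr(observed, predicted).statistic)


def pccc(observed_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Fraction of positions with equal labels, in [0, 1]."""
    observed_labels = np.asarray(observed_labels)
    predicted_labels = np.asarray(predicted_labels)
    if observed_labels.shape != predicted_labels.shape:
        raise ValidationError("observed and predicted lengths differ")
    if observed_labels.size == 0:
        raise ValidationError("pccc needs at least one pair")
    return float(np.mean(observed_labels == predicted_labels))


def aggregate_metrics(rows: pd.DataFrame, fold_details: list[dict] | None = None) -> MetricReport:
    """Fold-average per trait x environment, excluding missing fold values.

    ``rows`` must carry columns trait, environment, fold, metric, value.
    Cells with no valid fold value get a NaN summary with ``n_folds`` 0.
    """
    required = {"trait", "environment", "fold", "metric", "value"}
    if not required.issubset(rows.columns):
        raise ValidationError(f"metric rows need columns {sorted(required)}")
    summaries = []
    for (trait, env, metric), grp in rows.groupby(
        ["trait", "environment", "metric"], sort=False
    ):
        valid = grp["value"].dropna()
        summaries.append(
            {
                "trait": trait,
                "environment": env,
                "metric": metric,
                "value": float(valid.mean()) if len(valid) else float("nan"),
                "n_folds": int(len(valid)),
            }
        )
        if not len(valid):
            logger.warning(
                "no valid fold values for trait=%s environment=%s", trait, env
            )
    return MetricReport(
        rows=rows.reset_index(drop=True),
        summary=pd.DataFrame(summaries),
        fold_details=fold_details or [],
    )
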