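"""Strict YAML config parsing for runs and simulations (fail fast on typos)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from gpmix.errors import SchemaError
from gpmix.pipeline import RunConfig
from gpmix.simulate import SimulatedTrait, SimulationConfig
from gpmix.traits import TraitSpec
from gpmix.tuning import TuningGrid

_RUN_KEYS = {
    "traits",
    "model",
    "interaction",
    "layers",
    "folds",
    "inner_validation_fraction",
    "dropout_rate",
    "learning_rate",
    "batch_size",
    "seed",
    "grid",
    "qc",
    "standardize_features",
}
_TRAIT_KEYS = {"name", "kind", "n_categories"}
_GRID_KEYS = {"preset", "epochs", "units"}
_QC_KEYS = {"max_marker_missing", "min_maf", "max_het", "max_line_missing", "apply"}
_SIM_KEYS = {
    "n_lines",
    "n_environments",
    "n_markers",
    "maf_range",
    "traits",
    "genetic_correlation",
    "gxe_variance_ratio",
    "env_effect_scale",
    "observed_fraction",
    "seed",
}
_SIM_TRAIT_KEYS = {"name", "kind", "heritability", "quantile_cuts"}


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    return doc


def _check_keys(doc: dict, allowed: set[str], where: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise SchemaError(f"{where}: unknown keys {sorted(unknown)}")


def _parse_grid(doc: dict | str | None) -> TuningGrid:
    if doc is None:
        return TuningGrid.reduced()
    if isinstance(doc, str):
        doc = {"preset": doc}
    _check_keys(doc, _GRID_KEYS, "grid")
    preset = doc.get("preset")
    if preset is not None:
        if preset == "reduced":
            base = TuningGrid.reduced()
        elif preset == "full":
            base = TuningGrid()
        else:
            raise SchemaError(f"grid.preset must be 'reduced' or 'full', got {preset!r}")
    else:
        base = TuningGrid.reduced()
    epochs = tuple(doc["epochs"]) if "epochs" in doc else base.epoch_candidates
    units = tuple(doc["units"]) if "units" in doc else base.unit_candidates
    return TuningGrid(epoch_candidates=epochs, unit_candidates=units)


def _parse_traits(items: list) -> list[TraitSpec]:
    if not isinstance(items, list) or not items:
        raise SchemaError("traits must be a non-empty list")
    specs = []
    for item in items:
        if not isinstance(item, dict):
            raise SchemaError("each trait must be a mapping")
        _check_keys(item, _TRAIT_KEYS, f"trait {item.get('name', '?')!r}")
        if "name" not in item or "kind" not in item:
            raise SchemaError("each trait needs 'name' and 'kind'")
        specs.append(
            TraitSpec(item["name"], item["kind"], item.get("n_categories"))
        )
    return specs


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration document."""
    doc = _load_yaml(path)
    _check_keys(doc, _RUN_KEYS, str(path))
    if "traits" not in doc:
        raise SchemaError(f"{path}: 'traits' is required")
    qc = doc.get("qc") or {}
    _check_keys(qc, _QC_KEYS, "qc")
    return RunConfig(
        trait_specs=_parse_traits(doc["traits"]),
        model_kind=str(doc.get("model", "MTDLMP")),
        interaction_mode=str(doc.get("interaction", "I")),
        n_hidden_layers=int(doc.get("layers", 1)),
        grid=_parse_grid(doc.get("grid")),
        n_outer_folds=int(doc.get("folds", 5)),
        inner_validation_fraction=float(doc.get("inner_validation_fraction", 0.20)),
        dropout_rate=float(doc.get("dropout_rate", 0.3)),
        learning_rate=float(doc.get("learning_rate", 0.001)),
        batch_size=int(doc.get("batch_size", 32)),
        seed=int(doc.get("seed", 0)),
        max_marker_missing=float(qc.get("max_marker_missing", 0.60)),
        min_maf=float(qc.get("min_maf", 0.05)),
        max_het=float(qc.get("max_het", 0.10)),
        max_line_missing=float(qc.get("max_line_missing", 0.50)),
        apply_qc=bool(qc.get("apply", True)),
        standardize_features=bool(doc.get("standardize_features", False)),
    )


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a simulation configuration document."""
    doc = _load_yaml(path)
    _check_keys(doc, _SIM_KEYS, str(path))
    traits = []
    for item in doc.get("traits", []):
        _check_keys(item, _SIM_TRAIT_KEYS, f"trait {item.get('name', '?')!r}")
        cuts = item.get("quantile_cuts")
        traits.append(
            SimulatedTrait(
                name=item["name"],
                kind=item.get("kind", "continuous"),
                heritability=float(item.get("heritability", 0.5)),
                quantile_cuts=tuple(cuts) if cuts is not None else None,
            )
        )
    R = doc.get("genetic_correlation")
    kwargs = dict(
        n_lines=int(doc.get("n_lines", 100)),
        n_environments=int(doc.get("n_environments", 3)),
        n_markers=int(doc.get("n_markers", 200)),
        gxe_variance_ratio=float(doc.get("gxe_variance_ratio", 0.0)),
        env_effect_scale=float(doc.get("env_effect_scale", 1.0)),
        observed_fraction=float(doc.get("observed_fraction", 1.0)),
        seed=int(doc.get("seed", 0)),
    )
    if "maf_range" in doc:
        lo, hi = doc["maf_range"]
        kwargs["maf_range"] = (float(lo), float(hi))
    if traits:
        kwargs["traits"] = traits
    if R is not None:
        kwargs["genetic_correlation"] = np.asarray(R, dtype=float)
    return SimulationConfig(**kwargs)
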