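"""Synthetic marker and mixed-phenotype data with known genetic structure.

Markers are Hardy-Weinberg binomial dosages. Latent trait values decompose
into environment main effects, line genetic values drawn from the
marker-derived relationship matrix with a configured genetic correlation
across traits, independent per-environment G-by-E deviations, and residual
noise calibrated to a per-trait latent-scale heritability. Binary/ordinal
traits are produced by per-environment quantile discretization of the
latent values, mirroring a liability-threshold construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gpmix.errors import ValidationError
from gpmix.features import compute_grm
from gpmix.markers import MarkerMatrix
from gpmix.phenotypes import PhenotypeTable
from gpmix.traits import TraitSpec


@dataclass(frozen=True)
class SimulatedTrait:
    """One simulated trait: kind, heritability and discretization cuts."""

    name: str
    kind: str = "continuous"
    heritability: float = 0.5
    quantile_cuts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise ValidationError(f"trait {self.name!r}: heritability must be in [0,1]")
        if self.kind == "continuous":
            if self.quantile_cuts is not None:
                raise ValidationError(
                    f"trait {self.name!r}: continuous traits take no quantile cuts"
                )
        elif self.kind in ("binary", "ordinal"):
            cuts = self.quantile_cuts
            if cuts is None or not cuts:
                raise ValidationError(
                    f"trait {self.name!r}: categorical traits need quantile cuts"
                )
            if any(not 0.0 < c < 1.0 for c in cuts) or any(
                b <= a for a, b in zip(cuts, cuts[1:])
            ):
                raise ValidationError(
                    f"trait {self.name!r}: cuts must be strictly increasing in (0,1)"
                )
            if self.kind == "binary" and len(cuts) != 1:
                raise ValidationError(f"trait {self.name!r}: binary needs one cut")
            if self.kind == "ordinal" and len(cuts) < 2:
                raise ValidationError(f"trait {self.name!r}: ordinal needs >= 2 cuts")
        else:
            raise ValidationError(f"trait {self.name!r}: unknown kind {self.kind!r}")

    def to_spec(self) -> TraitSpec:
        if self.kind == "continuous":
            return TraitSpec(self.name, "continuous")
        n_cat = len(self.quantile_cuts) + 1  # type: ignore[arg-type]
        return TraitSpec(self.name, self.kind, n_cat)


@dataclass
class SimulationConfig:
    """Dimensions, genetic architecture and sampling seed."""

    n_lines: int = 100
    n_environments: int = 3
    n_markers: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    traits: list[SimulatedTrait] = field(
        default_factory=lambda: [SimulatedTrait("trait1", "continuous", 0.5)]
    )
    genetic_correlation: np.ndarray | None = None  # default: identity
    gxe_variance_ratio: float = 0.0
    env_effect_scale: float = 1.0
    observed_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_markers < 1 or self.n_environments < 1:
            raise ValidationError("need n_lines >= 2, n_markers >= 1, n_environments >= 1")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValidationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not self.traits:
            raise ValidationError("at least one simulated trait is required")
        if self.gxe_variance_ratio < 0:
            raise ValidationError("gxe_variance_ratio must be >= 0")
        if not 0.0 < self.observed_fraction <= 1.0:
            raise ValidationError("observed_fraction must be in (0, 1]")
        T = len(self.traits)
        if self.genetic_correlation is None:
            self.genetic_correlation = np.eye(T)
        R = np.asarray(self.genetic_correlation, dtype=float)
        if R.shape != (T, T):
            raise ValidationError(f"genetic_correlation must be {T}x{T}")
        if np.abs(R - R.T).max() > 1e-10 or np.abs(np.diag(R) - 1.0).max() > 1e-10:
            raise ValidationError("genetic_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R)[0] < -1e-8:
            raise ValidationError("genetic_correlation must be PSD within 1e-8")
        self.genetic_correlation = R

    @property
    def trait_specs(self) -> list[TraitSpec]:
        return [t.to_spec() for t in self.traits]


@dataclass
class SimulatedDataset:
    """Markers, phenotypes and the underlying truth for recovery testing."""

    markers: MarkerMatrix
    phenotypes: PhenotypeTable
    config: SimulationConfig
    genetic_main: np.ndarray  # (J, T) line genetic values (shared across envs)
    genetic_values: np.ndarray  # (I, J, T) main + G-by-E deviation
    latent: np.ndarray  # (I, J, T) latent phenotypes (env + genetic + noise)
    env_effects: np.ndarray  # (I, T)

    def truth_table(self) -> pd.DataFrame:
        """Long-format true genetic values per line x environment x trait."""
        env_ids = [f"env{i + 1}" for i in range(self.genetic_values.shape[0])]
        rows = []
        for i, env in enumerate(env_ids):
            for j, line in enumerate(self.markers.line_ids):
                row = {"line": line, "environment": env}
                for t, trait in enumerate(self.config.traits):
                    row[trait.name] = self.genetic_values[i, j, t]
                rows.append(row)
        return pd.DataFrame(rows)

    def realized_heritability(self, trait_name: str) -> float:
        """Variance of genetic values over the variance of latent minus env effect."""
        t = [tr.name for tr in self.config.traits].index(trait_name)
        g = self.genetic_values[:, :, t].ravel()
        centered = (self.latent[:, :, t] - self.env_effects[:, t][:, None]).ravel()
        return float(np.var(g) / np.var(centered))

    def realized_genetic_correlation(self, trait_a: str, trait_b: str) -> float:
        names = [tr.name for tr in self.config.traits]
        a, b = names.index(trait_a), names.index(trait_b)
        return float(
            np.corrcoef(self.genetic_main[:, a], self.genetic_main[:, b])[0, 1]
        )


def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Hardy-Weinberg dosages: per-marker frequency ~ U(maf_range), binomial(2, f)."""
    rng = np.random.default_rng(config.seed)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_markers)
    dosages = rng.binomial(2, freqs, size=(config.n_lines, config.n_markers)).astype(float)
    line_ids = [f"L{j + 1:05d}" for j in range(config.n_lines)]
    marker_ids = [f"M{k + 1:05d}" for k in range(config.n_markers)]
    return MarkerMatrix(line_ids, marker_ids, dosages)


def _correlation_chol(R: np.ndarray) -> np.ndarray:
    """Lower Cholesky of a PSD correlation matrix, with minimal jitter."""
    eps = 0.0
    while eps <= 1e-6:
        try:
            return np.linalg.cholesky(R + (eps * np.eye(R.shape[0]) if eps else 0.0))
        except np.linalg.LinAlgError:
            eps = 1e-12 if eps == 0.0 else eps * 100.0
    raise ValidationError("genetic correlation matrix is not PSD")


def discretize_by_quantiles(
    values: np.ndarray, quantile_cuts: tuple[float, ...] | list[float]
) -> np.ndarray:
    """Map values to 1-based categories via empirical quantile thresholds.

    Thresholds are the linear-interpolation empirical quantiles of
    ``values``; a value's category is one plus the number of thresholds
    strictly below it (a value exactly equal to a threshold goes to the
    lower category). Emits a warning, not an error, if ties leave some
    category empty.
    """
    cuts = tuple(quantile_cuts)
    if not cuts or any(not 0.0 < c < 1.0 for c in cuts) or any(
        b <= a for a, b in zip(cuts, cuts[1:])
    ):
        raise ValidationError("quantile cuts must be strictly increasing in (0, 1)")
    values = np.asarray(values, dtype=float)
    if values.size < len(cuts) + 1:
        raise ValidationError(
            f"need at least {len(cuts) + 1} values for {len(cuts)} cuts"
        )
    thresholds = np.quantile(values, cuts)  # linear interpolation convention
    categories = np.searchsorted(thresholds, values, side="left") + 1
    n_cat = len(cuts) + 1
    present = set(categories.tolist())
    empty = [c for c in range(1, n_cat + 1) if c not in present]
    if empty:
        warnings.warn(
            f"quantile discretization left categories {empty} empty (ties)",
            stacklevel=2,
        )
    return categories


def simulate_multitrait_phenotypes(
    markers: MarkerMatrix, config: SimulationConfig
) -> SimulatedDataset:
    """Draw correlated genetic values from the GRM and emit mixed phenotypes.

    Per-trait variance budget on the latent scale: main genetic variance
    ``h2 / (1 + gxe_ratio)``, G-by-E variance ``gxe_ratio`` times that, and
    residual variance ``1 - h2``, so the heritability of (genetic + G-by-E)
    equals ``h2`` and the total latent variance is 1.
    """
    rng = np.random.default_rng(config.seed + 1)
    J, I, T = markers.n_lines, config.n_environments, len(config.traits)
    h2 = np.array([t.heritability for t in config.traits])
    sigma_g2 = h2 / (1.0 + config.gxe_variance_ratio)
    sigma_ge2 = config.gxe_variance_ratio * sigma_g2
    sigma_e2 = 1.0 - h2

    grm = compute_grm(markers)
    L_G = np.linalg.cholesky(grm.G + 1e-6 * np.eye(J))
    L_R = _correlation_chol(np.asarray(config.genetic_correlation, dtype=float))
    C_t = np.diag(np.sqrt(sigma_g2)) @ L_R  # trait-covariance factor

    genetic_main = L_G @ rng.standard_normal((J, T)) @ C_t.T
    env_effects = rng.normal(0.0, config.env_effect_scale, size=(I, T))
    genetic_values = np.empty((I, J, T))
    latent = np.empty((I, J, T))
    for i in range(I):
        ge = L_G @ rng.standard_normal((J, T)) @ np.diag(np.sqrt(sigma_ge2))
        genetic_values[i] = genetic_main + ge
        noise = rng.standard_normal((J, T)) * np.sqrt(sigma_e2)
        latent[i] = env_effects[i] + genetic_values[i] + noise

    # observed subset of the line x environment grid
    n_cells = I * J
    n_obs = int(round(config.observed_fraction * n_cells))
    obs_flat = np.sort(rng.choice(n_cells, size=n_obs, replace=False))
    obs_env, obs_line = np.unravel_index(obs_flat, (I, J))

    env_ids = [f"env{i + 1}" for i in range(I)]
    line_col = [markers.line_ids[j] for j in obs_line]
    env_col = [env_ids[i] for i in obs_env]
    values: dict[str, np.ndarray] = {}
    for t, trait in enumerate(config.traits):
        lat = latent[obs_env, obs_line, t]
        if trait.kind == "continuous":
            values[trait.name] = lat
        else:
            labels = np.empty(n_obs)
            for i in range(I):
                in_env = obs_env == i
                if not in_env.any():
                    continue
                labels[in_env] = discretize_by_quantiles(
                    lat[in_env], trait.quantile_cuts  # type: ignore[arg-type]
                )
            values[trait.name] = labels
    phenotypes = PhenotypeTable(line_col, env_col, values, config.trait_specs)
    return SimulatedDataset(
        markers=markers,
        phenotypes=phenotypes,
        config=config,
        genetic_main=genetic_main,
        genetic_values=genetic_values,
        latent=latent,
        env_effects=env_effects,
    )


def shuffle_phenotypes_within_environments(
    phenotypes: PhenotypeTable, seed: int
) -> PhenotypeTable:
    """Null control: permute trait values across lines within each environment.

    Breaks both the marker-phenotype association and the cross-environment
    coherence of line effects while preserving each environment's value
    distribution.
    """
    rng = np.random.default_rng(seed)
    env_arr = np.array(phenotypes.environment_ids)
    new_values = {k: v.copy() for k, v in phenotypes.values.items()}
    for env in phenotypes.environments:
        idx = np.nonzero(env_arr == env)[0]
        for name in new_values:
            perm = rng.permutation(len(idx))
            new_values[name][idx] = new_values[name][idx[perm]]
    return PhenotypeTable(
        list(phenotypes.line_ids),
        list(phenotypes.environment_ids),
        new_values,
        list(phenotypes.specs),
    )
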