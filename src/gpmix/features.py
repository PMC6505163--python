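"""Genomic relationship matrix, Cholesky features, and network inputs.

The network input is ``X = [ZE | ZG_star | ZGE_star]`` where ``ZE``, ``ZG``
and ``ZGE`` are 0/1 incidence matrices of environments, lines and
(environment, line) cells, ``ZG_star = ZG @ Q.T`` with ``Q`` the upper
Cholesky factor of the genomic relationship matrix ``G`` (so that
``ZG_star @ ZG_star.T == ZG @ G @ ZG.T``), and
``ZGE_star = ZGE @ kron(I, Q.T)``. In mode ``"WI"`` the interaction block
is omitted: ``X = [ZE | ZG_star]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gpmix.errors import ValidationError
from gpmix.markers import MarkerMatrix
from gpmix.phenotypes import PhenotypeTable

INTERACTION_MODES = ("I", "WI")


@dataclass
class GenomicRelationship:
    """Marker-derived covariance among lines (VanRaden method 1)."""

    G: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        J = len(self.line_ids)
        if self.G.shape != (J, J):
            raise ValidationError(f"G must be {J}x{J}, got {self.G.shape}")
        if np.abs(self.G - self.G.T).max() > 1e-10:
            raise ValidationError("G is not symmetric within 1e-10")


@dataclass
class CholeskyFactor:
    """Upper-triangular Q with Q.T @ Q == G (+ jitter on the diagonal)."""

    Q: np.ndarray
    jitter: float

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if np.abs(np.tril(self.Q, k=-1)).max() > 0:
            raise ValidationError("Q must be upper triangular")

    @property
    def dim(self) -> int:
        return self.Q.shape[0]


@dataclass
class DesignAndFeatureMatrices:
    """Incidence matrices and (after assembly) the Cholesky-transformed input."""

    ZE: np.ndarray
    ZG: np.ndarray
    ZGE: np.ndarray
    environment_ids: list[str]
    line_ids: list[str]
    ZG_star: np.ndarray | None = None
    ZGE_star: np.ndarray | None = None
    X: np.ndarray | None = None
    interaction_mode: str | None = None


def compute_grm(markers: MarkerMatrix) -> GenomicRelationship:
    """VanRaden method-1 genomic relationship matrix.

    ``G = W @ W.T / (2 * sum_k p_k (1 - p_k))`` with ``p_k`` the observed
    allele frequency (mean dosage / 2) and ``W`` the column-centered dosage
    matrix. Requires imputed (complete) dosages and at least one polymorphic
    marker.
    """
    M = np.asarray(markers.dosages, dtype=float)
    if np.isnan(M).any():
        raise ValidationError("compute_grm requires imputed (complete) dosages")
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValidationError("all markers are monomorphic; GRM denominator is zero")
    W = M - 2.0 * p
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0  # exact symmetry
    return GenomicRelationship(G, list(markers.line_ids))


def cholesky_upper(
    grm: GenomicRelationship, jitter: float = 1e-6, max_jitter: float = 1e-2
) -> CholeskyFactor:
    """Upper-triangular factor Q with ``Q.T @ Q = G + jitter * I``.

    Jitter is added only if the plain factorization fails, starting at
    ``jitter`` and escalating tenfold up to ``max_jitter``.
    """
    if jitter < 0:
        raise ValidationError("jitter must be >= 0")
    G = grm.G
    try:
        L = np.linalg.cholesky(G)
        return CholeskyFactor(L.T, 0.0)
    except np.linalg.LinAlgError:
        pass
    eps = jitter if jitter > 0 else 1e-6
    eye = np.eye(G.shape[0])
    while eps <= max_jitter:
        try:
            L = np.linalg.cholesky(G + eps * eye)
            return CholeskyFactor(L.T, eps)
        except np.linalg.LinAlgError:
            eps *= 10.0
    smallest = float(np.linalg.eigvalsh(G)[0])
    raise ValidationError(
        f"Cholesky failed up to jitter {max_jitter:g}; "
        f"smallest eigenvalue of G is {smallest:.3e}"
    )


def build_design_matrices(
    phenotypes: PhenotypeTable,
    line_ids: list[str],
    environment_ids: list[str],
) -> DesignAndFeatureMatrices:
    """0/1 incidence matrices ZE (n x I), ZG (n x J) and ZGE (n x I*J).

    The ZGE column for (environment i, line j) is ``i * J + j``
    (environment-major, matching the block structure of ``kron(I_I, Q.T)``).
    One row per phenotype record; each row of each matrix has exactly one 1.
    """
    env_index = {e: i for i, e in enumerate(environment_ids)}
    line_index = {l: j for j, l in enumerate(line_ids)}
    if len(env_index) != len(environment_ids):
        raise ValidationError("duplicated environment IDs")
    if len(line_index) != len(line_ids):
        raise ValidationError("duplicated line IDs")
    n = phenotypes.n_records
    I, J = len(environment_ids), len(line_ids)
    ZE = np.zeros((n, I))
    ZG = np.zeros((n, J))
    ZGE = np.zeros((n, I * J))
    for r, (line, env) in enumerate(phenotypes.record_keys):
        if env not in env_index:
            raise ValidationError(f"record ({line!r}, {env!r}): unknown environment")
        if line not in line_index:
            raise ValidationError(f"record ({line!r}, {env!r}): unknown line")
        i, j = env_index[env], line_index[line]
        ZE[r, i] = 1.0
        ZG[r, j] = 1.0
        ZGE[r, i * J + j] = 1.0
    return DesignAndFeatureMatrices(ZE, ZG, ZGE, list(environment_ids), list(line_ids))


def assemble_feature_matrix(
    design: DesignAndFeatureMatrices,
    Q: CholeskyFactor,
    interaction_mode: str = "I",
) -> DesignAndFeatureMatrices:
    """Complete the feature matrices: ZG_star, ZGE_star and the input X.

    The Kronecker product ``kron(I_I, Q.T)`` is never materialized: each ZGE
    row selects a single (environment, line) cell, so its transformed row is
    the corresponding row of ``Q.T`` placed in that environment's column
    block. The result is identical to the dense computation.
    """
    if interaction_mode not in INTERACTION_MODES:
        raise ValidationError(
            f"interaction_mode must be one of {INTERACTION_MODES}, "
            f"got {interaction_mode!r}"
        )
    J = len(design.line_ids)
    I = len(design.environment_ids)
    if Q.dim != J:
        raise ValidationError(f"Q is {Q.dim}x{Q.dim} but there are {J} lines")
    Qt = Q.Q.T
    ZG_star = design.ZG @ Qt
    design.ZG_star = ZG_star
    design.interaction_mode = interaction_mode
    if interaction_mode == "WI":
        design.ZGE_star = None
        design.X = np.hstack([design.ZE, ZG_star])
        return design
    n = design.ZGE.shape[0]
    ZGE_star = np.zeros((n, I * J))
    rows, cols = np.nonzero(design.ZGE)
    env_of = cols // J
    line_of = cols % J
    for r, i, j in zip(rows, env_of, line_of):
        ZGE_star[r, i * J : (i + 1) * J] = Qt[j]
    design.ZGE_star = ZGE_star
    design.X = np.hstack([design.ZE, ZG_star, ZGE_star])
    return design
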