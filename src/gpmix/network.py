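"""Multi-output dense network with per-trait-type heads, in plain NumPy.

Architecture: a shared trunk of 1-3 fully connected hidden layers (ReLU,
equal unit counts, inverted dropout during training) feeding one output head
per trait. Head activation and loss follow the trait kind: ReLU + squared
error for continuous traits (on the standardized scale), sigmoid + binary
cross-entropy for binary traits, softmax + categorical cross-entropy for
ordinal traits. The total training loss is the unweighted sum over traits of
the mean per-record loss. Optimization is mini-batch Adam; everything is
seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gpmix.errors import ValidationError
from gpmix.phenotypes import PhenotypeTable
from gpmix.traits import TraitSpec, validate_trait_specs

_PROB_EPS = 1e-7


@dataclass
class NetworkConfig:
    """Architecture and optimizer hyperparameters."""

    n_hidden_layers: int = 1
    units: int = 50
    epochs: int = 50
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_layers not in (1, 2, 3):
            raise ValidationError("n_hidden_layers must be 1, 2 or 3")
        if self.units < 1:
            raise ValidationError("units must be >= 1")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass
class NetworkWeights:
    """All weight matrices and bias vectors.

    ``hidden[l] = (W, b)`` maps layer input to layer ``l``'s units;
    ``heads[name] = (W, b)`` maps the last hidden layer to that trait's
    output (width 1, or one unit per ordinal category).
    """

    hidden: list[tuple[np.ndarray, np.ndarray]]
    heads: dict[str, tuple[np.ndarray, np.ndarray]]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            [(W.copy(), b.copy()) for W, b in self.hidden],
            {k: (W.copy(), b.copy()) for k, (W, b) in self.heads.items()},
        )

    @property
    def n_parameters(self) -> int:
        total = sum(W.size + b.size for W, b in self.hidden)
        total += sum(W.size + b.size for W, b in self.heads.values())
        return total

    def _arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for l, (W, b) in enumerate(self.hidden):
            out[f"hidden_{l}_W"] = W
            out[f"hidden_{l}_b"] = b
        for name, (W, b) in self.heads.items():
            out[f"head_{name}_W"] = W
            out[f"head_{name}_b"] = b
        return out

    def save(self, path: str | Path) -> None:
        """Save as a flat key->tensor archive; load() round-trips bit-for-bit."""
        np.savez(path, **self._arrays())

    @classmethod
    def load(cls, path: str | Path) -> "NetworkWeights":
        with np.load(path) as archive:
            arrays = {k: archive[k] for k in archive.files}
        n_hidden = sum(1 for k in arrays if k.startswith("hidden_") and k.endswith("_W"))
        hidden = [
            (arrays[f"hidden_{l}_W"], arrays[f"hidden_{l}_b"])
            for l in range(n_hidden)
        ]
        heads = {}
        for k in arrays:
            if k.startswith("head_") and k.endswith("_W"):
                name = k[len("head_") : -len("_W")]
                heads[name] = (arrays[k], arrays[f"head_{name}_b"])
        return cls(hidden, heads)


@dataclass
class PredictionBundle:
    """Per-trait network outputs.

    Continuous traits: real vector (standardized scale until
    :func:`predict_traits` destandardizes it). Binary traits: probability of
    the upper category. Ordinal traits: row-stochastic probability matrix.
    """

    outputs: dict[str, np.ndarray]

    def validate(self, specs: list[TraitSpec]) -> None:
        for spec in specs:
            out = self.outputs[spec.name]
            if spec.kind == "binary":
                if out.min() < 0 or out.max() > 1:
                    raise ValidationError(f"{spec.name}: probabilities outside [0,1]")
            elif spec.kind == "ordinal":
                if out.min() < 0 or out.max() > 1:
                    raise ValidationError(f"{spec.name}: probabilities outside [0,1]")
                if np.abs(out.sum(axis=1) - 1.0).max() > 1e-6:
                    raise ValidationError(f"{spec.name}: rows do not sum to 1")


def initialize_weights(
    n_inputs: int, specs: list[TraitSpec], config: NetworkConfig
) -> NetworkWeights:
    """Variance-scaled uniform initialization seeded from the config.

    Hidden (ReLU) layers use He-uniform limits sqrt(6 / fan_in); heads use
    Glorot-uniform limits sqrt(6 / (fan_in + fan_out)). Biases start at 0.
    """
    validate_trait_specs(specs)
    rng = np.random.default_rng(config.seed)
    hidden: list[tuple[np.ndarray, np.ndarray]] = []
    fan_in = n_inputs
    for _ in range(config.n_hidden_layers):
        limit = np.sqrt(6.0 / fan_in)
        W = rng.uniform(-limit, limit, size=(fan_in, config.units))
        hidden.append((W, np.zeros(config.units)))
        fan_in = config.units
    heads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for spec in specs:
        width = spec.head_width
        limit = np.sqrt(6.0 / (fan_in + width))
        W = rng.uniform(-limit, limit, size=(fan_in, width))
        heads[spec.name] = (W, np.zeros(width))
    return NetworkWeights(hidden, heads)


# ---------------------------------------------------------------------------
# Target encoding and standardization


def encode_targets(
    phenotypes: PhenotypeTable, specs: list[TraitSpec]
) -> dict[str, np.ndarray]:
    """Encode raw trait columns into training targets.

    Binary labels {1, 2} become scalars {0, 1}; ordinal label c becomes an
    indicator vector with a 1 at position c; continuous values pass through
    unchanged (standardization is a separate, per-training-set step).
    Missing values are rejected: multi-trait training requires a complete
    trait vector per record.
    """
    validate_trait_specs(specs)
    targets: dict[str, np.ndarray] = {}
    for spec in specs:
        vec = phenotypes.values[spec.name]
        if np.isnan(vec).any():
            raise ValidationError(
                f"trait {spec.name!r}: missing values in training records; "
                "complete trait vectors are required"
            )
        if spec.kind == "continuous":
            targets[spec.name] = vec.astype(float)
        elif spec.kind == "binary":
            targets[spec.name] = (vec - 1.0).astype(float)
        else:
            K = spec.n_categories
            onehot = np.zeros((len(vec), K))
            onehot[np.arange(len(vec)), vec.astype(int) - 1] = 1.0
            targets[spec.name] = onehot
    return targets


def standardize_continuous(
    train_values: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, float, float]:
    """Standardize with training-set mean and sample SD (n-1 denominator).

    Returns ``(standardized, mean, sd)`` where ``standardized`` transforms
    ``apply_to`` (default: the training values themselves). The inverse
    transform is ``value * sd + mean``.
    """
    train_values = np.asarray(train_values, dtype=float)
    if train_values.size < 2:
        raise ValidationError("standardization needs >= 2 training values")
    mean = float(train_values.mean())
    sd = float(train_values.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("constant training vector; cannot standardize")
    target = train_values if apply_to is None else np.asarray(apply_to, dtype=float)
    return (target - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# Forward / backward


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=1, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=1, keepdims=True)


def _trunk_forward(
    X: np.ndarray,
    weights: NetworkWeights,
    training_mode: bool,
    dropout_rate: float,
    rng: np.random.Generator | None,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray | None]]:
    """Hidden-layer forward pass; returns (pre-activations, activations, masks)."""
    pre: list[np.ndarray] = []
    act: list[np.ndarray] = [X]
    masks: list[np.ndarray | None] = []
    A = X
    for W, b in weights.hidden:
        Z = A @ W + b
        A = _relu(Z)
        mask = None
        if training_mode and dropout_rate > 0.0:
            if rng is None:
                raise ValidationError("dropout in training mode requires an rng")
            keep = 1.0 - dropout_rate
            mask = (rng.random(A.shape) < keep) / keep
            A = A * mask
        pre.append(Z)
        act.append(A)
        masks.append(mask)
    return pre, act, masks


def _head_forward(
    A_last: np.ndarray, weights: NetworkWeights, specs: list[TraitSpec]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-trait head outputs; returns (net inputs, activated outputs)."""
    nets: dict[str, np.ndarray] = {}
    outs: dict[str, np.ndarray] = {}
    for spec in specs:
        W, b = weights.heads[spec.name]
        H = A_last @ W + b
        nets[spec.name] = H
        if spec.kind == "continuous":
            outs[spec.name] = _relu(H[:, 0])
        elif spec.kind == "binary":
            outs[spec.name] = _sigmoid(H[:, 0])
        else:
            outs[spec.name] = _softmax(H)
    return nets, outs


def forward_pass(
    X: np.ndarray,
    weights: NetworkWeights,
    specs: list[TraitSpec],
    training_mode: bool = False,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PredictionBundle:
    """Full forward pass; deterministic when ``training_mode`` is off.

    Dropout (inverted scaling) is applied after every hidden activation and
    only in training mode; heads apply each trait's output activation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (records x features)")
    W0 = weights.hidden[0][0]
    if X.shape[1] != W0.shape[0]:
        raise ValidationError(
            f"X has {X.shape[1]} features but the network expects {W0.shape[0]}"
        )
    _, act, _ = _trunk_forward(X, weights, training_mode, dropout_rate, rng)
    _, outs = _head_forward(act[-1], weights, specs)
    return PredictionBundle(outs)


def compute_total_loss(
    predictions: PredictionBundle,
    targets: dict[str, np.ndarray],
    specs: list[TraitSpec],
) -> float:
    """Unweighted sum over traits of the mean per-record loss.

    Squared error for continuous traits (standardized scale), binary
    cross-entropy for binary, categorical cross-entropy for ordinal;
    probabilities are clipped to [1e-7, 1 - 1e-7] before logs.
    """
    total = 0.0
    for spec in specs:
        out = predictions.outputs[spec.name]
        y = targets[spec.name]
        if out.shape != y.shape:
            raise ValidationError(
                f"trait {spec.name!r}: prediction shape {out.shape} does not "
                f"match target shape {y.shape}"
            )
        if spec.kind == "continuous":
            total += float(np.mean((out - y) ** 2))
        elif spec.kind == "binary":
            p = np.clip(out, _PROB_EPS, 1.0 - _PROB_EPS)
            total += float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
        else:
            p = np.clip(out, _PROB_EPS, 1.0 - _PROB_EPS)
            total += float(-np.mean(np.sum(y * np.log(p), axis=1)))
    return total


def _batch_gradients(
    X: np.ndarray,
    targets: dict[str, np.ndarray],
    weights: NetworkWeights,
    specs: list[TraitSpec],
    dropout_rate: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Gradients of the total loss for one mini-batch."""
    n = X.shape[0]
    pre, act, masks = _trunk_forward(X, weights, True, dropout_rate, rng)
    nets, _ = _head_forward(act[-1], weights, specs)
    A_last = act[-1]
    dA_last = np.zeros_like(A_last)
    head_grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for spec in specs:
        H = nets[spec.name]
        y = targets[spec.name]
        if spec.kind == "continuous":
            yhat = _relu(H[:, 0])
            dH = (2.0 * (yhat - y) / n * (H[:, 0] > 0))[:, None]
        elif spec.kind == "binary":
            p = _sigmoid(H[:, 0])
            dH = ((p - y) / n)[:, None]
        else:
            P = _softmax(H)
            dH = (P - y) / n
        W, _ = weights.heads[spec.name]
        head_grads[spec.name] = (A_last.T @ dH, dH.sum(axis=0))
        dA_last += dH @ W.T
    hidden_grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(weights.hidden)  # type: ignore[list-item]
    dA = dA_last
    for l in range(len(weights.hidden) - 1, -1, -1):
        if masks[l] is not None:
            dA = dA * masks[l]
        dZ = dA * (pre[l] > 0)
        W, _ = weights.hidden[l]
        hidden_grads[l] = (act[l].T @ dZ, dZ.sum(axis=0))
        dA = dZ @ W.T
    return hidden_grads, head_grads


class _Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_network(
    X: np.ndarray,
    targets: dict[str, np.ndarray],
    config: NetworkConfig,
    specs: list[TraitSpec],
    validation: tuple[np.ndarray, dict[str, np.ndarray]] | None = None,
    initial_weights: NetworkWeights | None = None,
) -> tuple[NetworkWeights, dict[str, list[float]]]:
    """Mini-batch Adam training of the total loss for ``config.epochs`` epochs.

    Weights are initialized from the seeded RNG (or taken from
    ``initial_weights``); with ``epochs=0`` the initialization is returned
    unchanged. The loss trace holds one entry per epoch per split
    (``"train"``, and ``"val"`` when a validation set is given), evaluated
    with dropout off at the end of each epoch.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 1:
        raise ValidationError("training requires at least one record")
    validate_trait_specs(specs)
    if initial_weights is None:
        weights = initialize_weights(X.shape[1], specs, config)
    else:
        weights = initial_weights.copy()
    trace: dict[str, list[float]] = {"train": []}
    if validation is not None:
        trace["val"] = []
    if config.epochs == 0:
        return weights, trace
    train_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0]
    )
    params = [a for pair in weights.hidden for a in pair]
    head_names = [s.name for s in specs]
    params += [a for name in head_names for a in weights.heads[name]]
    opt = _Adam(params, config.learning_rate)
    n = X.shape[0]
    for _epoch in range(config.epochs):
        order = train_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            bt = {k: v[idx] for k, v in targets.items()}
            hg, hd = _batch_gradients(
                X[idx], bt, weights, specs, config.dropout_rate, train_rng
            )
            grads = [a for pair in hg for a in pair]
            grads += [a for name in head_names for a in hd[name]]
            opt.step(grads)
        train_loss = compute_total_loss(forward_pass(X, weights, specs), targets, specs)
        if not np.isfinite(train_loss):
            raise ValidationError(
                "training loss is not finite; try a smaller learning rate"
            )
        trace["train"].append(train_loss)
        if validation is not None:
            Xv, tv = validation
            trace["val"].append(
                compute_total_loss(forward_pass(Xv, weights, specs), tv, specs)
            )
    return weights, trace


def predict_traits(
    X_test: np.ndarray,
    weights: NetworkWeights,
    specs: list[TraitSpec],
    standardization: dict[str, tuple[float, float]] | None = None,
) -> tuple[PredictionBundle, dict[str, np.ndarray]]:
    """Predict and decode: destandardized values and 1-based category labels.

    Continuous predictions are destandardized with the training-fold
    (mean, sd); binary probabilities >= 0.5 decode to category 2; ordinal
    probabilities decode by arg-max with ties going to the lowest category.
    """
    bundle = forward_pass(X_test, weights, specs, training_mode=False)
    decoded: dict[str, np.ndarray] = {}
    outputs: dict[str, np.ndarray] = {}
    for spec in specs:
        out = bundle.outputs[spec.name]
        if spec.kind == "continuous":
            if standardization is None or spec.name not in standardization:
                raise ValidationError(
                    f"trait {spec.name!r}: standardization stats are required "
                    "to destandardize continuous predictions"
                )
            mean, sd = standardization[spec.name]
            values = out * sd + mean
            outputs[spec.name] = values
            decoded[spec.name] = values
        elif spec.kind == "binary":
            outputs[spec.name] = out
            decoded[spec.name] = np.where(out >= 0.5, 2, 1)
        else:
            outputs[spec.name] = out
            decoded[spec.name] = out.argmax(axis=1) + 1
    return PredictionBundle(outputs), decoded
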