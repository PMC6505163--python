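"""Trait specifications: kind, category count, output activation and loss."""

from __future__ import annotations

from dataclasses import dataclass, field

from gpmix.errors import ValidationError

KINDS = ("continuous", "binary", "ordinal")

# kind -> (output activation, loss); fixed by construction, not configurable
_ACTIVATION = {"continuous": "relu", "binary": "sigmoid", "ordinal": "softmax"}
_LOSS = {
    "continuous": "squared_error",
    "binary": "binary_crossentropy",
    "ordinal": "categorical_crossentropy",
}


@dataclass(frozen=True)
class TraitSpec:
    """One output trait: its measurement kind and the induced head.

    Parameters
    ----------
    name:
        Column name in the phenotype table.
    kind:
        ``"continuous"``, ``"binary"`` or ``"ordinal"``.
    n_categories:
        Number of categories; forced to 2 for binary, must be >= 3 for
        ordinal, and absent for continuous traits. Category labels are
        1-based integers ``1..n_categories``.
    """

    name: str
    kind: str
    n_categories: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("trait name must be non-empty")
        if self.kind not in KINDS:
            raise ValidationError(
                f"trait {self.name!r}: kind must be one of {KINDS}, got {self.kind!r}"
            )
        if self.kind == "continuous":
            if self.n_categories is not None:
                raise ValidationError(
                    f"trait {self.name!r}: continuous traits take no n_categories"
                )
        elif self.kind == "binary":
            if self.n_categories is None:
                object.__setattr__(self, "n_categories", 2)
            elif self.n_categories != 2:
                raise ValidationError(
                    f"trait {self.name!r}: binary traits have exactly 2 categories"
                )
        else:  # ordinal
            if self.n_categories is None or self.n_categories < 3:
                raise ValidationError(
                    f"trait {self.name!r}: ordinal traits need n_categories >= 3"
                )

    @property
    def is_categorical(self) -> bool:
        return self.kind in ("binary", "ordinal")

    @property
    def output_activation(self) -> str:
        return _ACTIVATION[self.kind]

    @property
    def loss(self) -> str:
        return _LOSS[self.kind]

    @property
    def head_width(self) -> int:
        """Output units for this trait's head: 1, except one per ordinal category."""
        if self.kind == "ordinal":
            assert self.n_categories is not None
            return self.n_categories
        return 1


def validate_trait_specs(specs: list[TraitSpec]) -> None:
    """Reject empty or duplicated trait lists."""
    if not specs:
        raise ValidationError("at least one trait spec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicated trait names in spec list: {names}")
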