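"""Long-format phenotype tables: one record per (line, environment) cell."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gpmix.errors import ParseError, SchemaError, ValidationError
from gpmix.markers import MISSING_TOKENS, _sniff_delimiter
from gpmix.traits import TraitSpec, validate_trait_specs


@dataclass
class PhenotypeTable:
    """Phenotype records keyed by (line, environment).

    ``values[trait]`` is a float vector aligned with ``line_ids`` /
    ``environment_ids``; categorical labels are stored as 1-based floats
    (1.0, 2.0, ...) and missing values as NaN.
    """

    line_ids: list[str]
    environment_ids: list[str]
    values: dict[str, np.ndarray]
    specs: list[TraitSpec]

    def __post_init__(self) -> None:
        validate_trait_specs(self.specs)
        n = len(self.line_ids)
        if len(self.environment_ids) != n:
            raise ValidationError("line_ids and environment_ids differ in length")
        spec_names = {s.name for s in self.specs}
        if set(self.values) != spec_names:
            raise SchemaError(
                f"trait columns {sorted(self.values)} do not match "
                f"trait specs {sorted(spec_names)}"
            )
        for name, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            self.values[name] = vec
            if vec.shape != (n,):
                raise ValidationError(f"trait {name!r}: expected {n} values")
        keys = list(zip(self.line_ids, self.environment_ids))
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicated (line, environment) record {dup}")
        for spec in self.specs:
            if spec.is_categorical:
                vec = self.values[spec.name]
                obs = vec[~np.isnan(vec)]
                ok = np.isin(obs, np.arange(1, spec.n_categories + 1, dtype=float))
                if not ok.all():
                    bad = obs[~ok][0]
                    raise ValidationError(
                        f"trait {spec.name!r}: label {bad:g} outside "
                        f"1..{spec.n_categories}"
                    )

    @property
    def n_records(self) -> int:
        return len(self.line_ids)

    @property
    def record_keys(self) -> list[tuple[str, str]]:
        return list(zip(self.line_ids, self.environment_ids))

    @property
    def environments(self) -> list[str]:
        """Unique environment IDs in order of first appearance."""
        seen: dict[str, None] = {}
        for e in self.environment_ids:
            seen.setdefault(e)
        return list(seen)

    @property
    def lines(self) -> list[str]:
        """Unique line IDs in order of first appearance."""
        seen: dict[str, None] = {}
        for l in self.line_ids:
            seen.setdefault(l)
        return list(seen)

    def subset(self, index: np.ndarray) -> "PhenotypeTable":
        """Row subset by integer or boolean index, preserving order."""
        idx = np.asarray(index)
        return PhenotypeTable(
            [self.line_ids[i] for i in np.arange(self.n_records)[idx]]
            if idx.dtype == bool
            else [self.line_ids[i] for i in idx],
            [self.environment_ids[i] for i in np.arange(self.n_records)[idx]]
            if idx.dtype == bool
            else [self.environment_ids[i] for i in idx],
            {k: v[idx] for k, v in self.values.items()},
            list(self.specs),
        )


def read_phenotype_table(path: str | Path, specs: list[TraitSpec]) -> PhenotypeTable:
    """Read a long-format phenotype table with columns line, environment, traits.

    Categorical labels are validated against each trait's category count;
    "NA" or empty cells are missing. Duplicate (line, environment) pairs and
    out-of-range labels raise errors.
    """
    validate_trait_specs(specs)
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = [c.strip() for c in next(reader)]
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        required = ["line", "environment"] + [s.name for s in specs]
        missing_cols = [c for c in required if c not in header]
        if missing_cols:
            raise SchemaError(f"{path}: missing required columns {missing_cols}")
        col = {c: header.index(c) for c in required}
        line_ids: list[str] = []
        env_ids: list[str] = []
        values: dict[str, list[float]] = {s.name: [] for s in specs}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"found {len(row)}"
                )
            line_ids.append(row[col["line"]].strip())
            env_ids.append(row[col["environment"]].strip())
            for spec in specs:
                tok = row[col[spec.name]].strip()
                if tok in MISSING_TOKENS:
                    values[spec.name].append(np.nan)
                    continue
                try:
                    val = float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric value {tok!r} "
                        f"for trait {spec.name!r}"
                    ) from None
                if spec.is_categorical and val != int(val):
                    raise ValidationError(
                        f"{path}: line {lineno}: non-integer label {tok!r} "
                        f"for categorical trait {spec.name!r}"
                    )
                values[spec.name].append(val)
    return PhenotypeTable(
        line_ids,
        env_ids,
        {k: np.array(v, dtype=float) for k, v in values.items()},
        list(specs),
    )


def write_phenotype_table(
    table: PhenotypeTable, path: str | Path, sep: str = "\t"
) -> None:
    """Write a table readable back by :func:`read_phenotype_table`."""
    path = Path(path)
    cat = {s.name: s.is_categorical for s in table.specs}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["line", "environment", *[s.name for s in table.specs]])
        for i in range(table.n_records):
            row = [table.line_ids[i], table.environment_ids[i]]
            for spec in table.specs:
                v = table.values[spec.name][i]
                if np.isnan(v):
                    row.append("NA")
                elif cat[spec.name]:
                    row.append(str(int(v)))
                else:
                    row.append(repr(float(v)))
            writer.writerow(row)
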