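"""Marker dosage matrix: parsing, quality control and mode imputation.

Dosages are coded 0/1/2 copies of the reference allele; missing calls are
stored as NaN in a float matrix ("NA" or an empty cell in the input files).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gpmix.errors import ParseError, ValidationError

MISSING_TOKENS = ("", "NA")


@dataclass
class MarkerMatrix:
    """Lines x markers dosage table.

    Attributes
    ----------
    line_ids:
        Unique line identifiers, one per row.
    marker_ids:
        Marker identifiers, one per column.
    dosages:
        Float array of shape ``(n_lines, n_markers)`` with entries in
        ``{0, 1, 2}`` or NaN for missing calls.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D array")
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicated line IDs in marker matrix")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(observed) - {0.0, 1.0, 2.0})
            raise ValidationError(f"dosages outside {{0,1,2}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_marker_table(path: str | Path) -> MarkerMatrix:
    """Read a lines x markers dosage table (CSV or TSV).

    First column holds line IDs; the header row holds marker IDs. Cells are
    0/1/2 or missing ("NA" / empty). Raises :class:`ParseError` on malformed
    rows (with the offending line number) and :class:`ValidationError` on
    out-of-domain dosages or duplicated line IDs.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        marker_ids = [c.strip() for c in header[1:]]
        if not marker_ids:
            raise ParseError(f"{path}: no marker columns in header")
        line_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # trailing blank line
            if len(row) != len(marker_ids) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(marker_ids) + 1} "
                    f"fields, found {len(row)}"
                )
            line_ids.append(row[0].strip())
            vals = []
            for tok in row[1:]:
                tok = tok.strip()
                if tok in MISSING_TOKENS:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric dosage {tok!r}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if len(set(line_ids)) != len(line_ids):
        seen: set[str] = set()
        dup = next(l for l in line_ids if l in seen or seen.add(l))  # type: ignore[func-returns-value]
        raise ValidationError(f"{path}: duplicated line ID {dup!r}")
    return MarkerMatrix(line_ids, marker_ids, np.array(rows, dtype=float))


def write_marker_table(markers: MarkerMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a dosage table readable back by :func:`read_marker_table`."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["line_id", *markers.marker_ids])
        for i, line_id in enumerate(markers.line_ids):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in markers.dosages[i]
            ]
            writer.writerow([line_id, *row])


def _marker_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (missing fraction, MAF, heterozygosity) over non-missing calls."""
    missing = np.isnan(dosages)
    n_lines = dosages.shape[0]
    n_obs = n_lines - missing.sum(axis=0)
    miss_frac = missing.sum(axis=0) / n_lines
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * np.maximum(n_obs, 1))
        maf = np.minimum(p, 1.0 - p)
        het = np.nansum(dosages == 1.0, axis=0) / np.maximum(n_obs, 1)
    # markers with zero observed calls: undefined MAF/het; flag via missingness
    maf = np.where(n_obs == 0, 0.0, maf)
    het = np.where(n_obs == 0, 0.0, het)
    return miss_frac, maf, het


def marker_qc(
    markers: MarkerMatrix,
    max_marker_missing: float = 0.60,
    min_maf: float = 0.05,
    max_het: float = 0.10,
    max_line_missing: float = 0.50,
) -> MarkerMatrix:
    """Filter markers, then lines, by missingness / MAF / heterozygosity.

    A marker is removed when its missing fraction is strictly greater than
    ``max_marker_missing``, its minor allele frequency strictly less than
    ``min_maf``, or its heterozygosity (fraction of dosage-1 calls among
    non-missing calls) strictly greater than ``max_het``. Lines with a
    missing fraction strictly above ``max_line_missing`` across the
    surviving markers are then removed. Ordering of survivors is preserved.
    """
    for name, thr in (
        ("max_marker_missing", max_marker_missing),
        ("min_maf", min_maf),
        ("max_het", max_het),
        ("max_line_missing", max_line_missing),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {thr}")

    miss_frac, maf, het = _marker_stats(markers.dosages)
    keep_markers = ~(
        (miss_frac > max_marker_missing) | (maf < min_maf) | (het > max_het)
    )
    if not keep_markers.any():
        raise ValidationError("marker QC removed every marker")
    dosages = markers.dosages[:, keep_markers]
    marker_ids = [m for m, k in zip(markers.marker_ids, keep_markers) if k]

    line_miss = np.isnan(dosages).sum(axis=1) / dosages.shape[1]
    keep_lines = line_miss <= max_line_missing
    if not keep_lines.any():
        raise ValidationError("marker QC removed every line")
    line_ids = [l for l, k in zip(markers.line_ids, keep_lines) if k]
    return MarkerMatrix(line_ids, marker_ids, dosages[keep_lines])


def impute_markers(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing dosages by the per-marker mode; ties go to the smaller dosage."""
    dosages = markers.dosages.copy()
    n_obs = (~np.isnan(dosages)).sum(axis=0)
    if (n_obs == 0).any():
        bad = markers.marker_ids[int(np.argmax(n_obs == 0))]
        raise ValidationError(
            f"marker {bad!r} has no observed calls; run marker_qc first"
        )
    # counts[d, k] = number of lines with dosage d at marker k
    counts = np.stack([(dosages == d).sum(axis=0) for d in (0.0, 1.0, 2.0)])
    modes = counts.argmax(axis=0).astype(float)  # argmax ties -> smaller dosage
    missing = np.isnan(dosages)
    dosages[missing] = np.broadcast_to(modes, dosages.shape)[missing]
    return MarkerMatrix(list(markers.line_ids), list(markers.marker_ids), dosages)
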