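"""Readers and writers for the delimited-text schemas of the pipeline.

All files are headered delimited text (comma-separated written, tabs
accepted on read, UTF-8, "." decimal).  Readers validate as they parse
and report malformed rows with their line numbers.

Schemas
-------
cross counts        ``cross,wt,wrap,bulky`` with rows AxB, BxC, AxC
dispersal distances ``strain,phenotype,replicate,distance_cm``
germination plates  ``strain,phenotype,carbon_source,concentration_pct,
                    rep1,...,expected,first_day``
contingency tables  headered r x c integer table, first column = row labels
design override     YAML mapping with three 3x6 row-major matrices
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dispersal import DistanceSample
from .germination import GerminationRecord
from .inheritance import CrossCountsTable, GeneticDesign
from .phenotypes import PhenotypeLabel

__all__ = [
    "load_f2_counts",
    "read_counts",
    "write_counts",
    "read_distances",
    "write_distances",
    "read_germination",
    "write_germination",
    "read_contingency",
    "load_design",
]

_CROSS_ROWS = ("AxB", "BxC", "AxC")
_COUNT_COLUMNS = ("cross", "wt", "wrap", "bulky")


class SchemaError(ValueError):
    """Malformed input file; the message carries the file location."""


def _read_delimited(path) -> pd.DataFrame:
    """Read comma- or tab-separated text with a mandatory header row."""
    import csv

    path = Path(path)
    if not path.read_text(encoding="utf-8").strip():
        raise SchemaError(f"{path}: file is empty (missing header row)")
    try:
        frame = pd.read_csv(path, sep=None, engine="python",
                            skip_blank_lines=True)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SchemaError(f"{path}: unreadable header row: {exc}") from None
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    return frame


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}; "
                          f"found {list(frame.columns)}")


def read_counts(path) -> CrossCountsTable:
    """Read a 3-cross phenotype counts table.

    Expects header ``cross,wt,wrap,bulky`` and one row per cross in the
    fixed order AxB, BxC, AxC (labels validated, 'x' case-insensitive).
    """
    frame = _read_delimited(path)
    _require_columns(frame, _COUNT_COLUMNS, path)
    if len(frame) != 3:
        raise SchemaError(f"{path}: expected exactly 3 cross rows, "
                          f"got {len(frame)}")
    counts = np.zeros((3, 3))
    for pos, (_, row) in enumerate(frame.iterrows()):
        line = pos + 2  # header occupies line 1
        label = str(row["cross"]).strip().replace("×", "x").lower()
        if label != _CROSS_ROWS[pos].lower():
            raise SchemaError(
                f"{path}:{line}: expected cross {_CROSS_ROWS[pos]!r} at this "
                f"position, got {row['cross']!r}")
        for j, col in enumerate(("wt", "wrap", "bulky")):
            value = row[col]
            try:
                count = int(value)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}:{line}: count {value!r} in column {col!r} is "
                    "not an integer") from None
            if count < 0:
                raise SchemaError(
                    f"{path}:{line}: negative count {count} in column {col!r}")
            counts[pos, j] = count
    try:
        return CrossCountsTable(counts=counts)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_counts(table: CrossCountsTable, path) -> None:
    frame = pd.DataFrame(table.counts.astype(int),
                         columns=["wt", "wrap", "bulky"])
    frame.insert(0, "cross", list(_CROSS_ROWS))
    frame.to_csv(path, index=False)


def load_f2_counts() -> CrossCountsTable:
    """The packaged F2 progeny phenotype counts of the three crosses."""
    source = resources.files("conidiokit.data") / "f2_counts.csv"
    with resources.as_file(source) as path:
        return read_counts(path)


def read_distances(path) -> list[DistanceSample]:
    """Read per-colony dispersal distances, pooled per strain.

    Expects ``strain,phenotype,replicate,distance_cm``; returns one
    sample per strain with the replicates combined (the standard
    presentation pools biological replicates).
    """
    frame = _read_delimited(path)
    _require_columns(frame, ("strain", "phenotype", "replicate",
                             "distance_cm"), path)
    samples = []
    for strain, group in frame.groupby("strain", sort=False):
        first = group.index[0] + 2
        try:
            phenotype = PhenotypeLabel.parse(group["phenotype"].iloc[0])
        except ValueError as exc:
            raise SchemaError(f"{path}:{first}: {exc}") from None
        distances = pd.to_numeric(group["distance_cm"], errors="coerce")
        if distances.isna().any():
            line = int(distances.index[distances.isna()][0]) + 2
            raise SchemaError(f"{path}:{line}: distance is not a number")
        if (distances < 0).any():
            line = int(distances.index[distances < 0][0]) + 2
            raise SchemaError(f"{path}:{line}: negative distance")
        samples.append(DistanceSample(
            distances=distances.to_numpy(float),
            strain_label=str(strain), phenotype=phenotype))
    return samples


def write_distances(samples: list[DistanceSample], path) -> None:
    rows = []
    for sample in samples:
        for d in sample.distances:
            rows.append({
                "strain": sample.strain_label,
                "phenotype": sample.phenotype.value if sample.phenotype else "",
                "replicate": sample.replicate if sample.replicate is not None else 1,
                "distance_cm": d,
            })
    pd.DataFrame(rows, columns=["strain", "phenotype", "replicate",
                                "distance_cm"]).to_csv(path, index=False)


def read_germination(path) -> list[GerminationRecord]:
    """Read plate-count records with expected colony numbers.

    Expects ``strain,phenotype,carbon_source,concentration_pct,rep1,
    rep2,...,expected,first_day`` (any number of ``rep*`` columns;
    ``first_day`` may be empty).
    """
    frame = _read_delimited(path)
    base = ("strain", "phenotype", "carbon_source", "concentration_pct",
            "expected")
    _require_columns(frame, base, path)
    rep_cols = [c for c in frame.columns if c.startswith("rep")]
    if not rep_cols:
        raise SchemaError(f"{path}: no replicate count columns (rep1, ...)")
    records = []
    for idx, row in frame.iterrows():
        line = idx + 2
        try:
            raw_phenotype = row["phenotype"]
            phenotype = (None if pd.isna(raw_phenotype)
                         or not str(raw_phenotype).strip()
                         else PhenotypeLabel.parse(raw_phenotype))
            reps = tuple(int(row[c]) for c in rep_cols if pd.notna(row[c]))
            day = row.get("first_day")
            first_day = None if pd.isna(day) or day == "" else int(day)
            records.append(GerminationRecord(
                strain=str(row["strain"]),
                phenotype=phenotype,
                carbon_source=str(row["carbon_source"]),
                concentration=float(row["concentration_pct"]),
                replicate_colony_counts=reps,
                expected_colonies=float(row["expected"]),
                first_germination_day=first_day,
            ))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}:{line}: {exc}") from None
    return records


def write_germination(records: list[GerminationRecord], path) -> None:
    n_reps = max(len(r.replicate_colony_counts) for r in records)
    rows = []
    for r in records:
        row = {
            "strain": r.strain,
            "phenotype": r.phenotype.value if r.phenotype else "",
            "carbon_source": r.carbon_source,
            "concentration_pct": r.concentration,
        }
        for k in range(n_reps):
            row[f"rep{k + 1}"] = (r.replicate_colony_counts[k]
                                  if k < len(r.replicate_colony_counts) else "")
        row["expected"] = r.expected_colonies
        row["first_day"] = (r.first_germination_day
                            if r.first_germination_day is not None else "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contingency(path) -> pd.DataFrame:
    """Read a headered contingency table; first column = row labels."""
    frame = _read_delimited(path)
    if frame.shape[1] < 3:
        raise SchemaError(f"{path}: contingency table needs at least two "
                          "category columns besides the row labels")
    frame = frame.set_index(frame.columns[0])
    try:
        return frame.astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric cell in table: {exc}") from None


def load_design(path) -> GeneticDesign:
    """Load a design-matrix override from a YAML mapping.

    The file maps cross labels (AxB, BxC, AxC) to 3x6 row-major
    matrices; column-sum-zero is validated on construction.
    """
    with open(path, "r", encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: expected a mapping of cross -> matrix")
    matrices = []
    for label in _CROSS_ROWS:
        key = next((k for k in payload
                    if str(k).replace("×", "x").lower() == label.lower()),
                   None)
        if key is None:
            raise SchemaError(f"{path}: missing design matrix for {label!r}")
        matrix = np.asarray(payload[key], float)
        if matrix.shape != (3, 6):
            raise SchemaError(
                f"{path}: design matrix for {label!r} must be 3x6, "
                f"got {matrix.shape}")
        matrices.append(matrix)
    try:
        return GeneticDesign(per_cross=np.stack(matrices))
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None
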