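"""CSV/JSON I/O for assay records and mate-choice tables.

The plain-text schemas are defined here (the assays have no standard
community format): assay CSVs carry one replicate per row with integer
count columns ``start_egi, start_wt, offspring_egi, offspring_wt`` plus
optional ``temperature`` and ``replicate``; mate-choice CSVs carry the
four labelled cells ``n_ee, n_ew, n_we, n_ww``.  Unknown columns are
tolerated and preserved as record metadata.  A defensive importer for
spreadsheet workbooks is provided for raw-data supplements.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .fitting import AssayRecord, FitResult
from .matestats import MatingCountTable

__all__ = [
    "RunConfig",
    "read_assay_csv",
    "write_assay_csv",
    "read_mating_table_csv",
    "write_mating_table_csv",
    "write_fit_json",
    "import_workbook",
    "file_digest",
]

logger = logging.getLogger(__name__)

REQUIRED_ASSAY_COLUMNS = ("start_egi", "start_wt", "offspring_egi", "offspring_wt")
OPTIONAL_ASSAY_COLUMNS = ("temperature", "replicate")
MATING_COLUMNS = ("n_ee", "n_ew", "n_we", "n_ww")

PathLike = Union[str, Path]


class AssayParseError(ValueError):
    """A CSV row or column violates the assay-record schema."""


@dataclass
class RunConfig:
    """Settings shared across CLI subcommands; loadable from YAML."""

    seed: Optional[int] = None
    variant: str = "F_and_c"
    max_iter: int = 100
    step_tol: float = 1e-8
    n_sims: int = 100_000
    fisher_alternative: str = "two_sided"
    preset: str = "vial40"
    mean_offspring_per_female: float = 78.6 / 20.0
    report_decimals: int = 4
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require_int(value, row: int, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise AssayParseError(
            f"row {row}, column {column!r}: {value!r} is not a number"
        ) from None
    if pd.isna(f):
        raise AssayParseError(f"row {row}, column {column!r}: missing value")
    if f != int(f):
        raise AssayParseError(
            f"row {row}, column {column!r}: count {value!r} is not an integer"
        )
    if f < 0:
        raise AssayParseError(
            f"row {row}, column {column!r}: count {value!r} is negative"
        )
    return int(f)


def read_assay_csv(path: PathLike) -> list:
    """Read assay records from CSV, validating counts row by row.

    Malformed cells raise :class:`AssayParseError` naming the 1-based data
    row and column.  Extra columns are preserved in ``record.extra``.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise AssayParseError(f"missing required column(s): {missing}")
    extra_cols = [
        c
        for c in df.columns
        if c not in REQUIRED_ASSAY_COLUMNS + OPTIONAL_ASSAY_COLUMNS
    ]
    records = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        vals = {c: _require_int(row[c], i, c) for c in REQUIRED_ASSAY_COLUMNS}
        temp = row.get("temperature")
        if temp is not None and pd.isna(temp):
            temp = None
        rep = row.get("replicate")
        if rep is not None and pd.isna(rep):
            rep = None
        records.append(
            AssayRecord(
                **vals,
                temperature=None if temp is None else float(temp),
                replicate=None if rep is None else str(rep),
                extra={c: row[c] for c in extra_cols},
            )
        )
    logger.info("read %d assay record(s) from %s", len(records), path)
    return records


def write_assay_csv(records: Iterable[AssayRecord], path: PathLike) -> None:
    """Write assay records to CSV (lossless round-trip with the reader)."""
    rows = []
    for r in records:
        row = {
            "start_egi": r.start_egi,
            "start_wt": r.start_wt,
            "offspring_egi": r.offspring_egi,
            "offspring_wt": r.offspring_wt,
        }
        if r.temperature is not None:
            row["temperature"] = r.temperature
        if r.replicate is not None:
            row["replicate"] = r.replicate
        row.update(r.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mating_table_csv(path: PathLike) -> MatingCountTable:
    """Read a single 2x2 mate-choice table (columns n_ee, n_ew, n_we, n_ww)."""
    df = pd.read_csv(path)
    missing = [c for c in MATING_COLUMNS if c not in df.columns]
    if missing:
        raise AssayParseError(f"missing required column(s): {missing}")
    if len(df) != 1:
        raise AssayParseError(f"expected exactly one data row, found {len(df)}")
    row = df.iloc[0]
    cells = {c: _require_int(row[c], 1, c) for c in MATING_COLUMNS}
    labels = ("EGI", "wt")
    if "label_a" in df.columns and "label_b" in df.columns:
        labels = (str(row["label_a"]), str(row["label_b"]))
    return MatingCountTable(**cells, labels=labels)


def write_mating_table_csv(table: MatingCountTable, path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "n_ee": table.n_ee,
                "n_ew": table.n_ew,
                "n_we": table.n_we,
                "n_ww": table.n_ww,
                "label_a": table.labels[0],
                "label_b": table.labels[1],
            }
        ]
    ).to_csv(path, index=False)


def write_fit_json(fit: FitResult, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")


def import_workbook(path: PathLike, sheet: Optional[str] = None) -> list:
    """Best-effort importer for a raw-data spreadsheet workbook.

    Scans the given sheet (or every sheet) for a header row containing the
    four required assay-count columns, case-insensitively, and parses the
    rows beneath it.  The upstream workbook layout is not standardized, so
    this reader is defensive: it raises with a clear message when no sheet
    matches rather than guessing.
    """
    xls = pd.ExcelFile(path, engine="openpyxl")
    sheets = [sheet] if sheet is not None else xls.sheet_names
    wanted = {c.lower() for c in REQUIRED_ASSAY_COLUMNS}
    for name in sheets:
        df = xls.parse(name)
        cols = {str(c).strip().lower(): c for c in df.columns}
        if wanted <= set(cols):
            df = df.rename(columns={cols[w]: w for w in wanted})
            tmp = Path(path).with_suffix(".import.tmp.csv")
            try:
                df.to_csv(tmp, index=False)
                return read_assay_csv(tmp)
            finally:
                tmp.unlink(missing_ok=True)
    raise AssayParseError(
        f"no sheet in {path} contains the columns {sorted(wanted)}; "
        "export the relevant sheet to CSV with those headers instead"
    )


def file_digest(path: PathLike) -> str:
    """SHA-256 digest of a file, for reproducibility logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
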