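"""Reading and writing the five-column pre/postoperative cylinder dataset.

The reference dialect is a single-worksheet XLSX with columns A–E:

    eye ("OD"/"OS"), preop magnitude (D), preop axis (°),
    postop magnitude (D), postop axis (°)

and **no header row**.  A CSV dialect (comma-separated, UTF-8, same five
columns, no header) is supported for convenience.  Numbers must use
point-decimal notation; comma decimals are rejected with an explicit
error rather than silently discarded.  Rows with a missing, blank or
non-numeric cell, an unrecognized eye label, or an out-of-range value
are discarded, logged with their 1-based row number, and counted.
"""

from __future__ import annotations

import csv
import datetime
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import openpyxl

from .vectors import CylinderReading, EyeRecord

__all__ = [
    "Dataset",
    "DataFormatError",
    "EmptyDatasetError",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)

_COMMA_DECIMAL_RE = re.compile(r"^\s*[+-]?\d+,\d+\s*$")

# Fixed workbook timestamp so identical datasets serialize byte-identically.
_FIXED_STAMP = datetime.datetime(2000, 1, 1)


class DataFormatError(ValueError):
    """The input file does not conform to the five-column format."""


class EmptyDatasetError(DataFormatError):
    """No parseable data rows remain after validation."""


@dataclass
class Dataset:
    """An ordered collection of validated eye records.

    ``n_discarded`` counts non-empty rows dropped during reading, so
    that rows_in_file == len(records) + n_discarded.  Only ``records``
    participate in equality: two datasets with the same eyes are equal
    regardless of provenance.
    """

    records: list[EyeRecord]
    n_discarded: int = field(default=0, compare=False)
    source_path: Optional[Path] = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.records)


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("xlsx", "csv"):
            raise ValueError(f"dialect must be 'xlsx' or 'csv', got {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        return "xlsx"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer dialect from extension {suffix!r}; pass dialect=")


def _raw_rows_xlsx(path: Path) -> list[list[object]]:
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        ws = wb.worksheets[0]
        return [list(row) for row in ws.iter_rows(values_only=True)]
    finally:
        wb.close()


def _raw_rows_csv(path: Path) -> list[list[object]]:
    with open(path, newline="", encoding="utf-8-sig") as fh:
        return [list(row) for row in csv.reader(fh)]


def _parse_number(cell: object) -> float:
    """Parse one numeric cell; None on missing/blank, raises on comma decimals."""
    if cell is None:
        raise _MissingCell()
    if isinstance(cell, (int, float)):
        value = float(cell)
    else:
        text = str(cell).strip()
        if not text:
            raise _MissingCell()
        if _COMMA_DECIMAL_RE.match(text):
            raise DataFormatError(
                f"comma-decimal value {text!r}: please use point decimal "
                "notation (e.g. 1.50, not 1,50)"
            )
        try:
            value = float(text)
        except ValueError:
            raise _NonNumericCell(text) from None
    if not math.isfinite(value):
        raise _NonNumericCell(repr(cell))
    return value


class _MissingCell(Exception):
    pass


class _NonNumericCell(Exception):
    def __init__(self, text: str):
        self.text = text


def _normalize_width(row: Sequence[object], row_no: int) -> list[object]:
    """Trim trailing empty cells and pad to five columns; error otherwise."""
    cells = list(row)
    while cells and (cells[-1] is None or (isinstance(cells[-1], str) and not cells[-1].strip())):
        cells.pop()
    if len(cells) > 5:
        raise DataFormatError(
            f"row {row_no}: expected 5 columns "
            f"(eye, preop magnitude, preop axis, postop magnitude, postop axis), "
            f"found {len(cells)}"
        )
    cells.extend([None] * (5 - len(cells)))
    return cells


def _looks_like_header(cells: list[object]) -> bool:
    """True if every numeric column of the row holds non-numeric text."""
    n_text = 0
    for cell in cells[1:5]:
        try:
            _parse_number(cell)
        except (_NonNumericCell, DataFormatError):
            n_text += 1
        except _MissingCell:
            return False
    return n_text == 4


def read_dataset(
    path, dialect: Optional[str] = None, max_magnitude: float = 30.0
) -> Dataset:
    """Read and validate a five-column pre/postoperative dataset.

    Rows are kept in file order.  Any non-empty row with a missing,
    blank or non-numeric cell in columns 2–5, an eye label other than
    OD/OS (case-insensitive), or a value outside the sanity bounds
    (|magnitude| < ``max_magnitude`` D, axis in [0, 180]) is discarded,
    logged, and counted in ``n_discarded``.  Eyes with 0.00 D of
    astigmatism are **not** auto-discarded.

    Raises :class:`DataFormatError` on a header-looking first row, a
    wrong column count, or comma-decimal notation, and
    :class:`EmptyDatasetError` when no parseable rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _infer_dialect(path, dialect)
    raw = _raw_rows_xlsx(path) if kind == "xlsx" else _raw_rows_csv(path)

    # Keep only non-empty rows, remembering original 1-based positions.
    rows: list[tuple[int, list[object]]] = []
    for i, row in enumerate(raw, start=1):
        if all(c is None or (isinstance(c, str) and not c.strip()) for c in row):
            continue
        rows.append((i, _normalize_width(row, i)))
    if not rows:
        raise EmptyDatasetError(f"{path}: empty dataset (no data rows)")

    if _looks_like_header(rows[0][1]):
        raise DataFormatError(
            f"{path}: first row looks like a header ({rows[0][1]!r}); the format "
            "has no header row — remove the header row from the file"
        )

    records: list[EyeRecord] = []
    n_discarded = 0
    for row_no, cells in rows:
        record = _parse_row(row_no, cells, max_magnitude)
        if record is None:
            n_discarded += 1
        else:
            records.append(record)

    if not records:
        raise EmptyDatasetError(
            f"{path}: empty dataset ({n_discarded} rows discarded, none parseable)"
        )
    return Dataset(records=records, n_discarded=n_discarded, source_path=path)


def _parse_row(
    row_no: int, cells: list[object], max_magnitude: float
) -> Optional[EyeRecord]:
    eye_raw = cells[0]
    eye = str(eye_raw).strip().upper() if eye_raw is not None else ""
    if eye not in ("OD", "OS"):
        logger.warning("row %d discarded: eye label %r is not OD/OS", row_no, eye_raw)
        return None
    names = ("preop magnitude", "preop axis", "postop magnitude", "postop axis")
    values = []
    for name, cell in zip(names, cells[1:5]):
        try:
            values.append(_parse_number(cell))
        except _MissingCell:
            logger.warning("row %d discarded: missing %s", row_no, name)
            return None
        except _NonNumericCell as exc:
            logger.warning("row %d discarded: non-numeric %s %r", row_no, name, exc.text)
            return None
    try:
        preop = CylinderReading(values[0], values[1], max_magnitude=max_magnitude)
        postop = CylinderReading(values[2], values[3], max_magnitude=max_magnitude)
    except ValueError as exc:
        logger.warning("row %d discarded: %s", row_no, exc)
        return None
    return EyeRecord(eye=eye, preop=preop, postop=postop, source_row=row_no)  # type: ignore[arg-type]


def write_dataset(dataset: Dataset, path, dialect: Optional[str] = None) -> Path:
    """Write a dataset back out in the five-column format.

    The written file re-reads (via :func:`read_dataset`) to an equal
    dataset.  XLSX output pins the workbook timestamps so identical
    datasets produce byte-identical files.
    """
    if not dataset.records:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    kind = _infer_dialect(path, dialect)
    if kind == "xlsx":
        wb = openpyxl.Workbook()
        wb.properties.created = _FIXED_STAMP
        wb.properties.modified = _FIXED_STAMP
        ws = wb.active
        for rec in dataset.records:
            ws.append(
                [rec.eye, rec.preop.magnitude, rec.preop.axis,
                 rec.postop.magnitude, rec.postop.axis]
            )
        wb.save(path)
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            for rec in dataset.records:
                writer.writerow(
                    [rec.eye, repr(rec.preop.magnitude), repr(rec.preop.axis),
                     repr(rec.postop.magnitude), repr(rec.postop.axis)]
                )
    return path
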