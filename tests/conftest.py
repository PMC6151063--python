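"""Shared fixtures: programmatically built data files and cohorts."""

from __future__ import annotations

import csv

import openpyxl
import pytest

from astigvec.synthetic import CohortParams, generate_cohort

# Reproduction of the documented example file: row 1 is a complete
# unambiguous substitute (the published row is typographically garbled),
# row 2 has a missing postoperative axis and must be discarded, rows 3-4
# use negative-cylinder notation.
TABLE1_ROWS = [
    ["OD", 0.25, 70, 0.0, 0],
    ["OS", 0.75, 88, -0.25, None],
    ["OD", -2.00, 90, 0.0, 0],
    ["OS", -1.00, 180, 0.0, 0],
]


def write_rows_xlsx(path, rows):
    wb = openpyxl.Workbook()
    ws = wb.active
    for row in rows:
        ws.append(row)
    wb.save(path)
    return path


def write_rows_csv(path, rows):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        for row in rows:
            writer.writerow(["" if c is None else c for c in row])
    return path


@pytest.fixture
def table1_xlsx(tmp_path):
    return write_rows_xlsx(tmp_path / "table1.xlsx", TABLE1_ROWS)


@pytest.fixture
def table1_csv(tmp_path):
    return write_rows_csv(tmp_path / "table1.csv", TABLE1_ROWS)


@pytest.fixture
def wtr_cohort():
    """25-eye with-the-rule cohort with known ground truth, no rounding."""
    return generate_cohort(
        CohortParams(astig_type="WTR", seed=42, round_clinical=False,
                     correction_ratio=0.9, postop_axis_noise_sd=0.0)
    )
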