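"""Variant notation and cohort table input/output.

Variant grammar (whitespace-tolerant, case-insensitive prefix)::

    del:<a>        single-exon deletion          e.g. "del:52"
    del:<a>-<b>    multi-exon deletion           e.g. "del:45-47"
    dup:<a>        single-exon duplication       e.g. "dup:2"
    dup:<a>-<b>    multi-exon duplication        e.g. "dup:3-7"
    point          point mutation (not scoreable by the exon frame rule)

Cohort tables are TSV (canonical) or CSV (sniffed on read), UTF-8, one row
per patient, empty cell = missing; booleans are 0/1.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import re
from pathlib import Path

from .classify import POINT_MUTATION, PatientRecord
from .gene_model import N_EXONS, VariantEvent, VariantKind

__all__ = [
    "COHORT_COLUMNS",
    "CohortFormatError",
    "VariantParseError",
    "format_variant",
    "parse_variant",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger("dmdframe")

COHORT_COLUMNS = (
    "patient_id",
    "sex",
    "variant",
    "first_walking_age_months",
    "onset_age_years",
    "diagnosis_age_years",
    "ck_u_per_l",
    "ambulation_lost",
    "age_at_ambulation_loss_years",
    "age_at_last_followup_years",
)


class VariantParseError(ValueError):
    """Malformed variant notation."""


class CohortFormatError(ValueError):
    """Cohort file violates the schema; carries per-row messages."""

    def __init__(self, message: str, row_errors: list[str] | None = None) -> None:
        self.row_errors = row_errors or []
        if self.row_errors:
            message = message + "\n  " + "\n  ".join(self.row_errors)
        super().__init__(message)


_RANGE_RE = re.compile(r"^(del|dup)\s*:\s*(\d+)\s*(?:-\s*(\d+)\s*)?$")


def parse_variant(raw: str) -> VariantEvent | str:
    """Parse variant notation; returns a :class:`VariantEvent` or the
    point-mutation marker."""
    text = raw.strip().lower()
    if text == "point":
        return POINT_MUTATION
    m = _RANGE_RE.match(text)
    if not m:
        raise VariantParseError(
            f"unrecognised variant notation {raw!r} "
            "(expected del:<a>[-<b>], dup:<a>[-<b>], or point)"
        )
    kind = VariantKind.DELETION if m.group(1) == "del" else VariantKind.DUPLICATION
    start = int(m.group(2))
    end = int(m.group(3)) if m.group(3) is not None else start
    for value in (start, end):
        if not 1 <= value <= N_EXONS:
            raise VariantParseError(f"exon {value} out of range 1..{N_EXONS} in {raw!r}")
    if start > end:
        raise VariantParseError(
            f"reversed exon range in {raw!r}: {start} > {end} (write {end}-{start})"
        )
    return VariantEvent(kind=kind, start_exon=start, end_exon=end)


def format_variant(variant: VariantEvent | str) -> str:
    if variant == POINT_MUTATION:
        return "point"
    prefix = "del" if variant.kind is VariantKind.DELETION else "dup"
    if variant.start_exon == variant.end_exon:
        return f"{prefix}:{variant.start_exon}"
    return f"{prefix}:{variant.start_exon}-{variant.end_exon}"


def _parse_float(cell: str, column: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValueError(f"non-numeric {column}: {cell!r}") from exc


def _parse_bool(cell: str, column: str) -> bool:
    cell = cell.strip().lower()
    if cell in ("1", "true", "yes"):
        return True
    if cell in ("", "0", "false", "no"):
        return False
    raise ValueError(f"non-boolean {column}: {cell!r}")


def _record_from_row(row: dict[str, str]) -> PatientRecord:
    walk = _parse_float(row["first_walking_age_months"], "first_walking_age_months")
    followup = _parse_float(
        row["age_at_last_followup_years"], "age_at_last_followup_years"
    )
    if followup is None:
        raise ValueError("age_at_last_followup_years is required")
    return PatientRecord(
        patient_id=row["patient_id"].strip(),
        sex=row["sex"].strip().lower(),
        variant=parse_variant(row["variant"]),
        first_walking_age_months=walk,
        onset_age_years=_parse_float(row["onset_age_years"], "onset_age_years"),
        diagnosis_age_years=_parse_float(
            row["diagnosis_age_years"], "diagnosis_age_years"
        ),
        ck_u_per_l=_parse_float(row["ck_u_per_l"], "ck_u_per_l"),
        ambulation_lost=_parse_bool(row["ambulation_lost"], "ambulation_lost"),
        age_at_ambulation_loss_years=_parse_float(
            row["age_at_ambulation_loss_years"], "age_at_ambulation_loss_years"
        ),
        age_at_last_followup_years=followup,
    )


def read_cohort(path: str | Path, skip_bad_rows: bool = False) -> list[PatientRecord]:
    """Read and validate a cohort TSV/CSV.

    All-or-nothing by default: any malformed row raises
    :class:`CohortFormatError` listing every offending line.  With
    ``skip_bad_rows`` the bad rows are logged and dropped instead.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first_line = text.splitlines()[0] if text.splitlines() else ""
    delimiter = "\t" if "\t" in first_line else ","

    reader = csv.DictReader(_io.StringIO(text), delimiter=delimiter)
    header = tuple(reader.fieldnames or ())
    unknown = [c for c in header if c not in COHORT_COLUMNS]
    missing = [c for c in COHORT_COLUMNS if c not in header]
    if unknown or missing:
        parts = []
        if unknown:
            parts.append(f"unknown column(s) {unknown}")
        if missing:
            parts.append(f"missing column(s) {missing}")
        raise CohortFormatError(f"{path}: " + "; ".join(parts))

    records: list[PatientRecord] = []
    row_errors: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            row_errors.append(f"line {lineno}: {exc}")
    if row_errors:
        if not skip_bad_rows:
            raise CohortFormatError(f"{path}: {len(row_errors)} bad row(s)", row_errors)
        for msg in row_errors:
            logger.warning("%s: skipped %s", path, msg)
    return records


def _fmt(value: float | bool | str | None) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(records: list[PatientRecord], path: str | Path) -> None:
    """Write records as canonical TSV; :func:`read_cohort` round-trips it."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.sex,
                    format_variant(r.variant),
                    _fmt(r.first_walking_age_months),
                    _fmt(r.onset_age_years),
                    _fmt(r.diagnosis_age_years),
                    _fmt(r.ck_u_per_l),
                    _fmt(r.ambulation_lost),
                    _fmt(r.age_at_ambulation_loss_years),
                    _fmt(r.age_at_last_followup_years),
                ]
            )
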