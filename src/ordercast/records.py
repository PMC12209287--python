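"""Judgment-record schema and CSV input/output.

A :class:`JudgmentRecord` holds one Superior Court treatment-order
judgment: who the defendant is, what was diagnosed and requested, and
what the court decided.  Files are plain RFC-4180 CSV with one column
per variable; list-valued cells (comorbidities, substances, accessory
requests) use ``;`` as the internal separator.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import (
    NoModellableCasesError,
    RecordParseError,
    RecordValidationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Canonical column headers, in file order, mapped to record field names.
COLUMNS: dict[str, str] = {
    "Was the defendant represented?": "represented",
    "If represented was it by legal aid?": "legal_aid",
    "Age of the defendant": "age_years",
    "Sex of the defendant": "sex",
    "Main diagnosis of the defendant": "main_diagnosis",
    "Other diagnoses listed": "other_diagnoses",
    "Symptoms and signs": "symptoms_text",
    "Was substance use reported?": "substance_use_reported",
    "If so, what are the substances listed": "substances",
    "Was it a treatment order request or was it treatment and housing?": "request_type",
    "What treatment is requested": "treatment_requested",
    "What are the accessory requests (e.g., blood samples, urinary tests, ECT, etc)": "accessory_requests",
    "What was the time (in years) requested by the treating team": "time_requested_years",
    "Was the request accepted or denied?": "decision",
    "Number of time granted (in years)": "time_granted_years",
    "If accepted, was it partially or entirely?": "acceptance_extent",
}

LIST_SEPARATOR = ";"

_TRUE = {"yes", "y", "1", "true", "oui"}
_FALSE = {"no", "n", "0", "false", "non", ""}


@dataclass
class JudgmentRecord:
    """One treatment-order judgment (one row of the dataset)."""

    represented: bool
    legal_aid: bool
    age_years: float
    sex: str                      # "male" | "female"
    main_diagnosis: str
    other_diagnoses: list[str]
    symptoms_text: str
    substance_use_reported: bool
    substances: list[str]
    request_type: str             # "treatment" | "treatment_and_housing"
    treatment_requested: str
    accessory_requests: list[str]
    time_requested_years: float
    decision: str                 # "accepted" | "denied"
    time_granted_years: float
    acceptance_extent: str        # "entire" | "partial" | "not_applicable"

    def validate(self) -> "JudgmentRecord":
        """Check schema invariants; return self for chaining."""
        if not 0 <= self.age_years <= 130:
            raise RecordValidationError(
                f"age_years={self.age_years} outside [0, 130]")
        for name in ("time_requested_years", "time_granted_years"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise RecordValidationError(f"{name}={v} outside [0, 10]")
        if self.sex not in ("male", "female"):
            raise RecordValidationError(f"sex={self.sex!r}")
        if self.request_type not in ("treatment", "treatment_and_housing"):
            raise RecordValidationError(f"request_type={self.request_type!r}")
        if self.decision not in ("accepted", "denied"):
            raise RecordValidationError(f"decision={self.decision!r}")
        if self.acceptance_extent not in ("entire", "partial", "not_applicable"):
            raise RecordValidationError(
                f"acceptance_extent={self.acceptance_extent!r}")
        if (self.acceptance_extent == "not_applicable") != (self.decision == "denied"):
            raise RecordValidationError(
                "acceptance_extent must be not_applicable exactly when the "
                f"request was denied (got extent={self.acceptance_extent!r}, "
                f"decision={self.decision!r})")
        return self


def _parse_bool(cell: str) -> bool:
    s = cell.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {cell!r}")


def _parse_list(cell: str) -> list[str]:
    return [p.strip() for p in cell.split(LIST_SEPARATOR) if p.strip()]


def _parse_sex(cell: str) -> str:
    s = cell.strip().lower()
    if s in ("male", "m", "homme"):
        return "male"
    if s in ("female", "f", "femme"):
        return "female"
    raise ValueError(f"not a sex value: {cell!r}")


def _parse_request_type(cell: str) -> str:
    s = " ".join(cell.strip().lower().split())
    if s in ("treatment", "treatment order", "treatment_only"):
        return "treatment"
    if s in ("treatment and housing", "treatment_and_housing",
             "treatment plus housing", "treatment order plus housing"):
        return "treatment_and_housing"
    raise ValueError(f"not a request type: {cell!r}")


def _parse_decision(cell: str) -> str:
    s = cell.strip().lower()
    if s in ("accepted", "accept", "granted"):
        return "accepted"
    if s in ("denied", "deny", "refused", "rejected"):
        return "denied"
    raise ValueError(f"not a decision: {cell!r}")


def _parse_extent(cell: str) -> str:
    s = cell.strip().lower()
    if s in ("entirely", "entire", "fully", "full"):
        return "entire"
    if s in ("partially", "partial"):
        return "partial"
    if s in ("", "not applicable", "n/a", "na", "not_applicable"):
        return "not_applicable"
    raise ValueError(f"not an acceptance extent: {cell!r}")


_PARSERS = {
    "represented": _parse_bool,
    "legal_aid": _parse_bool,
    "age_years": float,
    "sex": _parse_sex,
    "main_diagnosis": str.strip,
    "other_diagnoses": _parse_list,
    "symptoms_text": str.strip,
    "substance_use_reported": _parse_bool,
    "substances": _parse_list,
    "request_type": _parse_request_type,
    "treatment_requested": str.strip,
    "accessory_requests": _parse_list,
    "time_requested_years": float,
    "decision": _parse_decision,
    "time_granted_years": float,
    "acceptance_extent": _parse_extent,
}


def read_records(
    path: str | Path,
    header_map: Mapping[str, str] | None = None,
    validate: bool = True,
) -> list[JudgmentRecord]:
    """Read judgment records from a CSV file.

    Parameters
    ----------
    path
        CSV file with the canonical column headers (one per variable).
    header_map
        Optional mapping from alternative headers (e.g. French ones) to
        the canonical English headers, applied before schema checking.
    validate
        Run :meth:`JudgmentRecord.validate` on every row.

    Raises
    ------
    SchemaError
        If a required column is missing from the header row.
    RecordParseError
        If a cell cannot be parsed; names the row and the field.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if header_map:
            header = [header_map.get(h, h) for h in header]
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        canonical_of = {orig: mapped for orig, mapped
                        in zip(reader.fieldnames or [], header)}
        records = []
        for i, row in enumerate(reader):
            kwargs = {}
            for orig, cell in row.items():
                column = canonical_of.get(orig, orig)
                fieldname = COLUMNS.get(column)
                if fieldname is None:
                    continue  # extra columns are ignored
                parser = _PARSERS[fieldname]
                try:
                    kwargs[fieldname] = parser(cell if cell is not None else "")
                except (ValueError, TypeError) as exc:
                    raise RecordParseError(i, fieldname, str(exc)) from exc
            rec = JudgmentRecord(**kwargs)
            if validate:
                try:
                    rec.validate()
                except RecordValidationError as exc:
                    raise RecordParseError(i, "record", str(exc)) from exc
            records.append(rec)
    return records


def _format_cell(fieldname: str, value) -> str:
    if fieldname in ("represented", "legal_aid", "substance_use_reported"):
        return "yes" if value else "no"
    if fieldname in ("other_diagnoses", "substances", "accessory_requests"):
        return LIST_SEPARATOR.join(value)
    if fieldname == "request_type":
        return {"treatment": "Treatment",
                "treatment_and_housing": "Treatment and housing"}[value]
    if fieldname == "decision":
        return value.capitalize()
    if fieldname == "acceptance_extent":
        return {"entire": "Entirely", "partial": "Partially",
                "not_applicable": "Not applicable"}[value]
    if fieldname in ("age_years", "time_requested_years", "time_granted_years"):
        return format(value, "g")
    return str(value)


def write_records(records: Iterable[JudgmentRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical headers (round-trips with
    :func:`read_records`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS.keys())
        for rec in records:
            writer.writerow(_format_cell(f, getattr(rec, f))
                            for f in COLUMNS.values())


def filter_modellable(records: Sequence[JudgmentRecord]) -> list[JudgmentRecord]:
    """Keep only cases the outcome model applies to: accepted requests
    resolved as entire or partial acceptance.

    Denied requests carry no entire-vs-partial outcome and are dropped
    (the count is logged so corpus statistics stay reportable).

    Raises
    ------
    NoModellableCasesError
        If no record survives the filter.
    """
    kept = [r for r in records
            if r.decision == "accepted"
            and r.acceptance_extent in ("entire", "partial")]
    excluded = len(records) - len(kept)
    if excluded:
        logger.info("filter_modellable: excluded %d non-modellable record(s)",
                    excluded)
    if not kept:
        raise NoModellableCasesError(
            "no modellable cases: every record is denied or lacks an "
            "entire/partial outcome")
    return kept
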