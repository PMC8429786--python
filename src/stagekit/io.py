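"""CSV/JSON readers and writers for assessment records and staging results.

CSV schema (UTF-8, comma-separated, header mandatory, one person-occasion
per row):

* ``person_id``, ``occasion`` (ISO date)
* ``qids_01`` .. ``qids_16`` — QIDS-SR16 item answers 0-3 (blank = unanswered)
* ``phq9_01`` .. ``phq9_09`` — PHQ-9 item answers 0-3 (blank = unanswered)
* ``functioning`` — band name (``none_mild`` / ``moderate_severe`` /
  ``major_ongoing``), and/or ``functioning_score`` — 0-100
* flag columns: ``hypomania``, ``psychosis``, ``comorbidity``,
  ``substance_misuse`` (none/possible/probable), ``severe_suicidality``,
  ``hospitalization_history``, ``course_flag``, ``manic_syndrome``,
  ``psychotic_syndrome``, ``severe_anxiety_syndrome``,
  ``specific_severe_anxiety`` (booleans)

Rows that fail validation are collected into an error report with their
row number and offending field — never silently dropped. The JSON format
carries the same content nested per record; a JSON Schema document for it
ships with the package (``data/assessment_record.schema.json``).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .models import (
    AssessmentRecord,
    ClinicalFlags,
    Functioning,
    FunctioningBand,
    OrdinalFlag,
    ScaleId,
    ScaleResponse,
    StageLabel,
    StagingResult,
)

PathLike = Union[str, Path]

_QIDS_COLS = [f"qids_{i:02d}" for i in range(1, 17)]
_PHQ9_COLS = [f"phq9_{i:02d}" for i in range(1, 10)]
_ORDINAL_FLAGS = ("hypomania", "psychosis", "comorbidity", "substance_misuse")
_BOOL_FLAGS = (
    "severe_suicidality",
    "hospitalization_history",
    "course_flag",
    "manic_syndrome",
    "psychotic_syndrome",
    "severe_anxiety_syndrome",
    "specific_severe_anxiety",
)
MANDATORY_COLUMNS = ("person_id", "occasion")


class SchemaError(ValueError):
    """The file as a whole does not match the documented schema."""


@dataclass(frozen=True)
class RowError:
    row: int  # 0-based data row (or list index for JSON)
    person_id: str
    message: str


@dataclass
class ReadResult:
    """Validated records plus a report of rows that failed validation."""

    records: list[AssessmentRecord] = field(default_factory=list)
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def raise_on_errors(self) -> "ReadResult":
        if self.errors:
            lines = "; ".join(f"row {e.row}: {e.message}" for e in self.errors[:5])
            raise SchemaError(f"{len(self.errors)} invalid row(s): {lines}")
        return self


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


def _parse_item(v, col: str) -> int:
    iv = int(float(v))
    if not 0 <= iv <= 3:
        raise ValueError(f"{col}={v!r} outside the 0-3 item range")
    if float(v) != iv:
        raise ValueError(f"{col}={v!r} is not an integer item response")
    return iv


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n", ""):
        return False
    raise ValueError(f"cannot parse boolean from {v!r}")


def _record_from_flat(row: dict, idx: int) -> AssessmentRecord:
    person_id = str(row.get("person_id", "")).strip()
    if not person_id or _is_missing(row.get("person_id")):
        raise ValueError("missing person_id")
    occ_raw = row.get("occasion")
    if _is_missing(occ_raw):
        raise ValueError("missing occasion")
    occasion = _dt.date.fromisoformat(str(occ_raw).strip()[:10])

    scales = []
    for scale_id, cols in ((ScaleId.QIDS_SR16, _QIDS_COLS), (ScaleId.PHQ9, _PHQ9_COLS)):
        items: dict[int, int] = {}
        for i, col in enumerate(cols, start=1):
            v = row.get(col)
            if _is_missing(v):
                continue
            items[i] = _parse_item(v, col)
        if items:
            scales.append(ScaleResponse(scale_id=scale_id, items=items))

    ordinals = {
        name: OrdinalFlag.parse(row.get(name)) if not _is_missing(row.get(name)) else OrdinalFlag.NONE
        for name in _ORDINAL_FLAGS
    }
    booleans = {
        name: _parse_bool(row.get(name)) if not _is_missing(row.get(name)) else False
        for name in _BOOL_FLAGS
    }
    flags = ClinicalFlags(**ordinals, **booleans)

    band = None
    if not _is_missing(row.get("functioning")):
        band = FunctioningBand.parse(row["functioning"])
    score = None
    if not _is_missing(row.get("functioning_score")):
        score = float(row["functioning_score"])
    functioning = Functioning(band=band, score=score)

    return AssessmentRecord(
        person_id=person_id,
        occasion=occasion,
        scales=tuple(scales),
        flags=flags,
        functioning=functioning,
    )


def _record_from_json_obj(obj: dict) -> AssessmentRecord:
    flat: dict = {
        "person_id": obj.get("person_id"),
        "occasion": obj.get("occasion"),
        "functioning": (obj.get("functioning") or {}).get("band"),
        "functioning_score": (obj.get("functioning") or {}).get("score"),
    }
    scales = obj.get("scales") or {}
    for key, cols in (("qids_sr16", _QIDS_COLS), ("phq9", _PHQ9_COLS)):
        values = scales.get(key)
        if values is None:
            continue
        if len(values) > len(cols):
            raise ValueError(f"scale {key} has {len(values)} items, max {len(cols)}")
        for i, v in enumerate(values):
            flat[cols[i]] = v
    for name, v in (obj.get("flags") or {}).items():
        flat[name] = v
    return _record_from_flat(flat, 0)


def read_assessments(path: PathLike, format: Optional[str] = None) -> ReadResult:
    """Read assessment records from CSV or JSON.

    ``format`` defaults to the file extension. Returns a
    :class:`ReadResult` whose ``errors`` list names every row that failed
    validation and why.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "json"):
        raise SchemaError(f"unsupported format {fmt!r} (expected csv or json)")
    out = ReadResult()
    if fmt == "csv":
        df = pd.read_csv(path, dtype=object)
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        for idx, row in enumerate(df.to_dict(orient="records")):
            try:
                out.records.append(_record_from_flat(row, idx))
            except (ValueError, TypeError) as exc:
                pid = str(row.get("person_id", "?"))
                out.errors.append(RowError(row=idx, person_id=pid, message=str(exc)))
    else:
        objs = json.loads(Path(path).read_text())
        if not isinstance(objs, list):
            raise SchemaError("JSON input must be a list of assessment objects")
        for idx, obj in enumerate(objs):
            try:
                out.records.append(_record_from_json_obj(obj))
            except (ValueError, TypeError) as exc:
                pid = str(obj.get("person_id", "?")) if isinstance(obj, dict) else "?"
                out.errors.append(RowError(row=idx, person_id=pid, message=str(exc)))
    return out


def _record_to_flat(record: AssessmentRecord) -> dict:
    row: dict = {
        "person_id": record.person_id,
        "occasion": record.occasion.isoformat(),
    }
    for scale_id, cols in ((ScaleId.QIDS_SR16, _QIDS_COLS), (ScaleId.PHQ9, _PHQ9_COLS)):
        resp = record.scale(scale_id)
        for i, col in enumerate(cols, start=1):
            row[col] = resp.items.get(i) if resp is not None else None
    for name in _ORDINAL_FLAGS:
        row[name] = getattr(record.flags, name).name.lower()
    for name in _BOOL_FLAGS:
        row[name] = bool(getattr(record.flags, name))
    row["functioning"] = (
        record.functioning.band.name.lower() if record.functioning.band is not None else None
    )
    row["functioning_score"] = record.functioning.score
    return row


def _record_to_json_obj(record: AssessmentRecord) -> dict:
    obj: dict = {
        "person_id": record.person_id,
        "occasion": record.occasion.isoformat(),
        "scales": {},
        "flags": {},
        "functioning": {
            "band": record.functioning.band.name.lower()
            if record.functioning.band is not None
            else None,
            "score": record.functioning.score,
        },
    }
    for scale_id, key, n in (
        (ScaleId.QIDS_SR16, "qids_sr16", 16),
        (ScaleId.PHQ9, "phq9", 9),
    ):
        resp = record.scale(scale_id)
        if resp is not None:
            obj["scales"][key] = [resp.items.get(i) for i in range(1, n + 1)]
    for name in _ORDINAL_FLAGS:
        obj["flags"][name] = getattr(record.flags, name).name.lower()
    for name in _BOOL_FLAGS:
        obj["flags"][name] = bool(getattr(record.flags, name))
    return obj


def write_assessments(
    records: Sequence[AssessmentRecord], path: PathLike, format: Optional[str] = None
) -> None:
    """Write assessment records to CSV or JSON (round-trips with the reader)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        cols = (
            list(MANDATORY_COLUMNS)
            + _QIDS_COLS
            + _PHQ9_COLS
            + list(_ORDINAL_FLAGS)
            + list(_BOOL_FLAGS)
            + ["functioning", "functioning_score"]
        )
        df = pd.DataFrame([_record_to_flat(r) for r in records], columns=cols)
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(
            json.dumps([_record_to_json_obj(r) for r in records], indent=1)
        )
    else:
        raise SchemaError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# staging results

def write_results(
    results: Sequence[StagingResult], path: PathLike, format: Optional[str] = None
) -> None:
    """Write staging results; ``read_results(write_results(x)) == x``.

    CSV cells for the trace and warnings hold JSON arrays so that arbitrary
    (including non-ASCII) criterion names survive the round trip exactly.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    rows = [
        {
            "person_id": r.person_id,
            "occasion": r.occasion.isoformat(),
            "stage": r.stage.code,
            "fired_criteria": list(r.fired_criteria),
            "warnings": list(r.warnings),
        }
        for r in results
    ]
    if fmt == "json":
        path.write_text(json.dumps(rows, ensure_ascii=False, indent=1))
    elif fmt == "csv":
        flat = [
            {
                **row,
                "fired_criteria": json.dumps(row["fired_criteria"], ensure_ascii=False),
                "warnings": json.dumps(row["warnings"], ensure_ascii=False),
            }
            for row in rows
        ]
        df = pd.DataFrame(
            flat, columns=["person_id", "occasion", "stage", "fired_criteria", "warnings"]
        )
        df.to_csv(path, index=False)
    else:
        raise SchemaError(f"unsupported format {fmt!r}")


def read_results(path: PathLike, format: Optional[str] = None) -> list[StagingResult]:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        rows = json.loads(path.read_text())
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=object)
        if len(df) == 0:
            return []
        rows = [
            {
                "person_id": r["person_id"],
                "occasion": r["occasion"],
                "stage": r["stage"],
                "fired_criteria": json.loads(r["fired_criteria"]),
                "warnings": json.loads(r["warnings"]),
            }
            for r in df.to_dict(orient="records")
        ]
    else:
        raise SchemaError(f"unsupported format {fmt!r}")
    return [
        StagingResult(
            person_id=str(r["person_id"]),
            occasion=_dt.date.fromisoformat(str(r["occasion"])),
            stage=StageLabel.parse(r["stage"]),
            fired_criteria=tuple(r["fired_criteria"]),
            warnings=tuple(r["warnings"]),
        )
        for r in rows
    ]
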