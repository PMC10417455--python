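"""CSV readers/writers for patient records.

Dialect: comma separator, dot decimal, UTF-8, LF endings, header row.
Columns: id, gender {M,F}, age (integer), bmi (decimal) or height_m +
weight_kg, smoker {0,1}, dm {0,1}, dysl {0,1}, hta {0,1}, fobt {pos,neg,
empty = missing}, residence {urban,rural, empty = unknown} (optional).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    FOBTResult,
    Gender,
    PatientRecord,
    Residence,
    bmi_from_height_weight,
)

__all__ = ["read_patients", "write_patients", "CsvValidationError"]

logger = logging.getLogger(__name__)

_GENDER_IN = {"M": Gender.MALE, "F": Gender.FEMALE}
_FOBT_IN = {"pos": FOBTResult.POSITIVE, "neg": FOBTResult.NEGATIVE,
            "": FOBTResult.MISSING}
_RES_IN = {"urban": Residence.URBAN, "rural": Residence.RURAL,
           "": Residence.UNKNOWN}

_REQUIRED = ("id", "gender", "age", "smoker", "dm", "dysl", "hta")


class CsvValidationError(ValueError):
    """A patient CSV failed schema or per-row validation."""


def _cell(row: pd.Series, name: str) -> str:
    v = row.get(name, "")
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return ""
    return str(v).strip()


def _parse_row(row: pd.Series, has_bmi: bool) -> PatientRecord:
    gender_tok = _cell(row, "gender")
    if gender_tok not in _GENDER_IN:
        raise ValueError(f"unknown gender token {gender_tok!r} (expected M or F)")
    fobt_tok = _cell(row, "fobt")
    if fobt_tok not in _FOBT_IN:
        raise ValueError(f"unknown fobt token {fobt_tok!r} (expected pos, neg or empty)")
    res_tok = _cell(row, "residence")
    if res_tok not in _RES_IN:
        raise ValueError(f"unknown residence token {res_tok!r}")

    def flag(name: str) -> bool:
        tok = _cell(row, name)
        if tok not in ("0", "1"):
            raise ValueError(f"column {name!r} must be 0 or 1, got {tok!r}")
        return tok == "1"

    if has_bmi:
        bmi = float(_cell(row, "bmi"))
    else:
        bmi = bmi_from_height_weight(
            float(_cell(row, "height_m")), float(_cell(row, "weight_kg"))
        )
    return PatientRecord(
        id=_cell(row, "id"),
        gender=_GENDER_IN[gender_tok],
        age=int(_cell(row, "age")),
        bmi=bmi,
        current_smoker=flag("smoker"),
        dm=flag("dm"),
        dysl=flag("dysl"),
        hta=flag("hta"),
        fobt=_FOBT_IN[fobt_tok],
        residence=_RES_IN[res_tok],
    )


def read_patients(path, strict: bool = True) -> list[PatientRecord]:
    """Read and validate a patient CSV.

    In strict mode (default) the first invalid row aborts with a
    :class:`CsvValidationError` naming the row; in lenient mode invalid
    rows are skipped with a logged warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = set(frame.columns)
    missing = [c for c in _REQUIRED if c not in cols]
    has_bmi = "bmi" in cols
    if not has_bmi and not {"height_m", "weight_kg"} <= cols:
        missing.append("bmi (or height_m + weight_kg)")
    if missing:
        raise CsvValidationError(
            f"{path.name}: malformed header, missing column(s): {', '.join(missing)}"
        )

    records: list[PatientRecord] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        rownum = i + 2  # 1-based, after the header line
        try:
            records.append(_parse_row(row, has_bmi))
        except (ValueError, TypeError) as exc:
            msg = f"{path.name} row {rownum}: {exc}"
            if strict:
                raise CsvValidationError(msg) from exc
            errors.append(msg)
            logger.warning("skipping invalid row: %s", msg)
    if errors:
        logger.warning("%d row(s) skipped in lenient mode", len(errors))
    return records


_FOBT_OUT = {FOBTResult.POSITIVE: "pos", FOBTResult.NEGATIVE: "neg",
             FOBTResult.MISSING: ""}
_RES_OUT = {Residence.URBAN: "urban", Residence.RURAL: "rural",
            Residence.UNKNOWN: ""}


def write_patients(records: Iterable[PatientRecord], path) -> None:
    """Write records in the documented CSV dialect (round-trips with read)."""
    rows = [
        {
            "id": r.id,
            "gender": "M" if r.gender is Gender.MALE else "F",
            "age": r.age,
            "bmi": f"{r.bmi:.2f}",
            "smoker": int(r.current_smoker),
            "dm": int(r.dm),
            "dysl": int(r.dysl),
            "hta": int(r.hta),
            "fobt": _FOBT_OUT[r.fobt],
            "residence": _RES_OUT[r.residence],
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
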