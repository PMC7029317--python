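"""ABC-DS record validation and scoring.

A record is one subject at one visit: 13 item levels (Q1..Q13, each an
integer 1-9, 1 = worst), a global CDR level, and optionally the CDR
sum-of-boxes and auxiliary scale scores (DAD, NPI, MMSE) carried for I/O.

Domain membership is fixed by the scale definition:

* ADL  = Q1 + Q2 + Q3 + Q4 + Q11 + Q12          (range 6-54)
* BPSD = Q7 + Q8 + Q9                            (range 3-27)
* CF   = Q5 + Q6 + Q10 + Q13                     (range 4-36)

Severity is summarized either by the total score (sum of all 13 items) or
by the three-dimensional distance TDD = sqrt(ADL^2 + BPSD^2 + CF^2).  The
TDD cannot be fooled by opposite-sign domain changes cancelling in the
total, which is why it is the preferred overall-severity statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ADL_ITEMS",
    "BPSD_ITEMS",
    "CF_ITEMS",
    "ALLOWED_CDR",
    "AUX_SCALES",
    "PatientRecord",
    "DomainScores",
    "RecordValidationError",
    "validate_record",
    "domain_scores",
    "tdd",
    "read_cohort_csv",
    "score_cohort",
    "write_scored_csv",
]

#: 1-based item numbers per domain; the three sets partition {1..13}.
ADL_ITEMS: frozenset[int] = frozenset({1, 2, 3, 4, 11, 12})
BPSD_ITEMS: frozenset[int] = frozenset({7, 8, 9})
CF_ITEMS: frozenset[int] = frozenset({5, 6, 10, 13})

ALLOWED_CDR: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0)
AUX_SCALES: tuple[str, ...] = ("dad", "npi", "mmse")

ITEM_MIN, ITEM_MAX = 1, 9
N_ITEMS = 13


class RecordValidationError(ValueError):
    """A raw row failed ABC-DS validation.

    Carries the offending row id and field name so batch loaders can report
    precisely which cell is bad.
    """

    def __init__(self, message: str, *, row_id: str = "?", fieldname: str = "?"):
        super().__init__(f"row {row_id!r}, field {fieldname!r}: {message}")
        self.row_id = row_id
        self.fieldname = fieldname


@dataclass(frozen=True)
class PatientRecord:
    """One subject at one visit with validated ABC-DS items."""

    patient_id: str
    visit: str
    cdr: float
    items: tuple[int, ...]  # Q1..Q13 in order
    cdr_sob: float | None = None
    aux: Mapping[str, float] = field(default_factory=dict)

    def item(self, q: int) -> int:
        """Return the level of item Q<q> (1-based)."""
        return self.items[q - 1]


@dataclass(frozen=True)
class DomainScores:
    """Derived ADL/BPSD/CF sums, total, and TDD for one record."""

    adl: int
    bpsd: int
    cf: int
    total: int
    tdd: float


def tdd(adl: float, bpsd: float, cf: float) -> float:
    """Three-dimensional distance: the Euclidean norm of (ADL, BPSD, CF).

    Internal value at full precision; rounding to one decimal is purely a
    presentation matter.  Raises ``ValueError`` on negative input — domain
    scores are nonnegative by construction.
    """
    if adl < 0 or bpsd < 0 or cf < 0:
        raise ValueError("TDD requires nonnegative domain scores")
    return math.sqrt(adl * adl + bpsd * bpsd + cf * cf)


def _parse_number(value, *, row_id: str, fieldname: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise RecordValidationError(
            f"not a number: {value!r}", row_id=row_id, fieldname=fieldname
        ) from None
    if not math.isfinite(out):
        raise RecordValidationError(
            f"non-finite value: {value!r}", row_id=row_id, fieldname=fieldname
        )
    return out


def validate_record(raw_row: Mapping) -> PatientRecord:
    """Build a :class:`PatientRecord` from a raw CSV row mapping.

    Expected keys: ``patient_id``, ``visit``, ``cdr``, ``q1``..``q13``,
    optionally ``cdr_sob`` and auxiliary scales (``dad``/``npi``/``mmse``).
    Missing or out-of-range values are rejected with the row id and field
    name; nothing is ever imputed.
    """
    row_id = str(raw_row.get("patient_id", "?"))
    if "patient_id" not in raw_row or _is_blank(raw_row["patient_id"]):
        raise RecordValidationError("missing patient_id", row_id=row_id, fieldname="patient_id")

    visit = str(raw_row.get("visit", "baseline"))
    if _is_blank(raw_row.get("visit")):
        visit = "baseline"

    cdr = _parse_number(raw_row.get("cdr"), row_id=row_id, fieldname="cdr")
    if cdr not in ALLOWED_CDR:
        raise RecordValidationError(
            f"invalid CDR level {cdr!r}; allowed: 0, 0.5, 1, 2, 3",
            row_id=row_id,
            fieldname="cdr",
        )

    items = []
    for q in range(1, N_ITEMS + 1):
        key = f"q{q}"
        if key not in raw_row or _is_blank(raw_row[key]):
            raise RecordValidationError("missing item", row_id=row_id, fieldname=key)
        val = _parse_number(raw_row[key], row_id=row_id, fieldname=key)
        if val != int(val):
            raise RecordValidationError(
                f"item level must be an integer, got {val}", row_id=row_id, fieldname=key
            )
        val = int(val)
        if not ITEM_MIN <= val <= ITEM_MAX:
            raise RecordValidationError(
                f"item out of range [1, 9]: {val}", row_id=row_id, fieldname=key
            )
        items.append(val)

    cdr_sob = None
    if not _is_blank(raw_row.get("cdr_sob")):
        cdr_sob = _parse_number(raw_row["cdr_sob"], row_id=row_id, fieldname="cdr_sob")
        if not (0.0 <= cdr_sob <= 18.0) or (cdr_sob * 2) != int(cdr_sob * 2):
            raise RecordValidationError(
                f"cdr_sob must lie in [0, 18] in 0.5 steps, got {cdr_sob}",
                row_id=row_id,
                fieldname="cdr_sob",
            )

    aux = {}
    for name in AUX_SCALES:
        if not _is_blank(raw_row.get(name)):
            aux[name] = _parse_number(raw_row[name], row_id=row_id, fieldname=name)

    return PatientRecord(
        patient_id=str(raw_row["patient_id"]),
        visit=visit,
        cdr=cdr,
        items=tuple(items),
        cdr_sob=cdr_sob,
        aux=aux,
    )


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def domain_scores(rec: PatientRecord) -> DomainScores:
    """Sum a validated record into ADL/BPSD/CF, total, and TDD."""
    adl = sum(rec.item(q) for q in sorted(ADL_ITEMS))
    bpsd = sum(rec.item(q) for q in sorted(BPSD_ITEMS))
    cf = sum(rec.item(q) for q in sorted(CF_ITEMS))
    total = adl + bpsd + cf
    return DomainScores(adl=adl, bpsd=bpsd, cf=cf, total=total, tdd=tdd(adl, bpsd, cf))


# ---------------------------------------------------------------------------
# Cohort-level I/O

def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a long-format cohort CSV (one row per patient-visit).

    Columns: patient_id, visit, cdr, optional cdr_sob, q1..q13, optional
    dad/npi/mmse.  Every row must validate; the first bad row aborts the read.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "visit": str})
    return [validate_record(row) for row in df.to_dict("records")]


def score_cohort(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Score records into a tidy DataFrame (one row per patient-visit)."""
    rows = []
    for rec in records:
        ds = domain_scores(rec)
        row = {
            "patient_id": rec.patient_id,
            "visit": rec.visit,
            "cdr": rec.cdr,
            "cdr_sob": rec.cdr_sob,
        }
        row.update({f"q{q}": rec.item(q) for q in range(1, N_ITEMS + 1)})
        row.update(
            adl=ds.adl, bpsd=ds.bpsd, cf=ds.cf, total=ds.total, tdd=ds.tdd
        )
        for name in AUX_SCALES:
            if name in rec.aux:
                row[name] = rec.aux[name]
        rows.append(row)
    return pd.DataFrame(rows)


def write_scored_csv(records: Iterable[PatientRecord], path) -> pd.DataFrame:
    """Write scored records to CSV; CDR is written as text to avoid float drift."""
    df = score_cohort(records)
    out = df.copy()
    out["cdr"] = out["cdr"].map(format_cdr)
    out.to_csv(path, index=False)
    return df


def format_cdr(cdr: float) -> str:
    """Render a CDR level as its canonical string (0, 0.5, 1, 2, 3)."""
    return "0.5" if cdr == 0.5 else str(int(cdr))
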