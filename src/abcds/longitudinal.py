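"""Longitudinal responsiveness statistics for 12-week score changes.

For each baseline-CDR stratum and each measure the change `follow-up -
baseline` is summarized by its mean, a two-sided Student-t confidence
interval, and the coefficient of variation (sd of the changes divided by
their mean).  Strata follow the published layout: CDR 3, CDR 2, CDR 1, and
CDR 0 and 0.5 pooled.

The t interval is used rather than the normal approximation because the
strata are small (n down to 33); CV is computed on the signed mean, with
its absolute value reported alongside, and is flagged undefined when the
mean change is exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from abcds.scale import AUX_SCALES, PatientRecord, format_cdr, score_cohort

__all__ = [
    "ChangeSummary",
    "change_ci",
    "paired_changes",
    "responsiveness_table",
    "responsiveness_tsv",
    "STRATA",
    "MEASURES",
]

logger = logging.getLogger(__name__)

#: stratum label -> CDR levels pooled into it, in the published column order
STRATA: dict[str, tuple[float, ...]] = {
    "CDR 3": (3.0,),
    "CDR 2": (2.0,),
    "CDR 1": (1.0,),
    "CDR 0.5/0": (0.5, 0.0),
}

MEASURES: tuple[str, ...] = ("adl", "bpsd", "cf", "total", "tdd", "cdr_sob")


@dataclass(frozen=True)
class ChangeSummary:
    """Mean change with 95% CI and CV for one stratum x measure cell."""

    stratum: str
    measure: str
    n: int
    mean_change: float
    ci_lower: float
    ci_upper: float
    sd: float
    cv: float | None  # None when mean change is exactly zero
    cv_abs: float | None
    excludes_zero: bool
    level: float = 0.95


def change_ci(
    changes: Sequence[float],
    level: float = 0.95,
    *,
    stratum: str = "",
    measure: str = "",
) -> ChangeSummary:
    """Two-sided Student-t interval for the mean of paired changes.

    mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n), with sd the sample
    standard deviation (ddof=1).  Requires n >= 2.
    """
    x = np.asarray(changes, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("change_ci requires at least two paired changes")
    if not np.all(np.isfinite(x)):
        raise ValueError("changes must be finite")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    tq = float(stats.t.ppf((1 + level) / 2, df=n - 1))
    half = tq * sd / math.sqrt(n)
    lo, hi = mean - half, mean + half
    if mean == 0.0:
        cv = cv_abs = None
    else:
        cv = sd / mean
        cv_abs = abs(cv)
    return ChangeSummary(
        stratum=stratum,
        measure=measure,
        n=n,
        mean_change=mean,
        ci_lower=lo,
        ci_upper=hi,
        sd=sd,
        cv=cv,
        cv_abs=cv_abs,
        excludes_zero=not (lo <= 0.0 <= hi),
        level=level,
    )


def paired_changes(
    cohort: Iterable[PatientRecord],
    baseline_visit: str = "baseline",
    followup_visit: str = "week12",
) -> pd.DataFrame:
    """Match baseline/follow-up rows per patient and compute score changes.

    Returns one row per matched patient with the baseline CDR and the change
    (follow-up minus baseline) in each measure.  Patients without both
    visits are skipped; the skipped count is logged.
    """
    scored = score_cohort(cohort)
    base = scored[scored["visit"] == baseline_visit].set_index("patient_id")
    follow = scored[scored["visit"] == followup_visit].set_index("patient_id")
    matched = base.index.intersection(follow.index)
    n_skipped = len(base.index.symmetric_difference(follow.index))
    if n_skipped:
        logger.warning("skipped %d patients without a matched visit pair", n_skipped)

    cols = list(MEASURES) + [name for name in AUX_SCALES if name in scored.columns]
    out = {"patient_id": matched, "cdr": base.loc[matched, "cdr"].to_numpy()}
    for col in cols:
        if col in scored.columns:
            delta = follow.loc[matched, col].astype(float) - base.loc[
                matched, col
            ].astype(float)
            out[col] = delta.to_numpy()
    return pd.DataFrame(out).reset_index(drop=True)


def responsiveness_table(
    cohort: Iterable[PatientRecord],
    level: float = 0.95,
    baseline_visit: str = "baseline",
    followup_visit: str = "week12",
) -> list[ChangeSummary]:
    """One :class:`ChangeSummary` per stratum x available measure.

    Strata are taken at baseline CDR; measures with fewer than two
    non-missing paired changes in a stratum are omitted.
    """
    deltas = paired_changes(cohort, baseline_visit, followup_visit)
    summaries: list[ChangeSummary] = []
    for stratum, levels in STRATA.items():
        block = deltas[deltas["cdr"].isin(levels)]
        if block.empty:
            continue
        for measure in [c for c in deltas.columns if c not in ("patient_id", "cdr")]:
            vals = block[measure].dropna().to_numpy()
            if vals.size < 2:
                continue
            summaries.append(
                change_ci(vals, level, stratum=stratum, measure=measure)
            )
    return summaries


def responsiveness_tsv(summaries: Sequence[ChangeSummary]) -> str:
    """Render summaries as a TSV mirroring the published responsiveness table."""
    lines = ["stratum\tmeasure\tn\tmean\tci_lower\tci_upper\tcv"]
    for s in summaries:
        cv = "NA" if s.cv is None else f"{s.cv:.2f}"
        lines.append(
            f"{s.stratum}\t{s.measure}\t{s.n}\t{s.mean_change:.2f}"
            f"\t{s.ci_lower:.2f}\t{s.ci_upper:.2f}\t{cv}"
        )
    return "\n".join(lines) + "\n"


def cohort_counts(records: Iterable[PatientRecord], visit: str = "baseline") -> pd.Series:
    """Patient counts per CDR level at the given visit."""
    cdrs = [r.cdr for r in records if r.visit == visit]
    return pd.Series(cdrs).value_counts().sort_index()


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Share of a cohort as a percentage rounded to `decimals` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)
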