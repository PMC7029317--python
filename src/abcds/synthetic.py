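"""Synthetic ABC-DS cohorts matching published summary statistics.

No raw patient data were deposited with the study this package reanalyzes;
what is public are per-subgroup six-statistic summaries of the domain
scores and 95% confidence intervals for 12-week changes.  This module
generates item-level cohorts that emulate exactly those published
quantities:

* domain scores are drawn from the piecewise-linear quantile function
  interpolating each subgroup's printed five-number summary (quantile
  matching), optionally shrunk about the median by ``dispersion_scale``;
* item levels are uniform random compositions of the sampled domain score,
  so scoring a simulated record reproduces the sampled (ADL, BPSD, CF)
  triple exactly;
* 12-week follow-up scores add Gaussian changes whose mean and standard
  deviation are back-derived from the published confidence intervals.

Domains are sampled independently within a subgroup (no within-subgroup
correlation is published); an optional correlation hook is deliberately
not provided in the default path.  Everything is deterministic given a
seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from abcds.profiles import SubgroupProfile
from abcds.scale import PatientRecord

__all__ = [
    "DOMAIN_BOUNDS",
    "SubgroupSpec",
    "ChangeSpec",
    "sample_domain_score",
    "decompose_domain_score",
    "simulate_cohort",
    "simulate_changes",
    "load_subgroup_specs",
    "load_change_specs",
    "load_fixture_profiles",
    "derive_mu_sigma",
]

#: inclusive score bounds per sampled measure
DOMAIN_BOUNDS: dict[str, tuple[float, float]] = {
    "adl": (6, 54),
    "bpsd": (3, 27),
    "cf": (4, 36),
    "cdr_sob": (0, 18),
}

#: item slots per domain, in ascending question order
DOMAIN_ITEMS: dict[str, tuple[int, ...]] = {
    "adl": (1, 2, 3, 4, 11, 12),
    "bpsd": (7, 8, 9),
    "cf": (5, 6, 10, 13),
}

FIVE_NUM = ("min", "q1", "median", "q3", "max")


@dataclass(frozen=True)
class SubgroupSpec:
    """Generation target for one subgroup: five-number summaries per measure."""

    name: str
    stratum: float
    n: int
    summaries: Mapping[str, Mapping[str, float]]  # measure -> five-number summary
    dispersion_scale: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("subgroup size must be >= 1")
        if self.dispersion_scale <= 0:
            raise ValueError("dispersion_scale must be positive")
        for measure, summ in self.summaries.items():
            chain = [summ[s] for s in FIVE_NUM]
            if any(b < a for a, b in zip(chain, chain[1:])):
                raise ValueError(f"{self.name}/{measure}: five-number summary not ordered")
            lo, hi = DOMAIN_BOUNDS.get(measure, (-math.inf, math.inf))
            if chain[0] < lo or chain[-1] > hi:
                raise ValueError(f"{self.name}/{measure}: summary outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ChangeSpec:
    """Gaussian 12-week change model for one stratum, per measure."""

    stratum: str
    cdr_levels: tuple[float, ...]
    n: int
    measures: Mapping[str, tuple[float, float]]  # measure -> (mu, sigma)
    flag: str | None = None


def derive_mu_sigma(ci_lower: float, ci_upper: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Back-derive the change mean and SD from a published t interval.

    mu is the interval midpoint; sigma = half-width * sqrt(n) / t quantile,
    inverting mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    mu = (ci_lower + ci_upper) / 2.0
    half = (ci_upper - ci_lower) / 2.0
    tq = float(stats.t.ppf((1 + level) / 2, df=n - 1))
    return mu, half * math.sqrt(n) / tq


def sample_domain_score(
    summary: Mapping[str, float],
    rng: np.random.Generator,
    dispersion_scale: float = 1.0,
    bounds: tuple[float, float] | None = None,
    size: int | None = None,
    integer: bool = True,
):
    """Draw scores through the piecewise-linear quantile function.

    u ~ Uniform(0, 1) is mapped through the interpolant of
    (0, min), (0.25, q1), (0.5, median), (0.75, q3), (1, max); the draw is
    then scaled about the median by ``dispersion_scale``, rounded to the
    nearest integer (unless ``integer=False``) and clamped to ``bounds``.
    A degenerate summary (min = max) yields a constant.
    """
    knots_p = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    knots_q = np.array([summary[s] for s in FIVE_NUM], dtype=float)
    u = rng.random(size if size is not None else 1)
    vals = np.interp(u, knots_p, knots_q)
    med = summary["median"]
    vals = med + dispersion_scale * (vals - med)
    if integer:
        vals = np.rint(vals)
    if bounds is not None:
        vals = np.clip(vals, bounds[0], bounds[1])
    if integer:
        vals = vals.astype(int)
    return vals if size is not None else vals[0]


@lru_cache(maxsize=None)
def _composition_counts(parts: int) -> np.ndarray:
    """counts[p, s] = number of compositions of s into p parts each in [1, 9]."""
    max_s = 9 * parts
    counts = np.zeros((parts + 1, max_s + 1), dtype=np.int64)
    counts[0, 0] = 1
    for p in range(1, parts + 1):
        for s in range(p, 9 * p + 1):
            lo = max(1, s - 9 * (p - 1))
            hi = min(9, s - (p - 1))
            counts[p, s] = counts[p - 1, s - hi : s - lo + 1].sum()
    return counts


def decompose_domain_score(score: int, m: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Split a domain score into m item levels, uniformly at random.

    Returns a uniformly distributed composition of ``score`` into ``m``
    parts, each in [1, 9], summing to ``score`` exactly.  Sequential
    sampling with exact composition counts guarantees uniformity over all
    valid compositions.
    """
    if not m * 1 <= score <= m * 9:
        raise ValueError(f"score {score} cannot split into {m} items in [1, 9]")
    counts = _composition_counts(m)
    items = []
    remaining, parts_left = int(score), m
    for _ in range(m):
        lo = max(1, remaining - 9 * (parts_left - 1))
        hi = min(9, remaining - (parts_left - 1))
        weights = np.array(
            [counts[parts_left - 1, remaining - v] for v in range(lo, hi + 1)], dtype=float
        )
        v = lo + rng.choice(len(weights), p=weights / weights.sum())
        items.append(int(v))
        remaining -= v
        parts_left -= 1
    return tuple(items)


def _record_from_scores(
    patient_id: str,
    visit: str,
    cdr: float,
    scores: Mapping[str, int],
    cdr_sob: float | None,
    rng: np.random.Generator,
) -> PatientRecord:
    items = [0] * 13
    for domain, slots in DOMAIN_ITEMS.items():
        for q, level in zip(slots, decompose_domain_score(scores[domain], len(slots), rng)):
            items[q - 1] = level
    return PatientRecord(
        patient_id=patient_id, visit=visit, cdr=cdr, items=tuple(items), cdr_sob=cdr_sob
    )


def simulate_cohort(
    specs: Sequence[SubgroupSpec],
    seed: int | np.random.Generator,
    visit: str = "baseline",
) -> list[PatientRecord]:
    """Generate one patient record per subgroup member.

    Patient ids are ``<subgroup>-<index>`` so planted membership stays
    recoverable in cluster-recovery experiments.  ADL, BPSD, and CF are
    sampled independently from their quantile interpolants, decomposed into
    item levels, and CDR-SOB (when specified) is rounded to the 0.5 grid.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    records = []
    for spec in specs:
        for i in range(spec.n):
            scores = {
                domain: int(
                    sample_domain_score(
                        spec.summaries[domain],
                        rng,
                        spec.dispersion_scale,
                        DOMAIN_BOUNDS[domain],
                    )
                )
                for domain in ("adl", "bpsd", "cf")
            }
            cdr_sob = None
            if "cdr_sob" in spec.summaries:
                raw = sample_domain_score(
                    spec.summaries["cdr_sob"],
                    rng,
                    spec.dispersion_scale,
                    DOMAIN_BOUNDS["cdr_sob"],
                    integer=False,
                )
                cdr_sob = float(np.clip(np.round(raw * 2) / 2, 0.0, 18.0))
            records.append(
                _record_from_scores(
                    f"{spec.name}-{i + 1:03d}", visit, spec.stratum, scores, cdr_sob, rng
                )
            )
    return records


def simulate_changes(
    baseline: Iterable[PatientRecord],
    change_specs: Sequence[ChangeSpec],
    seed: int | np.random.Generator,
    visit: str = "week12",
) -> list[PatientRecord]:
    """Generate follow-up records by adding Gaussian domain-score changes.

    Per patient and domain: week-12 score = clamp(round(baseline +
    Normal(mu, sigma))) with (mu, sigma) from the stratum's change spec;
    items are re-decomposed to match the new domain scores, so scoring the
    follow-up record reproduces them exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    by_level: dict[float, ChangeSpec] = {}
    for cs in change_specs:
        for level in cs.cdr_levels:
            by_level[level] = cs
    out = []
    for rec in baseline:
        spec = by_level.get(rec.cdr)
        if spec is None:
            raise ValueError(f"no change spec covers CDR {rec.cdr}")
        base = {
            "adl": sum(rec.item(q) for q in DOMAIN_ITEMS["adl"]),
            "bpsd": sum(rec.item(q) for q in DOMAIN_ITEMS["bpsd"]),
            "cf": sum(rec.item(q) for q in DOMAIN_ITEMS["cf"]),
        }
        new_scores = {}
        for domain in ("adl", "bpsd", "cf"):
            mu, sigma = spec.measures.get(domain, (0.0, 0.0))
            delta = rng.normal(mu, sigma) if sigma > 0 else mu
            lo, hi = DOMAIN_BOUNDS[domain]
            new_scores[domain] = int(np.clip(round(base[domain] + delta), lo, hi))
        cdr_sob = rec.cdr_sob
        if cdr_sob is not None and "cdr_sob" in spec.measures:
            mu, sigma = spec.measures["cdr_sob"]
            delta = rng.normal(mu, sigma) if sigma > 0 else mu
            cdr_sob = float(np.clip(np.round((cdr_sob + delta) * 2) / 2, 0.0, 18.0))
        out.append(
            _record_from_scores(rec.patient_id, visit, rec.cdr, new_scores, cdr_sob, rng)
        )
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures

def _load_json(name: str, path=None) -> dict:
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    return json.loads(
        resources.files("abcds").joinpath("data", name).read_text("utf-8")
    )


def load_subgroup_specs(
    path=None,
    stratum: float | None = None,
    dispersion_scale: float = 1.0,
) -> list[SubgroupSpec]:
    """Load the packaged subgroup summary fixture as generation specs."""
    raw = _load_json("tables_2_3_4.json", path)
    specs = []
    for sub in raw["subgroups"]:
        if stratum is not None and float(sub["stratum"]) != float(stratum):
            continue
        summaries = {
            measure: {s: sub[measure][s] for s in FIVE_NUM}
            for measure in ("adl", "bpsd", "cf", "cdr_sob")
            if measure in sub
        }
        specs.append(
            SubgroupSpec(
                name=sub["name"],
                stratum=float(sub["stratum"]),
                n=int(sub["n"]),
                summaries=summaries,
                dispersion_scale=dispersion_scale,
            )
        )
    return specs


def load_fixture_profiles(path=None, stratum: float | None = None) -> list[SubgroupProfile]:
    """Load the packaged subgroup summaries as :class:`SubgroupProfile` objects."""
    raw = _load_json("tables_2_3_4.json", path)
    profiles = []
    for sub in raw["subgroups"]:
        if stratum is not None and float(sub["stratum"]) != float(stratum):
            continue
        stats_ = {
            measure: dict(sub[measure])
            for measure in ("adl", "bpsd", "cf", "tdd", "cdr_sob")
            if measure in sub
        }
        profiles.append(
            SubgroupProfile(
                name=sub["name"], stratum=float(sub["stratum"]), n=int(sub["n"]), stats=stats_
            )
        )
    return profiles


def load_change_specs(path=None, level: float = 0.95) -> list[ChangeSpec]:
    """Load the packaged change-CI fixture, back-deriving (mu, sigma) per measure."""
    raw = _load_json("table_1_changes.json", path)
    specs = []
    for st in raw["strata"]:
        n = int(st["n"])
        measures = {
            name: derive_mu_sigma(ci["ci_lower"], ci["ci_upper"], n, level)
            for name, ci in st["measures"].items()
        }
        specs.append(
            ChangeSpec(
                stratum=st["stratum"],
                cdr_levels=tuple(float(x) for x in st["cdr_levels"]),
                n=n,
                measures=measures,
                flag=st.get("flag"),
            )
        )
    return specs
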