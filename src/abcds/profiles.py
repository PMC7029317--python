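"""Subgroup profiling and cross-stratum merging.

A cluster of patients is summarized into the six-statistic block used in
the published subgroup tables — min, first quartile, median, mean, third
quartile, max — for each of ADL, BPSD, CF, TDD, and CDR-SOB.  Quartiles
use linear interpolation of order statistics at position h = (n-1)p + 1
(R's default ``summary()`` convention, numpy's ``"linear"``).  TDD is
summarized over per-patient TDD values: the median TDD of a subgroup is an
order statistic of TDDs, not the TDD of the median domain scores.

Subgroups are named ``C<stratum>.<index>`` with the index assigned by
descending median TDD within each stratum, so C1.1 is always the least
severe CDR-1 subgroup.

Subgroups with similar median profiles across strata are merged into named
groups (GI, GII, ...) by single-linkage agglomeration over the Euclidean
distance between (ADL, BPSD, CF, TDD) median vectors, stopping at a
distance threshold ``tau``.  The designated reference subgroup (C1.1 in
the published analysis) is excluded from merging; CDR-SOB is excluded from
the distance because merging crosses CDR strata where CDR-SOB necessarily
differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from abcds.cluster import ClusterAssignment

__all__ = [
    "STAT_NAMES",
    "PROFILE_MEASURES",
    "SubgroupProfile",
    "MergedGroup",
    "summarize",
    "profiles_from_assignment",
    "merge_similar",
    "characterize",
    "emit_tables",
    "read_table",
]

STAT_NAMES = ("min", "q1", "median", "mean", "q3", "max")
PROFILE_MEASURES = ("adl", "bpsd", "cf", "tdd", "cdr_sob")
#: measures entering the merge distance (CDR-SOB deliberately excluded)
MERGE_MEASURES = ("adl", "bpsd", "cf", "tdd")


@dataclass(frozen=True)
class SubgroupProfile:
    """Six-statistic summary of one patient subgroup."""

    name: str
    stratum: float
    n: int
    stats: Mapping[str, Mapping[str, float]]  # measure -> stat -> value

    def stat(self, measure: str, stat: str) -> float:
        return self.stats[measure][stat]

    def median_vector(self, measures: Sequence[str] = MERGE_MEASURES) -> np.ndarray:
        return np.array([self.stats[m]["median"] for m in measures], dtype=float)


@dataclass(frozen=True)
class MergedGroup:
    """A merged cross-stratum group (or a singleton passed through)."""

    name: str
    members: tuple[str, ...]
    profile: Mapping[str, float]  # measure -> representative median

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def vector(self, measures: Sequence[str] = MERGE_MEASURES) -> np.ndarray:
        return np.array([self.profile[m] for m in measures], dtype=float)


def _five_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "mean": float(values.mean()),
        "q3": float(q3),
        "max": float(values.max()),
    }


def summarize(members: pd.DataFrame, name: str, stratum: float | None = None) -> SubgroupProfile:
    """Summarize a scored member block into a :class:`SubgroupProfile`.

    ``members`` must carry ``adl``, ``bpsd``, ``cf``, ``tdd`` columns;
    ``cdr_sob`` is summarized when present and non-missing.
    """
    if len(members) < 1:
        raise ValueError("cannot summarize an empty subgroup")
    stats: dict[str, dict[str, float]] = {}
    for measure in PROFILE_MEASURES:
        if measure not in members.columns:
            continue
        vals = members[measure].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        stats[measure] = _five_stats(vals)
    if stratum is None:
        stratum = float(members["cdr"].iloc[0]) if "cdr" in members.columns else float("nan")
    return SubgroupProfile(name=name, stratum=stratum, n=len(members), stats=stats)


def profiles_from_assignment(
    scored: pd.DataFrame, assignment: ClusterAssignment, stratum: float
) -> tuple[list[SubgroupProfile], pd.Series]:
    """Profile each cluster of one stratum, naming by descending median TDD.

    Returns the named profiles plus a per-row Series mapping each patient to
    its subgroup name (index aligned with ``scored``).
    """
    if len(scored) != len(assignment.labels):
        raise ValueError("assignment does not match the scored block")
    labels = np.asarray(assignment.labels)
    medians = {
        lab: float(np.median(scored.loc[labels == lab, "tdd"])) for lab in np.unique(labels)
    }
    # rank clusters by descending median TDD: index 1 = least severe
    order = sorted(medians, key=lambda lab: -medians[lab])
    stratum_tag = "0.5" if stratum == 0.5 else str(int(stratum))
    names = {lab: f"C{stratum_tag}.{i + 1}" for i, lab in enumerate(order)}
    profiles = [
        summarize(scored.loc[labels == lab], names[lab], stratum) for lab in order
    ]
    member_names = pd.Series([names[lab] for lab in labels], index=scored.index, name="subgroup")
    return profiles, member_names


def merge_similar(
    profiles: Sequence[SubgroupProfile],
    reference: str,
    tau: float = 8.0,
) -> list[MergedGroup]:
    """Merge subgroups with similar median profiles into GI/GII/... groups.

    Single-linkage agglomeration over Euclidean distances between
    (ADL, BPSD, CF, TDD) median vectors, cut at ``tau``: two subgroups land
    in one group iff they are connected by a chain of pairwise distances
    <= tau.  The reference subgroup never participates and is returned as a
    singleton.  Multi-member groups are named GI, GII, ... by descending
    group median TDD (size-weighted mean of member medians); singletons
    keep their subgroup name.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    names = [p.name for p in profiles]
    if reference not in names:
        raise ValueError(f"unknown reference subgroup {reference!r}")
    if len(set(names)) != len(names):
        raise ValueError("duplicate subgroup names")

    mergeable = [p for p in profiles if p.name != reference]
    vecs = np.array([p.median_vector() for p in mergeable], dtype=float)
    m = len(mergeable)
    # single-linkage cut at tau == connected components of the <=tau graph
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if np.linalg.norm(vecs[i] - vecs[j]) <= tau:
                parent[find(i)] = find(j)

    components: dict[int, list[SubgroupProfile]] = {}
    for i, prof in enumerate(mergeable):
        components.setdefault(find(i), []).append(prof)

    def group_profile(members: list[SubgroupProfile]) -> dict[str, float]:
        weights = np.array([p.n for p in members], dtype=float)
        out = {}
        for measure in MERGE_MEASURES:
            vals = np.array([p.stats[measure]["median"] for p in members])
            out[measure] = float(np.average(vals, weights=weights))
        return out

    multi = [sorted(ms, key=lambda p: p.name) for ms in components.values() if len(ms) > 1]
    multi.sort(key=lambda ms: -group_profile(ms)["tdd"])
    groups: list[MergedGroup] = []
    for i, members in enumerate(multi):
        groups.append(
            MergedGroup(
                name="G" + _roman(i + 1),
                members=tuple(p.name for p in members),
                profile=group_profile(members),
            )
        )
    singles = [ms[0] for ms in components.values() if len(ms) == 1]
    singles += [p for p in profiles if p.name == reference]
    for prof in singles:
        groups.append(
            MergedGroup(
                name=prof.name,
                members=(prof.name,),
                profile={m_: prof.stats[m_]["median"] for m_ in MERGE_MEASURES},
            )
        )
    groups.sort(key=lambda g: -g.profile["tdd"])
    return groups


def _roman(i: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    if not 1 <= i <= len(numerals):
        raise ValueError("too many merged groups to name")
    return numerals[i - 1]


def characterize(
    profile: Mapping[str, float],
    reference: Mapping[str, float],
    delta_tol: float = 1.0,
) -> dict[str, str]:
    """Per-domain status of a profile relative to the reference medians.

    A domain is ``"deteriorated"`` when its median sits more than
    ``delta_tol`` points below the reference, ``"improved"`` when more than
    ``delta_tol`` above, else ``"comparable"``.
    """
    out = {}
    for measure in ("adl", "bpsd", "cf"):
        delta = profile[measure] - reference[measure]
        if delta < -delta_tol:
            out[measure] = "deteriorated"
        elif delta > delta_tol:
            out[measure] = "improved"
        else:
            out[measure] = "comparable"
    return out


def emit_tables(profiles: Sequence[SubgroupProfile]) -> dict[float, str]:
    """Render one TSV per stratum in the published row-block layout.

    Six stat rows per subgroup, one column per measure, 1-decimal
    formatting; the subgroup's n repeats on every row so the file
    round-trips through :func:`read_table`.
    """
    by_stratum: dict[float, list[SubgroupProfile]] = {}
    for p in profiles:
        by_stratum.setdefault(p.stratum, []).append(p)
    tables = {}
    for stratum, profs in sorted(by_stratum.items()):
        lines = ["group\tn\tstat\t" + "\t".join(m.upper() for m in PROFILE_MEASURES)]
        for p in profs:
            for stat in STAT_NAMES:
                cells = [
                    f"{p.stats[m][stat]:.1f}" if m in p.stats else "NA"
                    for m in PROFILE_MEASURES
                ]
                lines.append(f"{p.name}\t{p.n}\t{stat}\t" + "\t".join(cells))
        tables[stratum] = "\n".join(lines) + "\n"
    return tables


def read_table(text: str, stratum: float) -> list[SubgroupProfile]:
    """Parse a TSV produced by :func:`emit_tables` back into profiles."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    measures = [h.lower() for h in header[3:]]
    blocks: dict[str, dict] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        name, n, stat = cells[0], int(cells[1]), cells[2]
        block = blocks.setdefault(name, {"n": n, "stats": {}})
        for m, cell in zip(measures, cells[3:]):
            if cell != "NA":
                block["stats"].setdefault(m, {})[stat] = float(cell)
    return [
        SubgroupProfile(name=name, stratum=stratum, n=b["n"], stats=b["stats"])
        for name, b in blocks.items()
    ]
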