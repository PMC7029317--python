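# Methods

## The scale and its statistics

The ABC Dementia Scale (ABC-DS) is a 13-item caregiver interview for
Alzheimer's disease. Each item Q1–Q13 is rated 1 (worst) to 9 (best) and
the items sum into three domain scores:

* **ADL** (activities of daily living) = Q1 + Q2 + Q3 + Q4 + Q11 + Q12, range 6–54;
* **BPSD** (behavioral and psychological symptoms) = Q7 + Q8 + Q9, range 3–27;
* **CF** (cognitive function) = Q5 + Q6 + Q10 + Q13, range 4–36.

Overall severity is either the **total score** (sum of all 13 items,
13–117) or the **three-dimensional distance**

TDD = √(ADL² + BPSD² + CF²),

which, unlike the total, cannot be fooled by opposite-sign domain changes
cancelling out. Lower values are more severe on every measure. For any
valid record, total = ADL + BPSD + CF exactly, total/√3 ≤ TDD ≤ total, and
the achievable TDD range is [√61, √4941]. Validation is strict: missing or
out-of-range items are rejected, never imputed — a score over a partial
item set would not be comparable across patients.

## Longitudinal responsiveness

Twelve-week changes (follow-up − baseline, per patient) are summarized per
baseline-CDR stratum (CDR 3, 2, 1, and 0/0.5 pooled) by the mean, a
two-sided Student-t interval mean ± t₍0.975,n−1₎·sd/√n, and the
coefficient of variation CV = sd/mean. The source analysis does not state
whether its intervals are t- or normal-based; t is the standard choice at
the stratum sizes involved (n down to 33) and is the default here, with
the confidence level configurable. CV is computed on the signed mean (the
reported |CV| ≈ 3.2 for TDD in the mildest stratum only makes sense for a
near-zero mean change, i.e. a signed ratio), with the absolute value
reported alongside and a zero mean flagged as undefined rather than
producing an infinity.

## Hierarchical clustering

Patients within one CDR stratum are clustered on their raw (ADL, BPSD,
CF) vectors — no standardization, matching an analysis that clusters the
three domain scores directly — using a from-scratch Lance–Williams
agglomeration with Ward, complete, and average linkage. Ward runs on
squared Euclidean distances with square-rooted heights, so reported
heights live on the distance scale (the documented-correct Ward
criterion, identical to scipy's); the historical variant that applies the
same recurrence to unsquared distances is available as
`ward_flavor="legacy"`. Ties are broken by merging the pair with the
lexicographically smallest (older node id, newer node id), which makes
the tree deterministic across platforms and input orderings. All three
linkages are inversion-free, so merge heights are non-decreasing and the
cut at any k is well defined; cutting undoes the last k−1 merges and
renumbers clusters 1..k by first leaf appearance.

The published analysis cut each stratum's dendrogram "at the first
generation", yielding 4/5/3 subgroups for CDR 1/2/3, without stating a
numeric criterion. This package formalizes the choice as the largest
height gap: select the k in [k_min, k_max] maximizing h₍n−k+1₎ − h₍n−k₎,
ties to the smallest k, with an explicit `--k` override so the published
4/5/3 can be imposed directly. **Known limitation:** on synthetic CDR-1
cohorts the four planted subgroups are hierarchically nested — the
(C1.1+C1.2) vs (C1.3+C1.4) split towers over every other merge — so the
absolute-gap rule selects k = 2 at essentially every seed even though the
k = 4 cut recovers ≥ 90 % of planted membership. Relative-gap and
squared-scale variants behave the same way. The rule is kept as specified
and the limitation documented rather than papered over; the CDR-3
structure (3 subgroups) is recovered by the gap rule in roughly four out
of five seeds.

## Subgroup profiles and merging

Each cluster is summarized by min, Q1, median, mean, Q3, max for ADL,
BPSD, CF, TDD, and CDR-SOB. Quartiles interpolate order statistics at
position h = (n−1)p + 1 (R's default `summary()`, numpy's `"linear"`), the
convention of the environment the source analysis names. TDD statistics
are order statistics of per-patient TDD values — the median TDD of a
subgroup is *not* the TDD of its median domain scores (for the reference
subgroup the two differ by half a point). Subgroups are named
C&lt;stratum&gt;.&lt;index&gt; by descending median TDD, so C1.1 is the least severe
CDR-1 subgroup.

Similar subgroups across strata are merged by single-linkage
agglomeration over Euclidean distances between (ADL, BPSD, CF, TDD)
median vectors, cut at a threshold τ (equivalently: connected components
of the ≤ τ graph). CDR-SOB is excluded from the distance because merging
crosses CDR strata where CDR-SOB necessarily differs. The reference
subgroup C1.1 is excluded from merging — without that exclusion no pure
distance rule reproduces the published grouping, since C1.1 sits closer
to C2.1 (≈ 4.3) than C1.2 does (≈ 5.5). On the published medians the
grouping {C1.2, C2.1, C2.2}, {C1.4, C2.3}, {C2.5, C3.1} is reproduced for
every τ strictly between 7.60 (the largest within-group pairwise
distance, C2.1–C2.2) and 8.65 (the smallest cross-group distance,
C1.3–C2.2); the default τ = 8.0 sits mid-interval. Merged groups are
named GI, GII, … by descending group median TDD; a group's representative
profile is the member-size-weighted mean of member medians. No
between-subgroup significance testing is performed (none was reported).

## Progression roadmap

Roadmap nodes are the merged groups plus pass-through singletons, ordered
by descending median TDD: C1.1 (61.1) ≻ GI (57.3) ≻ C1.3 (50.6) ≻ GII
(46.1) ≻ C2.4 (41.6) ≻ GIII (35.6) ≻ C3.2 (34.2) ≻ C3.3 (15.1, the
terminal node). Edges are expert judgment, not a computed object; the
packaged edge list transcribes the narrative progression steps (C1.1→GI,
C1.1→C1.3, GI→C1.3, GI→GII, GI→C2.4, C2.4→GIII, C2.4→C3.2, GII→GIII,
C1.3→GIII, GIII→C3.3, and terminal paths C2.4→C3.3, C3.2→C3.3). The
module validates and classifies edges rather than discovering them; an
experimental discovery mode proposes monotone-TDD edges between
successive severity layers.

A domain "deteriorates" along an edge when its median drops by more than
`delta_tol` = 1.0 points (operationalizing "almost unchanged";
configurable). Colors: red = all three deteriorate; blue = ADL and/or CF
but not BPSD; yellow = only BPSD; green = BPSD and CF but not ADL;
orange = ADL and BPSD but not CF. The taxonomy is exhaustive and
exclusive over deterioration patterns; a pair with no qualifying pattern
is rejected, as is any edge whose destination median TDD is not strictly
below its source — that monotone potential function makes the graph
acyclic by construction. One caption in the source figure writes "BPD"
for the green line; it is read as a typo for BPSD. With the weighted GI
representative, two narrative edges (GI→C2.4, C1.3→GIII) classify red
although the narrative describes them as BPSD-sparing — their BPSD deltas
sit 0.1–1.7 points past the tolerance; the exact published edge colors
cannot be verified from text.

## Synthetic cohorts

No raw patient data were deposited; the generator emulates exactly what
is public. Domain scores are drawn by inverse transform through the
piecewise-linear quantile function interpolating (0, min), (0.25, Q1),
(0.5, median), (0.75, Q3), (1, max) of each published subgroup summary,
scaled about the median by `dispersion_scale`, rounded, and clamped to
domain bounds. Item levels are uniform random compositions of the sampled
domain score (exact dynamic-programming counts guarantee uniformity over
all compositions with parts in [1, 9]), so scoring a simulated record
reproduces its sampled domain scores exactly. Twelve-week changes are
Gaussian per domain with mean = CI midpoint and sd = half-width·√n/t
back-derived from the published intervals, then rounded and clamped, with
items re-decomposed.

What the generator does **not** emulate: within-subgroup correlation
between domains (not published; domains are sampled independently, which
inflates multivariate spread relative to real patients), item-level
response processes (the scale's item-response-theory calibration is not
published), and any correlation between baseline severity and change. A
green recovery test therefore establishes that the pipeline works on
cohorts with the published marginal structure, not that it would
reproduce the published trees on the real data. Printed means are not
generation targets (the five quantiles determine the sampler); generated
means land within ≈ 1.5 points as a diagnostic. `dispersion_scale` = 0.5
is the stated default for cluster-recovery experiments because published
IQRs overlap across adjacent subgroups; at 1.0 the planted structure is
only partially recoverable. The CDR-0.5/0 stratum size 114 carries an
unexplained asterisk in its source table; the fixture records 114 and
flags it.

## Numerical and engineering choices

* Quantiles: numpy `"linear"` everywhere, matching (n−1)p + 1.
* t quantiles from scipy; the change-sd back-derivation uses the same t
  convention as the CI computation.
* Linkage determinism: exact-equality tie-break, no jitter; permutation
  invariance holds whenever pairwise distances are distinct.
* Heights are checked non-decreasing (tolerance 1e−9) after every run.
* CSV I/O: UTF-8, comma-separated, "." decimal; CDR written as the
  strings 0, 0.5, 1, 2, 3 to avoid float drift on round trips.
* The pipeline buffers all artifacts and writes only after every stage
  succeeds, so failures leave no partial outputs; the manifest records
  config, config hash, seed, and retained/dropped counts.
* Out of scope by design: item-response-theory calibration, Z-score
  linkage of item levels, MMSE↔TDD conversion, concurrent-validity
  correlations against DAD/NPI/MMSE (these require the undeposited raw
  data), transition-probability estimation on the roadmap.
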