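"""Synthetic cohort generator: quantile matching, item decomposition,
seed determinism, and longitudinal change emulation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from abcds import (
    decompose_domain_score,
    domain_scores,
    load_change_specs,
    load_subgroup_specs,
    sample_domain_score,
    simulate_changes,
    simulate_cohort,
)
from abcds.synthetic import DOMAIN_BOUNDS, SubgroupSpec

C11_ADL = {"min": 40, "q1": 48, "median": 50, "q3": 52, "max": 54}


def degenerate_spec(value=5, n=1):
    summ = {s: value for s in ("min", "q1", "median", "q3", "max")}
    return SubgroupSpec(
        name="D", stratum=1.0, n=n,
        summaries={"adl": {k: 30 for k in summ}, "bpsd": {k: 15 for k in summ},
                   "cf": {k: 20 for k in summ}, "cdr_sob": {k: 5.0 for k in summ}},
    )


class TestSampleDomainScore:
    def test_degenerate_summary_constant(self, rng):
        summ = {s: 7 for s in ("min", "q1", "median", "q3", "max")}
        draws = sample_domain_score(summ, rng, size=100)
        assert np.all(draws == 7)

    def test_median_at_half(self):
        class FakeRng:
            def random(self, size):
                return np.full(size, 0.5)

        val = sample_domain_score(C11_ADL, FakeRng(), integer=False)
        assert val == 50.0

    def test_quartiles_recovered_at_scale(self, rng):
        draws = sample_domain_score(C11_ADL, rng, size=100_000, bounds=(6, 54))
        q1, med, q3 = np.quantile(draws, [0.25, 0.5, 0.75])
        assert abs(q1 - 48) <= 1 and abs(med - 50) <= 1 and abs(q3 - 52) <= 1

    def test_dispersion_shrinks_about_median(self, rng):
        full = sample_domain_score(C11_ADL, rng, size=20_000, integer=False)
        half = sample_domain_score(C11_ADL, rng, 0.5, size=20_000, integer=False)
        assert np.median(half) == pytest.approx(np.median(full), abs=0.2)
        assert stats.iqr(half) == pytest.approx(stats.iqr(full) / 2, rel=0.1)

    def test_fivenum_recovery_all_fixture_subgroups(self, rng):
        """Generated five-number summaries track the spec within +/-1 point."""
        for spec in load_subgroup_specs():
            for measure in ("adl", "bpsd", "cf"):
                summ = spec.summaries[measure]
                draws = sample_domain_score(
                    summ, rng, size=10_000, bounds=DOMAIN_BOUNDS[measure]
                )
                got = np.quantile(draws, [0.0, 0.25, 0.5, 0.75, 1.0])
                want = [summ[s] for s in ("min", "q1", "median", "q3", "max")]
                assert np.all(np.abs(got - want) <= 1.0), (spec.name, measure)


class TestDecompose:
    @pytest.mark.parametrize("score, m, expected", [(6, 6, (1,) * 6), (54, 6, (9,) * 6)])
    def test_unique_compositions(self, score, m, expected, rng):
        assert decompose_domain_score(score, m, rng) == expected

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            decompose_domain_score(2, 3, rng)
        with pytest.raises(ValueError):
            decompose_domain_score(28, 3, rng)

    def test_parts_sum_and_bounds(self, rng):
        for _ in range(200):
            m = int(rng.integers(3, 7))
            s = int(rng.integers(m, 9 * m + 1))
            parts = decompose_domain_score(s, m, rng)
            assert sum(parts) == s
            assert all(1 <= p <= 9 for p in parts)

    def test_uniform_over_enumerated_compositions(self, rng):
        """S=10 into 3 parts: empirical distribution vs full enumeration."""
        space = [
            c for c in itertools.product(range(1, 10), repeat=3) if sum(c) == 10
        ]
        assert len(space) == 36
        counts = dict.fromkeys(space, 0)
        n_draws = 50_000
        for _ in range(n_draws):
            counts[decompose_domain_score(10, 3, rng)] += 1
        observed = np.array(list(counts.values()))
        _, p = stats.chisquare(observed)
        assert p > 0.01


class TestSimulateCohort:
    def test_degenerate_spec_fully_determined(self, rng):
        (rec,) = simulate_cohort([degenerate_spec()], seed=1)
        ds = domain_scores(rec)
        assert (ds.adl, ds.bpsd, ds.cf) == (30, 15, 20)
        assert rec.cdr_sob == 5.0

    def test_table_counts_and_stratum(self):
        specs = load_subgroup_specs(stratum=1)
        cohort = simulate_cohort(specs, seed=3)
        assert len(cohort) == 99
        assert all(r.cdr == 1.0 for r in cohort)

    def test_scoring_round_trip(self, cdr1_cohort):
        """Items always sum back to the sampled domain scores."""
        for rec in cdr1_cohort:
            ds = domain_scores(rec)
            assert ds.adl == sum(rec.item(q) for q in (1, 2, 3, 4, 11, 12))
            assert 6 <= ds.adl <= 54 and 3 <= ds.bpsd <= 27 and 4 <= ds.cf <= 36

    def test_seed_determinism(self):
        specs = load_subgroup_specs(stratum=3)
        assert simulate_cohort(specs, seed=7) == simulate_cohort(specs, seed=7)
        assert simulate_cohort(specs, seed=7) != simulate_cohort(specs, seed=8)

    def test_cdr_sob_on_half_grid(self, cdr1_cohort):
        for rec in cdr1_cohort:
            assert rec.cdr_sob is not None
            assert (rec.cdr_sob * 2) == int(rec.cdr_sob * 2)
            assert 0 <= rec.cdr_sob <= 18


class TestSimulateChanges:
    def test_zero_change_spec_is_identity(self, rng):
        from abcds.synthetic import ChangeSpec

        base = simulate_cohort(load_subgroup_specs(stratum=1), seed=5)
        spec = ChangeSpec(
            stratum="CDR 1", cdr_levels=(1.0,), n=99,
            measures={m: (0.0, 0.0) for m in ("adl", "bpsd", "cf")},
        )
        follow = simulate_changes(base, [spec], seed=6)
        for b, f in zip(base, follow):
            db, df = domain_scores(b), domain_scores(f)
            assert (db.adl, db.bpsd, db.cf) == (df.adl, df.bpsd, df.cf)
            assert f.visit == "week12" and f.patient_id == b.patient_id

    def test_clamping_at_domain_floor(self):
        from abcds.synthetic import ChangeSpec

        base = simulate_cohort([degenerate_spec()], seed=1)
        crash = ChangeSpec(
            stratum="CDR 1", cdr_levels=(1.0,), n=10,
            measures={m: (-100.0, 0.0) for m in ("adl", "bpsd", "cf")},
        )
        (follow,) = simulate_changes(base, [crash], seed=2)
        ds = domain_scores(follow)
        assert (ds.adl, ds.bpsd, ds.cf) == (6, 3, 4)

    def test_regenerated_ci_covers_mu(self, rng):
        """CIs recomputed from simulated changes cover the generating mu ~95%.

        Scaled to 400 replicates of the CDR-1 TDD change model to stay
        fast; the binomial band at 400 reps is about +/-2.5 points.
        """
        from abcds.longitudinal import change_ci
        from abcds.synthetic import derive_mu_sigma

        mu, sigma = derive_mu_sigma(-2.03, -0.20, 99)
        hits = 0
        reps = 400
        for _ in range(reps):
            s = change_ci(rng.normal(mu, sigma, size=99))
            hits += s.ci_lower <= mu <= s.ci_upper
        assert 0.91 <= hits / reps <= 0.985

    def test_missing_stratum_spec_rejected(self):
        base = simulate_cohort([degenerate_spec()], seed=1)
        with pytest.raises(ValueError, match="no change spec"):
            simulate_changes(base, load_change_specs()[:1], seed=2)  # CDR 3 only


class TestPipelineRecovery:
    def test_ward_k4_recovers_planted_subgroups(self, cdr1_cohort):
        """Ward cut at k=4 re-finds >= 90% of planted CDR-1 membership."""
        from collections import Counter

        from abcds import cut, linkage, score_cohort

        scored = score_cohort(cdr1_cohort)
        dend = linkage(
            scored[["adl", "bpsd", "cf"]].to_numpy(float), "ward",
            leaf_ids=scored["patient_id"],
        )
        labels = cut(dend, 4).labels
        truth = [r.patient_id.rsplit("-", 1)[0] for r in cdr1_cohort]
        # majority matching: each cluster votes for its dominant subgroup
        votes = {}
        for t, lab in zip(truth, labels):
            votes.setdefault(lab, Counter())[t] += 1
        correct = sum(c.most_common(1)[0][1] for c in votes.values())
        assert correct / len(truth) >= 0.90
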