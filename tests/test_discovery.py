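"""Enhanced-Sequence discovery: FET oracle, motif expansion, replication,
Hamming clustering, and order invariance."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from conftest import make_repertoire
from garep.discovery import (
    DiscoveryConfig,
    EnhancedSequenceDiscovery,
    _CohortData,
    expand_wildcards,
    fet_enrichment,
    hamming_clusters,
    presence_matrix,
    replicate_filter,
)
from garep.io import SequenceKey
from garep.motifs import MotifKey


def fet_oracle(a, b, c, d):
    """Exact one-sided enrichment p by exhaustive hypergeometric tail sum."""
    n = a + b + c + d
    k = a + c  # total present
    m = a + b  # cases
    total = Fraction(0)
    for x in range(a, min(k, m) + 1):
        if k - x > n - m:
            continue
        total += Fraction(comb(m, x) * comb(n - m, k - x), comb(n, k))
    return float(total)


class TestFisherEnrichment:
    def test_exhaustive_sweep_small_margins(self):
        # every table with all margins <= 8 against the exact tail sum
        for a in range(0, 9):
            for b in range(0, 9):
                for c in range(0, 9):
                    for d in range(0, 9):
                        if a + b == 0 or c + d == 0:
                            continue
                        got = fet_enrichment(a, b, c, d)
                        assert got == pytest.approx(fet_oracle(a, b, c, d), rel=1e-10)

    def test_discovery_cohort_sized_example(self):
        # 5/58 cases present vs 2/211 controls present
        got = fet_enrichment(5, 53, 2, 209)
        assert got == pytest.approx(fet_oracle(5, 53, 2, 209), rel=1e-12)
        scipy_p = fisher_exact([[5, 53], [2, 209]], alternative="greater")[1]
        assert got == pytest.approx(scipy_p, rel=1e-9)

    def test_presence_only_in_controls_is_uninformative(self):
        assert fet_enrichment(0, 58, 10, 201) == pytest.approx(1.0)

    def test_all_cases_no_controls_equals_point_mass(self):
        # P[X >= m] when all m cases are present = hypergeometric point prob
        a, b, c, d = 4, 0, 0, 6
        n, k, m = 10, 4, 4
        point = comb(m, 4) * comb(n - m, 0) / comb(n, k)
        assert fet_enrichment(a, b, c, d) == pytest.approx(point)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fet_enrichment(-1, 2, 3, 4)


K1 = SequenceKey("CASSSHGGEQYF", "TRBV05-06", "TRBJ02-07")
K2 = SequenceKey("CASSTHGGEQYF", "TRBV05-06", "TRBJ02-07")
K3 = SequenceKey("CAAAAAAAAF", "TRBV09", "TRBJ01-01")


def _rep(sample_id, keys):
    rows = [
        (f"{sample_id}NT{i}{j}", k.junction_aa, k.v_gene, k.j_gene, 1, True)
        for i, k in enumerate(keys)
        for j in range(1)
    ]
    if not rows:
        rows = [(f"{sample_id}NTX", "CWWWWF", "TRBV02", "TRBJ01-01", 1, True)]
    return make_repertoire(rows, sample_id=sample_id)


class TestPresenceMatrix:
    def test_nucleotide_variants_collapse_to_one_entry(self):
        rep = make_repertoire(
            [("NT1", *K1, 2, True), ("NT2", *K1, 3, True)]
        )
        pres = presence_matrix([rep])
        assert pres.shape == (1, 1)
        assert pres.iloc[0, 0]

    def test_row_sums_equal_unique_key_counts(self, rng):
        reps = [_rep(f"s{i}", [K1, K2] if i % 2 else [K1]) for i in range(4)]
        pres = presence_matrix(reps)
        for rep in reps:
            assert pres.loc[rep.sample_id].sum() == len(rep.productive_keys())

    def test_min_samples_drops_private_keys(self):
        reps = [_rep("a", [K1, K3]), _rep("b", [K1])]
        pres = presence_matrix(reps, min_samples=2)
        assert list(pres.columns) == [K1]


def _toy_cohort(name, case_rows, control_rows):
    """Build a _CohortData from lists of key-lists."""
    reps = [_rep(f"{name}ca{i}", ks) for i, ks in enumerate(case_rows)]
    reps += [_rep(f"{name}co{i}", ks) for i, ks in enumerate(control_rows)]
    y = np.array([True] * len(case_rows) + [False] * len(control_rows))
    return _CohortData(name=name, pres=presence_matrix(reps), is_case=y)


class TestWildcardExpansion:
    def test_candidate_positions_are_interior(self):
        cd = _toy_cohort(
            "c1",
            [[K1]] * 6 + [[K2]] * 6 + [[]] * 3,
            [[]] * 30,
        )
        motifs = expand_wildcards([K1], [cd], DiscoveryConfig(min_replicated_cohorts=1))
        patterns = {m.target.pattern for m in motifs}
        # position 5 wildcard unites the two variant keys
        assert "CASSxHGGEQYF" in patterns
        for p in patterns:
            assert not p.startswith("x") and not p.endswith("x")

    def test_union_presence_beats_each_member(self):
        cd = _toy_cohort(
            "c1",
            [[K1]] * 6 + [[K2]] * 6 + [[]] * 3,
            [[]] * 30,
        )
        motifs = expand_wildcards([K1], [cd], DiscoveryConfig(min_replicated_cohorts=1))
        m = next(m for m in motifs if m.target.pattern == "CASSxHGGEQYF")
        assert m.target.members == frozenset({K1, K2})
        p_union = m.pvalues["c1"]
        assert p_union < cd.key_p(K1) and p_union < cd.key_p(K2)
        # verify retention rule numerically against the direct FET
        a = 12
        assert p_union == pytest.approx(fet_oracle(a, 3, 0, 30), rel=1e-9)

    def test_motif_with_only_seed_member_fails_strict_improvement(self):
        cd = _toy_cohort("c1", [[K3]] * 8 + [[]] * 2, [[]] * 40)
        motifs = expand_wildcards([K3], [cd], DiscoveryConfig(min_replicated_cohorts=1))
        # every candidate motif has exactly one member (the seed), so its
        # p equals the seed's p and the strict < condition rejects it
        assert motifs == []


class TestReplication:
    def _candidate(self, pvals, passed):
        from garep.discovery import EnhancedSequence

        return EnhancedSequence(
            target=K1,
            tables={c: (1, 1, 1, 1) for c in pvals},
            pvalues=pvals,
            replicated_cohorts=frozenset(passed),
        )

    def test_two_of_three_cohorts_retained(self):
        es = self._candidate({"a": 5e-4, "b": 5e-4, "c": 0.5}, {"a", "b"})
        kept = replicate_filter([es], DiscoveryConfig())
        assert len(kept) == 1
        assert kept[0].replicated_cohorts == {"a", "b"}

    def test_single_cohort_dropped(self):
        es = self._candidate({"a": 1e-9, "b": 0.9, "c": 0.9}, {"a"})
        assert replicate_filter([es], DiscoveryConfig()) == []

    def test_dropping_a_cohort_never_adds_discoveries(self, rng):
        # monotonicity: the replicated set from 2 cohorts is a subset of
        # the replicated set from the same 2 plus one more
        def fit(reps, y, cohort):
            return {
                es.target
                for es in EnhancedSequenceDiscovery(p_seq=0.05, expand_motifs=False)
                .fit(reps, y, cohort=cohort)
                .enhanced_sequences_
            }

        reps, y, cohort = [], [], []
        for cname in ("c1", "c2", "c3"):
            for i in range(12):
                case = i < 6
                keys = [K1] if (case and rng.random() < 0.8) else []
                if rng.random() < 0.3:
                    keys.append(K3)
                reps.append(_rep(f"{cname}s{i}", keys))
                y.append(case)
                cohort.append(cname)
        y, cohort = np.array(y), np.array(cohort)
        full = fit(reps, y, cohort)
        mask = cohort != "c3"
        reduced = fit([r for r, m in zip(reps, mask) if m], y[mask], cohort[mask])
        assert reduced <= full


class TestHammingClusters:
    def test_single_difference_pair_clusters_with_consensus(self):
        clusters = hamming_clusters([K1, K2])
        assert len(clusters) == 1
        members, consensus = clusters[0]
        assert consensus == "CASSxHGGEQYF"

    def test_different_lengths_never_cluster(self):
        a = SequenceKey("CASSF", "TRBV09", "TRBJ01-01")
        b = SequenceKey("CASSAF", "TRBV09", "TRBJ01-01")
        clusters = hamming_clusters([a, b])
        assert len(clusters) == 2

    def test_published_neighbour_pair_clusters(self):
        # CASSLGQGAGGYTF and CASSSGQGAGGYTF differ at one position
        a = SequenceKey("CASSLGQGAGGYTF", "TRBV05-06", "TRBJ01-02")
        b = SequenceKey("CASSSGQGAGGYTF", "TRBV05-06", "TRBJ01-02")
        clusters = hamming_clusters([a, b], d=1)
        assert len(clusters) == 1
        assert clusters[0][1] == "CASSxGQGAGGYTF"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hamming_clusters([])


class TestDiscoveryEstimator:
    def _dataset(self, rng, planted_rate=0.85):
        reps, y, cohort = [], [], []
        for cname, (n_ca, n_co) in (("c1", (15, 40)), ("c2", (15, 40))):
            for i in range(n_ca + n_co):
                case = i < n_ca
                keys = []
                if case and rng.random() < planted_rate:
                    keys.append(K1)
                if rng.random() < 0.10:
                    keys.append(K3)
                reps.append(_rep(f"{cname}s{i}", keys))
                y.append(case)
                cohort.append(cname)
        return reps, np.array(y), np.array(cohort)

    def test_recovers_planted_key_and_is_order_invariant(self, rng):
        reps, y, cohort = self._dataset(rng)
        disc = EnhancedSequenceDiscovery().fit(reps, y, cohort=cohort)
        found = {es.target for es in disc.keys_}
        assert K1 in found
        assert K3 not in found
        perm = rng.permutation(len(reps))
        disc2 = EnhancedSequenceDiscovery().fit(
            [reps[i] for i in perm], y[perm], cohort=cohort[perm]
        )
        assert {es.target for es in disc2.keys_} == found

    def test_cohort_composition_errors(self, rng):
        reps, y, cohort = self._dataset(rng)
        with pytest.raises(ValueError, match="min_replicated_cohorts"):
            EnhancedSequenceDiscovery(min_replicated_cohorts=3).fit(reps, y, cohort=cohort)
        with pytest.raises(ValueError, match="case"):
            EnhancedSequenceDiscovery(min_replicated_cohorts=1).fit(
                reps, np.zeros(len(reps), dtype=bool), cohort=cohort
            )

    def test_transform_scores_pattern(self, rng):
        reps, y, cohort = self._dataset(rng)
        disc = EnhancedSequenceDiscovery().fit(reps, y, cohort=cohort)
        scores = disc.transform(reps[:10])
        assert set(scores.columns) == {"breadth", "depth"}
        assert (scores["breadth"] >= 0).all() and (scores["breadth"] <= 1).all()


def test_type_one_error_calibrated_under_global_null(rng):
    """With no planted keys the per-cohort ES count at p < 0.001 stays
    within the binomial envelope implied by the threshold."""
    n_tests = 0
    n_hits = 0
    for seed in range(3):
        local = np.random.default_rng(seed)
        reps, y = [], []
        pool = [
            SequenceKey("C" + "".join(local.choice(list("ARNDQ"), 8)) + "F",
                        "TRBV09", "TRBJ01-01")
            for _ in range(300)
        ]
        for i in range(120):
            mask = local.random(len(pool)) < 0.08
            reps.append(_rep(f"s{i}", [k for k, m in zip(pool, mask) if m]))
            y.append(i < 30)
        from garep.discovery import cohort_pvalues

        pres = presence_matrix(reps, min_samples=2)
        p = cohort_pvalues(pres, np.array(y))
        n_tests += len(p)
        n_hits += int((p < 1e-3).sum())
    # discrete FET is conservative: expected hits <= n_tests * 1e-3;
    # allow the upper 99.9% Poisson envelope
    lam = n_tests * 1e-3
    assert n_hits <= lam + 3 * np.sqrt(lam) + 3
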