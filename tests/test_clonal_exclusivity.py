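"""Exclusivity labelling, the exact Poisson-binomial null, and cohort tests."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from clonepair.clonal_exclusivity import test_all_pairs as all_pairs_test
from clonepair.clonal_exclusivity import (
    exclusivity_test,
    label_pair,
    pair_null_probability,
    permutation_pvalue,
    poisson_binomial_tail,
    propagate_to_descendants,
)
from clonepair.io_formats import PathwayCloneMatrix


def matrix(patient, k, clones_a, clones_b, a="A", b="B"):
    clone_ids = [f"c{i}" for i in range(k)]
    rows = np.zeros((2, k), dtype=int)
    rows[0, list(clones_a)] = 1
    rows[1, list(clones_b)] = 1
    return PathwayCloneMatrix(patient, [a, b], clone_ids, rows)


def excl_prob_by_enumeration(k, sa, sb):
    """Exact P(disjoint) enumerating all C(k,sa) x C(k,sb) placements."""
    hits = total = 0
    for A in combinations(range(k), sa):
        for B in combinations(range(k), sb):
            total += 1
            hits += not set(A) & set(B)
    return Fraction(hits, total)


def tail_by_enumeration(probs, t):
    """Exact P(T >= t) by dynamic programming over exact rationals."""
    dist = {0: Fraction(1)}
    for p in probs:
        nxt = {}
        for s, q in dist.items():
            nxt[s] = nxt.get(s, Fraction(0)) + q * (1 - p)
            nxt[s + 1] = nxt.get(s + 1, Fraction(0)) + q * p
        dist = nxt
    return float(sum(q for s, q in dist.items() if s >= t))


class TestLabelling:
    def test_disjoint_sets_exclusive(self):
        m = matrix("P8", 3, [0], [2])
        assert label_pair(m, "A", "B").label == "exclusive"

    def test_overlap_co_occurring(self):
        m = matrix("P", 3, [0, 1], [1])
        assert label_pair(m, "A", "B").label == "co_occurring"

    def test_empty_set_not_comparable(self):
        m = matrix("P", 3, [], [0])
        assert label_pair(m, "A", "B").label == "not_comparable"

    def test_absent_entity_not_comparable(self):
        m = matrix("P", 3, [0], [1])
        assert label_pair(m, "A", "ZZZ").label == "not_comparable"


class TestNullProbability:
    @pytest.mark.parametrize(
        "k,sa,sb,expected",
        [
            (3, 1, 1, Fraction(2, 3)),
            (3, 2, 2, Fraction(0)),          # pigeonhole
            (5, 2, 2, Fraction(3, 10)),
        ],
    )
    def test_closed_form(self, k, sa, sb, expected):
        # only the set sizes enter the null probability
        m = matrix("P", k, list(range(sa)), list(range(k - sb, k)))
        assert pair_null_probability(m, "A", "B") == pytest.approx(float(expected))

    def test_matches_enumeration_for_all_small_cases(self):
        for k in range(1, 6):
            for sa in range(1, k + 1):
                for sb in range(1, k + 1):
                    m = matrix("P", k, list(range(sa)),
                               list(range(max(k - sb, 0), k)))
                    got = pair_null_probability(m, "A", "B")
                    assert got == pytest.approx(
                        float(excl_prob_by_enumeration(k, sa, sb)), abs=1e-12
                    )

    def test_symmetric_in_a_and_b(self):
        m = matrix("P", 5, [0, 1], [3])
        assert pair_null_probability(m, "A", "B") == pytest.approx(
            pair_null_probability(m, "B", "A")
        )

    def test_empty_set_errors(self):
        m = matrix("P", 3, [], [0])
        with pytest.raises(ValueError):
            pair_null_probability(m, "A", "B")


class TestCohortTest:
    def test_two_patient_worked_example(self):
        """Two K=3 patients with singleton sets, both exclusive: p = (2/3)^2."""
        ms = [matrix("P8", 3, [0], [2]), matrix("P14", 3, [1], [2])]
        res = exclusivity_test(ms, "A", "B")
        assert res.n_patients_both == 2 and res.n_exclusive == 2
        assert res.p == pytest.approx(4 / 9)

    def test_small_per_patient_probability_product(self):
        """Exclusive in 2 of 2 patients with P_excl = 0.01 each: p = 1e-4."""
        assert poisson_binomial_tail([0.01, 0.01], 2) == pytest.approx(1e-4)

    def test_zero_observed_gives_p_one(self):
        ms = [matrix("P1", 3, [0], [0]), matrix("P2", 3, [1], [1])]
        res = exclusivity_test(ms, "A", "B")
        assert res.n_exclusive == 0 and res.p == pytest.approx(1.0)

    def test_min_patients_gate(self):
        ms = [matrix("P1", 3, [0], [2])]
        assert exclusivity_test(ms, "A", "B", min_patients=2) is None
        with pytest.raises(ValueError):
            exclusivity_test(ms, "A", "B", min_patients=0)

    def test_symmetry_in_entities(self):
        ms = [matrix("P1", 4, [0], [2, 3]), matrix("P2", 3, [0, 1], [2])]
        r1 = exclusivity_test(ms, "A", "B")
        r2 = exclusivity_test(ms, "B", "A")
        assert r1.p == pytest.approx(r2.p)
        assert (r1.n_patients_both, r1.n_exclusive) == (
            r2.n_patients_both, r2.n_exclusive
        )

    def test_tail_matches_exact_enumeration_small_instances(self, rng):
        """Poisson-binomial tail equals rational-arithmetic DP on all
        configurations with <= 6 patients and K <= 5."""
        for _ in range(200):
            n = int(rng.integers(1, 7))
            probs, t = [], int(rng.integers(0, n + 1))
            for _ in range(n):
                k = int(rng.integers(1, 6))
                sa = int(rng.integers(1, k + 1))
                sb = int(rng.integers(1, k + 1))
                probs.append(float(excl_prob_by_enumeration(k, sa, sb)))
            assert poisson_binomial_tail(probs, t) == pytest.approx(
                tail_by_enumeration(probs, t), abs=1e-12
            )

    def test_matches_seeded_permutation_mode(self):
        ms = [matrix("P1", 4, [0], [2]), matrix("P2", 4, [1], [3]),
              matrix("P3", 5, [0, 1], [3])]
        exact = exclusivity_test(ms, "A", "B").p
        mc = permutation_pvalue(ms, "A", "B", n_permutations=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)


class TestAllPairs:
    def test_planted_pair_flagged_in_both_patients(self):
        ms = [matrix("P5", 4, [0], [2], a="TP53", b="MUC16"),
              matrix("P81", 4, [1], [3], a="TP53", b="MUC16")]
        (res,) = all_pairs_test(ms)
        assert {res.entity_a, res.entity_b} == {"TP53", "MUC16"}
        assert res.n_exclusive == 2
        labels = [o.label for o in res.per_patient]
        assert labels == ["exclusive", "exclusive"]

    def test_single_patient_cohort_empty(self):
        assert all_pairs_test([matrix("P1", 3, [0], [2])], min_patients=2) == []

    def test_bh_family_is_tested_pairs_only(self):
        ms = []
        for pid in ("P1", "P2", "P3"):
            clone_ids = ["c0", "c1", "c2", "c3"]
            rows = np.array([[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0]])
            ms.append(PathwayCloneMatrix(pid, ["A", "B", "C"], clone_ids, rows))
        results = all_pairs_test(ms)
        assert len(results) == 3  # AB, AC, BC
        ps = [r.p for r in results]
        assert results == sorted(results, key=lambda r: (r.p, r.entity_a,
                                                         r.entity_b))
        assert all(r.q >= r.p - 1e-12 for r in results)

    def test_enumeration_on_planted_small_instance(self):
        """4 patients, K=4, singleton sets, always exclusive: tail agrees with
        full enumeration over all 4^8 singleton placements."""
        ms = [matrix(f"P{i}", 4, [0], [2]) for i in range(4)]
        res = exclusivity_test(ms, "A", "B")
        hits = total = 0
        for placements in np.ndindex(*(4,) * 8):
            total += 1
            t = sum(placements[2 * i] != placements[2 * i + 1] for i in range(4))
            hits += t >= 4
        assert res.p == pytest.approx(hits / total, abs=1e-12)


def test_propagate_to_descendants():
    m = matrix("P", 3, [0], [2])
    out = propagate_to_descendants(m, parents=[-1, 0, 1])  # chain c0->c1->c2
    assert out.clones_of("A") == {"c0", "c1", "c2"}
    assert out.clones_of("B") == {"c2"}
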