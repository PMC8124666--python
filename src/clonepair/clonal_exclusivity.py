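"""Clonal-exclusivity testing for gene or pathway pairs.

Two entities (genes or pathways) altered in the same tumour are *clonally
exclusive* in a patient when their clone sets are non-empty and disjoint —
the alterations live on parallel branches of the tumour's evolution.  Across
a cohort, the test statistic T is the number of comparable patients labelled
exclusive.  Under the null hypothesis each entity's clone set is a uniformly
random subset of the patient's K clones of its observed size, so patient i
contributes an independent Bernoulli with

    P_excl,i = C(K_i - |A_i|, |B_i|) / C(K_i, |B_i|)

(symmetric in A and B; zero when |A|+|B| > K by pigeonhole).  T then follows
a Poisson-binomial distribution whose tail P(T >= t_obs) is computed exactly
by convolution, making p-values deterministic.  A seeded Monte-Carlo
permutation mode exists for cross-checking.  Conditioning on the observed
set sizes and clone counts controls the two obvious confounders, per-entity
mutation burden and per-patient clone number.

Clones are unordered labels: a mutation counts only in its assigned clone.
``propagate_to_descendants`` is available upstream when matrices are built
from a clone tree, but the deposited-matrix representation does not use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import PathwayCloneMatrix

LABELS = ("exclusive", "co_occurring", "not_comparable")


@dataclass
class PairObservation:
    patient_id: str
    entity_a: str
    entity_b: str
    clones_a: frozenset[str]
    clones_b: frozenset[str]

    @property
    def label(self) -> str:
        if not self.clones_a or not self.clones_b:
            return "not_comparable"
        return "exclusive" if self.clones_a.isdisjoint(self.clones_b) else "co_occurring"


@dataclass
class ExclusivityResult:
    entity_a: str
    entity_b: str
    n_patients_both: int
    n_exclusive: int
    p: float
    q: float = float("nan")
    per_patient: list[PairObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_exclusive <= self.n_patients_both
        assert 0.0 < self.p <= 1.0 + 1e-12


def label_pair(matrix: PathwayCloneMatrix, a: str, b: str) -> PairObservation:
    """Label one entity pair in one patient from its clone matrix."""
    return PairObservation(
        patient_id=matrix.patient_id,
        entity_a=a,
        entity_b=b,
        clones_a=matrix.clones_of(a),
        clones_b=matrix.clones_of(b),
    )


def pair_null_probability(matrix: PathwayCloneMatrix, a: str, b: str) -> float:
    """Null probability that the pair is exclusive in this patient.

    Both clone sets are redrawn uniformly at their observed sizes from the
    patient's K clones; disjointness then has probability
    C(K-|A|, |B|) / C(K, |B|).
    """
    size_a = len(matrix.clones_of(a))
    size_b = len(matrix.clones_of(b))
    if size_a == 0 or size_b == 0:
        raise ValueError(
            f"{matrix.patient_id}: entity with empty clone set ({a!r}, {b!r})"
        )
    k = matrix.n_clones
    if size_a + size_b > k:
        return 0.0
    return comb(k - size_a, size_b) / comb(k, size_b)


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by convolution."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def poisson_binomial_tail(probs: Sequence[float], t: int) -> float:
    """P(T >= t) for the Poisson-binomial sum; 1 when t <= 0."""
    if t <= 0:
        return 1.0
    pmf = poisson_binomial_pmf(probs)
    if t >= len(pmf):
        return 0.0
    return float(min(1.0, pmf[t:].sum()))


def exclusivity_test(
    matrices: Sequence[PathwayCloneMatrix],
    a: str,
    b: str,
    min_patients: int = 2,
) -> ExclusivityResult | None:
    """Cohort-level exclusivity test for one entity pair.

    Patients where both entities have non-empty clone sets are *comparable*.
    With fewer than ``min_patients`` comparable patients the pair is not
    tested (returns None).  p = P(T >= observed exclusive count) under the
    exact Poisson-binomial null.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    observations = [label_pair(m, a, b) for m in matrices]
    comparable = [
        (m, o) for m, o in zip(matrices, observations)
        if o.label != "not_comparable"
    ]
    if len(comparable) < min_patients:
        return None
    probs = [pair_null_probability(m, a, b) for m, _ in comparable]
    t_obs = sum(1 for _, o in comparable if o.label == "exclusive")
    p = poisson_binomial_tail(probs, t_obs)
    return ExclusivityResult(
        entity_a=a,
        entity_b=b,
        n_patients_both=len(comparable),
        n_exclusive=t_obs,
        p=max(p, 5e-324),
        per_patient=observations,
    )


def permutation_pvalue(
    matrices: Sequence[PathwayCloneMatrix],
    a: str,
    b: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Seeded Monte-Carlo cross-check of the exact Poisson-binomial tail.

    Redraws both clone sets at their observed sizes in every comparable
    patient and counts how often the permuted exclusive count reaches the
    observed one.  Add-one smoothed.
    """
    rng = np.random.default_rng(seed)
    sizes = []
    t_obs = 0
    for m in matrices:
        o = label_pair(m, a, b)
        if o.label == "not_comparable":
            continue
        sizes.append((m.n_clones, len(o.clones_a), len(o.clones_b)))
        t_obs += o.label == "exclusive"
    hits = 0
    for _ in range(n_permutations):
        t = 0
        for k, sa, sb in sizes:
            set_a = set(rng.choice(k, size=sa, replace=False))
            set_b = set(rng.choice(k, size=sb, replace=False))
            t += not (set_a & set_b)
        hits += t >= t_obs
    return (hits + 1) / (n_permutations + 1)


def test_all_pairs(
    matrices: Sequence[PathwayCloneMatrix],
    min_patients: int = 2,
) -> list[ExclusivityResult]:
    """Test every unordered entity pair with enough comparable patients.

    BH q-values are computed across the tested family only; results are
    sorted by p then lexicographically.
    """
    entities = sorted({e for m in matrices for e in m.pathway_ids})
    results = []
    for a, b in combinations(entities, 2):
        res = exclusivity_test(matrices, a, b, min_patients=min_patients)
        if res is not None:
            results.append(res)
    if results:
        _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.entity_a, r.entity_b))
    return results


def propagate_to_descendants(
    matrix: PathwayCloneMatrix, parents: Sequence[int]
) -> PathwayCloneMatrix:
    """Alternative representation: mark every descendant of an altered clone.

    ``parents`` is the clone-tree parent vector aligned with
    ``matrix.clone_ids`` (-1 for the root).
    """
    k = matrix.n_clones
    children: dict[int, list[int]] = {i: [] for i in range(k)}
    for i, p in enumerate(parents):
        if p >= 0:
            children[p].append(i)
    altered = matrix.altered.copy()
    for row in altered:
        stack = [i for i in range(k) if row[i]]
        while stack:
            c = stack.pop()
            for ch in children[c]:
                if not row[ch]:
                    row[ch] = 1
                    stack.append(ch)
    return PathwayCloneMatrix(
        patient_id=matrix.patient_id,
        pathway_ids=list(matrix.pathway_ids),
        clone_ids=list(matrix.clone_ids),
        altered=altered,
    )


__all__ = [
    "LABELS",
    "PairObservation",
    "ExclusivityResult",
    "label_pair",
    "pair_null_probability",
    "poisson_binomial_pmf",
    "poisson_binomial_tail",
    "exclusivity_test",
    "permutation_pvalue",
    "test_all_pairs",
    "propagate_to_descendants",
]
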