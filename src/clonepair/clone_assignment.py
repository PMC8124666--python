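"""Clone assignment from paired-biopsy VAFs.

Mutations of one patient are clustered in the two-dimensional space of
per-sample variant allele frequencies under a binomial mixture: cluster c has
centre (theta_c1, theta_c2) and the alt count of mutation m in sample s is
Binomial(depth_ms, theta_cs).  The number of clusters K is selected by BIC
over a configurable range (ties broken toward smaller K) and each K is fitted
with multiple k-means++-seeded EM restarts, keeping the best log-likelihood.

Input variants are assumed pre-filtered to copy-number-neutral territory, so
the cancer cell fraction of cluster c in sample s is min(1, 2*theta_cs)
(pure diploid heterozygous mutations).  Reported clone fractions are the
increments of the cluster CCFs after sorting by mean CCF, i.e. the clusters
are mapped onto a linear chain with the largest-CCF cluster ancestral; the
top row of the fraction matrix is preceded by a normal-cell row 1 - CCF_max.
Pigeonhole violations (a negative increment, meaning the chain assumption is
inconsistent with the data) are reported on the profile, not corrected.

This is a deliberately light-weight stand-in for full phylogenetic latent-
feature inference: downstream clonal-exclusivity testing needs only the
mutation-to-clone assignment and the per-sample clone fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .heterogeneity import PatientVariantSet
from .io_formats import PathwayCloneMatrix

log = logging.getLogger(__name__)

_THETA_EPS = 1e-6


@dataclass
class CloneProfile:
    """Fitted clone structure of one patient."""

    patient_id: str
    K: int
    clone_ids: list[str]
    #: (K+1, 2) matrix: clone rows ordered ancestral -> terminal, then the
    #: normal-cell row "N"; columns TU1, TU2; each column sums to 1.
    fractions: np.ndarray
    centres: np.ndarray  # (K, 2) binomial success rates per sample
    assignment: dict[tuple, str]  # mutation key -> clone id
    fit_score: float  # best model log-likelihood
    n_restarts: int
    bic: float
    pigeonhole_violations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        col_sums = self.fractions.sum(axis=0)
        assert np.allclose(col_sums, 1.0, atol=1e-9), col_sums


def _log_binom_coeff(alt: np.ndarray, depth: np.ndarray) -> np.ndarray:
    return gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)


def _loglik_matrix(alt, depth, theta):
    """(n, K) log P(alt | depth, theta_c) summed over the two samples."""
    # alt, depth: (n, 2); theta: (K, 2)
    t = np.clip(theta, _THETA_EPS, 1 - _THETA_EPS)
    ll = (
        alt[:, None, :] * np.log(t)[None, :, :]
        + (depth - alt)[:, None, :] * np.log1p(-t)[None, :, :]
    )
    return ll.sum(axis=2)


def _kmeanspp_init(vafs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding over the VAF pairs."""
    n = len(vafs)
    centres = [vafs[rng.integers(n)]]
    while len(centres) < k:
        d2 = np.min(
            [((vafs - c) ** 2).sum(axis=1) for c in centres], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centres.append(vafs[rng.integers(n)])
            continue
        centres.append(vafs[rng.choice(n, p=d2 / total)])
    return np.clip(np.array(centres), _THETA_EPS, 1 - _THETA_EPS)


def _em_fit(alt, depth, k, rng, max_iter=500, tol=1e-8):
    """One EM run; returns (loglik, theta, log_pi, responsibilities)."""
    n = len(alt)
    vafs = alt / np.maximum(depth, 1)
    theta = _kmeanspp_init(vafs, k, rng)
    log_pi = np.full(k, -np.log(k))
    const = _log_binom_coeff(alt, depth).sum()
    prev = -np.inf
    for _ in range(max_iter):
        joint = _loglik_matrix(alt, depth, theta) + log_pi[None, :]
        norm = logsumexp(joint, axis=1)
        loglik = norm.sum() + const
        resp = np.exp(joint - norm[:, None])
        weights = resp.sum(axis=0)
        log_pi = np.log(np.maximum(weights, 1e-12)) - np.log(n)
        num = resp.T @ alt
        den = resp.T @ depth
        theta = np.clip(num / np.maximum(den, 1e-12), _THETA_EPS, 1 - _THETA_EPS)
        if loglik - prev < tol:
            prev = loglik
            break
        prev = loglik
    joint = _loglik_matrix(alt, depth, theta) + log_pi[None, :]
    norm = logsumexp(joint, axis=1)
    resp = np.exp(joint - norm[:, None])
    return norm.sum() + const, theta, log_pi, resp


def fit_clones(
    variants: PatientVariantSet,
    k_range: tuple[int, int] = (1, 4),
    n_restarts: int = 20,
    seed: int = 0,
) -> CloneProfile:
    """Cluster a patient's mutations into clones and estimate clone fractions.

    Each K in ``k_range`` is fitted ``n_restarts`` times from k-means++ seeds
    (all randomness flows from ``seed``); the best run per K enters BIC model
    selection, -2 logL + (3K - 1) log n, with ties broken toward smaller K.
    """
    keys, alt, depth = [], [], []
    for v in variants.variants:
        if v.depth_tu1 == 0 and v.depth_tu2 == 0:
            log.warning(
                "%s: variant %s has zero depth in both samples; excluded",
                variants.patient_id, v.key,
            )
            continue
        keys.append(v.key)
        alt.append((v.alt_tu1, v.alt_tu2))
        depth.append((max(v.depth_tu1, 1), max(v.depth_tu2, 1)))
    n = len(keys)
    k_lo, k_hi = k_range
    if n < k_lo:
        raise ValueError(
            f"{variants.patient_id}: {n} usable mutations < minimum K {k_lo}"
        )
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    k_hi = min(k_hi, n)

    ss = np.random.SeedSequence(seed)
    best = None  # (bic, k, loglik, theta, resp)
    for k in range(k_lo, k_hi + 1):
        best_k = None
        # per-restart child seeds: restart r of K k is stable in r, so the
        # best over n restarts is non-decreasing in n
        for r in range(n_restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(k, r))
            )
            ll, theta, log_pi, resp = _em_fit(alt, depth, k, rng)
            if best_k is None or ll > best_k[0]:
                best_k = (ll, theta, resp)
        ll, theta, resp = best_k
        n_params = 3 * k - 1  # 2K centres + (K-1) free weights
        bic = -2.0 * ll + n_params * np.log(n)
        if best is None or bic < best[0] - 1e-12:
            best = (bic, k, ll, theta, resp)
    bic, k, loglik, theta, resp = best

    # order clusters as a chain by mean CCF, largest (ancestral) first
    ccf = np.minimum(1.0, 2.0 * theta)  # (k, 2)
    order = np.argsort(-ccf.mean(axis=1), kind="stable")
    ccf = ccf[order]
    theta = theta[order]
    relabel = {int(old): new for new, old in enumerate(order)}
    hard = np.argmax(resp, axis=1)
    clone_ids = [f"clone{i + 1}" for i in range(k)]
    assignment = {key: clone_ids[relabel[int(c)]] for key, c in zip(keys, hard)}

    fractions = np.zeros((k + 1, 2))
    violations = []
    for s in range(2):
        cum = ccf[:, s]
        inc = np.diff(np.concatenate([cum, [0.0]])) * -1.0  # cum_i - cum_{i+1}
        fractions[1:, s] = inc
        fractions[0, s] = 1.0 - cum[0]
        for i, x in enumerate(inc):
            if x < -1e-9:
                violations.append((clone_ids[i], ["TU1", "TU2"][s]))
    # rows: normal first internally; reorder to clones then normal
    fractions = np.vstack([fractions[1:], fractions[0]])
    fractions[fractions == 0] = 0.0  # normalise -0.0
    if violations:
        log.warning(
            "%s: pigeonhole violations under chain assumption: %s",
            variants.patient_id, violations,
        )
    return CloneProfile(
        patient_id=variants.patient_id,
        K=k,
        clone_ids=clone_ids,
        fractions=fractions,
        centres=theta,
        assignment=assignment,
        fit_score=float(loglik),
        n_restarts=n_restarts,
        bic=float(bic),
        pigeonhole_violations=violations,
    )


def to_entity_clone_matrix(
    profile: CloneProfile,
    entity_map: dict[tuple, list[str]],
) -> PathwayCloneMatrix:
    """Binary entity-by-clone matrix from a clone profile.

    ``entity_map`` sends each mutation key to its entities (gene, or the
    pathways of its gene); keys without entities are dropped (counted in a
    log message).  Entry (e, c) is 1 iff some mutation of entity e is
    assigned to clone c.
    """
    marked: dict[str, set[str]] = {}
    unmapped = 0
    for key, clone in profile.assignment.items():
        entities = entity_map.get(key, [])
        if not entities:
            unmapped += 1
            continue
        for e in entities:
            marked.setdefault(e, set()).add(clone)
    if unmapped:
        log.info("%s: %d mutations without entity mapping dropped",
                 profile.patient_id, unmapped)
    if not marked:
        log.warning("%s: empty entity map; 0-row matrix", profile.patient_id)
    entities = sorted(marked)
    altered = np.array(
        [[1 if c in marked[e] else 0 for c in profile.clone_ids] for e in entities],
        dtype=int,
    ).reshape(len(entities), profile.K)
    return PathwayCloneMatrix(
        patient_id=profile.patient_id,
        pathway_ids=entities,
        clone_ids=list(profile.clone_ids),
        altered=altered,
    )


def gene_entity_map(variants: PatientVariantSet) -> dict[tuple, list[str]]:
    return {
        v.key: [v.gene] for v in variants.variants if v.gene is not None
    }


def pathway_entity_map(variants: PatientVariantSet, db) -> dict[tuple, list[str]]:
    out = {}
    for v in variants.variants:
        if v.gene is None:
            continue
        pws = db.pathways_of(v.gene)
        if pws:
            out[v.key] = pws
    return out


__all__ = [
    "CloneProfile",
    "fit_clones",
    "to_entity_clone_matrix",
    "gene_entity_map",
    "pathway_entity_map",
]
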