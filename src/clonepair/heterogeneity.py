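"""Shared/private mutation classification across paired tumour biopsies.

A mutation detected in both biopsies of a patient is *shared*; one detected
in only one biopsy is *private* to that sample.  Presence means membership in
the sample's post-filter call set — no VAF re-thresholding happens at merge
time.  Variants are keyed by (chrom, pos, ref, alt); indels are assumed
left-aligned upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import VariantCall

STATUSES = ("shared", "private_TU1", "private_TU2")


class DuplicateVariantError(ValueError):
    """The same variant key appears twice within a single sample's call list."""


@dataclass
class MergedVariant:
    """One variant of a patient with presence flags across the two biopsies."""

    chrom: str
    pos: int
    ref: str
    alt: str
    in_tu1: bool
    in_tu2: bool
    gene: str | None = None
    effect: str | None = None
    alt_tu1: int = 0
    depth_tu1: int = 0
    alt_tu2: int = 0
    depth_tu2: int = 0

    def __post_init__(self) -> None:
        if not (self.in_tu1 or self.in_tu2):
            raise ValueError("variant present in neither sample")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def status(self) -> str:
        if self.in_tu1 and self.in_tu2:
            return "shared"
        return "private_TU1" if self.in_tu1 else "private_TU2"


@dataclass
class PatientVariantSet:
    patient_id: str
    variants: list[MergedVariant] = field(default_factory=list)

    def count(self, status: str) -> int:
        return sum(1 for v in self.variants if v.status == status)

    @property
    def n_shared(self) -> int:
        return self.count("shared")

    @property
    def n_private(self) -> int:
        return self.count("private_TU1") + self.count("private_TU2")


@dataclass
class CohortSummary:
    """Cohort-level intra-tumour-heterogeneity summary."""

    per_patient: dict[str, dict[str, int]]  # patient -> status -> count
    mean_private_fraction: float
    n_patients_with_private: int
    gene_frequency: dict[str, float]
    convergent_events: list[tuple[str, str, list]]  # (patient, gene, loci)


def merge_samples(
    tu1: Sequence[VariantCall], tu2: Sequence[VariantCall], patient_id: str | None = None
) -> PatientVariantSet:
    """Merge the two biopsies' call sets of one patient by variant key."""
    if patient_id is None:
        patient_id = tu1[0].patient_id if tu1 else (tu2[0].patient_id if tu2 else "?")

    def index(calls: Sequence[VariantCall], label: str) -> dict:
        out: dict[tuple, VariantCall] = {}
        for c in calls:
            if c.key in out:
                raise DuplicateVariantError(
                    f"{patient_id}/{label}: duplicate variant key {c.key}"
                )
            out[c.key] = c
        return out

    i1, i2 = index(tu1, "TU1"), index(tu2, "TU2")
    merged = []
    for key in sorted(set(i1) | set(i2)):
        a, b = i1.get(key), i2.get(key)
        src = a or b
        merged.append(
            MergedVariant(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                in_tu1=a is not None, in_tu2=b is not None,
                gene=src.gene, effect=src.effect,
                alt_tu1=a.alt_count if a else 0, depth_tu1=a.depth if a else 0,
                alt_tu2=b.alt_count if b else 0, depth_tu2=b.depth if b else 0,
            )
        )
    return PatientVariantSet(patient_id=patient_id, variants=merged)


def private_fraction(p: PatientVariantSet) -> float:
    """(private_TU1 + private_TU2) / total mutations of the patient."""
    total = len(p.variants)
    if total == 0:
        raise ValueError(f"patient {p.patient_id}: private fraction undefined "
                         "for an empty variant set")
    return p.n_private / total


def gene_frequency(cohort: Sequence[PatientVariantSet]) -> dict[str, float]:
    """Fraction of patients carrying at least one mutation per gene."""
    if not cohort:
        raise ValueError("empty cohort")
    counts: dict[str, int] = {}
    for p in cohort:
        genes = {v.gene for v in p.variants if v.gene is not None}
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    n = len(cohort)
    return {g: c / n for g, c in sorted(counts.items())}


def detect_convergence(p: PatientVariantSet) -> list[tuple[str, list, list]]:
    """Genes hit by distinct mutations with differing biopsy presence patterns.

    The signature of convergent evolution at the biopsy level: the same gene
    carries two or more distinct mutations whose shared/private patterns are
    not all identical (e.g. a private TU1 hit and a different private TU2
    hit).  Same-biopsy multiplicity alone does not qualify.
    Returns (gene, sorted loci, statuses) tuples.
    """
    by_gene: dict[str, list[MergedVariant]] = {}
    for v in p.variants:
        if v.gene is not None:
            by_gene.setdefault(v.gene, []).append(v)
    events = []
    for gene in sorted(by_gene):
        vs = by_gene[gene]
        if len({v.key for v in vs}) < 2:
            continue
        patterns = {(v.in_tu1, v.in_tu2) for v in vs}
        if len(patterns) > 1:
            vs_sorted = sorted(vs, key=lambda v: v.key)
            events.append(
                (gene, [v.key for v in vs_sorted], [v.status for v in vs_sorted])
            )
    return events


def summarise_cohort(cohort: Sequence[PatientVariantSet]) -> CohortSummary:
    per_patient = {
        p.patient_id: {s: p.count(s) for s in STATUSES} for p in cohort
    }
    fractions = [private_fraction(p) for p in cohort if p.variants]
    events = []
    for p in cohort:
        for gene, loci, statuses in detect_convergence(p):
            events.append((p.patient_id, gene, loci))
    return CohortSummary(
        per_patient=per_patient,
        mean_private_fraction=sum(fractions) / len(fractions) if fractions else 0.0,
        n_patients_with_private=sum(1 for p in cohort if p.n_private > 0),
        gene_frequency=gene_frequency(cohort) if cohort else {},
        convergent_events=events,
    )


__all__ = [
    "STATUSES",
    "DuplicateVariantError",
    "MergedVariant",
    "PatientVariantSet",
    "CohortSummary",
    "merge_samples",
    "private_fraction",
    "gene_frequency",
    "detect_convergence",
    "summarise_cohort",
]
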