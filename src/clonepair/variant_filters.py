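"""Post-calling variant filters.

Three bespoke filters applied after UMI-consensus variant calling:

* **FFPE artifact filter** — formalin fixation deaminates cytosine, producing
  spurious C>T (and reverse-strand G>A) calls at low allele frequency; such
  substitutions with VAF strictly below 10% are removed.  Indels are exempt
  (deamination produces substitutions only).
* **Copy-number-neutrality filter** — a germline SNP heterozygous in the
  normal (VAF in [0.40, 0.60]) whose tumour VAF falls outside those bounds
  marks a likely copy-number change; somatic calls within 4000 bp (inclusive)
  of such an imbalanced SNP on the same chromosome are removed.
* **Impact-category filter** — keeps HIGH and MODERATE impact variants, keeps
  LOW except synonymous / start-retained / stop-retained changes, and drops
  all MODIFIER-class (intronic, UTR, upstream) variants.

The FFPE and copy-number predicates are independent per-variant tests, so
their composition commutes and each filter is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import EFFECT_PRIORITY, GermlineSNP, IMPACT_CLASSES, VariantCall

log = logging.getLogger(__name__)

REASONS = ("ffpe_artifact", "near_imbalanced_snp", "silent_category")

#: LOW-impact effects that are nevertheless silent and excluded.
SILENT_LOW_EFFECTS = frozenset({"synonymous", "start_retained", "stop_retained"})


@dataclass
class FilterReport:
    """Outcome of one filter pass: retained calls plus removals with reasons."""

    input_count: int
    retained: list[VariantCall]
    removed: list[tuple[VariantCall, str]]

    def __post_init__(self) -> None:
        assert self.input_count == len(self.retained) + len(self.removed)

    @property
    def removed_calls(self) -> list[VariantCall]:
        return [v for v, _ in self.removed]


def ffpe_filter(
    variants: Sequence[VariantCall], vaf_threshold: float = 0.10
) -> FilterReport:
    """Remove C>T / G>A SNVs with VAF strictly below ``vaf_threshold``.

    The inequality is strict: a deamination-type change at exactly the
    threshold VAF is retained.  Indels pass through (logged).
    """
    retained, removed = [], []
    for v in variants:
        if not v.is_snv:
            log.debug("ffpe_filter: indel %s:%s %s>%s exempt", v.chrom, v.pos, v.ref, v.alt)
            retained.append(v)
            continue
        if (v.ref, v.alt) in (("C", "T"), ("G", "A")) and v.vaf < vaf_threshold:
            removed.append((v, "ffpe_artifact"))
        else:
            retained.append(v)
    return FilterReport(len(variants), retained, removed)


def find_imbalanced_snps(
    snps: Sequence[GermlineSNP],
    tumour_sample: str,
    normal_bounds: tuple[float, float] = (0.40, 0.60),
) -> list[GermlineSNP]:
    """Germline SNPs heterozygous in the normal but allelically imbalanced in
    the tumour.

    A SNP qualifies iff its normal VAF lies inside ``normal_bounds``
    (inclusive) and its VAF in ``tumour_sample`` lies strictly outside them —
    the signature of a local copy-number change.
    """
    lo, hi = normal_bounds
    out = []
    for s in snps:
        if tumour_sample not in s.vaf_tumour:
            raise ValueError(
                f"SNP {s.chrom}:{s.pos} has no tumour VAF for sample "
                f"{tumour_sample!r}"
            )
        vt = s.vaf_tumour[tumour_sample]
        if lo <= s.vaf_normal <= hi and not lo <= vt <= hi:
            out.append(s)
    return out


def cn_neutral_filter(
    variants: Sequence[VariantCall],
    imbalanced: Sequence[GermlineSNP],
    window: int = 4000,
) -> FilterReport:
    """Remove variants within ``window`` bp (inclusive) of an imbalanced SNP.

    Distance is ``|variant.pos - snp.pos|`` on the same chromosome; positions
    are 1-based.  Retained variants sit in putatively copy-number-neutral
    territory, the input assumption of downstream clone assignment.
    """
    by_chrom: dict[str, list[int]] = {}
    for s in imbalanced:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    retained, removed = [], []
    for v in variants:
        near = any(
            abs(v.pos - p) <= window for p in by_chrom.get(v.chrom, ())
        )
        if near:
            removed.append((v, "near_imbalanced_snp"))
        else:
            retained.append(v)
    return FilterReport(len(variants), retained, removed)


def impact_filter(variants: Sequence[VariantCall]) -> FilterReport:
    """Keep potentially phenotype-changing variants only.

    HIGH and MODERATE impact are kept; LOW is kept except silent changes
    (synonymous, start-retained, stop-retained); MODIFIER is dropped.
    """
    retained, removed = [], []
    for v in variants:
        if v.impact not in IMPACT_CLASSES:
            raise ValueError(
                f"unknown impact {v.impact!r} at {v.chrom}:{v.pos}"
            )
        if v.impact in ("HIGH", "MODERATE"):
            retained.append(v)
        elif v.impact == "LOW":
            if v.effect in SILENT_LOW_EFFECTS:
                removed.append((v, "silent_category"))
            else:
                retained.append(v)
        else:  # MODIFIER
            removed.append((v, "silent_category"))
    return FilterReport(len(variants), retained, removed)


def prioritise_effect(effects: set[str]) -> str:
    """Highest-priority effect for display, under the fixed ordering
    stop gained > start gained > frameshift indel > inframe indel > missense >
    splice site > 5' UTR > 3' UTR > synonymous (anything else ranks last)."""
    if not effects:
        raise ValueError("empty effect set")
    rank = {e: i for i, e in enumerate(EFFECT_PRIORITY)}
    return min(effects, key=lambda e: (rank.get(e, len(EFFECT_PRIORITY)), e))


def apply_filters(
    variants: Sequence[VariantCall],
    snps: Sequence[GermlineSNP],
    tumour_sample: str,
    *,
    vaf_threshold: float = 0.10,
    window: int = 4000,
    normal_bounds: tuple[float, float] = (0.40, 0.60),
    with_impact: bool = False,
) -> FilterReport:
    """FFPE then copy-number filter (order is immaterial), optionally the
    impact filter, merged into a single report."""
    rep1 = ffpe_filter(variants, vaf_threshold)
    imbalanced = find_imbalanced_snps(snps, tumour_sample, normal_bounds)
    rep2 = cn_neutral_filter(rep1.retained, imbalanced, window)
    removed = rep1.removed + rep2.removed
    retained = rep2.retained
    if with_impact:
        rep3 = impact_filter(retained)
        removed += rep3.removed
        retained = rep3.retained
    return FilterReport(len(variants), retained, removed)


__all__ = [
    "REASONS",
    "SILENT_LOW_EFFECTS",
    "FilterReport",
    "ffpe_filter",
    "find_imbalanced_snps",
    "cn_neutral_filter",
    "impact_filter",
    "prioritise_effect",
    "apply_filters",
]
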