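"""Readers and writers for the external formats the pipeline touches.

Variant calls travel as VCF 4.2 with per-sample ``AD``/``DP`` FORMAT fields
and an optional SnpEff-style ``ANN`` INFO field carrying gene and effect
annotation.  Pathway gene sets use GMT, germline SNP tables and
pathway-by-clone matrices use plain TSV.  Coordinates are 1-based inclusive
(VCF convention) throughout the package; the distance between two positions
is ``|pos1 - pos2|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

SAMPLE_IDS = ("TU1", "TU2", "N")

#: Variant effect categories, ordered from highest to lowest display priority
#: (the ordering used when one colour must represent several mutations of a
#: gene with identical shared/private status).
EFFECT_PRIORITY = (
    "stop_gained",
    "start_gained",
    "frameshift_indel",
    "inframe_indel",
    "missense",
    "splice_site",
    "five_prime_utr",
    "three_prime_utr",
    "synonymous",
)

#: Fixed effect -> SnpEff-style impact class mapping.  ``start_retained`` and
#: ``stop_retained`` are LOW-class effects that the silent-category filter
#: drops alongside synonymous changes.
EFFECT_IMPACT: dict[str, str] = {
    "stop_gained": "HIGH",
    "start_gained": "HIGH",
    "frameshift_indel": "HIGH",
    "inframe_indel": "MODERATE",
    "missense": "MODERATE",
    "splice_site": "LOW",
    "synonymous": "LOW",
    "start_retained": "LOW",
    "stop_retained": "LOW",
    "five_prime_utr": "MODIFIER",
    "three_prime_utr": "MODIFIER",
    "intronic": "MODIFIER",
    "other_modifier": "MODIFIER",
}

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class CountsUnavailableError(FormatError):
    """A VCF record lacks the AD/DP fields needed to compute read counts."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV/indel observed in one sample."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    gene: str | None = None
    effect: str | None = None
    impact: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.effect is not None and self.impact is None:
            object.__setattr__(self, "impact", EFFECT_IMPACT.get(self.effect))

    @property
    def vaf(self) -> float:
        """Variant allele frequency alt_count / depth (0 if depth is 0)."""
        return self.alt_count / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant irrespective of sample: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GermlineSNP:
    """A germline heterozygous SNP with normal and per-tumour-sample VAFs."""

    chrom: str
    pos: int
    vaf_normal: float
    vaf_tumour: Mapping[str, float] = field(default_factory=dict)
    patient_id: str | None = None

    def __post_init__(self) -> None:
        for v in (self.vaf_normal, *self.vaf_tumour.values()):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"VAF {v} outside [0,1] at {self.chrom}:{self.pos}")


@dataclass
class PathwayDB:
    """Mapping from pathway id to its member gene symbols."""

    gene_sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for pw, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"empty gene set for pathway {pw!r}")

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.gene_sets[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.gene_sets

    def __len__(self) -> int:
        return len(self.gene_sets)

    def pathways_of(self, gene: str) -> list[str]:
        return [pw for pw, genes in self.gene_sets.items() if gene in genes]


@dataclass
class PathwayCloneMatrix:
    """Binary altered/not-altered matrix of entities (pathways or genes) x clones."""

    patient_id: str
    pathway_ids: list[str]
    clone_ids: list[str]
    altered: np.ndarray  # shape (n_pathways, n_clones), entries 0/1

    def __post_init__(self) -> None:
        self.altered = np.asarray(self.altered, dtype=int)
        if self.altered.shape != (len(self.pathway_ids), len(self.clone_ids)):
            raise ValueError(
                f"matrix shape {self.altered.shape} inconsistent with "
                f"{len(self.pathway_ids)} pathways x {len(self.clone_ids)} clones"
            )
        bad = ~np.isin(self.altered, (0, 1))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"non-binary cell {self.altered[r, c]!r} at (row {r + 1}, col {c + 1})"
            )

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def clones_of(self, entity: str) -> frozenset[str]:
        """Clone ids in which ``entity`` is altered; empty set if absent."""
        if entity not in self.pathway_ids:
            return frozenset()
        row = self.altered[self.pathway_ids.index(entity)]
        return frozenset(c for c, v in zip(self.clone_ids, row) if v)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    ('INFO', '##INFO=<ID=ANN,Number=.,Type=String,Description='
             '"Functional annotations: Allele|Annotation|Impact|Gene_Name">'),
    ('FORMAT', '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
               '"Allelic depths for the ref and alt alleles">'),
    ('FORMAT', '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'),
]


def read_vcf(
    path: str | Path,
    patient_id: str,
    sample_id: str,
    *,
    ad_alt_first: bool = False,
    annotations: Mapping[tuple[str, int, str, str], tuple[str, str]] | None = None,
) -> list[VariantCall]:
    """Read per-sample somatic calls from a VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one call per ALT allele.  Gene/effect
    annotation is taken from a SnpEff-style ``ANN`` INFO subfield
    (``Allele|Annotation|Impact|Gene_Name``) when present, else from the
    optional ``annotations`` side table keyed by (chrom, pos, ref, alt).

    ``ad_alt_first`` selects the AD dialect: default GATK-style ref count
    first; some callers emit alt first.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    calls: list[VariantCall] = []
    with vcf:
        if len(vcf.header.samples) == 0:
            raise FormatError(f"{path}: VCF has no sample column")
        sample = vcf.header.samples[0]
        for rec in vcf:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            if ad is None or all(a is None for a in ad) or dp is None:
                raise CountsUnavailableError(
                    f"{path}: counts unavailable (missing AD/DP) at "
                    f"{rec.chrom}:{rec.pos}"
                )
            ad = list(ad)
            if ad_alt_first:
                # alt counts first, ref count last
                alt_counts = ad[:-1]
            else:
                alt_counts = ad[1:]
            ann = _parse_ann(rec)
            for i, alt in enumerate(rec.alts or ()):
                gene = effect = impact = None
                if ann and alt in ann:
                    effect, impact, gene = ann[alt]
                elif annotations is not None:
                    side = annotations.get((rec.chrom, rec.pos, rec.ref, alt))
                    if side is not None:
                        gene, effect = side
                        impact = EFFECT_IMPACT.get(effect)
                calls.append(
                    VariantCall(
                        patient_id=patient_id,
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        alt_count=int(alt_counts[i]),
                        depth=int(dp),
                        gene=gene,
                        effect=effect,
                        impact=impact,
                    )
                )
    return calls


def _parse_ann(rec) -> dict[str, tuple[str, str, str]]:
    """ANN entries as {allele: (effect, impact, gene)}."""
    try:
        raw = rec.info.get("ANN")
    except (KeyError, ValueError):  # ANN not declared in this header
        return {}
    if raw is None:
        return {}
    if isinstance(raw, str):
        raw = (raw,)
    out: dict[str, tuple[str, str, str]] = {}
    for entry in raw:
        parts = entry.split("|")
        if len(parts) >= 4:
            allele, effect, impact, gene = parts[:4]
            out.setdefault(allele, (effect, impact, gene))
    return out


def write_vcf(
    path: str | Path,
    calls: Sequence[VariantCall],
    *,
    contigs: Mapping[str, int] | None = None,
    sample_name: str | None = None,
) -> None:
    """Write calls for one sample to a VCF 4.2 file (GATK-style AD, ref first)."""
    header = pysam.VariantHeader()
    if contigs is None:
        seen: dict[str, int] = {}
        for c in calls:
            seen[c.chrom] = max(seen.get(c.chrom, 0), c.pos + len(c.ref) + 1000)
        contigs = seen or {"chr1": 1000}
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for _, line in _VCF_HEADER_LINES:
        header.add_line(line)
    if sample_name is None:
        sample_name = calls[0].sample_id if calls else "SAMPLE"
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
            )
            if c.effect is not None:
                rec.info["ANN"] = f"{c.alt}|{c.effect}|{c.impact}|{c.gene or ''}"
            rec.samples[sample_name]["AD"] = (c.depth - c.alt_count, c.alt_count)
            rec.samples[sample_name]["DP"] = c.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT gene-set file: name TAB description TAB gene [TAB gene ...]."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    "expected at least 3 (name, description, gene...)"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in gene_sets:
                log.warning("duplicate GMT line for pathway %r: taking union", name)
                gene_sets[name] |= set(genes)
            else:
                gene_sets[name] = set(genes)
    return PathwayDB({k: frozenset(v) for k, v in gene_sets.items()})


def write_gmt(path: str | Path, db: PathwayDB) -> None:
    with open(path, "w") as fh:
        for name, genes in db.gene_sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Clone matrices
# ---------------------------------------------------------------------------

def read_clone_matrix(
    path: str | Path,
    patient_id: str | None = None,
    *,
    transposed: bool = False,
) -> PathwayCloneMatrix:
    """Read a pathway-by-clone TSV: header = clone ids, first column = pathway ids.

    ``transposed=True`` accepts the clone-by-pathway orientation instead.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transposed:
        df = df.T
    values = np.empty(df.shape, dtype=int)
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            cell = str(df.iat[r, c]).strip()
            if cell not in ("0", "1"):
                raise FormatError(
                    f"{path}: non-binary cell {cell!r} at (row {r + 1}, col {c + 1})"
                )
            values[r, c] = int(cell)
    if patient_id is None:
        patient_id = Path(path).stem
    return PathwayCloneMatrix(
        patient_id=patient_id,
        pathway_ids=[str(i) for i in df.index],
        clone_ids=[str(c) for c in df.columns],
        altered=values,
    )


def write_clone_matrix(path: str | Path, matrix: PathwayCloneMatrix) -> None:
    df = pd.DataFrame(
        matrix.altered, index=matrix.pathway_ids, columns=matrix.clone_ids
    )
    df.to_csv(path, sep="\t", index_label="pathway")


# ---------------------------------------------------------------------------
# Germline SNP tables
# ---------------------------------------------------------------------------

def read_germline_tsv(path: str | Path) -> list[GermlineSNP]:
    """Read a germline SNP TSV with columns patient_id, chrom, pos, vaf_normal,
    vaf_TU1, vaf_TU2."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "vaf_normal"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    tumour_cols = [c for c in df.columns if c.startswith("vaf_") and c != "vaf_normal"]
    snps = []
    for row in df.itertuples(index=False):
        vaf_t = {c[len("vaf_"):]: float(getattr(row, c)) for c in tumour_cols}
        snps.append(
            GermlineSNP(
                chrom=str(row.chrom),
                pos=int(row.pos),
                vaf_normal=float(row.vaf_normal),
                vaf_tumour=vaf_t,
                patient_id=str(row.patient_id) if hasattr(row, "patient_id") else None,
            )
        )
    return snps


def write_germline_tsv(path: str | Path, snps: Iterable[GermlineSNP]) -> None:
    rows = []
    for s in snps:
        row = {
            "patient_id": s.patient_id,
            "chrom": s.chrom,
            "pos": s.pos,
            "vaf_normal": s.vaf_normal,
        }
        for sample, v in s.vaf_tumour.items():
            row[f"vaf_{sample}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


__all__ = [
    "SAMPLE_IDS",
    "EFFECT_PRIORITY",
    "EFFECT_IMPACT",
    "IMPACT_CLASSES",
    "FormatError",
    "CountsUnavailableError",
    "VariantCall",
    "GermlineSNP",
    "PathwayDB",
    "PathwayCloneMatrix",
    "read_vcf",
    "write_vcf",
    "read_gmt",
    "write_gmt",
    "read_clone_matrix",
    "write_clone_matrix",
    "read_germline_tsv",
    "write_germline_tsv",
]
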