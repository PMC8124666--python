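"""Synthetic paired-biopsy cohorts with ground truth.

Each simulated patient mirrors the study design this package targets: two
spatially separated tumour biopsies (TU1, TU2) plus a matched normal, a small
clone tree with per-sample clone fractions, copy-number-neutral diploid
somatic VAFs with binomial read-count noise, low-VAF C>T/G>A FFPE artifacts
confined to a single sample, germline heterozygous SNPs whose tumour-sample
allelic imbalance marks copy-number-variant regions, and optionally planted
clonally exclusive pathway pairs.

The expected VAF of a mutation assigned to clone c in sample s is

    v(m, s) = 0.5 * sum_{c' in subtree(c)} F[c', s]

(diploid, copy-number neutral; descendants inherit ancestral mutations).
Observed alt counts are Binomial(depth, v); a ``noise="none"`` mode replaces
the draw by its rounded expectation for noise-controlled tests.

Two deliberate departures from real data keep truth labels unambiguous: true
somatic substitutions never use the C>T/G>A deamination channel (reserved for
artifacts), and germline SNPs outside CNV regions draw all VAFs inside
[0.44, 0.56] so they can never be called imbalanced.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    EFFECT_IMPACT,
    GermlineSNP,
    PathwayCloneMatrix,
    PathwayDB,
    VariantCall,
    write_germline_tsv,
    write_vcf,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: ccRCC-flavoured default gene panel: recurrently altered kidney-cancer genes
#: padded with generic filler symbols.
DEFAULT_PANEL_GENES = (
    "VHL", "PBRM1", "SETD2", "BAP1", "TP53", "MUC6", "MUC16", "MUC3A",
    "MTOR", "KDM5C", "PTEN", "PIK3CA", "LAMA2", "LRP2", "ERCC1", "POLR2A",
    "XPC", "WDR18", "THSD4", "DDX49", "ADAMTS14",
) + tuple(f"GENE{i:03d}" for i in range(1, 30))

#: Default mix of variant effect categories for true somatic mutations.
DEFAULT_EFFECT_WEIGHTS = {
    "missense": 0.55,
    "frameshift_indel": 0.08,
    "inframe_indel": 0.05,
    "stop_gained": 0.05,
    "splice_site": 0.05,
    "synonymous": 0.12,
    "five_prime_utr": 0.05,
    "three_prime_utr": 0.05,
}

NON_SILENT_EFFECTS = ("missense", "frameshift_indel", "inframe_indel",
                      "stop_gained", "splice_site")

_BASES = "ACGT"
#: substitutions excluded from the true-mutation channel (FFPE signature)
_FFPE_CHANGES = {("C", "T"), ("G", "A")}


@dataclass
class SimulationConfig:
    n_patients: int = 4
    n_clones_range: tuple[int, int] = (2, 4)
    n_mutations_per_clone: int = 8
    depth: int = 500
    purity: float = 0.7
    ffpe_artifact_count: int = 5
    ffpe_vaf_bounds: tuple[float, float] = (0.01, 0.10)
    n_germline_snps: int = 40
    cnv_region_count: int = 2
    cnv_region_length: int = 20_000
    snps_per_cnv: int = 3
    p_mutation_in_cnv: float = 0.15
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    pathway_db: PathwayDB | None = None
    planted_exclusive_pairs: tuple[tuple[str, str], ...] = ()
    planted_clone_set_size: int = 1
    seed: int = 0
    contig: str = "chr_sim"
    contig_length: int = 10_000_000
    tree_topology: str = "random"  # "random" (uniform labelled) or "chain"
    p_clone_absent: float = 0.5
    min_clone_fraction: float = 0.0
    noise: str = "binomial"  # "binomial" or "none"
    effect_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    cn_window_pad: int = 4001  # keep non-CNV loci at least this far from CNV regions
    read_length: int = 30
    family_size_mean: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ConfigError(f"purity {self.purity} outside (0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        lo, hi = self.ffpe_vaf_bounds
        if not (0.0 < lo < hi <= 0.10):
            raise ConfigError(
                f"ffpe_vaf_bounds {self.ffpe_vaf_bounds} must lie inside (0, 0.10]"
            )
        if self.n_clones_range[0] < 1 or self.n_clones_range[0] > self.n_clones_range[1]:
            raise ConfigError(f"bad n_clones_range {self.n_clones_range}")
        if self.tree_topology not in ("random", "chain"):
            raise ConfigError(f"unknown tree_topology {self.tree_topology!r}")
        if self.noise not in ("binomial", "none"):
            raise ConfigError(f"unknown noise mode {self.noise!r}")
        if self.planted_exclusive_pairs:
            if self.pathway_db is None:
                raise ConfigError("planted pairs require a pathway_db")
            panel = set(self.panel_genes)
            for pa, pb in self.planted_exclusive_pairs:
                for pw in (pa, pb):
                    if pw not in self.pathway_db:
                        raise ConfigError(f"planted pathway {pw!r} not in pathway_db")
                    missing = self.pathway_db[pw] - panel
                    if missing:
                        raise ConfigError(
                            f"pathway {pw!r} genes absent from panel_genes: "
                            f"{sorted(missing)}"
                        )
            if 2 * self.planted_clone_set_size > self.n_clones_range[0]:
                raise ConfigError(
                    "planted_clone_set_size too large for the minimum clone count"
                )


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    clone_ids: list[str]
    parents: list[int]  # parent index per clone, -1 for the root
    fractions: np.ndarray  # (K+1, 2): rows clones then normal; cols TU1, TU2
    mutation_clone: dict[tuple, int]
    expected_vaf: dict[tuple, tuple[float, float]]
    status: dict[tuple, str]  # shared / private_TU1 / private_TU2
    genes: dict[tuple, str]
    effects: dict[tuple, str]
    artifacts: dict[str, set]  # sample -> set of variant keys
    cnv_regions: list[tuple[int, int]]
    mutations_in_cnv: set
    pathway_clone: PathwayCloneMatrix | None = None

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def subtree(self, clone: int) -> list[int]:
        children: dict[int, list[int]] = {i: [] for i in range(self.n_clones)}
        for i, p in enumerate(self.parents):
            if p >= 0:
                children[p].append(i)
        stack, out = [clone], []
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(children[c])
        return sorted(out)


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    patients: dict[str, PatientTruth]


def patient_rng(global_seed: int, patient_id: str) -> np.random.Generator:
    """Per-patient generator: reproducible independently of cohort order."""
    sub = zlib.crc32(patient_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([global_seed, sub]))


def _uniform_rooted_tree(k: int, rng: np.random.Generator) -> list[int]:
    """Parent vector of a uniform random labelled tree on k nodes rooted at 0."""
    if k == 1:
        return [-1]
    if k == 2:
        return [-1, 0]
    prufer = rng.integers(0, k, size=k - 2)
    degree = np.ones(k, dtype=int)
    for v in prufer:
        degree[v] += 1
    edges = []
    import heapq

    leaves = [i for i in range(k) if degree[i] == 1]
    heapq.heapify(leaves)
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(v)))
        degree[leaf] = 0
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, int(v))
    u, v = (i for i in range(k) if degree[i] == 1)
    edges.append((u, v))
    # orient away from root 0 by BFS
    adj: dict[int, list[int]] = {i: [] for i in range(k)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parents = [-2] * k
    parents[0] = -1
    stack = [0]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if parents[nb] == -2:
                parents[nb] = node
                stack.append(nb)
    return parents


def _sample_fractions(
    k: int, present: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """(K+1, 2) fraction matrix; last row is the normal-cell fraction."""
    F = np.zeros((k + 1, 2))
    for s in range(2):
        normal = 1.0 - cfg.purity * rng.uniform(0.85, 1.0)
        mask = present[:, s]
        n_present = int(mask.sum())
        tumour_mass = 1.0 - normal
        floor = min(cfg.min_clone_fraction, tumour_mass / max(n_present, 1) * 0.9)
        raw = rng.dirichlet(np.ones(n_present))
        fracs = floor + raw * (tumour_mass - n_present * floor)
        F[:k, s][mask] = fracs
        F[k, s] = normal
    return F


def _draw_locus(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    used: set[int],
    cnv_regions: list[tuple[int, int]],
    *,
    inside_cnv: bool = False,
) -> int:
    """A fresh 1-based position, inside a CNV region or padded away from all."""
    for _ in range(10_000):
        if inside_cnv:
            lo, hi = cnv_regions[rng.integers(len(cnv_regions))]
            pos = int(rng.integers(lo, hi + 1))
        else:
            pos = int(rng.integers(1, cfg.contig_length + 1))
            pad = cfg.cn_window_pad
            if any(lo - pad <= pos <= hi + pad for lo, hi in cnv_regions):
                continue
        if pos not in used:
            used.add(pos)
            return pos
    raise RuntimeError("could not place a unique locus; contig too crowded")


def _draw_alleles(rng: np.random.Generator, effect: str) -> tuple[str, str]:
    if effect in ("frameshift_indel", "inframe_indel"):
        ref = _BASES[rng.integers(4)]
        ins_len = 3 if effect == "inframe_indel" else int(rng.integers(1, 3))
        alt = ref + "".join(_BASES[rng.integers(4)] for _ in range(ins_len))
        return ref, alt
    while True:
        ref = _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(4)]
        if alt != ref and (ref, alt) not in _FFPE_CHANGES:
            return ref, alt


def _observe(
    rng: np.random.Generator, depth_mean: int, vaf: float, noise: str
) -> tuple[int, int]:
    """(alt_count, depth) under the configured noise model."""
    if noise == "none":
        # floor, not round: the discretised VAF never exceeds the true VAF,
        # so threshold-based filters see noise-free values on the correct side
        depth = depth_mean
        alt = int(np.floor(vaf * depth + 1e-12))
        if vaf > 0:
            alt = max(alt, 1)
        return alt, depth
    depth = max(1, int(rng.poisson(depth_mean)))
    alt = int(rng.binomial(depth, vaf)) if vaf > 0 else 0
    return alt, depth


def simulate_patient(
    patient_id: str, cfg: SimulationConfig
) -> tuple[PatientTruth, dict[str, list[VariantCall]], list[GermlineSNP]]:
    """Simulate one patient; returns truth, per-sample calls, germline SNPs."""
    rng = patient_rng(cfg.seed, patient_id)
    k = int(rng.integers(cfg.n_clones_range[0], cfg.n_clones_range[1] + 1))
    if cfg.tree_topology == "chain":
        parents = [-1] + list(range(k - 1))
    else:
        parents = _uniform_rooted_tree(k, rng)

    # clone presence: root in both samples, others may be spatially absent
    present = np.ones((k, 2), dtype=bool)
    for c in range(1, k):
        if rng.random() < cfg.p_clone_absent:
            present[c, int(rng.integers(2))] = False

    truth = PatientTruth(
        patient_id=patient_id,
        clone_ids=[f"clone{i + 1}" for i in range(k)],
        parents=parents,
        fractions=np.zeros((k + 1, 2)),
        mutation_clone={},
        expected_vaf={},
        status={},
        genes={},
        effects={},
        artifacts={"TU1": set(), "TU2": set()},
        cnv_regions=[],
        mutations_in_cnv=set(),
    )
    truth.fractions = _sample_fractions(k, present, cfg, rng)

    # cumulative (subtree) fraction per clone and sample
    cum = np.zeros((k, 2))
    for c in range(k):
        cum[c] = truth.fractions[truth.subtree(c), :].sum(axis=0)

    # CNV regions (non-overlapping, padded apart)
    used_loci: set[int] = set()
    regions: list[tuple[int, int]] = []
    span = cfg.cnv_region_length
    while len(regions) < cfg.cnv_region_count:
        start = int(rng.integers(1, cfg.contig_length - span))
        if all(
            start > hi + 2 * cfg.cn_window_pad or start + span < lo - 2 * cfg.cn_window_pad
            for lo, hi in regions
        ):
            regions.append((start, start + span))
    truth.cnv_regions = sorted(regions)

    planted_genes: set[str] = set()
    planted_assign: dict[str, int] = {}  # gene -> clone index
    if cfg.planted_exclusive_pairs:
        size = cfg.planted_clone_set_size
        clones_perm = list(rng.permutation(k))
        set_a = clones_perm[:size]
        set_b = clones_perm[size: 2 * size]
        for pa, pb in cfg.planted_exclusive_pairs:
            for pw, clone_set in ((pa, set_a), (pb, set_b)):
                for gene in sorted(cfg.pathway_db[pw]):
                    if gene not in planted_assign:
                        planted_assign[gene] = int(
                            clone_set[rng.integers(len(clone_set))]
                        )
                    planted_genes.add(gene)

    effect_names = list(cfg.effect_weights)
    effect_p = np.array([cfg.effect_weights[e] for e in effect_names], dtype=float)
    effect_p /= effect_p.sum()
    gene_pool = [g for g in cfg.panel_genes if g not in planted_genes]

    def add_mutation(clone: int, gene: str, effect: str, *, in_cnv: bool) -> None:
        pos = _draw_locus(rng, cfg, used_loci, truth.cnv_regions, inside_cnv=in_cnv)
        ref, alt = _draw_alleles(rng, effect)
        key = (cfg.contig, pos, ref, alt)
        v1, v2 = 0.5 * cum[clone, 0], 0.5 * cum[clone, 1]
        truth.mutation_clone[key] = clone
        truth.expected_vaf[key] = (v1, v2)
        truth.genes[key] = gene
        truth.effects[key] = effect
        if in_cnv:
            truth.mutations_in_cnv.add(key)
        if v1 > 0 and v2 > 0:
            truth.status[key] = "shared"
        elif v1 > 0:
            truth.status[key] = "private_TU1"
        else:
            truth.status[key] = "private_TU2"

    for clone in range(k):
        for _ in range(cfg.n_mutations_per_clone):
            gene = gene_pool[int(rng.integers(len(gene_pool)))]
            effect = effect_names[int(rng.choice(len(effect_names), p=effect_p))]
            in_cnv = (
                cfg.cnv_region_count > 0 and rng.random() < cfg.p_mutation_in_cnv
            )
            add_mutation(clone, gene, effect, in_cnv=in_cnv)
    for gene, clone in sorted(planted_assign.items()):
        effect = NON_SILENT_EFFECTS[int(rng.integers(len(NON_SILENT_EFFECTS)))]
        add_mutation(clone, gene, effect, in_cnv=False)

    # observed calls per tumour sample
    calls: dict[str, list[VariantCall]] = {"TU1": [], "TU2": [], "N": []}
    for key in truth.mutation_clone:
        chrom, pos, ref, alt = key
        for s, sample in enumerate(("TU1", "TU2")):
            vaf = truth.expected_vaf[key][s]
            alt_n, depth = _observe(rng, cfg.depth, vaf, cfg.noise)
            if alt_n >= 1:
                calls[sample].append(
                    VariantCall(
                        patient_id=patient_id,
                        sample_id=sample,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        alt_count=alt_n,
                        depth=depth,
                        gene=truth.genes[key],
                        effect=truth.effects[key],
                    )
                )

    # FFPE artifacts: deamination-type, low VAF, single sample each
    for sample in ("TU1", "TU2"):
        for _ in range(cfg.ffpe_artifact_count):
            pos = _draw_locus(rng, cfg, used_loci, truth.cnv_regions)
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            true_vaf = float(rng.uniform(*cfg.ffpe_vaf_bounds))
            alt_n, depth = _observe(rng, cfg.depth, true_vaf, cfg.noise)
            alt_n = max(alt_n, 1)  # an artifact exists because it was read
            key = (cfg.contig, pos, ref, alt)
            truth.artifacts[sample].add(key)
            gene = gene_pool[int(rng.integers(len(gene_pool)))]
            calls[sample].append(
                VariantCall(
                    patient_id=patient_id,
                    sample_id=sample,
                    chrom=cfg.contig,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    alt_count=alt_n,
                    depth=max(depth, alt_n),
                    gene=gene,
                    effect="missense",
                )
            )

    for sample in calls:
        calls[sample].sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    # germline heterozygous SNPs; those inside CNV regions are imbalanced
    snps: list[GermlineSNP] = []
    for lo, hi in truth.cnv_regions:
        for _ in range(cfg.snps_per_cnv):
            pos = _draw_locus(rng, cfg, used_loci, truth.cnv_regions, inside_cnv=True)
            # keep drawing until the position falls in THIS region
            while not lo <= pos <= hi:
                pos = _draw_locus(
                    rng, cfg, used_loci, truth.cnv_regions, inside_cnv=True
                )
            shift = float(rng.uniform(0.12, 0.30)) * (1 if rng.random() < 0.5 else -1)
            vaf_t = float(np.clip(0.5 + shift, 0.05, 0.95))
            snps.append(
                GermlineSNP(
                    chrom=cfg.contig,
                    pos=pos,
                    vaf_normal=float(rng.uniform(0.45, 0.55)),
                    vaf_tumour={"TU1": vaf_t, "TU2": vaf_t},
                    patient_id=patient_id,
                )
            )
    n_outside = max(0, cfg.n_germline_snps - len(snps))
    for _ in range(n_outside):
        pos = _draw_locus(rng, cfg, used_loci, truth.cnv_regions)
        snps.append(
            GermlineSNP(
                chrom=cfg.contig,
                pos=pos,
                vaf_normal=float(rng.uniform(0.45, 0.55)),
                vaf_tumour={
                    "TU1": float(rng.uniform(0.44, 0.56)),
                    "TU2": float(rng.uniform(0.44, 0.56)),
                },
                patient_id=patient_id,
            )
        )
    snps.sort(key=lambda s: s.pos)

    if cfg.pathway_db is not None:
        truth.pathway_clone = _truth_pathway_matrix(truth, cfg.pathway_db)
    return truth, calls, snps


def _truth_pathway_matrix(truth: PatientTruth, db: PathwayDB) -> PathwayCloneMatrix:
    mutated_genes_by_clone: dict[int, set[str]] = {}
    for key, clone in truth.mutation_clone.items():
        mutated_genes_by_clone.setdefault(clone, set()).add(truth.genes[key])
    rows = []
    pw_ids = []
    for pw in sorted(db.gene_sets):
        row = [
            1 if db[pw] & mutated_genes_by_clone.get(c, set()) else 0
            for c in range(truth.n_clones)
        ]
        if any(row):
            pw_ids.append(pw)
            rows.append(row)
    return PathwayCloneMatrix(
        patient_id=truth.patient_id,
        pathway_ids=pw_ids,
        clone_ids=list(truth.clone_ids),
        altered=np.array(rows, dtype=int).reshape(len(pw_ids), truth.n_clones),
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[SyntheticTruth, list[VariantCall], list[GermlineSNP]]:
    """Simulate ``cfg.n_patients`` patients; identical seed gives identical output."""
    truth = SyntheticTruth(config=cfg, patients={})
    all_calls: list[VariantCall] = []
    all_snps: list[GermlineSNP] = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        pt, calls, snps = simulate_patient(pid, cfg)
        truth.patients[pid] = pt
        for sample in ("TU1", "TU2", "N"):
            all_calls.extend(calls[sample])
        all_snps.extend(snps)
    return truth, all_calls, all_snps


# ---------------------------------------------------------------------------
# UMI read families
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFamily:
    """A simulated UMI read family together with its true molecule sequence."""

    umi: str
    chrom: str
    pos: int
    reads: list[str]
    true_sequence: str

    def as_read_family(self):
        from .umi_consensus import ReadFamily

        return ReadFamily(umi=self.umi, chrom=self.chrom, pos=self.pos,
                          reads=list(self.reads))


def simulate_read_families(
    cfg: SimulationConfig,
    site: tuple[str, int],
    true_base: str,
    error_rate: float,
    n_families: int = 100,
    rng: np.random.Generator | None = None,
) -> list[SimulatedFamily]:
    """Simulate UMI families at one locus.

    Each family derives from one true molecule whose first base (at the
    mapping position) is ``true_base`` and whose remaining bases are random.
    Every read copies the molecule with independent per-base substitution
    errors at ``error_rate`` (uniform over the three other bases).  Family
    sizes are geometric with mean ``cfg.family_size_mean``, minimum 1.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError(f"error_rate {error_rate} outside [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chrom, pos = site
    base_idx = {b: i for i, b in enumerate(_BASES)}
    if true_base not in base_idx:
        raise ValueError(f"true_base must be one of {_BASES}")
    p_geo = 1.0 / max(cfg.family_size_mean, 1.0)
    umis: set[str] = set()
    families = []
    for _ in range(n_families):
        while True:
            umi = "".join(_BASES[i] for i in rng.integers(0, 4, size=10))
            if umi not in umis:
                umis.add(umi)
                break
        mol = np.concatenate(
            ([base_idx[true_base]], rng.integers(0, 4, size=cfg.read_length - 1))
        )
        size = int(rng.geometric(p_geo))
        reads = []
        for _ in range(size):
            read = mol.copy()
            err = rng.random(cfg.read_length) < error_rate
            if err.any():
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=int(err.sum()))
                read[err] = (read[err] + shift) % 4
            reads.append("".join(_BASES[b] for b in read))
        families.append(
            SimulatedFamily(
                umi=umi,
                chrom=chrom,
                pos=pos,
                reads=reads,
                true_sequence="".join(_BASES[b] for b in mol),
            )
        )
    return families


def unanimity_probability(error_rate: float, family_size: int) -> float:
    """P(all reads agree at one position) under the per-base error model.

    Agreement happens when every read keeps the true base, or every read is
    mis-called to the same one of the three alternatives.
    """
    e = error_rate
    return (1 - e) ** family_size + 3 * (e / 3) ** family_size


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    outdir: str | Path,
    truth: SyntheticTruth,
    calls: Sequence[VariantCall],
    snps: Sequence[GermlineSNP],
) -> None:
    """Emit per-patient VCFs (TU1, TU2, N), a germline SNP TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    contigs = {cfg.contig: cfg.contig_length}
    by_patient_sample: dict[tuple[str, str], list[VariantCall]] = {}
    for c in calls:
        by_patient_sample.setdefault((c.patient_id, c.sample_id), []).append(c)
    for pid in truth.patients:
        for sample in ("TU1", "TU2", "N"):
            write_vcf(
                outdir / f"{pid}.{sample}.vcf",
                by_patient_sample.get((pid, sample), []),
                contigs=contigs,
                sample_name=sample,
            )
    write_germline_tsv(outdir / "germline_snps.tsv", snps)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1, sort_keys=True)


def _key_str(key: tuple) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def _truth_to_json(truth: SyntheticTruth) -> dict:
    out: dict = {"seed": truth.config.seed, "patients": {}}
    for pid, pt in truth.patients.items():
        out["patients"][pid] = {
            "clone_ids": pt.clone_ids,
            "parents": pt.parents,
            "fractions": np.round(pt.fractions, 10).tolist(),
            "mutation_clone": {_key_str(k): c for k, c in pt.mutation_clone.items()},
            "status": {_key_str(k): s for k, s in pt.status.items()},
            "expected_vaf": {
                _key_str(k): [round(a, 10), round(b, 10)]
                for k, (a, b) in pt.expected_vaf.items()
            },
            "artifacts": {
                s: sorted(_key_str(k) for k in ks) for s, ks in pt.artifacts.items()
            },
            "cnv_regions": pt.cnv_regions,
            "mutations_in_cnv": sorted(_key_str(k) for k in pt.mutations_in_cnv),
        }
    return out


__all__ = [
    "ConfigError",
    "DEFAULT_PANEL_GENES",
    "DEFAULT_EFFECT_WEIGHTS",
    "SimulationConfig",
    "PatientTruth",
    "SyntheticTruth",
    "SimulatedFamily",
    "patient_rng",
    "simulate_patient",
    "simulate_cohort",
    "simulate_read_families",
    "unanimity_probability",
    "write_cohort",
]
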