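"""End-to-end orchestration: simulate -> filter -> heterogeneity -> clones ->
exclusivity.

Every stage writes its artifact under one output directory and a run-metadata
JSON records parameters and seeds, so a rerun with identical configuration
and inputs is byte-identical.  One global seed fans out to per-patient seeds
by stable hashing of the patient id, making per-patient results independent
of cohort order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clonal_exclusivity import test_all_pairs
from .clone_assignment import (
    fit_clones,
    gene_entity_map,
    pathway_entity_map,
    to_entity_clone_matrix,
)
from .heterogeneity import merge_samples, summarise_cohort
from .io_formats import PathwayDB, write_clone_matrix, write_vcf
from .synthetic_cohort import SimulationConfig, simulate_cohort, write_cohort
from .variant_filters import apply_filters, impact_filter

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and patient."""


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    vaf_threshold: float = 0.10
    window: int = 4000
    normal_bounds: tuple[float, float] = (0.40, 0.60)
    k_range: tuple[int, int] = (1, 4)
    n_restarts: int = 20
    clone_seed: int = 0
    level: str = "pathway"  # or "gene"
    min_patients: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path, pathway_db: PathwayDB | None = None):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("sim", {})
        if pathway_db is not None:
            sim_kwargs["pathway_db"] = pathway_db
        for tup_key in ("n_clones_range", "ffpe_vaf_bounds"):
            if tup_key in sim_kwargs:
                sim_kwargs[tup_key] = tuple(sim_kwargs[tup_key])
        if "planted_exclusive_pairs" in sim_kwargs:
            sim_kwargs["planted_exclusive_pairs"] = tuple(
                tuple(p) for p in sim_kwargs["planted_exclusive_pairs"]
            )
        for tup_key in ("normal_bounds", "k_range"):
            if tup_key in raw:
                raw[tup_key] = tuple(raw[tup_key])
        return cls(sim=SimulationConfig(**sim_kwargs), **raw)


def patient_seed(global_seed: int, patient_id: str) -> int:
    """Stable per-patient seed below 2**31."""
    return (global_seed * 2_654_435_761 + zlib.crc32(patient_id.encode())) % (2**31)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full happy path; returns the map of artifact names to paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, patient: str | None, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            where = f"stage {name!r}" + (f", patient {patient}" if patient else "")
            raise PipelineError(f"{where}: {exc}") from exc

    truth, calls, snps = stage("simulate", None, simulate_cohort, cfg.sim)
    simdir = outdir / "simulated"
    stage("simulate", None, write_cohort, simdir, truth, calls, snps)

    by_ps: dict[tuple[str, str], list] = {}
    for c in calls:
        by_ps.setdefault((c.patient_id, c.sample_id), []).append(c)
    snps_by_patient: dict[str, list] = {}
    for s in snps:
        snps_by_patient.setdefault(s.patient_id, []).append(s)

    contigs = {cfg.sim.contig: cfg.sim.contig_length}
    patient_sets = []
    matrices = []
    het_rows = []
    filtered_dir = outdir / "filtered"
    clones_dir = outdir / "clones"
    filtered_dir.mkdir(exist_ok=True)
    clones_dir.mkdir(exist_ok=True)
    for pid, pt in truth.patients.items():
        filtered = {}
        for sample in ("TU1", "TU2"):
            rep = stage(
                "filter", pid, apply_filters,
                by_ps.get((pid, sample), []), snps_by_patient.get(pid, []), sample,
                vaf_threshold=cfg.vaf_threshold, window=cfg.window,
                normal_bounds=cfg.normal_bounds,
            )
            filtered[sample] = rep.retained
            write_vcf(filtered_dir / f"{pid}.{sample}.vcf", rep.retained,
                      contigs=contigs, sample_name=sample)
            pd.DataFrame(
                [
                    {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "reason": reason}
                    for v, reason in rep.removed
                ]
            ).to_csv(filtered_dir / f"{pid}.{sample}.report.tsv", sep="\t",
                     index=False)
        pvs = stage("heterogeneity", pid, merge_samples,
                    filtered["TU1"], filtered["TU2"], pid)
        patient_sets.append(pvs)
        for v in pvs.variants:
            het_rows.append(
                {"patient_id": pid, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                 "alt": v.alt, "gene": v.gene, "effect": v.effect,
                 "status": v.status}
            )
        profile = stage(
            "clones", pid, fit_clones, pvs,
            k_range=cfg.k_range, n_restarts=cfg.n_restarts,
            seed=patient_seed(cfg.clone_seed, pid),
        )
        pd.DataFrame(
            [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "clone": c}
             for k, c in sorted(profile.assignment.items())]
        ).to_csv(clones_dir / f"{pid}.assignment.tsv", sep="\t", index=False)
        frac = pd.DataFrame(
            profile.fractions, columns=["TU1", "TU2"],
            index=[*profile.clone_ids, "N"],
        )
        frac.to_csv(clones_dir / f"{pid}.fractions.tsv", sep="\t",
                    index_label="clone")
        # silent mutations inform the fit but not the exclusivity analysis
        non_silent = {
            v.key for v in impact_filter(
                [c for s in ("TU1", "TU2") for c in filtered[s]]
            ).retained
        }
        if cfg.level == "pathway":
            if cfg.sim.pathway_db is None:
                raise PipelineError(
                    "stage 'exclusivity': pathway level requires a pathway_db"
                )
            emap = pathway_entity_map(pvs, cfg.sim.pathway_db)
        else:
            emap = gene_entity_map(pvs)
        emap = {k: v for k, v in emap.items() if k in non_silent}
        matrix = stage("clones", pid, to_entity_clone_matrix, profile, emap)
        matrices.append(matrix)
        write_clone_matrix(clones_dir / f"{pid}.{cfg.level}_clone_matrix.tsv",
                           matrix)

    het_path = outdir / "heterogeneity.tsv"
    pd.DataFrame(het_rows).to_csv(het_path, sep="\t", index=False)
    summary = summarise_cohort(patient_sets)
    summary_rows = [
        {"patient_id": pid, **counts,
         "private_fraction": (counts["private_TU1"] + counts["private_TU2"])
         / max(sum(counts.values()), 1)}
        for pid, counts in summary.per_patient.items()
    ]
    summary_path = outdir / "cohort_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)

    results = stage("exclusivity", None, test_all_pairs, matrices,
                    min_patients=cfg.min_patients)
    excl_path = outdir / "exclusivity.tsv"
    pd.DataFrame(
        [
            {"entity_a": r.entity_a, "entity_b": r.entity_b,
             "n_patients_both": r.n_patients_both, "n_exclusive": r.n_exclusive,
             "p": r.p, "q": r.q}
            for r in results
        ]
    ).to_csv(excl_path, sep="\t", index=False)

    meta_path = outdir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "clonepair_version": __version__,
                "seed": cfg.sim.seed,
                "clone_seed": cfg.clone_seed,
                "vaf_threshold": cfg.vaf_threshold,
                "window": cfg.window,
                "normal_bounds": list(cfg.normal_bounds),
                "k_range": list(cfg.k_range),
                "n_restarts": cfg.n_restarts,
                "level": cfg.level,
                "min_patients": cfg.min_patients,
                "n_patients": cfg.sim.n_patients,
            },
            fh, indent=1, sort_keys=True,
        )
    return {
        "heterogeneity": het_path,
        "cohort_summary": summary_path,
        "exclusivity": excl_path,
        "metadata": meta_path,
        "filtered": filtered_dir,
        "clones": clones_dir,
        "simulated": simdir,
    }


def hash_outputs(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every file under the output directory (for determinism tests)."""
    outdir = Path(outdir)
    out = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return out


__all__ = ["PipelineError", "PipelineConfig", "patient_seed", "run_pipeline",
           "hash_outputs"]
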