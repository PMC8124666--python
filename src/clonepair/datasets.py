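"""Bundled example data.

The two pathway-by-clone matrices shipped here are SYNTHETIC stand-ins: small
binary matrices reconstructed from the published textual description of two
kidney-cancer patients in which an rRNA-processing pathway and two
glycosylation pathways were altered in disjoint clones.  They reproduce the
qualitative clone-assignment pattern (pathway 1 in clones 1-2 of one patient
and clone 2 of the other; pathways 2 and 3 in clone 3 of both) and exist so
the worked example and its tests run without any download; they are not the
original deposited matrices.
"""

from __future__ import annotations

from importlib import resources

from .io_formats import PathwayCloneMatrix, PathwayDB, read_clone_matrix

#: The three pathway labels used in the worked example.
PATHWAY_1 = "rRNA_processing_nucleolus_cytosol"
PATHWAY_2 = "O_glycosylation_TSR_domain_proteins"
PATHWAY_3 = "defective_B3GALTL_PpS"


def load_worked_example_matrices() -> list[PathwayCloneMatrix]:
    """Synthetic stand-in pathway-by-clone matrices for patients 8 and 14."""
    out = []
    for pid, fname in (
        ("patient08", "pathway_clone_patient08.synthetic.tsv"),
        ("patient14", "pathway_clone_patient14.synthetic.tsv"),
    ):
        ref = resources.files("clonepair.data") / fname
        with resources.as_file(ref) as path:
            out.append(read_clone_matrix(path, patient_id=pid))
    return out


def demo_pathway_db() -> PathwayDB:
    """A small pathway database over the default gene panel, for simulations.

    PW_RRNA and PW_OGLYC mirror the worked example's gene membership
    (WDR18/DDX49 vs THSD4/ADAMTS14) and are the natural choice for planting
    a clonally exclusive pair.
    """
    return PathwayDB(
        {
            "PW_RRNA": frozenset({"WDR18", "DDX49"}),
            "PW_OGLYC": frozenset({"THSD4", "ADAMTS14"}),
            "PW_CHROMATIN": frozenset({"PBRM1", "SETD2", "BAP1", "KDM5C"}),
            "PW_HYPOXIA": frozenset({"VHL", "GENE001", "GENE002"}),
            "PW_PI3K": frozenset({"PIK3CA", "PTEN", "MTOR"}),
            "PW_MUCIN": frozenset({"MUC6", "MUC16", "MUC3A"}),
        }
    )


__all__ = [
    "PATHWAY_1",
    "PATHWAY_2",
    "PATHWAY_3",
    "load_worked_example_matrices",
    "demo_pathway_db",
]
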