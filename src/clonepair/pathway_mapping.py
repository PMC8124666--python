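"""Gene-to-pathway over-representation analysis (ORA).

Classic one-sided hypergeometric enrichment of a differentially-expressed
gene list against an expressed-gene background.  The background rule: a gene
is expressed, hence eligible, if it accumulated at least 10 sequenced
fragments across the compared tumour and normal samples (threshold
inclusive).  For a pathway with m background members, the p-value is the
upper tail P(X >= k) of Hypergeometric(n_bg, m, n_de), where k is the
observed overlap with the DE list; q-values are Benjamini-Hochberg across
all tested pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import PathwayDB

log = logging.getLogger(__name__)


@dataclass
class OraResult:
    pathway_id: str
    k: int      # DE genes in the pathway
    m: int      # background genes in the pathway
    n_de: int
    n_bg: int
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        assert self.k <= min(self.m, self.n_de)
        assert 0.0 < self.p <= 1.0


def build_background(
    counts: Mapping[str, int] | Mapping[str, Sequence[int]],
    threshold: int = 10,
) -> set[str]:
    """Genes with at least ``threshold`` total fragments (inclusive).

    ``counts`` maps gene symbol to a total fragment count or to per-sample
    counts that are summed.
    """
    bg = set()
    for gene, c in counts.items():
        total = int(c) if isinstance(c, (int, float)) else int(sum(c))
        if total < 0:
            raise ValueError(f"negative count for gene {gene!r}")
        if total >= threshold:
            bg.add(gene)
    return bg


def ora_test(
    de_genes: set[str], background: set[str], db: PathwayDB
) -> list[OraResult]:
    """Hypergeometric over-representation of each pathway in the DE list.

    DE genes outside the background are dropped with a warning; pathway
    memberships are intersected with the background; pathways with no
    background member are skipped.  Results are sorted by p then pathway id.
    """
    if not background:
        raise ValueError("empty background gene set")
    stray = de_genes - background
    if stray:
        log.warning("%d DE genes outside the background dropped", len(stray))
    de = de_genes & background
    n_bg, n_de = len(background), len(de)
    results = []
    for pw in sorted(db.gene_sets):
        members = db[pw] & background
        m = len(members)
        if m == 0:
            continue
        k = len(members & de)
        p = float(hypergeom.sf(k - 1, n_bg, m, n_de))
        results.append(
            OraResult(pathway_id=pw, k=k, m=m, n_de=n_de, n_bg=n_bg,
                      p=min(p, 1.0) if p > 0 else 1e-300)
        )
    if results:
        _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results


__all__ = ["OraResult", "build_background", "ora_test"]
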