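"""UMI read-family grouping and strict-unanimity consensus calling.

Reads carrying the same unique molecular identifier (UMI) and mapped to the
same genomic position derive from one original DNA molecule; a consensus over
the family corrects independent sequencing errors.  The consensus rule is
strict unanimity: any position where family members disagree — including a
literal ``N`` in any read, which cannot certify agreement — is masked with
``N``.  No majority voting and no base-quality weighting (a majority-vote
mode exists behind a flag for comparison, default off).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class ReadFamily:
    """Reads sharing a UMI and leftmost mapping position."""

    umi: str
    chrom: str
    pos: int  # 1-based leftmost mapping position
    reads: list[str]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(f"empty read family {self.key}")
        lengths = {len(r) for r in self.reads}
        if len(lengths) != 1:
            raise ValueError(
                f"unequal read lengths {sorted(lengths)} within family "
                f"(umi={self.umi}, {self.chrom}:{self.pos})"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.umi, self.chrom, self.pos)

    @property
    def size(self) -> int:
        return len(self.reads)


def group_reads(
    reads: Iterable[tuple[str, str, int, str]]
) -> list[ReadFamily]:
    """Group (umi, chrom, pos, sequence) tuples into families.

    Families are keyed by the exact (umi, chrom, pos) triple — no UMI
    edit-distance merging.  Output order is deterministic (sorted by key).
    """
    buckets: dict[tuple[str, str, int], list[str]] = defaultdict(list)
    for umi, chrom, pos, seq in reads:
        buckets[(umi, chrom, int(pos))].append(seq)
    families = []
    for (umi, chrom, pos) in sorted(buckets):
        families.append(ReadFamily(umi=umi, chrom=chrom, pos=pos, reads=buckets[(umi, chrom, pos)]))
    return families


def consensus(family: ReadFamily, *, majority_vote: bool = False) -> str:
    """Consensus sequence of one family.

    Under the default strict rule, position i carries base b iff every read
    has b at i (and b != N); otherwise it is masked ``N``.  With
    ``majority_vote=True`` the strict rule is relaxed to a plurality call
    (ties and all-N columns still yield ``N``).
    """
    reads = family.reads
    if len(reads) == 1 and not majority_vote:
        return reads[0]
    out = []
    for column in zip(*reads):
        if majority_vote:
            counts = Counter(b for b in column if b != "N")
            if not counts:
                out.append("N")
                continue
            top = counts.most_common(2)
            if len(top) > 1 and top[0][1] == top[1][1]:
                out.append("N")
            else:
                out.append(top[0][0])
        else:
            first = column[0]
            if first != "N" and all(b == first for b in column[1:]):
                out.append(first)
            else:
                out.append("N")
    return "".join(out)


def consensus_table(families: Sequence[ReadFamily], **kwargs) -> pd.DataFrame:
    """Consensus of every family as a table (umi, chrom, pos, consensus, family_size)."""
    return pd.DataFrame(
        {
            "umi": [f.umi for f in families],
            "chrom": [f.chrom for f in families],
            "pos": [f.pos for f in families],
            "consensus": [consensus(f, **kwargs) for f in families],
            "family_size": [f.size for f in families],
        }
    )


def read_reads_tsv(path: str | Path) -> list[tuple[str, str, int, str]]:
    """Read a (umi, chrom, pos, seq) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype={"umi": str, "chrom": str, "seq": str})
    return [
        (r.umi, r.chrom, int(r.pos), r.seq) for r in df.itertuples(index=False)
    ]


def read_reads_sam(path: str | Path, umi_tag: str = "RX") -> list[tuple[str, str, int, str]]:
    """Extract (umi, chrom, pos, seq) from a SAM file with a UMI tag (default RX)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or not aln.has_tag(umi_tag):
                continue
            out.append(
                (aln.get_tag(umi_tag), aln.reference_name, aln.reference_start + 1,
                 aln.query_sequence)
            )
    return out


def write_consensus_tsv(path: str | Path, families: Sequence[ReadFamily], **kwargs) -> None:
    consensus_table(families, **kwargs).to_csv(path, sep="\t", index=False)


__all__ = [
    "ReadFamily",
    "group_reads",
    "consensus",
    "consensus_table",
    "read_reads_tsv",
    "read_reads_sam",
    "write_consensus_tsv",
]
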