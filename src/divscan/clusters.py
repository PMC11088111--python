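"""Haplotype-resolved gene-cluster diversity.

Consumes per-haplotype copy annotations (copy-number tabulation) and
pre-aligned coding sequences of allelic copies (π as mean pairwise
p-distance), and contrasts the long-read estimates against short-read
window estimates over the same genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "CdsCopy",
    "HaplotypeCdsSet",
    "tabulate_copy_number",
    "cds_pi",
    "compare_pi",
    "read_aligned_fasta",
]

GAP_CHARS = frozenset("-Nn.")


@dataclass(frozen=True, slots=True)
class CdsCopy:
    """One annotated gene copy on one haplotype assembly."""

    haplotype: str
    copy_id: str
    sequence: str = ""
    status: str = "complete"  # complete | null | pseudogene

    def __post_init__(self) -> None:
        if self.status not in ("complete", "null", "pseudogene"):
            raise ValueError(f"unknown copy status {self.status!r}")


@dataclass(slots=True)
class HaplotypeCdsSet:
    """All copies of one gene across haplotype assemblies."""

    gene: str
    copies: list[CdsCopy]

    def complete_sequences(self) -> list[str]:
        return [c.sequence for c in self.copies if c.status == "complete"]


def tabulate_copy_number(
    annotations: Mapping[str, Sequence[CdsCopy]],
    regions: Mapping[str, tuple[int, int]],
) -> pd.DataFrame:
    """Per-assembly copy counts for a region.

    ``annotations`` maps assembly/haplotype id to its copies; ``regions``
    maps the same ids to the (start, end) interval harbouring the cluster
    on that assembly.  Complete and null copies both count as genes;
    pseudogenes (ψ) are tallied separately.  Span is reported in kb.
    """
    rows = []
    for assembly, copies in annotations.items():
        if assembly not in regions:
            raise KeyError(f"no region interval for assembly {assembly!r}")
        start, end = regions[assembly]
        if end <= start:
            raise ValueError(f"empty region for {assembly!r}")
        n_genes = sum(1 for c in copies if c.status in ("complete", "null"))
        n_pseudo = sum(1 for c in copies if c.status == "pseudogene")
        rows.append(
            {
                "assembly": assembly,
                "n_genes": n_genes,
                "n_pseudogenes": n_pseudo,
                "span_kb": (end - start) / 1000.0,
            }
        )
    return pd.DataFrame(rows)


def cds_pi(sequences: Sequence[str], gap_mode: str = "pairwise_deletion") -> float:
    """Nucleotide diversity of aligned sequences: mean pairwise p-distance.

    ``pi = (2 / (m(m-1))) * sum over pairs of (differences / valid sites)``.
    Under ``pairwise_deletion`` a position counts for a pair unless either
    member has a gap/N there; under ``complete_deletion`` positions with a
    gap/N in *any* sequence are excluded for all pairs.
    """
    if gap_mode not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    m = len(sequences)
    if m < 2:
        raise ValueError("need >= 2 sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be aligned to equal length")
    seqs = [s.upper() for s in sequences]

    if gap_mode == "complete_deletion":
        keep = [
            j for j in range(length) if all(s[j] not in GAP_CHARS for s in seqs)
        ]
        seqs = ["".join(s[j] for j in keep) for s in seqs]
        length = len(keep)

    total = 0.0
    n_pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            a, b = seqs[i], seqs[j]
            valid = 0
            diffs = 0
            for ca, cb in zip(a, b):
                if ca in GAP_CHARS or cb in GAP_CHARS:
                    continue
                valid += 1
                if ca != cb:
                    diffs += 1
            if valid == 0:
                raise ValueError("a sequence pair shares no valid sites")
            total += diffs / valid
            n_pairs += 1
    return total / n_pairs


def compare_pi(
    long_read: Mapping[str, float], short_read: Mapping[str, float]
) -> pd.DataFrame:
    """Side-by-side long-read vs short-read π per gene.

    ``ratio`` is short/long; ``inflated`` flags genes where the short-read
    estimate exceeds the long-read one — the signature expected when reads
    from collapsed copies cross-map.  Deflation (short < long) is reported
    unflagged: both directions occur in practice.
    """
    genes = sorted(set(long_read) & set(short_read))
    rows = []
    for g in genes:
        lr, sr = float(long_read[g]), float(short_read[g])
        rows.append(
            {
                "gene": g,
                "pi_long": lr,
                "pi_short": sr,
                "ratio": sr / lr if lr > 0 else float("inf") if sr > 0 else 1.0,
                "inflated": sr > lr,
            }
        )
    return pd.DataFrame(rows)


def read_aligned_fasta(path) -> dict[str, list[CdsCopy]]:
    """Read aligned CDS copies grouped by gene.

    Record ids follow ``gene|assembly|copy[|status]``; the status defaults
    to ``complete``.
    """
    groups: dict[str, list[CdsCopy]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise ValueError(
                f"FASTA id {rec.id!r} not in gene|assembly|copy[|status] form"
            )
        gene, assembly, copy_id = parts[0], parts[1], parts[2]
        status = parts[3] if len(parts) > 3 else "complete"
        groups.setdefault(gene, []).append(
            CdsCopy(
                haplotype=assembly,
                copy_id=copy_id,
                sequence=str(rec.seq),
                status=status,
            )
        )
    return groups
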