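"""Annotation of windows and regions: repeats, genes, two-group contrasts.

Repeat coverage uses *union* semantics: overlapping repeat intervals of the
same superclass are flattened before clipping to a window, so nested hits
are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .hdr import HDRegion
from .windows import WindowSpec

__all__ = [
    "RepeatFeature",
    "GeneFeature",
    "parse_repeatmasker_out",
    "window_repeat_proportion",
    "welch_t_test",
    "read_gff_genes",
    "genes_overlapping_regions",
]


@dataclass(frozen=True, slots=True)
class RepeatFeature:
    """One masked repeat interval (0-based half-open internally)."""

    chrom: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty repeat interval")

    @property
    def superclass(self) -> str:
        return self.repeat_class.split("/", 1)[0]


@dataclass(frozen=True, slots=True)
class GeneFeature:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty gene interval for {self.gene_id}")


def parse_repeatmasker_out(path) -> list[RepeatFeature]:
    """Parse the standard RepeatMasker ``.out`` table.

    Layout: three header lines, then whitespace-delimited columns with the
    query name in column 5, 1-based inclusive begin/end in columns 6-7 and
    the class/family string in column 11.
    """
    features: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
            try:
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            features.append(
                RepeatFeature(
                    chrom=fields[4],
                    start=begin - 1,
                    end=end,
                    repeat_class=fields[10],
                )
            )
    return features


def _union_coverage(intervals: np.ndarray, start: int, end: int) -> int:
    """Bases of [start, end) covered by the union of (start, end) rows."""
    if intervals.size == 0:
        return 0
    s = np.clip(intervals[:, 0], start, end)
    e = np.clip(intervals[:, 1], start, end)
    keep = e > s
    if not keep.any():
        return 0
    s, e = s[keep], e[keep]
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    covered = 0
    cur_s, cur_e = int(s[0]), int(e[0])
    for i in range(1, len(s)):
        if s[i] > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = int(s[i]), int(e[i])
        else:
            cur_e = max(cur_e, int(e[i]))
    covered += cur_e - cur_s
    return covered


def window_repeat_proportion(
    repeats: Iterable[RepeatFeature], windows: Sequence[WindowSpec]
) -> pd.DataFrame:
    """Per-window repeat coverage proportions, total and per superclass.

    A repeat spanning a window boundary contributes the clipped part to each
    window.  Columns: chrom/start/end, ``total`` and one column per observed
    superclass; all values in [0, 1].
    """
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    superclasses: set[str] = set()
    for rep in repeats:
        superclasses.add(rep.superclass)
        by_key.setdefault((rep.chrom, rep.superclass), []).append((rep.start, rep.end))
        by_key.setdefault((rep.chrom, "__all__"), []).append((rep.start, rep.end))
    arr = {k: np.array(v) for k, v in by_key.items()}

    sclasses = sorted(superclasses)
    rows = []
    for w in windows:
        row: dict[str, object] = {"chrom": w.chrom, "start": w.start + 1, "end": w.end}
        total = arr.get((w.chrom, "__all__"), np.empty((0, 2), dtype=int))
        row["total"] = _union_coverage(total, w.start, w.end) / w.length
        for sc in sclasses:
            iv = arr.get((w.chrom, sc), np.empty((0, 2), dtype=int))
            row[sc] = _union_coverage(iv, w.start, w.end) / w.length
        rows.append(row)
    return pd.DataFrame(rows)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: ``(t, df, p_two_sided)``.

    Requires at least two observations per group and a nonzero pooled
    standard error (both-groups-constant input is rejected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 finite values")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 == 0:
        raise ValueError("zero variance in both groups")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def read_gff_genes(path, protein_coding_only: bool = True) -> list[GeneFeature]:
    """Extract gene-level features from a GFF3 file.

    Uses an in-memory feature database; genes without an annotated biotype
    are kept (assumed protein coding).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneFeature] = []
    for feat in db.features_of_type("gene"):
        biotype = (
            feat.attributes.get("biotype")
            or feat.attributes.get("gene_biotype")
            or ["protein_coding"]
        )[0]
        if protein_coding_only and biotype != "protein_coding":
            continue
        gene_id = (feat.attributes.get("ID") or [feat.id])[0]
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or ".",
                biotype=biotype,
            )
        )
    return genes


def genes_overlapping_regions(
    genes: Sequence[GeneFeature], regions: Sequence[HDRegion]
) -> pd.DataFrame:
    """Flag genes with >= 1 bp overlap with any region (half-open logic)."""
    by_chrom: dict[str, list[HDRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for g in genes:
        hit = any(
            g.start < r.end and r.start < g.end for r in by_chrom.get(g.chrom, [])
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start + 1,
                "end": g.end,
                "in_region": hit,
            }
        )
    return pd.DataFrame(rows)
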