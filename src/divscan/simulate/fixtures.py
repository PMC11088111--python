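"""Annotation-side fixtures with implanted, known signal.

Each generator is seed-deterministic and returns in-memory objects plus a
plain-text serialisation, so tests and the CLI can either consume the
objects directly or write standard files (OBO, RepeatMasker ``.out``,
GFF3, TSV, FASTA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..annotate import GeneFeature, RepeatFeature
from ..clusters import CdsCopy
from ..windows import WindowSpec

__all__ = [
    "GoFixtureConfig",
    "GoFixture",
    "sim_go_fixture",
    "RepeatFixtureConfig",
    "sim_repeat_fixture",
    "write_repeatmasker_out",
    "sim_gene_fixture",
    "genes_to_gff3",
    "sim_recomb_fixture",
    "CdsFixtureConfig",
    "sim_cds_fixture",
    "sim_fixtures",
]


# ---------------------------------------------------------------------------
# GO fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class GoFixtureConfig:
    n_genes: int = 1000
    n_study: int = 50
    n_background_terms: int = 30
    background_term_size: tuple[int, int] = (30, 100)
    n_implant_children: int = 3
    implant_genes_per_child: int = 20
    implant_study_fraction: float = 0.8  # enrichment odds knob


@dataclass(slots=True)
class GoFixture:
    obo_text: str
    gene2go: dict[str, set[str]]
    study: set[str]
    universe: set[str]
    implanted: set[str]  # parent + children: the designed-significant family
    root: str
    parent: str


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def sim_go_fixture(cfg: GoFixtureConfig, seed: int) -> GoFixture:
    """Random BP DAG + gene2go with one implanted enriched term family.

    Background terms annotate study and non-study genes in exact proportion
    to the study fraction (stratified sampling), so they are null by
    construction; the implanted parent and its children are enriched at the
    configured odds.  Every gene receives at least one background term,
    making the annotated universe the full gene set.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    study = set(genes[: cfg.n_study])
    non_study = genes[cfg.n_study :]

    root = _term_id(1)
    parent = _term_id(2)
    children = [_term_id(3 + i) for i in range(cfg.n_implant_children)]
    background = [
        _term_id(100 + i) for i in range(cfg.n_background_terms)
    ]

    stanzas = [
        f"[Term]\nid: {root}\nname: root\nnamespace: biological_process\n",
        f"[Term]\nid: {parent}\nname: implanted parent\nnamespace: biological_process\nis_a: {root} ! root\n",
    ]
    for c in children:
        stanzas.append(
            f"[Term]\nid: {c}\nname: implanted child\nnamespace: biological_process\nis_a: {parent} ! implanted parent\n"
        )
    for b in background:
        stanzas.append(
            f"[Term]\nid: {b}\nname: background\nnamespace: biological_process\nis_a: {root} ! root\n"
        )
    obo_text = "format-version: 1.2\n\n" + "\n".join(stanzas)

    gene2go: dict[str, set[str]] = {g: set() for g in genes}

    study_frac = cfg.n_study / cfg.n_genes
    lo, hi = cfg.background_term_size
    study_list = sorted(study)
    for b in background:
        size = int(rng.integers(lo, hi + 1))
        k_study = int(round(size * study_frac))
        chosen = list(rng.choice(study_list, size=k_study, replace=False)) + list(
            rng.choice(non_study, size=size - k_study, replace=False)
        )
        for g in chosen:
            gene2go[g].add(b)

    # guarantee full annotation coverage
    for g in genes:
        if not gene2go[g]:
            gene2go[g].add(background[int(rng.integers(len(background)))])

    for c in children:
        k_study = int(round(cfg.implant_genes_per_child * cfg.implant_study_fraction))
        chosen = list(rng.choice(study_list, size=k_study, replace=False)) + list(
            rng.choice(non_study, size=cfg.implant_genes_per_child - k_study, replace=False)
        )
        for g in chosen:
            gene2go[g].add(c)

    return GoFixture(
        obo_text=obo_text,
        gene2go=gene2go,
        study=study,
        universe=set(genes),
        implanted={parent, *children},
        root=root,
        parent=parent,
    )


# ---------------------------------------------------------------------------
# repeats fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class RepeatFixtureConfig:
    base_density: float = 0.2  # target covered proportion in background windows
    hdr_multiplier: float = 0.5
    mean_repeat_len: int = 150
    superclass_mix: tuple[tuple[str, float], ...] = (
        ("DNA", 0.3),
        ("LINE", 0.2),
        ("LTR", 0.1),
        ("Simple_repeat", 0.25),
        ("Low_complexity", 0.15),
    )


def sim_repeat_fixture(
    windows: Sequence[WindowSpec],
    hdr_window_indices: set[int],
    cfg: RepeatFixtureConfig,
    seed: int,
) -> list[RepeatFeature]:
    """Poisson-placed repeats; designated windows get a density multiplier."""
    rng = np.random.default_rng(seed)
    names = [m[0] for m in cfg.superclass_mix]
    probs = np.array([m[1] for m in cfg.superclass_mix])
    probs = probs / probs.sum()
    features: list[RepeatFeature] = []
    for i, w in enumerate(windows):
        density = cfg.base_density * (
            cfg.hdr_multiplier if i in hdr_window_indices else 1.0
        )
        expected = w.length * density / cfg.mean_repeat_len
        n = rng.poisson(expected)
        for _ in range(n):
            length = max(10, int(rng.exponential(cfg.mean_repeat_len)))
            start = int(rng.integers(w.start, w.end))
            end = min(start + length, w.end)
            if end <= start:
                continue
            sc = names[int(rng.choice(len(names), p=probs))]
            family = sc if sc in ("Simple_repeat", "Low_complexity") else f"{sc}/fam1"
            features.append(RepeatFeature(w.chrom, start, end, family))
    return features


def write_repeatmasker_out(features: Sequence[RepeatFeature], path) -> None:
    """Serialise features in the standard ``.out`` column layout."""
    header = (
        "   SW   perc perc perc  query     position in queryryn    matching  repeat\n"
        "score   div. del. ins.  sequence  begin  end    (left)    repeat    class/family\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, f in enumerate(features):
            fh.write(
                f"  225   10.0  0.0  0.0  {f.chrom}  {f.start + 1}  {f.end}  (0)  + "
                f" rep{i}  {f.repeat_class}  1  {f.end - f.start}  (0)  {i + 1}\n"
            )


# ---------------------------------------------------------------------------
# genes / recombination fixtures
# ---------------------------------------------------------------------------


def sim_gene_fixture(
    chrom: str,
    chrom_length: int,
    n_genes: int,
    seed: int,
    mean_len: int = 2000,
    mean_gap: int = 1000,
) -> list[GeneFeature]:
    """Non-overlapping gene intervals along one chromosome."""
    rng = np.random.default_rng(seed)
    genes: list[GeneFeature] = []
    pos = int(rng.integers(0, mean_gap + 1))
    for i in range(n_genes):
        length = max(200, int(rng.exponential(mean_len)))
        if pos + length > chrom_length:
            break
        genes.append(
            GeneFeature(
                gene_id=f"gene{i:04d}",
                chrom=chrom,
                start=pos,
                end=pos + length,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        pos += length + max(50, int(rng.exponential(mean_gap)))
    return genes


def genes_to_gff3(genes: Sequence[GeneFeature]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};biotype={g.biotype}"
        )
    return "\n".join(lines) + "\n"


def sim_recomb_fixture(
    fst: np.ndarray,
    target_corr: float,
    seed: int,
    mean_rate: float = 2.0,
    sd_rate: float = 0.8,
) -> np.ndarray:
    """Per-window recombination rates with a target correlation to ``fst``.

    Rates are an affine mix of the standardised FST track and Gaussian
    noise, clipped at zero (a large negative target with a high mean keeps
    clipping negligible).
    """
    if not -1.0 <= target_corr <= 1.0:
        raise ValueError("target correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = np.asarray(fst, dtype=float)
    ok = np.isfinite(x)
    z = np.zeros_like(x)
    z[ok] = (x[ok] - x[ok].mean()) / x[ok].std()
    noise = rng.standard_normal(x.size)
    mix = target_corr * z + np.sqrt(max(0.0, 1 - target_corr**2)) * noise
    return np.clip(mean_rate + sd_rate * mix, 0.0, None)


# ---------------------------------------------------------------------------
# CDS fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CdsFixtureConfig:
    gene: str = "geneA"
    length: int = 100
    private_counts: tuple[int, ...] = (2, 1, 3)  # per-copy private mutations
    n_null: int = 0  # extra copies carrying a premature stop


@dataclass(slots=True)
class CdsFixture:
    gene: str
    copies: list[CdsCopy]
    pairwise: dict[tuple[int, int], int]
    expected_pi: float

    def fasta_text(self) -> str:
        out = []
        for c in self.copies:
            out.append(f">{self.gene}|{c.haplotype}|{c.copy_id}|{c.status}")
            out.append(c.sequence)
        return "\n".join(out) + "\n"


def sim_cds_fixture(cfg: CdsFixtureConfig, seed: int) -> CdsFixture:
    """Aligned gene copies with exactly planted pairwise distances.

    Copy ``i`` carries ``m_i`` private mutations at positions disjoint
    across copies, so the pairwise difference count is exactly
    ``m_i + m_j`` and the planted π is the mean of those over pairs.
    """
    rng = np.random.default_rng(seed)
    m = len(cfg.private_counts)
    if m < 2:
        raise ValueError("need >= 2 complete copies")
    total_private = sum(cfg.private_counts)
    if total_private > cfg.length:
        raise ValueError("too many mutations for the sequence length")
    bases = "ACGT"
    base_seq = [bases[int(b)] for b in rng.integers(0, 4, size=cfg.length)]
    positions = rng.choice(cfg.length, size=total_private, replace=False)

    copies: list[CdsCopy] = []
    cursor = 0
    for i, count in enumerate(cfg.private_counts):
        seq = list(base_seq)
        for p in positions[cursor : cursor + count]:
            old = seq[p]
            seq[p] = bases[(bases.index(old) + 1 + int(rng.integers(3))) % 4]
        cursor += count
        copies.append(
            CdsCopy(
                haplotype=f"hap{i + 1}",
                copy_id=f"c{i + 1}",
                sequence="".join(seq),
                status="complete",
            )
        )
    for j in range(cfg.n_null):
        seq = list(base_seq)
        stop_at = 3 * (int(rng.integers(1, max(2, cfg.length // 3 - 1))))
        if stop_at + 3 <= cfg.length:
            seq[stop_at : stop_at + 3] = list("TAA")
        copies.append(
            CdsCopy(
                haplotype=f"hap{m + j + 1}",
                copy_id=f"null{j + 1}",
                sequence="".join(seq),
                status="null",
            )
        )

    pairwise = {
        (i, j): cfg.private_counts[i] + cfg.private_counts[j]
        for i in range(m)
        for j in range(i + 1, m)
    }
    expected_pi = sum(pairwise.values()) / len(pairwise) / cfg.length
    return CdsFixture(
        gene=cfg.gene, copies=copies, pairwise=pairwise, expected_pi=expected_pi
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def sim_fixtures(kind: str, cfg, seed: int, **kwargs):
    """Dispatch to a fixture generator by kind (go|repeats|genes|recomb|cds)."""
    if kind == "go":
        return sim_go_fixture(cfg or GoFixtureConfig(), seed)
    if kind == "repeats":
        return sim_repeat_fixture(
            kwargs["windows"], kwargs.get("hdr_window_indices", set()),
            cfg or RepeatFixtureConfig(), seed,
        )
    if kind == "genes":
        return sim_gene_fixture(
            kwargs.get("chrom", "sim1"), kwargs["chrom_length"],
            kwargs.get("n_genes", 100), seed,
        )
    if kind == "recomb":
        return sim_recomb_fixture(
            kwargs["fst"], kwargs.get("target_corr", -0.5), seed
        )
    if kind == "cds":
        return sim_cds_fixture(cfg or CdsFixtureConfig(), seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
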