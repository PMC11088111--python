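"""AllSites VCF input/output, population maps, and hard filtering.

The estimators downstream require *all-sites* VCFs: records are emitted for
invariant positions (``ALT .``) as well as variants, so that window
denominators count every genotyped base.  This module reads such files into
:class:`SiteRecord` streams, writes them back out, and applies the site-level
and genotype-level hard filters of a standard short-read joint-calling
workflow (GATK-style INFO thresholds plus per-genotype GQ/DP bounds).

Internal coordinates are 0-based half-open throughout the package; the
1-based VCF convention is converted at the I/O boundary only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "SiteRecord",
    "PopulationMap",
    "FilterConfig",
    "read_allsites_vcf",
    "write_allsites_vcf",
    "apply_filters",
    "filter_stream",
    "read_population_map",
    "parse_site_filter_spec",
]

#: INFO keys recognised by :func:`apply_filters`.
SITE_INFO_KEYS = ("FS", "MQRankSum", "MQ", "QD", "ReadPosRankSum", "SOR")

MISSING = -1  # allele index for a missing call


@dataclass(slots=True)
class SiteRecord:
    """One genomic position with per-sample diploid genotypes.

    ``genotypes`` is an ``(n_samples, 2)`` int16 array of allele indices with
    ``-1`` for missing.  Half-called genotypes are normalised to fully
    missing on construction.  ``gq``/``dp`` are per-sample arrays (``-1``
    where the FORMAT field is absent) or ``None`` when the field was not
    present at all.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    info: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int16)
        if g.ndim != 2 or g.shape[1] != 2:
            raise ValueError("genotypes must be an (n_samples, 2) array")
        # half-called -> fully missing
        half = (g < 0).any(axis=1)
        g[half] = MISSING
        self.genotypes = g
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        n_alleles = 1 + len(self.alts)
        if g.max(initial=-1) >= n_alleles:
            raise ValueError(
                f"{self.chrom}:{self.pos + 1}: allele index exceeds 1+|alts|"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def is_invariant(self) -> bool:
        return len(self.alts) == 0

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
        )

    @property
    def is_indel(self) -> bool:
        if len(self.ref) != 1:
            return True
        return any(len(a) != 1 for a in self.alts)


class PopulationMap:
    """Sample → population assignment with stable per-population ordering."""

    def __init__(self, assignments: Mapping[str, str]):
        if not assignments:
            raise ValueError("empty population map")
        self._assignments = dict(assignments)
        self._groups: dict[str, list[str]] = {}
        for sample, pop in self._assignments.items():
            self._groups.setdefault(pop, []).append(sample)

    @property
    def samples(self) -> list[str]:
        return list(self._assignments)

    @property
    def populations(self) -> list[str]:
        return list(self._groups)

    def population_of(self, sample: str) -> str:
        return self._assignments[sample]

    def samples_in(self, population: str) -> list[str]:
        return list(self._groups[population])

    def indices(self, sample_order: Sequence[str]) -> dict[str, np.ndarray]:
        """Column indices of each population within ``sample_order``.

        Raises if a mapped sample is absent from ``sample_order``.
        """
        lookup = {s: i for i, s in enumerate(sample_order)}
        missing = [s for s in self._assignments if s not in lookup]
        if missing:
            raise KeyError(f"samples not in VCF/order: {sorted(missing)}")
        return {
            pop: np.array([lookup[s] for s in members], dtype=np.intp)
            for pop, members in self._groups.items()
        }

    def __len__(self) -> int:
        return len(self._assignments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationMap):
            return NotImplemented
        return self._assignments == other._assignments


def read_population_map(path, header: bool = False) -> PopulationMap:
    """Read a two-column (sample, population) TSV.

    Duplicate sample ids and empty files are errors.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sample, pop = parts[0].strip(), parts[1].strip()
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    if not assignments:
        raise ValueError(f"{path}: empty population map")
    return PopulationMap(assignments)


@dataclass(frozen=True, slots=True)
class FilterConfig:
    """Site INFO thresholds and per-genotype GQ/DP bounds.

    Defaults are conventional joint-calling hard-filter values: sites are
    removed when ``FS > 60``, ``MQRankSum < -12.5``, ``MQ < 40``, ``QD < 2``,
    ``ReadPosRankSum < -8`` or ``SOR > 3``; genotypes are masked when
    ``GQ < 20``, ``DP < 2`` or ``DP > 100``.  Absent INFO metrics never
    trigger removal.
    """

    fs_max: float = 60.0
    mq_rank_sum_min: float = -12.5
    mq_min: float = 40.0
    qd_min: float = 2.0
    read_pos_rank_sum_min: float = -8.0
    sor_max: float = 3.0
    gq_min: int = 20
    dp_min: int = 2
    dp_max: int = 100
    drop_indels: bool = True

    def __post_init__(self) -> None:
        if self.dp_min > self.dp_max:
            raise ValueError("dp_min must be <= dp_max")

    def site_fails(self, info: Mapping[str, float]) -> bool:
        def bad(key: str, *, gt: float | None = None, lt: float | None = None) -> bool:
            v = info.get(key)
            if v is None or not np.isfinite(v):
                return False
            if gt is not None and v > gt:
                return True
            if lt is not None and v < lt:
                return True
            return False

        return (
            bad("FS", gt=self.fs_max)
            or bad("MQRankSum", lt=self.mq_rank_sum_min)
            or bad("MQ", lt=self.mq_min)
            or bad("QD", lt=self.qd_min)
            or bad("ReadPosRankSum", lt=self.read_pos_rank_sum_min)
            or bad("SOR", gt=self.sor_max)
        )


def parse_site_filter_spec(spec: str) -> FilterConfig:
    """Parse a compact CLI filter spec like ``"FS>60,MQ<40,QD<2"``.

    Metrics not mentioned keep their defaults.  The comparison direction must
    match the removal semantics of the metric (``>`` for FS/SOR, ``<`` for
    the rest).
    """
    kwargs: dict[str, float] = {}
    field_of = {
        "FS": ("fs_max", ">"),
        "MQRankSum": ("mq_rank_sum_min", "<"),
        "MQ": ("mq_min", "<"),
        "QD": ("qd_min", "<"),
        "ReadPosRankSum": ("read_pos_rank_sum_min", "<"),
        "SOR": ("sor_max", ">"),
    }
    for clause in spec.split(","):
        clause = clause.strip()
        if not clause:
            continue
        for op in ("<", ">"):
            if op in clause:
                key, value = clause.split(op, 1)
                key = key.strip()
                if key not in field_of:
                    raise ValueError(f"unknown site filter metric {key!r}")
                fname, expected_op = field_of[key]
                if op != expected_op:
                    raise ValueError(
                        f"metric {key} uses {expected_op!r} (removal side), got {op!r}"
                    )
                kwargs[fname] = float(value)
                break
        else:
            raise ValueError(f"cannot parse filter clause {clause!r}")
    return FilterConfig(**kwargs)


def apply_filters(site: SiteRecord, cfg: FilterConfig) -> SiteRecord | None:
    """Apply site-level and genotype-level filters to one record.

    Returns ``None`` when the site is removed outright (indel while
    ``drop_indels``, or an INFO metric beyond its threshold); otherwise a
    copy with failing genotypes set to missing.  Total: never raises.
    """
    if cfg.drop_indels and site.is_indel:
        return None
    if site.info and cfg.site_fails(site.info):
        return None
    mask = np.zeros(site.n_samples, dtype=bool)
    if site.gq is not None:
        gq = np.asarray(site.gq)
        mask |= (gq >= 0) & (gq < cfg.gq_min)
    if site.dp is not None:
        dp = np.asarray(site.dp)
        mask |= (dp >= 0) & ((dp < cfg.dp_min) | (dp > cfg.dp_max))
    if not mask.any():
        return site
    genotypes = site.genotypes.copy()
    genotypes[mask] = MISSING
    return replace(site, genotypes=genotypes)


def filter_stream(
    sites: Iterable[SiteRecord], cfg: FilterConfig
) -> Iterator[SiteRecord]:
    """Apply :func:`apply_filters` across a stream, dropping removed sites."""
    for site in sites:
        kept = apply_filters(site, cfg)
        if kept is not None:
            yield kept


def read_allsites_vcf(
    path, samples: Sequence[str] | None = None
) -> tuple[list[str], Iterator[SiteRecord]]:
    """Open an all-sites VCF and return ``(sample_order, record_iterator)``.

    Invariant records (no ALT, or ALT ``.``) are yielded with empty ``alts``;
    missing genotypes are preserved.  Requesting samples absent from the
    header raises immediately, listing them.  Malformed input surfaces as a
    parse error carrying the htslib diagnostic and file path.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib error paths
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    if samples is not None:
        missing = sorted(set(samples) - set(vcf.samples))
        if missing:
            vcf.close()
            raise KeyError(f"samples absent from {path}: {missing}")
        vcf.set_samples(list(samples))
    order = list(vcf.samples)

    def _iter() -> Iterator[SiteRecord]:
        try:
            for variant in vcf:
                gts = np.asarray(variant.genotype.array(), dtype=np.int16)[:, :2]
                alts = tuple(a for a in variant.ALT if a != ".")
                info = {
                    k: float(variant.INFO[k])
                    for k in SITE_INFO_KEYS
                    if variant.INFO.get(k) is not None
                }
                gq = variant.format("GQ")
                dp = variant.format("DP")
                yield SiteRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS - 1,
                    ref=variant.REF,
                    alts=alts,
                    genotypes=gts,
                    gq=None if gq is None else gq[:, 0].astype(np.int32),
                    dp=None if dp is None else dp[:, 0].astype(np.int32),
                    info=info,
                )
        except Exception as exc:
            if isinstance(exc, (ValueError, KeyError)):
                raise
            raise ValueError(f"error parsing VCF {path}: {exc}") from exc
        finally:
            vcf.close()

    return order, _iter()


def write_allsites_vcf(
    path,
    records: Iterable[SiteRecord],
    samples: Sequence[str],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write records as an uncompressed all-sites VCF 4.2 text file."""
    with open(path, "w") as fh:
        _write_header(fh, samples, contig_lengths)
        for rec in records:
            fh.write(_format_record(rec, len(samples)))


def _write_header(fh: io.TextIOBase, samples, contig_lengths) -> None:
    fh.write("##fileformat=VCFv4.2\n")
    fh.write('##source=divscan\n')
    for name, length in contig_lengths.items():
        fh.write(f"##contig=<ID={name},length={length}>\n")
    for key in SITE_INFO_KEYS:
        fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
    fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    fh.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )


def _format_record(rec: SiteRecord, n_samples: int) -> str:
    if rec.n_samples != n_samples:
        raise ValueError("record sample count differs from header")
    alt = ",".join(rec.alts) if rec.alts else "."
    if rec.info:
        info = ";".join(f"{k}={rec.info[k]:g}" for k in SITE_INFO_KEYS if k in rec.info)
    else:
        info = "."
    has_gq = rec.gq is not None
    has_dp = rec.dp is not None
    fmt = "GT" + (":GQ" if has_gq else "") + (":DP" if has_dp else "")
    cols = [rec.chrom, str(rec.pos + 1), ".", rec.ref, alt, ".", "PASS", info, fmt]
    for i in range(n_samples):
        a, b = rec.genotypes[i]
        gt = "./." if a < 0 else f"{a}/{b}"
        parts = [gt]
        if has_gq:
            v = int(rec.gq[i])
            parts.append("." if v < 0 else str(v))
        if has_dp:
            v = int(rec.dp[i])
            parts.append("." if v < 0 else str(v))
        cols.append(":".join(parts))
    return "\t".join(cols) + "\n"
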