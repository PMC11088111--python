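"""Shared fixtures: tiny hand-built VCFs, population maps, random sites."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from divscan.allsites import PopulationMap, SiteRecord, write_allsites_vcf


@pytest.fixture
def two_pop_map() -> PopulationMap:
    return PopulationMap(
        {"s1": "atl", "s2": "atl", "s3": "pac", "s4": "pac"}
    )


def make_site(pos, genotypes, ref="A", alts=("T",), chrom="chr1", **kwargs) -> SiteRecord:
    return SiteRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        genotypes=np.array(genotypes, dtype=np.int16),
        **kwargs,
    )


@pytest.fixture
def site_factory():
    return make_site


def random_site_records(
    rng: np.random.Generator,
    n_samples: int,
    n_sites: int,
    missing_rate: float = 0.1,
    p_invariant: float = 0.55,
    p_multi: float = 0.05,
    p_indel: float = 0.05,
    chrom: str = "chr1",
) -> list[SiteRecord]:
    """Random all-sites records mixing invariant/biallelic/multiallelic/indel."""
    records = []
    for pos in range(n_sites):
        u = rng.random()
        if u < p_invariant:
            alts, high = (), 0
        elif u < p_invariant + p_multi:
            alts, high = ("C", "G"), 2
        elif u < p_invariant + p_multi + p_indel:
            alts, high = ("TTA",), 1
        else:
            alts, high = ("T",), 1
        g = rng.integers(0, high + 1, size=(n_samples, 2)).astype(np.int16)
        miss = rng.random(n_samples) < missing_rate
        g[miss] = -1
        records.append(
            SiteRecord(chrom=chrom, pos=pos, ref="A", alts=alts, genotypes=g)
        )
    return records


@pytest.fixture
def random_records():
    return random_site_records


def write_vcf(tmp_path: Path, records, samples, contig_lengths, name="test.vcf") -> Path:
    path = tmp_path / name
    write_allsites_vcf(path, records, samples, contig_lengths)
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf
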