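"""Collapsed multigene-cluster simulation.

Models the read cross-mapping artifact at copy-number-variable gene
clusters: ``K`` paralogous copies diverged at paralogous sequence variants
(PSVs) are represented by a *single* collapsed locus.  Every copy a
haplotype carries contributes its allele to the individual's pooled allele
set, and the emitted diploid genotype is heterozygous iff the pool holds
both alleles — so with all copies present everywhere, every PSV site is
called heterozygous in every individual.  With ``n`` called alleles the
apparent per-site π at such a site is ``n / (2(n-1))``, identical in both
populations, producing the characteristic low-FST / high-π signature
against a divergent split baseline.

An optional binomial read-sampling mode (``depth``) replaces the
deterministic pooled-genotype rule for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ..allsites import PopulationMap, SiteRecord, write_allsites_vcf
from .split import SplitModelConfig, sim_split_coalescent

__all__ = [
    "CollapseConfig",
    "CollapseSimResult",
    "sim_collapsed_cluster",
    "CompositeConfig",
    "sim_composite_genome",
    "apparent_site_pi",
]


def apparent_site_pi(n_alleles: int) -> float:
    """Apparent per-site π at a universally heterozygous site.

    ``n`` called alleles split evenly between the two PSV alleles give
    ``(n/2)^2`` differing pairs out of ``n(n-1)/2``, i.e. ``n / (2(n-1))``.
    """
    if n_alleles < 2:
        raise ValueError("need >= 2 alleles")
    return n_alleles / (2.0 * (n_alleles - 1))


@dataclass(frozen=True, slots=True)
class CollapseConfig:
    """Collapsed cluster with split-model flanks."""

    n1: int = 10
    n2: int = 10
    k_copies: int = 2
    psv_density: float = 0.02
    #: scalar applied to every copy, or one probability per copy
    presence_prob: float | tuple[float, ...] = 1.0
    allelic_theta: float = 0.0
    cluster_span: int = 4000
    flank_span: int = 4000
    flank_theta: float = 0.002
    flank_T: float = 1.0
    depth: int | None = None
    seed: int = 0
    pop1: str = "pop1"
    pop2: str = "pop2"
    chrom: str = "sim1"

    def __post_init__(self) -> None:
        if self.k_copies < 2:
            raise ValueError("need K >= 2 paralog copies")
        if not 0.0 < self.psv_density < 0.2:
            raise ValueError("psv_density must be in (0, 0.2)")
        probs = (
            self.presence_prob
            if isinstance(self.presence_prob, tuple)
            else (self.presence_prob,)
        )
        if isinstance(self.presence_prob, tuple) and len(probs) != self.k_copies:
            raise ValueError("need one presence probability per copy")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("presence_prob must be in [0, 1]")
        if self.cluster_span < 1 or self.flank_span < 0:
            raise ValueError("bad span")


@dataclass(slots=True)
class CollapseSimResult:
    config: CollapseConfig
    genotypes: np.ndarray  # (L, n, 2) int16, -1 missing
    refs: np.ndarray
    alts: np.ndarray
    cluster_start: int
    cluster_end: int
    truth: dict[str, object]

    @property
    def L(self) -> int:
        return self.genotypes.shape[0]

    @property
    def sample_names(self) -> list[str]:
        c = self.config
        return [f"{c.pop1}_{i}" for i in range(c.n1)] + [
            f"{c.pop2}_{i}" for i in range(c.n2)
        ]

    def population_map(self) -> PopulationMap:
        c = self.config
        return PopulationMap(
            {
                s: (c.pop1 if i < c.n1 else c.pop2)
                for i, s in enumerate(self.sample_names)
            }
        )

    def site_records(self) -> Iterator[SiteRecord]:
        for i in range(self.L):
            alt = self.alts[i]
            yield SiteRecord(
                chrom=self.config.chrom,
                pos=i,
                ref=str(self.refs[i]),
                alts=(str(alt),) if alt else (),
                genotypes=self.genotypes[i].copy(),
            )

    def to_vcf(self, path) -> None:
        write_allsites_vcf(
            path, self.site_records(), self.sample_names, {self.config.chrom: self.L}
        )


def _collapsed_block(
    rng: np.random.Generator,
    n1: int,
    n2: int,
    K: int,
    psv_density: float,
    presence_prob: float,
    allelic_theta: float,
    allelic_T: float,
    span: int,
    depth: int | None,
):
    """Genotypes over one collapsed cluster of ``span`` bp.

    Returns ``(G, is_variant, truth)`` where ``G`` is ``(span, n, 2)`` with
    -1 for individuals carrying no copy at all.
    """
    n = n1 + n2
    haps = 2 * n
    probs = np.broadcast_to(
        np.asarray(presence_prob, dtype=float), (K,)
    )
    presence = rng.random((haps, K)) < probs[None, :]  # copy presence per haplotype
    psv = rng.random(span) < psv_density
    psv_sites = np.flatnonzero(psv)
    owner = rng.integers(0, K, size=psv_sites.size)  # copy carrying the derived PSV allele

    # allelic (within-copy) variation: one split-model matrix per copy
    allelic: list[np.ndarray | None] = [None] * K
    if allelic_theta > 0:
        for c in range(K):
            sub = sim_split_coalescent(
                SplitModelConfig(
                    n1=n1,
                    n2=n2,
                    L=span,
                    theta=allelic_theta,
                    T=allelic_T,
                    seed=int(rng.integers(2**63 - 1)),
                )
            )
            allelic[c] = sub.genotypes  # (span, n, 2) of 0/1 derived indicators

    G = np.zeros((span, n, 2), dtype=np.int16)
    # individuals with no copy anywhere are missing at every cluster site
    copies_per_ind = presence.reshape(n, 2, K).sum(axis=(1, 2))
    no_copy = copies_per_ind == 0
    G[:, no_copy, :] = -1

    def pooled_genotype(alt_count: int, ref_count: int):
        if alt_count + ref_count == 0:
            return (-1, -1)
        if depth is not None:
            f = alt_count / (alt_count + ref_count)
            alt_reads = rng.binomial(depth, f)
            if alt_reads == 0:
                return (0, 0)
            if alt_reads == depth:
                return (1, 1)
            return (0, 1)
        if alt_count and ref_count:
            return (0, 1)
        return (1, 1) if alt_count else (0, 0)

    is_variant = np.zeros(span, dtype=bool)
    for site, own in zip(psv_sites, owner):
        for ind in range(n):
            pres = presence[2 * ind : 2 * ind + 2]  # (2, K)
            alt_count = int(pres[:, own].sum())
            ref_count = int(pres.sum() - alt_count)
            G[site, ind] = pooled_genotype(alt_count, ref_count)
        is_variant[site] = True

    if allelic_theta > 0:
        psv_set = set(psv_sites.tolist())
        derived_any = np.zeros(span, dtype=bool)
        for c in range(K):
            derived_any |= (allelic[c] == 1).any(axis=(1, 2))
        for site in np.flatnonzero(derived_any):
            if site in psv_set:
                continue  # keep sites biallelic: PSV takes precedence
            for ind in range(n):
                pres = presence[2 * ind : 2 * ind + 2]
                alt_count = 0
                total = 0
                for h in range(2):
                    for c in range(K):
                        if pres[h, c]:
                            total += 1
                            if allelic[c][site, ind, h] == 1:
                                alt_count += 1
                ref_count = total - alt_count
                G[site, ind] = pooled_genotype(alt_count, ref_count)
            if (G[site] == 1).any():
                is_variant[site] = True

    truth = {
        "psv_positions": psv_sites,
        "psv_owner": owner,
        "presence": presence,
        "n_psv": int(psv_sites.size),
        "psv_density": psv_density,
        "expected_site_pi_full_presence": apparent_site_pi(2 * (n1 + n2)),
        "per_copy_theta": allelic_theta,
    }
    return G, is_variant, truth


_BASES = np.array(list("ACGT"))


def _assign_alleles(rng: np.random.Generator, L: int, variant: np.ndarray):
    refs = rng.choice(_BASES, size=L)
    shift = rng.integers(1, 4, size=L)
    base_idx = np.searchsorted(_BASES, refs)
    alts = np.where(variant, _BASES[(base_idx + shift) % 4], "")
    return refs, alts


def sim_collapsed_cluster(cfg: CollapseConfig) -> CollapseSimResult:
    """Collapsed cluster flanked by split-model sequence on both sides."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n1 + cfg.n2
    blocks: list[np.ndarray] = []
    variants: list[np.ndarray] = []

    def flank(seed: int) -> None:
        if cfg.flank_span == 0:
            return
        res = sim_split_coalescent(
            SplitModelConfig(
                n1=cfg.n1,
                n2=cfg.n2,
                L=cfg.flank_span,
                theta=cfg.flank_theta,
                T=cfg.flank_T,
                seed=seed,
            )
        )
        blocks.append(res.genotypes)
        variants.append((res.genotypes == 1).any(axis=(1, 2)))

    flank(int(rng.integers(2**63 - 1)))
    G_cluster, var_cluster, truth = _collapsed_block(
        rng,
        cfg.n1,
        cfg.n2,
        cfg.k_copies,
        cfg.psv_density,
        cfg.presence_prob,
        cfg.allelic_theta,
        cfg.flank_T,
        cfg.cluster_span,
        cfg.depth,
    )
    cluster_start = cfg.flank_span
    blocks.append(G_cluster)
    variants.append(var_cluster)
    flank(int(rng.integers(2**63 - 1)))

    G = np.concatenate(blocks, axis=0) if len(blocks) > 1 else blocks[0]
    variant = np.concatenate(variants)
    refs, alts = _assign_alleles(rng, G.shape[0], variant)
    truth["psv_positions"] = truth["psv_positions"] + cluster_start
    truth["cluster_interval"] = (cluster_start, cluster_start + cfg.cluster_span)
    return CollapseSimResult(
        config=cfg,
        genotypes=G,
        refs=refs,
        alts=alts,
        cluster_start=cluster_start,
        cluster_end=cluster_start + cfg.cluster_span,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# composite genome: split baseline with embedded collapsed clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CompositeConfig:
    """A tiled chromosome: split baseline, some windows replaced by clusters."""

    n_windows: int = 400
    window_size: int = 4000
    cluster_windows: tuple[int, ...] = ()
    n1: int = 10
    n2: int = 10
    theta: float = 0.002
    T: float = 1.0
    k_copies: int = 2
    psv_density: float = 0.02
    presence_prob: float = 1.0
    allelic_theta: float = 0.0
    seed: int = 0
    pop1: str = "pop1"
    pop2: str = "pop2"
    chrom: str = "sim1"

    def __post_init__(self) -> None:
        if any(not 0 <= w < self.n_windows for w in self.cluster_windows):
            raise ValueError("cluster window index out of range")


@dataclass(slots=True)
class CompositeSimResult:
    config: CompositeConfig
    genotypes: np.ndarray
    refs: np.ndarray
    alts: np.ndarray
    truth: dict[str, object]

    @property
    def L(self) -> int:
        return self.genotypes.shape[0]

    @property
    def sample_names(self) -> list[str]:
        c = self.config
        return [f"{c.pop1}_{i}" for i in range(c.n1)] + [
            f"{c.pop2}_{i}" for i in range(c.n2)
        ]

    def population_map(self) -> PopulationMap:
        c = self.config
        return PopulationMap(
            {
                s: (c.pop1 if i < c.n1 else c.pop2)
                for i, s in enumerate(self.sample_names)
            }
        )

    def site_records(self) -> Iterator[SiteRecord]:
        for i in range(self.L):
            alt = self.alts[i]
            yield SiteRecord(
                chrom=self.config.chrom,
                pos=i,
                ref=str(self.refs[i]),
                alts=(str(alt),) if alt else (),
                genotypes=self.genotypes[i].copy(),
            )

    def to_vcf(self, path) -> None:
        write_allsites_vcf(
            path, self.site_records(), self.sample_names, {self.config.chrom: self.L}
        )


def sim_composite_genome(cfg: CompositeConfig) -> CompositeSimResult:
    """Split-model chromosome with designated windows collapsed.

    The truth table records the implanted window indices and the
    enumeration expectation of apparent π inside them.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_windows * cfg.window_size
    base = sim_split_coalescent(
        SplitModelConfig(
            n1=cfg.n1,
            n2=cfg.n2,
            L=L,
            theta=cfg.theta,
            T=cfg.T,
            seed=int(rng.integers(2**63 - 1)),
            pop1=cfg.pop1,
            pop2=cfg.pop2,
            chrom=cfg.chrom,
        )
    )
    G = base.genotypes
    variant = (G == 1).any(axis=(1, 2))
    refs, alts = np.array(base.refs), np.array(base.alts)

    cluster_truth = {}
    for w in cfg.cluster_windows:
        start = w * cfg.window_size
        Gc, var_c, t = _collapsed_block(
            rng,
            cfg.n1,
            cfg.n2,
            cfg.k_copies,
            cfg.psv_density,
            cfg.presence_prob,
            cfg.allelic_theta,
            cfg.T,
            cfg.window_size,
            depth=None,
        )
        G[start : start + cfg.window_size] = Gc
        variant[start : start + cfg.window_size] = var_c
        cluster_truth[w] = {
            "n_psv": t["n_psv"],
            "interval": (start, start + cfg.window_size),
        }
    # re-assign ALT bases where collapse introduced/removed variation
    _, new_alts = _assign_alleles(rng, L, variant)
    for w in cfg.cluster_windows:
        start = w * cfg.window_size
        alts[start : start + cfg.window_size] = new_alts[start : start + cfg.window_size]

    truth: dict[str, object] = {
        "cluster_windows": tuple(cfg.cluster_windows),
        "clusters": cluster_truth,
        "expected_site_pi_full_presence": apparent_site_pi(2 * (cfg.n1 + cfg.n2)),
        "expected_baseline_pi": cfg.theta,
        "expected_baseline_dxy": cfg.theta * (1 + cfg.T),
    }
    return CompositeSimResult(
        config=cfg, genotypes=G, refs=refs, alts=alts, truth=truth
    )
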