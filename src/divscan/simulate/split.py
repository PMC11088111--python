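"""Per-site structured-coalescent simulation of a two-population split.

Each site gets an independent genealogy: lineages coalesce within their
deme at rate C(k,2) until the split time ``T`` (in units of 2N
generations), after which the remaining lineages form one panmictic pool.
Each site carries at most one mutation, drawn with probability
``theta/2 * L_tree`` (``L_tree`` = total branch length) and placed on a
branch chosen proportionally to length.  This single-mutation thinning
keeps the output strictly biallelic-or-invariant and makes the
pair-difference expectation exactly linear in branch length, so the truth
values below are exact rather than first-order approximations (a Poisson
multi-hit model with re-drawing of 2+-mutation sites would bias them
downward by a factor ~1/(1+theta*L_tree/2)).

Closed-form expectations (recorded in the truth table):
``E[pi] = theta`` per population, ``E[dxy] = theta * (1 + T)`` and the
Hudson-style ``1 - pi/dxy -> T / (1 + T)``.

Event *times* are generated vectorised across sites; tree *topology* is
only replayed (cheaply, in Python) for the rare sites that receive a
mutation, which is exact because pair choices are independent of the
event-time process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from ..allsites import PopulationMap, SiteRecord, write_allsites_vcf

__all__ = ["SplitModelConfig", "SplitSimResult", "sim_split_coalescent"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True, slots=True)
class SplitModelConfig:
    """Two-deme split model: diploid sample sizes, θ per site, split time."""

    n1: int
    n2: int
    L: int
    theta: float
    T: float
    seed: int = 0
    pop1: str = "pop1"
    pop2: str = "pop2"
    chrom: str = "sim1"

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need >= 2 diploids per population")
        if not (0 <= self.theta <= 0.05):
            raise ValueError("theta must be in [0, 0.05] (multi-hit regime excluded)")
        if self.T < 0:
            raise ValueError("split time must be >= 0")
        if self.L < 1:
            raise ValueError("need at least one site")


@dataclass(slots=True)
class SplitSimResult:
    """Simulated genotypes plus ground truth."""

    config: SplitModelConfig
    genotypes: np.ndarray  # (L, n1+n2, 2) int16
    refs: np.ndarray  # (L,) base characters
    alts: np.ndarray  # (L,) base characters, "" at invariant sites
    truth: dict[str, float]

    @property
    def sample_names(self) -> list[str]:
        c = self.config
        return [f"{c.pop1}_{i}" for i in range(c.n1)] + [
            f"{c.pop2}_{i}" for i in range(c.n2)
        ]

    def population_map(self) -> PopulationMap:
        c = self.config
        names = self.sample_names
        return PopulationMap(
            {s: (c.pop1 if i < c.n1 else c.pop2) for i, s in enumerate(names)}
        )

    def site_records(self) -> Iterator[SiteRecord]:
        chrom = self.config.chrom
        for i in range(self.config.L):
            alt = self.alts[i]
            yield SiteRecord(
                chrom=chrom,
                pos=i,
                ref=str(self.refs[i]),
                alts=(str(alt),) if alt else (),
                genotypes=self.genotypes[i].copy(),
            )

    def to_vcf(self, path) -> None:
        write_allsites_vcf(
            path,
            self.site_records(),
            self.sample_names,
            {self.config.chrom: self.config.L},
        )


def sim_split_coalescent(cfg: SplitModelConfig) -> SplitSimResult:
    """Simulate an all-sites genotype matrix under the split model."""
    rng = np.random.default_rng(cfg.seed)
    ntot = cfg.n1 + cfg.n2
    G = np.zeros((cfg.L, ntot, 2), dtype=np.int16)

    if cfg.theta > 0:
        carriers = _simulate_derived_leaves(rng, cfg)
        for site_idx, leaves in carriers.items():
            hap = np.flatnonzero(leaves)
            G[site_idx, hap // 2, hap % 2] = 1

    variant = (G == 1).any(axis=(1, 2))
    refs = rng.choice(_BASES, size=cfg.L)
    shift = rng.integers(1, 4, size=cfg.L)
    base_idx = np.searchsorted(_BASES, refs)
    alt_bases = _BASES[(base_idx + shift) % 4]
    alts = np.where(variant, alt_bases, "")

    truth = {
        "theta": cfg.theta,
        "T": cfg.T,
        "expected_pi": cfg.theta,
        "expected_dxy": cfg.theta * (1.0 + cfg.T),
        "expected_fst_hudson": cfg.T / (1.0 + cfg.T) if cfg.T > 0 else 0.0,
    }
    return SplitSimResult(config=cfg, genotypes=G, refs=refs, alts=alts, truth=truth)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _simulate_derived_leaves(
    rng: np.random.Generator, cfg: SplitModelConfig
) -> dict[int, np.ndarray]:
    """Map site index -> boolean derived-allele indicator over haploid leaves."""
    return _sim_once(rng, cfg, cfg.L)


def _deme_event_times(
    rng: np.random.Generator, k: int, T: float, S: int
) -> np.ndarray:
    """Within-deme coalescence times before the split, ``(k-1, S)``.

    Row ``e`` holds the time of the ``e``-th coalescence; entries >= T mean
    the event did not happen (the deme still has multiple lineages at T).
    """
    if k < 2:
        return np.full((0, S), np.inf)
    rates = np.array([(k - e) * (k - e - 1) / 2.0 for e in range(k - 1)])
    dts = rng.exponential(1.0, size=(k - 1, S)) / rates[:, None]
    return np.cumsum(dts, axis=0)


def _sim_once(rng: np.random.Generator, cfg: SplitModelConfig, S: int):
    """One vectorised pass over ``S`` sites.

    Event times are generated for all sites at once; the per-site mutation
    indicator is Bernoulli(theta/2 * total branch length), and only mutated
    sites get their topology replayed.
    """
    k1, k2 = 2 * cfg.n1, 2 * cfg.n2
    T = cfg.T

    t1 = _deme_event_times(rng, k1, T, S)
    t2 = _deme_event_times(rng, k2, T, S)
    v1 = t1 < T
    v2 = t2 < T
    c1 = v1.sum(axis=0)
    c2 = v2.sum(axis=0)

    # branch length accrued during [0, T]: each coalescence at time t
    # removes (T - t) of lineage time from the k*T maximum.
    length = (k1 + k2) * T - np.where(v1, T - t1, 0.0).sum(axis=0) \
        - np.where(v2, T - t2, 0.0).sum(axis=0)

    # merged phase from T with k_rem lineages down to 1
    k_rem = (k1 - c1) + (k2 - c2)
    max_events = int(k_rem.max()) - 1
    tm = np.full((max_events, S), np.inf)
    t_cur = np.full(S, T)
    for e in range(max_events):
        kcur = k_rem - e
        active = kcur >= 2
        rate = kcur * (kcur - 1) / 2.0
        dt = rng.exponential(1.0, size=S) / np.maximum(rate, 1e-300)
        length += np.where(active, kcur * dt, 0.0)
        t_cur = t_cur + np.where(active, dt, 0.0)
        tm[e, active] = t_cur[active]

    lam = cfg.theta / 2.0 * length
    if lam.max(initial=0.0) > 1.0:
        raise ValueError(
            "theta too large for single-mutation thinning (theta/2 * L_tree > 1)"
        )
    mutated = rng.random(S) < lam
    singles: dict[int, np.ndarray] = {}
    for s in np.flatnonzero(mutated):
        d1 = np.sort(t1[v1[:, s], s])
        d2 = np.sort(t2[v2[:, s], s])
        merged = tm[np.isfinite(tm[:, s]), s]
        u = rng.uniform(0.0, length[s])
        t_mut, k_at = _locate_mutation(u, k1, k2, T, d1, d2, merged)
        singles[s] = _replay_partition(rng, k1, k2, T, d1, d2, merged, t_mut, k_at)
    return singles


def _locate_mutation(u, k1, k2, T, d1, d2, merged):
    """Convert a uniform draw on total branch length to a mutation time.

    Returns ``(t_mut, k_alive_at_t_mut)``; walks the piecewise-constant
    lineage-count function over the merged event timeline.
    """
    events = []  # (time, delta_k)
    for t in d1:
        events.append((t, -1))
    for t in d2:
        events.append((t, -1))
    for t in merged:
        events.append((t, -1))
    events.sort()
    k = k1 + k2
    t_prev = 0.0
    acc = 0.0
    for t, dk in events:
        span = (t - t_prev) * k
        if acc + span >= u:
            return t_prev + (u - acc) / k, k
        acc += span
        t_prev = t
        k += dk
    # numerically possible leftover: place on the final interval
    return t_prev, max(k, 1)


def _replay_partition(rng, k1, k2, T, d1, d2, merged, t_mut, k_at):
    """Re-draw tree topology consistent with the recorded event times and
    return the leaf set below the mutated lineage as a boolean vector."""
    ntot = k1 + k2
    deme1 = [[i] for i in range(k1)]
    deme2 = [[k1 + i] for i in range(k2)]

    def coalesce(pool: list[list[int]]) -> None:
        i = int(rng.integers(len(pool)))
        j = int(rng.integers(len(pool) - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        pool[i] = pool[i] + pool.pop(j)

    events = sorted(
        [(t, 1) for t in d1] + [(t, 2) for t in d2] + [(t, 0) for t in merged]
    )
    pool_merged: list[list[int]] | None = None
    for t, which in events:
        if t >= t_mut:
            break
        if which == 1:
            coalesce(deme1)
        elif which == 2:
            coalesce(deme2)
        else:
            if pool_merged is None:
                pool_merged = deme1 + deme2
            coalesce(pool_merged)
    if t_mut >= T and pool_merged is None:
        pool_merged = deme1 + deme2
    alive = pool_merged if pool_merged is not None else deme1 + deme2
    lineage = alive[int(rng.integers(len(alive)))]
    out = np.zeros(ntot, dtype=bool)
    out[lineage] = True
    return out
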