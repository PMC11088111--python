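"""Windowed diversity and differentiation estimators.

Per-window π (within each population), dxy (between two populations) and
Weir–Cockerham FST are computed as *ratios of sums*: per-site numerators and
denominators are accumulated over all contributing sites in a window and
divided once at the end.  Invariant sites contribute to the denominators, so
the estimates are unbiased in the presence of missing genotypes, provided the
input is an all-sites stream.

Per-site building blocks
------------------------
Within a population with ``n`` called alleles of which ``c_alt`` are the
alternate: ``diffs = c_ref * c_alt`` and ``comps = n(n-1)/2`` (requires
``n >= 2``).  Between populations: ``diffs = c_ref1*c_alt2 + c_alt1*c_ref2``
and ``comps = n1*n2``.  FST uses the diploid two-population variance
components *a*, *b*, *c* of Weir & Cockerham (1984), computed from per-site
called sample sizes and observed heterozygote counts; sites where either
population has fewer than two called genotypes contribute nothing to FST.
Multiallelic SNPs and indels contribute nothing to any statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .allsites import PopulationMap, SiteRecord

__all__ = [
    "WindowSpec",
    "SiteCounts",
    "WindowStats",
    "make_windows",
    "site_counts",
    "window_summaries",
    "region_pi",
    "pearson_correlation",
    "windows_to_dataframe",
    "write_windows_tsv",
    "read_windows_tsv",
    "read_recombination_track",
]


@dataclass(frozen=True, slots=True)
class WindowSpec:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class SiteCounts:
    """Per-site numerators/denominators for one biallelic or invariant site."""

    pi_diffs: dict[str, float]
    pi_comps: dict[str, float]
    dxy_diffs: float
    dxy_comps: float
    wc_a: float
    wc_b: float
    wc_c: float


@dataclass(slots=True)
class WindowStats:
    """Aggregated statistics for one window (NaN marks undefined)."""

    window: WindowSpec
    fst: float
    pi: dict[str, float]
    dxy: float
    pi_diffs: dict[str, float]
    pi_comps: dict[str, float]
    dxy_diffs: float
    dxy_comps: float
    wc_a: float
    wc_abc: float
    n_sites: int
    n_excluded: int

    @property
    def any_missing(self) -> bool:
        values = [self.fst, self.dxy, *self.pi.values()]
        return any(math.isnan(v) for v in values)


def make_windows(
    contig_lengths: Mapping[str, int], size: int
) -> list[WindowSpec]:
    """Tile each contig with nonoverlapping windows of ``size`` bp.

    The last window of a contig is truncated at the contig end.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    windows: list[WindowSpec] = []
    for chrom, length in contig_lengths.items():
        for start in range(0, length, size):
            windows.append(WindowSpec(chrom, start, min(start + size, length)))
    return windows


# ---------------------------------------------------------------------------
# per-site counts (batched core + scalar convenience wrapper)
# ---------------------------------------------------------------------------


def _pop_site_arrays(G: np.ndarray, idx: np.ndarray):
    """Called-genotype, alt-allele and het counts per site for one population.

    ``G`` is ``(S, n_samples, 2)``; returns ``(m, alt, het)`` each ``(S,)``.
    Genotypes are fully called or fully missing by construction.
    """
    Gp = G[:, idx, :]
    called = Gp[:, :, 0] >= 0
    m = called.sum(axis=1)
    alt = ((Gp == 1) & called[:, :, None]).sum(axis=(1, 2))
    het = (called & (Gp[:, :, 0] != Gp[:, :, 1])).sum(axis=1)
    return m.astype(np.float64), alt.astype(np.float64), het.astype(np.float64)


def _batch_counts(G: np.ndarray, usable: np.ndarray, idx1: np.ndarray, idx2: np.ndarray):
    """Vectorised per-site counts for a two-population comparison.

    Returns a dict of ``(S,)`` arrays: pi numerators/denominators per
    population, dxy numerators/denominators, and WC components ``a`` and
    ``a+b+c``.  ``usable`` masks out indels/multiallelic sites.
    """
    m1, alt1, het1 = _pop_site_arrays(G, idx1)
    m2, alt2, het2 = _pop_site_arrays(G, idx2)
    n1, n2 = 2.0 * m1, 2.0 * m2
    u = usable.astype(np.float64)

    pi_d1 = alt1 * (n1 - alt1) * u
    pi_c1 = np.where(n1 >= 2, n1 * (n1 - 1) / 2.0, 0.0) * u
    pi_d2 = alt2 * (n2 - alt2) * u
    pi_c2 = np.where(n2 >= 2, n2 * (n2 - 1) / 2.0, 0.0) * u

    dxy_d = ((n1 - alt1) * alt2 + alt1 * (n2 - alt2)) * u
    dxy_c = n1 * n2 * u

    # Weir & Cockerham (1984) two-population diploid components
    wc_ok = usable & (m1 >= 2) & (m2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, alt1 / np.maximum(n1, 1.0), 0.0)
        p2 = np.where(n2 > 0, alt2 / np.maximum(n2, 1.0), 0.0)
        h1 = np.where(m1 > 0, het1 / np.maximum(m1, 1.0), 0.0)
        h2 = np.where(m2 > 0, het2 / np.maximum(m2, 1.0), 0.0)
        msum = m1 + m2
        nbar = msum / 2.0
        nc = msum - (m1 * m1 + m2 * m2) / np.maximum(msum, 1.0)
        pbar = (m1 * p1 + m2 * p2) / np.maximum(msum, 1.0)
        s2 = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / np.maximum(nbar, 1.0)
        hbar = (m1 * h1 + m2 * h2) / np.maximum(msum, 1.0)
        inner = pbar * (1.0 - pbar) - s2 / 2.0
        # safe denominators: wc_ok implies nbar >= 2 and nc > 0
        nc_safe = np.where(wc_ok, nc, 1.0)
        nbar_m1 = np.where(wc_ok, nbar - 1.0, 1.0)
        nbar_safe = np.where(wc_ok, nbar, 1.0)
        a = (nbar_safe / nc_safe) * (s2 - (inner - hbar / 4.0) / nbar_m1)
        b = (nbar_safe / nbar_m1) * (
            inner - (2.0 * nbar_safe - 1.0) / (4.0 * nbar_safe) * hbar
        )
        c = hbar / 2.0
    a = np.where(wc_ok, a, 0.0)
    b = np.where(wc_ok, b, 0.0)
    c = np.where(wc_ok, c, 0.0)

    contributes = usable & ((pi_c1 > 0) | (pi_c2 > 0) | (dxy_c > 0))
    return {
        "pi_d1": pi_d1,
        "pi_c1": pi_c1,
        "pi_d2": pi_d2,
        "pi_c2": pi_c2,
        "dxy_d": dxy_d,
        "dxy_c": dxy_c,
        "a": a,
        "b": b,
        "c": c,
        "contributes": contributes,
    }


def site_counts(site: SiteRecord, pops: PopulationMap, sample_order: Sequence[str]) -> SiteCounts:
    """Per-site counts for one record (two-population map required)."""
    pop1, pop2 = _two_pops(pops)
    idx = pops.indices(sample_order)
    usable = np.array([site.is_biallelic_snp or site.is_invariant])
    G = site.genotypes[None, :, :]
    r = _batch_counts(G, usable, idx[pop1], idx[pop2])
    return SiteCounts(
        pi_diffs={pop1: float(r["pi_d1"][0]), pop2: float(r["pi_d2"][0])},
        pi_comps={pop1: float(r["pi_c1"][0]), pop2: float(r["pi_c2"][0])},
        dxy_diffs=float(r["dxy_d"][0]),
        dxy_comps=float(r["dxy_c"][0]),
        wc_a=float(r["a"][0]),
        wc_b=float(r["b"][0]),
        wc_c=float(r["c"][0]),
    )


def _two_pops(pops: PopulationMap) -> tuple[str, str]:
    names = pops.populations
    if len(names) != 2:
        raise ValueError(f"exactly two populations required, got {names}")
    return names[0], names[1]


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------


class _WindowIndex:
    """Assign 0-based positions to windows, per chromosome."""

    def __init__(self, windows: Sequence[WindowSpec]):
        self.windows = list(windows)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, w in enumerate(self.windows):
            per_chrom.setdefault(w.chrom, []).append((w.start, w.end, i))
        for chrom, triples in per_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples])
            ends = np.array([t[1] for t in triples])
            gidx = np.array([t[2] for t in triples])
            self.by_chrom[chrom] = (starts, ends, gidx)

    def assign(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Global window index per position, -1 where unassigned."""
        out = np.full(pos.shape, -1, dtype=np.int64)
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return out
        starts, ends, gidx = entry
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        out[ok] = gidx[j[ok]]
        return out


_SUM_KEYS = ("pi_d1", "pi_c1", "pi_d2", "pi_c2", "dxy_d", "dxy_c", "a", "abc")


def _accumulate(
    sites: Iterable[SiteRecord],
    index: _WindowIndex,
    idx1: np.ndarray,
    idx2: np.ndarray,
    batch_size: int = 8192,
):
    """Stream sites through the batched counter, summing per window."""
    W = len(index.windows)
    sums = {k: np.zeros(W) for k in _SUM_KEYS}
    n_sites = np.zeros(W, dtype=np.int64)
    n_excluded = np.zeros(W, dtype=np.int64)

    batch: list[SiteRecord] = []
    last: tuple[str, int] | None = None

    def flush() -> None:
        if not batch:
            return
        chrom = batch[0].chrom
        pos = np.array([r.pos for r in batch])
        widx = index.assign(chrom, pos)
        usable = np.array(
            [r.is_biallelic_snp or r.is_invariant for r in batch]
        )
        bad = ~usable & (widx >= 0)
        if bad.any():
            n_excluded[:] += np.bincount(widx[bad], minlength=W).astype(np.int64)
        keep = widx >= 0
        if keep.any():
            G = np.stack([r.genotypes for r in batch])
            r = _batch_counts(G, usable, idx1, idx2)
            w = widx[keep]
            for key in ("pi_d1", "pi_c1", "pi_d2", "pi_c2", "dxy_d", "dxy_c", "a"):
                sums[key] += np.bincount(w, weights=r[key][keep], minlength=W)
            abc = r["a"] + r["b"] + r["c"]
            sums["abc"] += np.bincount(w, weights=abc[keep], minlength=W)
            n_sites[:] += np.bincount(
                w, weights=r["contributes"][keep].astype(np.int64), minlength=W
            ).astype(np.int64)
        batch.clear()

    for site in sites:
        if last is not None and site.chrom == last[0] and site.pos < last[1]:
            raise ValueError(
                f"unsorted input at {site.chrom}:{site.pos + 1} (after {last[1] + 1})"
            )
        if batch and site.chrom != batch[0].chrom:
            flush()
        last = (site.chrom, site.pos)
        batch.append(site)
        if len(batch) >= batch_size:
            flush()
    flush()
    return sums, n_sites, n_excluded


def window_summaries(
    sites: Iterable[SiteRecord],
    windows: Sequence[WindowSpec],
    pops: PopulationMap,
    sample_order: Sequence[str],
    batch_size: int = 8192,
) -> list[WindowStats]:
    """Aggregate per-site counts into per-window statistics.

    ``sites`` must be position-sorted within each chromosome.  Statistics
    whose denominator is zero come back as NaN and flag the window via
    :attr:`WindowStats.any_missing` (such windows are excluded before
    percentile-based selection downstream).
    """
    pop1, pop2 = _two_pops(pops)
    idx = pops.indices(sample_order)
    index = _WindowIndex(windows)
    sums, n_sites, n_excluded = _accumulate(
        sites, index, idx[pop1], idx[pop2], batch_size
    )

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    out: list[WindowStats] = []
    for i, w in enumerate(index.windows):
        out.append(
            WindowStats(
                window=w,
                fst=sums["a"][i] / sums["abc"][i] if sums["abc"][i] != 0 else float("nan"),
                pi={
                    pop1: ratio(sums["pi_d1"][i], sums["pi_c1"][i]),
                    pop2: ratio(sums["pi_d2"][i], sums["pi_c2"][i]),
                },
                dxy=ratio(sums["dxy_d"][i], sums["dxy_c"][i]),
                pi_diffs={pop1: sums["pi_d1"][i], pop2: sums["pi_d2"][i]},
                pi_comps={pop1: sums["pi_c1"][i], pop2: sums["pi_c2"][i]},
                dxy_diffs=sums["dxy_d"][i],
                dxy_comps=sums["dxy_c"][i],
                wc_a=sums["a"][i],
                wc_abc=sums["abc"][i],
                n_sites=int(n_sites[i]),
                n_excluded=int(n_excluded[i]),
            )
        )
    return out


def region_pi(
    sites: Iterable[SiteRecord],
    intervals: Sequence[WindowSpec],
    pops: PopulationMap,
    population: str,
    sample_order: Sequence[str],
    pool_by_label: bool = True,
) -> dict[str, float]:
    """π over arbitrary (possibly non-tiling) intervals for one population.

    Intervals sharing a label (e.g. the exons of one gene) are pooled by
    summing numerators and denominators before dividing, so the result is
    identical to running on the concatenated interval.  Returns
    ``label -> pi`` (NaN when no called sites).
    """
    if not intervals:
        raise ValueError("empty interval set")
    if population not in pops.populations:
        raise KeyError(f"unknown population {population!r}")
    labelled = [
        WindowSpec(w.chrom, w.start, w.end, w.label or f"__iv{i}")
        for i, w in enumerate(intervals)
    ]
    stats = window_summaries(sites, labelled, pops, sample_order)
    diffs: dict[str, float] = {}
    comps: dict[str, float] = {}
    for st in stats:
        key = st.window.label if pool_by_label else f"{st.window.chrom}:{st.window.start}-{st.window.end}"
        diffs[key] = diffs.get(key, 0.0) + st.pi_diffs[population]
        comps[key] = comps.get(key, 0.0) + st.pi_comps[population]
    return {
        k: (diffs[k] / comps[k] if comps[k] > 0 else float("nan")) for k in diffs
    }


# ---------------------------------------------------------------------------
# track correlation
# ---------------------------------------------------------------------------


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p (t with k-2 df), NaNs dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("tracks differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a track")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def windows_to_dataframe(stats: Sequence[WindowStats], pops: PopulationMap) -> pd.DataFrame:
    """Stable tabular form: 1-based inclusive coordinates, NaN = undefined."""
    pop1, pop2 = _two_pops(pops)
    rows = []
    for st in stats:
        rows.append(
            {
                "chrom": st.window.chrom,
                "start": st.window.start + 1,
                "end": st.window.end,
                "n_sites": st.n_sites,
                "fst": st.fst,
                f"pi_{pop1}": st.pi[pop1],
                f"pi_{pop2}": st.pi[pop2],
                "dxy": st.dxy,
                f"pi_diffs_{pop1}": st.pi_diffs[pop1],
                f"pi_comps_{pop1}": st.pi_comps[pop1],
                f"pi_diffs_{pop2}": st.pi_diffs[pop2],
                f"pi_comps_{pop2}": st.pi_comps[pop2],
                "dxy_diffs": st.dxy_diffs,
                "dxy_comps": st.dxy_comps,
                "wc_a": st.wc_a,
                "wc_abc": st.wc_abc,
            }
        )
    return pd.DataFrame(rows)


def write_windows_tsv(path, stats: Sequence[WindowStats], pops: PopulationMap) -> None:
    windows_to_dataframe(stats, pops).to_csv(path, sep="\t", index=False)


def read_windows_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_recombination_track(path) -> pd.DataFrame:
    """Read a chrom/start/end/rate TSV (cM/Mb); rejects negative rates."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"recombination track needs columns {sorted(required)}")
    if (df["rate"] < 0).any():
        raise ValueError("negative recombination rate")
    return df
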