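"""Independent reference implementations used only by the test suite.

These deliberately re-derive every statistic from first principles (explicit
pair enumeration, generic multi-population variance components, exact
rational hypergeometric sums) so they share no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_pi_dxy(G: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, usable: np.ndarray):
    """All-pairs sequence comparison over a genotype block.

    ``G`` is ``(S, n, 2)`` with -1 missing.  Haploid sequences are compared
    pairwise, site by site, skipping pairs where either allele is missing.
    Returns sums of (diffs, comps) for pi in each population and for dxy.
    """
    def haplotypes(cols):
        return np.concatenate([G[:, cols, 0], G[:, cols, 1]], axis=1)

    H1 = haplotypes(idx1)  # (S, 2*n1)
    H2 = haplotypes(idx2)

    def within(H):
        diffs = comps = 0
        k = H.shape[1]
        for a in range(k):
            for b in range(a + 1, k):
                ok = (H[:, a] >= 0) & (H[:, b] >= 0) & usable
                comps += int(ok.sum())
                diffs += int(((H[:, a] != H[:, b]) & ok).sum())
        return diffs, comps

    def between(Ha, Hb):
        diffs = comps = 0
        for a in range(Ha.shape[1]):
            for b in range(Hb.shape[1]):
                ok = (Ha[:, a] >= 0) & (Hb[:, b] >= 0) & usable
                comps += int(ok.sum())
                diffs += int(((Ha[:, a] != Hb[:, b]) & ok).sum())
        return diffs, comps

    return within(H1), within(H2), between(H1, H2)


def wc_components_site(pop_genotypes: list[np.ndarray]):
    """Weir & Cockerham (1984) per-site a, b, c for r diploid populations.

    Coded from the published estimator in its general r-population form with
    plain Python loops; populations with fewer than two called genotypes
    make the site uninformative (zeros), matching the estimator contract.
    ``pop_genotypes[i]`` is an ``(n_i, 2)`` array with -1 for missing.
    """
    ns, ps, hs = [], [], []
    for gt in pop_genotypes:
        called = gt[(gt[:, 0] >= 0) & (gt[:, 1] >= 0)]
        if len(called) < 2:
            return 0.0, 0.0, 0.0
        n_i = len(called)
        p_i = (called == 1).sum() / (2 * n_i)
        h_i = (called[:, 0] != called[:, 1]).sum() / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    r = len(ns)
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def brute_window_fst(G: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, usable: np.ndarray):
    """Ratio-of-sums FST from per-site components, or NaN if no denominator."""
    num = den = 0.0
    for s in range(G.shape[0]):
        if not usable[s]:
            continue
        a, b, c = wc_components_site([G[s, idx1], G[s, idx2]])
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def exact_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P[X >= k] for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def pairwise_pdistance_mean(seqs: list[str], gap_chars=frozenset("-Nn.")) -> float:
    """Mean pairwise p-distance via an explicit double loop."""
    m = len(seqs)
    total = 0.0
    pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            valid = diffs = 0
            for a, b in zip(seqs[i].upper(), seqs[j].upper()):
                if a in gap_chars or b in gap_chars:
                    continue
                valid += 1
                if a != b:
                    diffs += 1
            total += diffs / valid
            pairs += 1
    return total / pairs
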