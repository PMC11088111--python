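"""Random genotype missingness injection."""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Iterator

import numpy as np

from ..allsites import MISSING, SiteRecord

__all__ = ["inject_missingness"]


def inject_missingness(
    sites: Iterable[SiteRecord], rate: float, seed: int
) -> Iterator[SiteRecord]:
    """Set each genotype missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    for site in sites:
        if rate == 0.0:
            yield site
            continue
        mask = rng.random(site.n_samples) < rate
        if not mask.any():
            yield site
            continue
        genotypes = site.genotypes.copy()
        genotypes[mask] = MISSING
        yield replace(site, genotypes=genotypes)
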