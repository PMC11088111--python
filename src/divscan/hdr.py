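"""High-diversity-region calling from per-window statistics.

Windows are selected jointly: FST strictly below its lower quantile and π
strictly above its upper quantile in *both* populations, with all thresholds
taken genome-wide over the retained (fully defined) window set.  Selected
windows are then merged into regions, allowing an optional gap of
unselected windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HDRThresholds",
    "HDRegion",
    "quantile_threshold",
    "select_hdr_windows",
    "merge_windows_to_regions",
    "call_hdrs",
    "regions_to_bed",
    "regions_to_dataframe",
]


@dataclass(frozen=True, slots=True)
class HDRThresholds:
    """Realized cutoff values together with the quantile levels used."""

    fst_cut: float
    pi_cuts: dict[str, float]
    q_fst: float
    q_pi: float


@dataclass(slots=True)
class HDRegion:
    """A maximal run of selected windows."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    n_windows: int
    mean_fst: float
    mean_pi: dict[str, float]
    mean_dxy: float
    window_rows: list[int]

    @property
    def length(self) -> int:
        return self.end - self.start


def quantile_threshold(values, q: float) -> float:
    """Empirical quantile with linear interpolation; NaNs are excluded."""
    if not 0 <= q <= 1:
        raise ValueError("quantile level must be in [0, 1]")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values for quantile")
    return float(np.quantile(v, q))


def _pi_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("pi_") and not c.startswith(("pi_diffs", "pi_comps"))]
    if len(cols) != 2:
        raise ValueError(f"expected two pi_<pop> columns, found {cols}")
    return cols


def retained_windows(df: pd.DataFrame) -> pd.DataFrame:
    """Drop windows with a missing value for any statistic."""
    cols = ["fst", "dxy", *_pi_columns(df)]
    return df.dropna(subset=cols)


def select_hdr_windows(
    df: pd.DataFrame, q_fst: float = 0.05, q_pi: float = 0.95
) -> tuple[pd.DataFrame, HDRThresholds]:
    """Flag windows with low FST and high π in both populations.

    ``df`` is the window table from :func:`divscan.windows.windows_to_dataframe`.
    Returns the retained table with a boolean ``selected`` column, plus the
    realized thresholds.  Inequalities are strict on both sides.
    """
    kept = retained_windows(df).copy()
    if kept.empty:
        raise ValueError("no fully defined windows to select from")
    pi_cols = _pi_columns(kept)
    fst_cut = quantile_threshold(kept["fst"], q_fst)
    pi_cuts = {c: quantile_threshold(kept[c], q_pi) for c in pi_cols}
    selected = kept["fst"] < fst_cut
    for c in pi_cols:
        selected &= kept[c] > pi_cuts[c]
    kept["selected"] = selected
    thresholds = HDRThresholds(
        fst_cut=fst_cut,
        pi_cuts={c.removeprefix("pi_"): v for c, v in pi_cuts.items()},
        q_fst=q_fst,
        q_pi=q_pi,
    )
    return kept, thresholds


def merge_windows_to_regions(flagged: pd.DataFrame, max_gap: int = 0) -> list[HDRegion]:
    """Merge runs of selected windows into regions.

    Consecutive selected windows on the same chromosome, with at most
    ``max_gap`` unselected windows between them, form one region.  Gap
    windows are absorbed into the region span but not into its means.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    pi_cols = _pi_columns(flagged)
    regions: list[HDRegion] = []
    run: list[int] = []  # positional indices of selected member windows
    gap = 0

    rows = flagged.reset_index(drop=True)

    def close(run: list[int]) -> None:
        if not run:
            return
        sub = rows.iloc[run[0] : run[-1] + 1]
        members = rows.iloc[run]
        regions.append(
            HDRegion(
                chrom=str(sub.iloc[0]["chrom"]),
                start=int(sub.iloc[0]["start"]) - 1,
                end=int(sub.iloc[-1]["end"]),
                n_windows=len(run),
                mean_fst=float(members["fst"].mean()),
                mean_pi={
                    c.removeprefix("pi_"): float(members[c].mean()) for c in pi_cols
                },
                mean_dxy=float(members["dxy"].mean()),
                window_rows=list(run),
            )
        )

    prev_chrom = None
    for i in range(len(rows)):
        row = rows.iloc[i]
        if row["chrom"] != prev_chrom:
            close(run)
            run, gap = [], 0
            prev_chrom = row["chrom"]
        if bool(row["selected"]):
            run.append(i)
            gap = 0
        elif run:
            gap += 1
            if gap > max_gap:
                close(run)
                run, gap = [], 0
    close(run)
    return regions


def call_hdrs(
    df: pd.DataFrame,
    q_fst: float = 0.05,
    q_pi: float = 0.95,
    max_gap: int = 0,
) -> tuple[pd.DataFrame, HDRThresholds, list[HDRegion]]:
    """Select windows and merge them into regions in one call."""
    flagged, thresholds = select_hdr_windows(df, q_fst=q_fst, q_pi=q_pi)
    regions = merge_windows_to_regions(flagged, max_gap=max_gap)
    return flagged, thresholds, regions


def regions_to_bed(regions: Sequence[HDRegion]) -> str:
    """BED (0-based half-open) text for the called regions."""
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\thdr_{i + 1}\n"
        for i, r in enumerate(regions)
    ]
    return "".join(lines)


def regions_to_dataframe(regions: Sequence[HDRegion]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(regions):
        row = {
            "region": f"hdr_{i + 1}",
            "chrom": r.chrom,
            "start": r.start + 1,
            "end": r.end,
            "n_windows": r.n_windows,
            "mean_fst": r.mean_fst,
            "mean_dxy": r.mean_dxy,
        }
        for pop, v in r.mean_pi.items():
            row[f"mean_pi_{pop}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
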