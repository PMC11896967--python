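"""Sliding-window aggregation, candidate-region calling, and site ranking.

Windows are anchored at position 1 and use half-open arithmetic: window k on a
chromosome covers positions [k*step + 1, k*step + 1 + window). Per-window
scores are plain means of the per-site statistic; empty windows are omitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WindowScore:
    """One genomic window: 1-based half-open [start, end), site count, mean stat."""

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_stat: float


@dataclass(frozen=True)
class CandidateRegion:
    """Maximal run of overlapping/consecutive windows above the score threshold."""

    chrom: str
    start: int
    end: int
    peak: WindowScore
    threshold: float

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class CandidateSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: str
    ed_ideal: float
    rank: int
    selected: bool


def sliding_window_mean(
    site_stats: pd.DataFrame,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    stat: str = "ed",
) -> list[WindowScore]:
    """Mean per-site statistic in sliding windows along each chromosome.

    ``site_stats`` needs columns ``chrom``, ``pos`` and ``stat``. Windows start
    at 1 + k*step for k = 0, 1, ... while they still cover a site position;
    an interior site therefore contributes to ceil(window/step) windows,
    fewer near the chromosome start.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if step_bp <= 0:
        raise ValueError("step_bp must be > 0")
    for col in ("chrom", "pos", stat):
        if col not in site_stats.columns:
            raise ValueError(f"site_stats lacks column {col!r}")

    windows: list[WindowScore] = []
    for chrom, group in site_stats.groupby("chrom", sort=True):
        group = group.sort_values("pos", kind="mergesort")
        pos = group["pos"].to_numpy()
        values = group[stat].to_numpy(dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(values)])
        max_pos = int(pos[-1])
        k = 0
        while True:
            start = k * step_bp + 1
            if start > max_pos:
                break
            end = start + window_bp
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")  # pos < end (half-open)
            n = int(hi - lo)
            if n > 0:
                windows.append(
                    WindowScore(str(chrom), start, end, n, float((cum[hi] - cum[lo]) / n))
                )
            k += 1
    return windows


def call_candidate_regions(
    windows: Sequence[WindowScore],
    quantile: float = 0.99,
    per_chromosome: bool = False,
) -> list[CandidateRegion]:
    """Merge windows scoring at or above the empirical quantile into regions.

    The threshold is the linearly interpolated empirical quantile of window
    mean scores, genome-wide by default (``per_chromosome=True`` recomputes it
    within each chromosome). Overlapping or abutting above-threshold windows
    are merged into maximal regions; each region records its peak window.
    """
    if not (0.0 <= quantile <= 1.0):
        raise ValueError("quantile must lie in [0, 1]")
    windows = [w for w in windows if w.n_sites > 0]
    if not windows:
        raise ValueError("no nonempty windows to threshold")

    by_chrom: dict[str, list[WindowScore]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    genome_threshold = float(np.quantile([w.mean_stat for w in windows], quantile))
    regions: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        chrom_windows = sorted(by_chrom[chrom], key=lambda w: w.start)
        if per_chromosome:
            threshold = float(np.quantile([w.mean_stat for w in chrom_windows], quantile))
        else:
            threshold = genome_threshold
        above = [w for w in chrom_windows if w.mean_stat >= threshold]
        current: list[WindowScore] = []
        for w in above:
            if current and w.start <= current[-1].end:
                current.append(w)
            else:
                if current:
                    regions.append(_make_region(current, threshold))
                current = [w]
        if current:
            regions.append(_make_region(current, threshold))
    return regions


def _make_region(run: list[WindowScore], threshold: float) -> CandidateRegion:
    peak = max(run, key=lambda w: w.mean_stat)
    return CandidateRegion(
        chrom=run[0].chrom,
        start=min(w.start for w in run),
        end=max(w.end for w in run),
        peak=peak,
        threshold=threshold,
    )


def rank_candidate_sites(
    site_stats: pd.DataFrame,
    regions: Sequence[CandidateRegion],
    region_classes: set[str] | None = frozenset({"exonic", "promoter"}),
    top_fraction: float = 0.05,
) -> list[CandidateSite]:
    """Rank in-region sites by ascending ideal-frequency distance.

    Eligible sites lie inside a candidate region and (when ``region_classes``
    is not None) carry one of the given functional-region labels. Ties break
    by position then chromosome. The smallest ``ceil(top_fraction * n)`` sites
    are marked selected; ceiling rounding guarantees a nonempty selection
    whenever any site is eligible and ``top_fraction > 0``.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    required = {"chrom", "pos", "ref", "alt", "region_class", "ed_ideal"}
    missing = required - set(site_stats.columns)
    if missing:
        raise ValueError(f"site_stats lacks columns {sorted(missing)}")

    def in_region(chrom: str, pos: int) -> bool:
        return any(r.contains(chrom, pos) for r in regions)

    eligible = [
        row
        for row in site_stats.itertuples(index=False)
        if in_region(row.chrom, row.pos)
        and (region_classes is None or row.region_class in region_classes)
    ]
    if not eligible:
        warnings.warn("no eligible sites in candidate regions; empty selection", stacklevel=2)
        return []
    eligible.sort(key=lambda r: (r.ed_ideal, r.pos, r.chrom))
    n_selected = math.ceil(top_fraction * len(eligible))
    return [
        CandidateSite(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            region_class=row.region_class,
            ed_ideal=float(row.ed_ideal),
            rank=i + 1,
            selected=i < n_selected,
        )
        for i, row in enumerate(eligible)
    ]


def windows_to_frame(windows: Iterable[WindowScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_sites": w.n_sites,
                "mean_stat": w.mean_stat,
            }
            for w in windows
        ],
        columns=["chrom", "start", "end", "n_sites", "mean_stat"],
    )


def write_windows_bed(windows: Iterable[WindowScore], path: str | Path) -> None:
    """BED export (0-based half-open): internal [start, end) maps to start-1, end-1."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end - 1}\t{w.mean_stat:.6g}\n")


def write_regions_bed(regions: Iterable[CandidateRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end - 1}\t"
                f"peak={r.peak.start}-{r.peak.end};threshold={r.threshold:.6g}\n"
            )


def candidates_to_frame(candidates: Sequence[CandidateSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "region_class": c.region_class,
                "ed_ideal": c.ed_ideal,
                "rank": c.rank,
                "selected": c.selected,
            }
            for c in candidates
        ],
        columns=["chrom", "pos", "ref", "alt", "region_class", "ed_ideal", "rank", "selected"],
    )
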