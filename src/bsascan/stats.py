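"""Per-site association statistics between the two bulks.

Four statistics per biallelic site: the Euclidean distance (ED) between the
pools' allele-frequency vectors, the 2x2 likelihood-ratio G-statistic, the
signed allele-frequency difference, and the distance to the recessive "ideal"
frequency vector (mutant pool fixed for alt, wild-type pool at 1/3 alt).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import PoolCounts, VariantSite

#: Expected alt fraction in the mutant bulk at the causal site of a recessive trait.
IDEAL_F_GT = 1.0
#: Expected alt fraction in the phenotypically wild-type bulk: the genotype mix
#: there is 1/3 hom-ref : 2/3 het, so the mutant allele is at 1/3.
IDEAL_F_WT = 1.0 / 3.0


def allele_frequency(counts: PoolCounts) -> float:
    """Alt-allele read fraction of one pool; requires depth > 0."""
    if counts.depth == 0:
        raise ValueError("allele frequency undefined at zero depth")
    return counts.alt_reads / counts.depth


def euclidean_distance(f_wt: float, f_gt: float) -> float:
    """ED between the two pools' (alt, ref) frequency vectors.

    Over both allele coordinates this reduces to ``sqrt(2) * |f_gt - f_wt|``
    for a biallelic site: 0 at equal frequencies, sqrt(2) at opposite fixation.
    """
    _check_fraction(f_wt)
    _check_fraction(f_gt)
    d = f_gt - f_wt
    return math.sqrt(2.0 * d * d)


def delta_af(f_wt: float, f_gt: float) -> float:
    """Signed allele-frequency difference ``f_gt - f_wt``."""
    _check_fraction(f_wt)
    _check_fraction(f_gt)
    return f_gt - f_wt


def g_statistic(wt: PoolCounts, gt: PoolCounts) -> float:
    """Likelihood-ratio G on the 2x2 (pool x allele) read-count table.

    ``G = 2 * sum(obs * ln(obs / exp))`` with expectations from the table
    margins and the convention ``0 * ln(0) = 0``. Any zero margin (e.g. no alt
    reads in either pool) gives G = 0.
    """
    obs = np.array(
        [[wt.ref_reads, wt.alt_reads], [gt.ref_reads, gt.alt_reads]], dtype=float
    )
    total = obs.sum()
    if total == 0:
        raise ValueError("G-statistic undefined at zero total depth")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    exp = np.outer(row, col) / total
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


def ideal_frequency_distance(f_wt: float, f_gt: float) -> float:
    """Distance from a site's pool alt fractions to the recessive ideal (1, 1/3).

    ``sqrt((f_gt - 1)^2 + (f_wt - 1/3)^2)``; smaller is more candidate-like.
    Computed on read-level alt fractions (see :func:`ideal_frequency_distance_genotype`
    for the 3-genotype-vector form).
    """
    _check_fraction(f_wt)
    _check_fraction(f_gt)
    return math.hypot(f_gt - IDEAL_F_GT, f_wt - IDEAL_F_WT)


def ideal_frequency_distance_genotype(f_wt: float, f_gt: float) -> float:
    """Alternative ideal-frequency distance over Hardy-Weinberg-free genotype vectors.

    Maps each pool's alt fraction f to the F2 genotype-frequency vector implied
    by the recessive model with no hom-alt escape in the WT pool, and measures
    distance to the ideal genotype frequencies: GT pool all hom-alt,
    WT pool (1/3 hom-ref, 2/3 het, 0 hom-alt). Ranks the perfect causal
    pattern identically to the read-fraction form.
    """
    _check_fraction(f_wt)
    _check_fraction(f_gt)
    # GT pool ideal: (0, 0, 1); observed proxy (1-f, 0, f) keeps distance
    # monotone in |1 - f|.  WT pool ideal: (1/3, 2/3, 0); proxy (1-2f, 2f, 0)
    # for f <= 1/2, clamped beyond.
    gt_vec = np.array([1.0 - f_gt, 0.0, f_gt])
    gt_ideal = np.array([0.0, 0.0, 1.0])
    het = min(2.0 * f_wt, 1.0)
    wt_vec = np.array([1.0 - het, het, 0.0])
    wt_ideal = np.array([1.0 / 3.0, 2.0 / 3.0, 0.0])
    return float(
        math.sqrt(np.sum((gt_vec - gt_ideal) ** 2) + np.sum((wt_vec - wt_ideal) ** 2))
    )


def compute_site_stats(sites: Sequence[VariantSite]) -> pd.DataFrame:
    """Per-site statistics table for a list of sites with positive pool depths.

    Sites with a zero-depth pool are excluded (allele frequency undefined);
    they should already have been removed by the depth filter.
    """
    rows = []
    for site in sites:
        if site.wt.depth == 0 or site.gt.depth == 0:
            continue
        f_wt = allele_frequency(site.wt)
        f_gt = allele_frequency(site.gt)
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "region_class": site.region_class,
                "wt_ref": site.wt.ref_reads,
                "wt_alt": site.wt.alt_reads,
                "gt_ref": site.gt.ref_reads,
                "gt_alt": site.gt.alt_reads,
                "f_wt": f_wt,
                "f_gt": f_gt,
                "ed": euclidean_distance(f_wt, f_gt),
                "g_stat": g_statistic(site.wt, site.gt),
                "delta_af": delta_af(f_wt, f_gt),
                "ed_ideal": ideal_frequency_distance(f_wt, f_gt),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "region_class",
            "wt_ref", "wt_alt", "gt_ref", "gt_alt",
            "f_wt", "f_gt", "ed", "g_stat", "delta_af", "ed_ideal",
        ],
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def expected_wt_pool_alt_fraction() -> "Fraction":
    """Mutant-allele frequency among phenotypically dominant F2 individuals, by enumeration.

    Selfing a heterozygote gives dosages {0: 1/4, 1: 1/2, 2: 1/4}; conditioning
    on the dominant phenotype (dosage < 2) leaves 1/3 homozygous wild-type and
    2/3 heterozygous, hence an exact mutant-allele frequency of 1/3 (a 1:2
    mutant:wild-type allele ratio).
    """
    from fractions import Fraction

    cross = {0: Fraction(1, 4), 1: Fraction(1, 2), 2: Fraction(1, 4)}
    dominant = {d: p for d, p in cross.items() if d < 2}
    total = sum(dominant.values())
    return sum(Fraction(d, 2) * p for d, p in dominant.items()) / total


def _check_fraction(f: float) -> None:
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"allele fraction must lie in [0, 1], got {f}")
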