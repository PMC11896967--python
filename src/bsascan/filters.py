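"""Site-exclusion rules applied ahead of the genome scan.

Pool "genotypes" are reconstructed from read allele fractions with configurable
hom-ref/hom-alt cutoffs (default 0.1/0.9) — a transparent proxy for caller
genotype columns, which are not required on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from scipy import stats as sp_stats

from .variants import PoolCounts, VariantSite

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
NOCALL = "nocall"


@dataclass(frozen=True)
class PoolGenotypeCall:
    call: str
    alt_fraction: float


@dataclass(frozen=True)
class GenotypeThresholds:
    hom_ref_max: float = 0.1
    hom_alt_min: float = 0.9
    min_call_depth: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.hom_ref_max < self.hom_alt_min <= 1.0):
            raise ValueError("need 0 <= hom_ref_max < hom_alt_min <= 1")
        if self.min_call_depth < 1:
            raise ValueError("min_call_depth must be >= 1")


def call_pool_genotype(
    counts: PoolCounts,
    hom_ref_max: float = 0.1,
    hom_alt_min: float = 0.9,
    min_call_depth: int = 5,
) -> PoolGenotypeCall:
    """Classify a pool as hom_ref / het / hom_alt from its alt read fraction.

    Depth below ``min_call_depth`` (including zero) yields ``nocall``.
    """
    GenotypeThresholds(hom_ref_max, hom_alt_min, min_call_depth)  # validates
    if counts.depth < min_call_depth:
        f = counts.alt_fraction if counts.depth > 0 else float("nan")
        return PoolGenotypeCall(NOCALL, f)
    f = counts.alt_fraction
    if f <= hom_ref_max:
        return PoolGenotypeCall(HOM_REF, f)
    if f >= hom_alt_min:
        return PoolGenotypeCall(HOM_ALT, f)
    return PoolGenotypeCall(HET, f)


@dataclass
class FilterReport:
    """Per-filter attrition log; one row per applied filter."""

    rows: list[dict] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_removed: int, flagged: int = 0) -> None:
        self.rows.append(
            {
                "filter": name,
                "n_in": n_in,
                "n_removed": n_removed,
                "n_retained": n_in - n_removed,
                "n_flagged": flagged,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("filter\tn_in\tn_removed\tn_retained\tn_flagged\n")
            for row in self.rows:
                fh.write(
                    f"{row['filter']}\t{row['n_in']}\t{row['n_removed']}"
                    f"\t{row['n_retained']}\t{row['n_flagged']}\n"
                )


def filter_depth(
    sites: Sequence[VariantSite],
    dp_min: int = 25,
    dp_max: int = 250,
    mode: str = "combined",
    report: FilterReport | None = None,
) -> list[VariantSite]:
    """Keep sites with depth within [dp_min, dp_max].

    ``mode="combined"`` (default) applies the bounds to the summed depth of the
    two pools; ``mode="per_pool"`` requires each pool's depth to satisfy them.
    """
    if mode not in ("combined", "per_pool"):
        raise ValueError("mode must be 'combined' or 'per_pool'")

    def ok(site: VariantSite) -> bool:
        if mode == "combined":
            return dp_min <= site.total_depth <= dp_max
        return (dp_min <= site.wt.depth <= dp_max) and (dp_min <= site.gt.depth <= dp_max)

    kept = [s for s in sites if ok(s)]
    if report is not None:
        report.record(f"depth_{mode}_{dp_min}_{dp_max}", len(sites), len(sites) - len(kept))
    return kept


def _paired_calls(site: VariantSite, thresholds: GenotypeThresholds):
    kw = dict(
        hom_ref_max=thresholds.hom_ref_max,
        hom_alt_min=thresholds.hom_alt_min,
        min_call_depth=thresholds.min_call_depth,
    )
    return call_pool_genotype(site.wt, **kw), call_pool_genotype(site.gt, **kw)


def filter_shared_hom_alt(
    sites: Sequence[VariantSite],
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    report: FilterReport | None = None,
) -> list[VariantSite]:
    """Drop sites homozygous-alt in both pools (line-vs-reference differences).

    Sites where both pools are nocall are never removed on missing evidence;
    they are retained and counted as flagged.
    """
    kept: list[VariantSite] = []
    flagged = 0
    for site in sites:
        wt_call, gt_call = _paired_calls(site, thresholds)
        if wt_call.call == NOCALL and gt_call.call == NOCALL:
            flagged += 1
            kept.append(site)
        elif not (wt_call.call == HOM_ALT and gt_call.call == HOM_ALT):
            kept.append(site)
    if report is not None:
        report.record("shared_hom_alt", len(sites), len(sites) - len(kept), flagged)
    return kept


def filter_shared_het(
    sites: Sequence[VariantSite],
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    report: FilterReport | None = None,
) -> list[VariantSite]:
    """Drop sites heterozygous in both pools (incompatible with a recessive causal site)."""
    kept: list[VariantSite] = []
    flagged = 0
    for site in sites:
        wt_call, gt_call = _paired_calls(site, thresholds)
        if wt_call.call == NOCALL and gt_call.call == NOCALL:
            flagged += 1
            kept.append(site)
        elif not (wt_call.call == HET and gt_call.call == HET):
            kept.append(site)
    if report is not None:
        report.record("shared_het", len(sites), len(sites) - len(kept), flagged)
    return kept


@dataclass(frozen=True)
class DepletionResult:
    pvalue: float
    observed_fraction: float
    expected_fraction: float
    depleted: bool


def exonic_depletion_test(
    n_exonic_variants: int,
    n_total_variants: int,
    exonic_fraction_genome: float,
) -> DepletionResult:
    """Exact two-sided binomial test of the observed exonic variant proportion
    against the genomic expectation; flags the direction of deviation."""
    if n_exonic_variants < 0 or n_total_variants <= 0:
        raise ValueError("need n_total_variants > 0 and n_exonic_variants >= 0")
    if n_exonic_variants > n_total_variants:
        raise ValueError("n_exonic_variants exceeds n_total_variants")
    if not (0.0 < exonic_fraction_genome < 1.0):
        raise ValueError("exonic_fraction_genome must lie in (0, 1)")
    test = sp_stats.binomtest(
        n_exonic_variants, n_total_variants, exonic_fraction_genome, alternative="two-sided"
    )
    observed = n_exonic_variants / n_total_variants
    return DepletionResult(
        pvalue=float(test.pvalue),
        observed_fraction=observed,
        expected_fraction=exonic_fraction_genome,
        depleted=observed < exonic_fraction_genome,
    )
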