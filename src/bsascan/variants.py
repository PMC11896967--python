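"""Pooled-variant input: VCF reading, gene models, and functional-region classification.

Coordinates are 1-based inclusive throughout this module (VCF/GFF3 convention);
half-open arithmetic appears only in the window-scan code, where it is documented.
Indels follow the VCF anchoring convention: POS is the first (shared) reference
base, so an insertion has ``len(alt) > len(ref)`` with identical leading base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

REGION_CLASSES = ("exonic", "promoter", "intronic", "intergenic", "unannotated")

WT_SAMPLE = "WT_pool"
GT_SAMPLE = "GT_pool"


@dataclass(frozen=True)
class PoolCounts:
    """Ref/alt read depths for one bulk at one site."""

    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def alt_fraction(self) -> float:
        """Alt-allele read fraction; NaN at zero depth (excluded upstream)."""
        if self.depth == 0:
            return float("nan")
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site with per-pool read counts — the atom of every scan."""

    chrom: str
    pos: int
    ref: str
    alt: str
    wt: PoolCounts
    gt: PoolCounts
    region_class: str = "unannotated"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError("VariantSite is biallelic; split multi-allelic records first")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")

    @property
    def total_depth(self) -> int:
        return self.wt.depth + self.gt.depth

    @property
    def indel_length(self) -> int:
        """Signed length change (insertions positive, deletions negative)."""
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene model: strand plus sorted, non-overlapping CDS intervals.

    ``cds_intervals`` are 1-based inclusive and stored in genomic (ascending)
    order regardless of strand; 5'->3' traversal on the minus strand reverses
    them.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id}: no CDS intervals")
        ivals = tuple(sorted(tuple(map(int, iv)) for iv in self.cds_intervals))
        for start, end in ivals:
            if start < 1 or end < start:
                raise ValueError(f"gene {self.gene_id}: bad CDS interval ({start}, {end})")
        for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        object.__setattr__(self, "cds_intervals", ivals)

    @property
    def start_codon_pos(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        if self.strand == "+":
            return self.cds_intervals[0][0]
        return self.cds_intervals[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def promoter_interval(self, promoter_len: int = 2000) -> tuple[int, int]:
        """Strand-aware window immediately 5' of the start codon (1-based inclusive).

        On the minus strand the promoter extends to *higher* coordinates.
        """
        if self.strand == "+":
            start = max(1, self.start_codon_pos - promoter_len)
            return start, self.start_codon_pos - 1
        return self.start_codon_pos + 1, self.start_codon_pos + promoter_len

    def contains_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_intervals)


@dataclass
class VcfReadResult:
    """Sites parsed from a two-pool VCF plus per-policy drop counters."""

    sites: list[VariantSite]
    n_multiallelic_dropped: int = 0
    n_multiallelic_split: int = 0
    n_missing_ad: int = 0


def read_vcf(
    path: str | Path,
    wt_sample: str = WT_SAMPLE,
    gt_sample: str = GT_SAMPLE,
    multiallelic: str = "drop",
) -> VcfReadResult:
    """Read a two-pool VCF into :class:`VariantSite` records.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped).
    wt_sample, gt_sample:
        Sample-column names of the two bulks.
    multiallelic:
        ``"drop"`` (default) removes multi-allelic records, counting them;
        ``"split"`` emits one biallelic site per alt allele.

    Raises
    ------
    ValueError
        If a pool sample column is absent or an AD field is malformed.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise ValueError(f"multiallelic policy must be 'drop' or 'split', got {multiallelic!r}")
    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        for name in (wt_sample, gt_sample):
            if name not in samples:
                raise ValueError(f"sample column {name!r} absent from {path} (has {samples})")
        i_wt = samples.index(wt_sample)
        i_gt = samples.index(gt_sample)

        result = VcfReadResult(sites=[])
        for record in vcf:
            alts = record.ALT
            if not alts:
                result.n_missing_ad += 1
                continue
            ad = record.format("AD")
            if ad is None:
                result.n_missing_ad += 1
                continue
            if ad.shape != (len(samples), len(alts) + 1):
                # cyvcf2 collapses an all-missing AD ('.') to a single column
                if (ad < 0).all():
                    result.n_missing_ad += 1
                    continue
                raise ValueError(
                    f"malformed AD at {record.CHROM}:{record.POS} (shape {ad.shape})"
                )
            if (ad[i_wt] < 0).any() or (ad[i_gt] < 0).any():
                result.n_missing_ad += 1
                continue
            if len(alts) > 1:
                if multiallelic == "drop":
                    result.n_multiallelic_dropped += 1
                    continue
                result.n_multiallelic_split += 1
                alt_indices = range(1, len(alts) + 1)
            else:
                alt_indices = (1,)
            for j in alt_indices:
                result.sites.append(
                    VariantSite(
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alts[j - 1],
                        wt=PoolCounts(int(ad[i_wt][0]), int(ad[i_wt][j])),
                        gt=PoolCounts(int(ad[i_gt][0]), int(ad[i_gt][j])),
                    )
                )
        return result
    finally:
        vcf.close()


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (CDS structure) from a GFF3 file.

    One model per gene; when a gene carries several mRNAs the transcript with
    the longest total CDS is used (ties broken by transcript id).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str, list[tuple[int, int]]] | None = None
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            for mrna in mrnas:
                cds = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
                if not cds:
                    continue
                key = (sum(e - s + 1 for s, e in cds), mrna.id)
                if best is None or (key[0], key[1]) > (best[0], best[1]):
                    best = (key[0], key[1], cds)
        else:
            # CDS parented directly to the gene
            cds = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
            if cds:
                best = (sum(e - s + 1 for s, e in cds), gene.id, cds)
        if best is None:
            continue
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple(sorted(best[2])),
            )
        )
    return models


def classify_regions(
    sites: Sequence[VariantSite],
    models: Iterable[GeneModel],
    promoter_len: int = 2000,
) -> list[VariantSite]:
    """Assign each site a functional-region class from gene models.

    Precedence across all models: exonic > promoter > intronic > intergenic.
    ``intronic`` means within a gene's CDS span but in no CDS interval;
    sites on chromosomes without any model are ``unannotated``. Models on
    chromosomes not present among the sites are skipped with a warning.
    The result is invariant under reordering of ``models``.
    """
    site_chroms = {s.chrom for s in sites}
    by_chrom: dict[str, list[GeneModel]] = {}
    for model in models:
        if model.chrom not in site_chroms:
            warnings.warn(
                f"gene model {model.gene_id} on unknown chromosome {model.chrom!r}; skipped",
                stacklevel=2,
            )
            continue
        by_chrom.setdefault(model.chrom, []).append(model)

    rank = {"exonic": 0, "promoter": 1, "intronic": 2, "intergenic": 3}
    out: list[VariantSite] = []
    for site in sites:
        chrom_models = by_chrom.get(site.chrom)
        if not chrom_models:
            out.append(replace(site, region_class="unannotated"))
            continue
        best = "intergenic"
        for model in chrom_models:
            if model.contains_cds(site.pos):
                label = "exonic"
            else:
                p_start, p_end = model.promoter_interval(promoter_len)
                span_start, span_end = model.span
                if p_start <= site.pos <= p_end:
                    label = "promoter"
                elif span_start <= site.pos <= span_end:
                    label = "intronic"
                else:
                    continue
            if rank[label] < rank[best]:
                best = label
            if best == "exonic":
                break
        out.append(replace(site, region_class=best))
    return out
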