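import numpy as np
import pytest

from bsascan.simulate import GeneticMapSpec, SimulationConfig, simulate_dataset
from bsascan.variants import GeneModel, PoolCounts, VariantSite


@pytest.fixture
def toy_map():
    return GeneticMapSpec(("chr1",), (10_000_000,))


@pytest.fixture
def small_dataset():
    """A small, error-free simulated dataset with the causal site at 5 Mb."""
    gmap = GeneticMapSpec(("chr1",), (10_000_000,))
    cfg = SimulationConfig(
        n_f2=240, bulk_size=30, n_sites=200, causal_chrom="chr1",
        causal_pos_bp=5_000_000, mean_depth=60.0, seq_error=0.0,
        depth_law="fixed", seed=11,
    )
    return simulate_dataset(cfg, gmap), cfg, gmap


@pytest.fixture
def plus_gene():
    # CDS 1001..1015 encodes ATGGATTTAAAGTGA on the + strand
    return GeneModel("geneA", "chr1", "+", ((1001, 1015),))


def make_site(chrom="chr1", pos=100, ref="A", alt="T",
              wt=(15, 15), gt=(15, 15), region_class="unannotated"):
    return VariantSite(chrom, pos, ref, alt,
                       PoolCounts(*wt), PoolCounts(*gt), region_class)


def write_vcf_text(path, records, samples=("WT_pool", "GT_pool")):
    """Hand-rolled VCF writer for fixtures, independent of the package's emitter.

    ``records`` are (chrom, pos, ref, alt, wt_ad, gt_ad) with AD strings like
    "21,10" (or "." for missing).
    """
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(r[0] for r in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, wt_ad, gt_ad in records:
        fmt_vals = [f"./.:{ad}" if ad != "." else "./.:." for ad in (wt_ad, gt_ad)]
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t" + "\t".join(fmt_vals)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def null_sites_rng():
    return np.random.default_rng(424242)
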