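"""Synthetic F2 bulked-segregant pooled-sequencing data.

Generates datasets with the statistical structure the downstream scan assumes:
two fully inbred parents opposite-homozygous at every placed site, F2 progeny
from a selfed F1 (gametes drawn by a Markov walk with Haldane recombination
fractions, no interference), a single fully recessive causal locus, two
phenotype bulks, and binomial read sampling per pool, emitted as VCF 4.2.

All randomness flows from one integer seed through a fixed stream order:
sites -> genotypes -> bulks -> depths -> reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .variants import GT_SAMPLE, WT_SAMPLE, PoolCounts

PHENOTYPE_WT = "WT"  # dominant class (waxy)
PHENOTYPE_GT = "GT"  # recessive class (glossy)

_N_STREAMS = 5
_STREAM_SITES, _STREAM_GENOTYPES, _STREAM_BULKS, _STREAM_DEPTHS, _STREAM_READS = range(
    _N_STREAMS
)


def _streams(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(_N_STREAMS)
    return [np.random.default_rng(c) for c in children]


@dataclass(frozen=True)
class GeneticMapSpec:
    """Chromosome sizes and recombination landscape for the simulator.

    ``recomb_rate`` is cM per Mb (a scalar applied to every chromosome, or one
    value per chromosome). ``suppressed_intervals`` are
    ``(chrom, start_bp, end_bp, rate_multiplier)`` blocks that scale the local
    rate, emulating low-recombination (e.g. pericentromeric) regions that
    produce large linked blocks.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths_bp: tuple[int, ...]
    recomb_rate: float | tuple[float, ...] = 1.0
    suppressed_intervals: tuple[tuple[str, int, int, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths_bp", tuple(int(x) for x in self.chrom_lengths_bp))
        object.__setattr__(self, "suppressed_intervals", tuple(self.suppressed_intervals))
        if len(self.chrom_names) != len(self.chrom_lengths_bp):
            raise ValueError("chrom_names and chrom_lengths_bp differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths_bp):
            raise ValueError("chromosome lengths must be > 0")
        rates = self.rates_per_chrom()
        if any(r < 0 for r in rates):
            raise ValueError("recombination rates must be >= 0")
        lengths = dict(zip(self.chrom_names, self.chrom_lengths_bp))
        for chrom, start, end, mult in self.suppressed_intervals:
            if chrom not in lengths:
                raise ValueError(f"suppressed interval on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(f"suppressed interval ({start}, {end}) outside {chrom}")
            if mult < 0:
                raise ValueError("rate multiplier must be >= 0")

    def rates_per_chrom(self) -> tuple[float, ...]:
        if isinstance(self.recomb_rate, (int, float)):
            return tuple(float(self.recomb_rate) for _ in self.chrom_names)
        rates = tuple(float(r) for r in self.recomb_rate)
        if len(rates) != len(self.chrom_names):
            raise ValueError("per-chromosome recomb_rate length mismatch")
        return rates

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths_bp[self.chrom_names.index(chrom)]

    def map_distance_cM(self, chrom: str, a_bp: int, b_bp: int) -> float:
        """Genetic distance between two positions, honouring suppressed blocks."""
        lo, hi = sorted((a_bp, b_bp))
        rate = self.rates_per_chrom()[self.chrom_names.index(chrom)]
        d = rate * (hi - lo) / 1e6
        for ichrom, istart, iend, mult in self.suppressed_intervals:
            if ichrom != chrom:
                continue
            overlap = min(hi, iend) - max(lo, istart)
            if overlap > 0:
                d += rate * overlap / 1e6 * (mult - 1.0)
        return d


@dataclass(frozen=True)
class SimulationConfig:
    n_f2: int
    causal_chrom: str
    causal_pos_bp: int
    bulk_size: int = 30
    n_sites: int = 1000
    mean_depth: float = 30.0
    seq_error: float = 0.001
    depth_law: str = "poisson"
    seed: int = 0

    def validate(self, gmap: GeneticMapSpec) -> None:
        if self.n_f2 < 1 or self.n_sites < 1 or self.bulk_size < 1:
            raise ValueError("n_f2, n_sites and bulk_size must be >= 1")
        if 2 * self.bulk_size > self.n_f2:
            raise ValueError("need 2 * bulk_size <= n_f2")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.depth_law not in ("poisson", "fixed"):
            raise ValueError("depth_law must be 'poisson' or 'fixed'")
        if self.causal_chrom not in gmap.chrom_names:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} not in map")
        if not (1 <= self.causal_pos_bp <= gmap.length_of(self.causal_chrom)):
            raise ValueError("causal position outside its chromosome")


@dataclass(frozen=True)
class Site:
    """A simulated variant site: coordinates plus parent-distinguishing alleles."""

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "T"


@dataclass
class F2Individual:
    """Simulated diploid: per-site mutant-parent allele dosage plus phenotype."""

    genotypes: np.ndarray  # dosage in {0, 1, 2} per site
    phenotype: str  # "WT" | "GT"


@dataclass
class TruthRecord:
    """Ground truth written next to the emitted VCF."""

    causal_chrom: str
    causal_pos: int
    sites: list[Site]
    true_wt_freq: np.ndarray
    true_gt_freq: np.ndarray
    phenotypes: list[str]

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#causal\t{self.causal_chrom}\t{self.causal_pos}\n")
            fh.write("chrom\tpos\tref\talt\ttrue_wt_alt_freq\ttrue_gt_alt_freq\n")
            for site, fw, fg in zip(self.sites, self.true_wt_freq, self.true_gt_freq):
                fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{fw:.6g}\t{fg:.6g}\n")
        pheno_path = path.with_suffix(path.suffix + ".phenotypes")
        with open(pheno_path, "w") as fh:
            fh.write("individual\tphenotype\n")
            for i, p in enumerate(self.phenotypes):
                fh.write(f"F2_{i:06d}\t{p}\n")


def haldane_r(d_cM: float) -> float:
    """Haldane map function: recombination fraction from distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


_BASES = np.array(list("ACGT"))


def place_sites(
    gmap: GeneticMapSpec,
    n_sites: int,
    seed: int | np.random.Generator,
    causal: tuple[str, int] | None = None,
) -> list[Site]:
    """Place ``n_sites`` unique variant sites uniformly over the genome.

    Chromosomes are weighted by length; the causal site (if given) is always
    included in the returned, (chrom, pos)-sorted list. The causal site gets an
    anchored 2-bp "AA" insertion allele; all other sites are SNVs.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    total = sum(gmap.chrom_lengths_bp)
    if n_sites > total:
        raise ValueError(f"n_sites={n_sites} exceeds available positions ({total})")
    rng = seed if isinstance(seed, np.random.Generator) else _streams(seed)[_STREAM_SITES]

    chosen: set[tuple[str, int]] = set()
    if causal is not None:
        chrom, pos = causal
        if chrom not in gmap.chrom_names:
            raise ValueError(f"causal chromosome {chrom!r} not in map")
        if not (1 <= pos <= gmap.length_of(chrom)):
            raise ValueError("causal position outside its chromosome")
        chosen.add((chrom, int(pos)))

    lengths = np.asarray(gmap.chrom_lengths_bp, dtype=float)
    weights = lengths / lengths.sum()
    while len(chosen) < n_sites:
        k = n_sites - len(chosen)
        idx = rng.choice(len(gmap.chrom_names), size=k, p=weights)
        pos = rng.integers(1, np.asarray(gmap.chrom_lengths_bp)[idx] + 1)
        for i, p in zip(idx, pos):
            if len(chosen) >= n_sites:
                break
            chosen.add((gmap.chrom_names[i], int(p)))

    coords = sorted(chosen)
    sites: list[Site] = []
    for chrom, pos in coords:
        if causal is not None and (chrom, pos) == (causal[0], int(causal[1])):
            base = str(rng.choice(_BASES))
            sites.append(Site(chrom, pos, ref=base, alt=base + "AA"))
        else:
            ref, alt = rng.choice(4, size=2, replace=False)
            sites.append(Site(chrom, pos, ref=str(_BASES[ref]), alt=str(_BASES[alt])))
    return sites


def _gamete_alleles(
    gmap: GeneticMapSpec,
    sites: Sequence[Site],
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw gametes from a heterozygous F1: (n_gametes, n_sites) in {0, 1}.

    A Markov walk per chromosome: the first allele is fair, then switches occur
    between adjacent sites with the Haldane recombination fraction.
    """
    m = len(sites)
    alleles = np.empty((n_gametes, m), dtype=np.int8)
    start = 0
    for chrom in gmap.chrom_names:
        idx = [i for i, s in enumerate(sites) if s.chrom == chrom]
        if not idx:
            continue
        positions = [sites[i].pos for i in idx]
        r = np.array(
            [
                haldane_r(gmap.map_distance_cM(chrom, a, b))
                for a, b in zip(positions, positions[1:])
            ]
        )
        block = np.empty((n_gametes, len(idx)), dtype=np.int8)
        block[:, 0] = rng.integers(0, 2, size=n_gametes)
        if len(idx) > 1:
            switches = rng.random((n_gametes, len(idx) - 1)) < r
            block[:, 1:] = np.cumsum(switches, axis=1) & 1
            block[:, 1:] ^= block[:, [0]]
        alleles[:, idx] = block
    return alleles


def simulate_f2(
    gmap: GeneticMapSpec,
    sites: Sequence[Site],
    causal: tuple[str, int],
    n_f2: int,
    seed: int | np.random.Generator,
) -> list[F2Individual]:
    """Simulate F2 individuals from a selfed F1 heterozygous at every site.

    Each individual is the sum of two independent gametes; an individual is
    phenotype GT iff its dosage of the mutant-parent allele at the causal site
    is 2 (fully recessive trait).
    """
    rng = seed if isinstance(seed, np.random.Generator) else _streams(seed)[_STREAM_GENOTYPES]
    causal_idx = _causal_index(sites, causal)
    gametes = _gamete_alleles(gmap, sites, 2 * n_f2, rng)
    dosage = gametes[0::2] + gametes[1::2]
    individuals = []
    for i in range(n_f2):
        pheno = PHENOTYPE_GT if dosage[i, causal_idx] == 2 else PHENOTYPE_WT
        individuals.append(F2Individual(genotypes=dosage[i], phenotype=pheno))
    return individuals


def _causal_index(sites: Sequence[Site], causal: tuple[str, int]) -> int:
    for i, s in enumerate(sites):
        if (s.chrom, s.pos) == (causal[0], int(causal[1])):
            return i
    raise ValueError(f"causal site {causal} not among placed sites")


def form_bulks(
    individuals: Sequence[F2Individual],
    bulk_size: int,
    seed: int | np.random.Generator,
) -> tuple[list[F2Individual], list[F2Individual]]:
    """Sample ``bulk_size`` individuals per phenotype class, without replacement."""
    rng = seed if isinstance(seed, np.random.Generator) else _streams(seed)[_STREAM_BULKS]
    wt = [ind for ind in individuals if ind.phenotype == PHENOTYPE_WT]
    gt = [ind for ind in individuals if ind.phenotype == PHENOTYPE_GT]
    for name, group in ((PHENOTYPE_WT, wt), (PHENOTYPE_GT, gt)):
        if len(group) < bulk_size:
            raise ValueError(
                f"insufficient {name} individuals: need {bulk_size}, have {len(group)}"
            )
    wt_bulk = [wt[i] for i in rng.choice(len(wt), size=bulk_size, replace=False)]
    gt_bulk = [gt[i] for i in rng.choice(len(gt), size=bulk_size, replace=False)]
    return wt_bulk, gt_bulk


def true_pool_freq(bulk: Sequence[F2Individual]) -> np.ndarray:
    """True alt (mutant-parent) allele frequency per site in a bulk."""
    dosages = np.stack([ind.genotypes for ind in bulk])
    return dosages.sum(axis=0) / (2.0 * len(bulk))


def simulate_pool_reads(
    bulk: Sequence[F2Individual],
    mean_depth: float = 30.0,
    seq_error: float = 0.001,
    depth_law: str = "poisson",
    seed: int | np.random.Generator | None = None,
    depth_rng: np.random.Generator | None = None,
    read_rng: np.random.Generator | None = None,
) -> list[PoolCounts]:
    """Binomial read sampling from a pooled bulk.

    At each site the true pool alt frequency is ``p = sum(dosages) / (2 * bulk
    size)``; depth is Poisson(``mean_depth``) or fixed; alt reads are
    Binomial(depth, ``p (1 - e) + (1 - p) e``) with symmetric per-read error
    ``e``; ref reads make up the remainder.
    """
    if not bulk:
        raise ValueError("bulk must be nonempty")
    if depth_rng is None or read_rng is None:
        if isinstance(seed, np.random.Generator):
            depth_rng = read_rng = seed
        else:
            streams = _streams(0 if seed is None else seed)
            depth_rng = streams[_STREAM_DEPTHS]
            read_rng = streams[_STREAM_READS]
    p = true_pool_freq(bulk)
    p_eff = p * (1.0 - seq_error) + (1.0 - p) * seq_error
    m = p.shape[0]
    if depth_law == "poisson":
        depth = depth_rng.poisson(mean_depth, size=m)
    elif depth_law == "fixed":
        depth = np.full(m, int(round(mean_depth)))
    else:
        raise ValueError("depth_law must be 'poisson' or 'fixed'")
    alt = read_rng.binomial(depth, p_eff)
    return [PoolCounts(int(d - a), int(a)) for d, a in zip(depth, alt)]


def _genotype_string(counts: PoolCounts, hom_ref_max: float = 0.1, hom_alt_min: float = 0.9,
                     min_call_depth: int = 5) -> str:
    if counts.depth < min_call_depth:
        return "./."
    f = counts.alt_fraction
    if f <= hom_ref_max:
        return "0/0"
    if f >= hom_alt_min:
        return "1/1"
    return "0/1"


def emit_vcf(
    sites: Sequence[Site],
    wt_counts: Sequence[PoolCounts],
    gt_counts: Sequence[PoolCounts],
    path: str | Path,
    gmap: GeneticMapSpec | None = None,
    truth: TruthRecord | None = None,
) -> Path:
    """Write sites and pool counts as a two-sample VCF 4.2 (GT:AD:DP).

    Output is byte-deterministic for a given input. If ``truth`` is given it is
    serialized as TSV next to the VCF.
    """
    if not (len(sites) == len(wt_counts) == len(gt_counts)):
        raise ValueError("sites and count vectors must be aligned")
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    if gmap is not None:
        for name, length in zip(gmap.chrom_names, gmap.chrom_lengths_bp):
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(s.chrom for s in sites):
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{WT_SAMPLE}\t{GT_SAMPLE}",
    ]
    for site, wc, gc in zip(sites, wt_counts, gt_counts):
        fields = [
            site.chrom,
            str(site.pos),
            ".",
            site.ref,
            site.alt,
            ".",
            "PASS",
            ".",
            "GT:AD:DP",
            f"{_genotype_string(wc)}:{wc.ref_reads},{wc.alt_reads}:{wc.depth}",
            f"{_genotype_string(gc)}:{gc.ref_reads},{gc.alt_reads}:{gc.depth}",
        ]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    if truth is not None:
        truth.write_tsv(path.with_suffix(".truth.tsv"))
    return path


def recovery_scenario(
    seed: int,
    n_f2: int = 200,
    bulk_size: int = 30,
    n_sites: int = 2000,
    chrom_length_bp: int = 20_000_000,
    mean_depth: float = 30.0,
    seq_error: float = 0.001,
    recomb_rate: float = 50.0,
    linked_block_halfwidth_bp: int = 450_000,
    block_rate_multiplier: float = 0.02,
) -> tuple[GeneticMapSpec, SimulationConfig]:
    """Standard parameter-recovery setup: one chromosome, causal locus at its midpoint.

    The single 20 Mb chromosome stands in genetically for a whole genome
    (50 cM/Mb, i.e. ~1000 cM total, so distant sites are effectively
    unlinked), with a recombination-suppressed block around the causal locus
    emulating a low-recombination linked region. With bulks of 30 the
    window-scan peak is then reliably pinned to the causal window.
    """
    causal = chrom_length_bp // 2
    gmap = GeneticMapSpec(
        chrom_names=("chr1",),
        chrom_lengths_bp=(chrom_length_bp,),
        recomb_rate=recomb_rate,
        suppressed_intervals=(
            (
                "chr1",
                causal - linked_block_halfwidth_bp,
                causal + linked_block_halfwidth_bp,
                block_rate_multiplier,
            ),
        ),
    )
    config = SimulationConfig(
        n_f2=n_f2,
        bulk_size=bulk_size,
        n_sites=n_sites,
        causal_chrom="chr1",
        causal_pos_bp=causal,
        mean_depth=mean_depth,
        seq_error=seq_error,
        depth_law="poisson",
        seed=seed,
    )
    return gmap, config


@dataclass
class SimulatedDataset:
    sites: list[Site]
    individuals: list[F2Individual]
    wt_bulk: list[F2Individual]
    gt_bulk: list[F2Individual]
    wt_counts: list[PoolCounts]
    gt_counts: list[PoolCounts]
    truth: TruthRecord


def simulate_dataset(config: SimulationConfig, gmap: GeneticMapSpec) -> SimulatedDataset:
    """Run the full generator: sites -> F2 genotypes -> bulks -> pooled reads."""
    config.validate(gmap)
    streams = _streams(config.seed)
    causal = (config.causal_chrom, config.causal_pos_bp)
    sites = place_sites(gmap, config.n_sites, streams[_STREAM_SITES], causal=causal)
    individuals = simulate_f2(gmap, sites, causal, config.n_f2, streams[_STREAM_GENOTYPES])
    wt_bulk, gt_bulk = form_bulks(individuals, config.bulk_size, streams[_STREAM_BULKS])
    kwargs = dict(
        mean_depth=config.mean_depth,
        seq_error=config.seq_error,
        depth_law=config.depth_law,
        depth_rng=streams[_STREAM_DEPTHS],
        read_rng=streams[_STREAM_READS],
    )
    wt_counts = simulate_pool_reads(wt_bulk, **kwargs)
    gt_counts = simulate_pool_reads(gt_bulk, **kwargs)
    truth = TruthRecord(
        causal_chrom=config.causal_chrom,
        causal_pos=config.causal_pos_bp,
        sites=sites,
        true_wt_freq=true_pool_freq(wt_bulk),
        true_gt_freq=true_pool_freq(gt_bulk),
        phenotypes=[ind.phenotype for ind in individuals],
    )
    return SimulatedDataset(sites, individuals, wt_bulk, gt_bulk, wt_counts, gt_counts, truth)


def write_dataset(
    dataset: SimulatedDataset,
    config: SimulationConfig,
    gmap: GeneticMapSpec,
    out_dir: str | Path,
    stem: str = "bulks",
) -> dict[str, Path]:
    """Serialize a simulated dataset: VCF, truth TSV, and a YAML config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{stem}.vcf"
    emit_vcf(dataset.sites, dataset.wt_counts, dataset.gt_counts, vcf_path,
             gmap=gmap, truth=dataset.truth)
    config_path = out_dir / f"{stem}.config.yaml"
    payload = {
        "simulate": {
            "n_f2": config.n_f2, "bulk_size": config.bulk_size,
            "n_sites": config.n_sites, "causal_chrom": config.causal_chrom,
            "causal_pos_bp": config.causal_pos_bp, "mean_depth": config.mean_depth,
            "seq_error": config.seq_error, "depth_law": config.depth_law,
            "seed": config.seed,
        },
        "genetic_map": {
            "chrom_names": list(gmap.chrom_names),
            "chrom_lengths_bp": list(gmap.chrom_lengths_bp),
            "recomb_rate": gmap.recomb_rate if isinstance(gmap.recomb_rate, (int, float))
            else list(gmap.recomb_rate),
            "suppressed_intervals": [list(iv) for iv in gmap.suppressed_intervals],
        },
    }
    config_path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return {
        "vcf": vcf_path,
        "truth": vcf_path.with_suffix(".truth.tsv"),
        "config": config_path,
    }
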