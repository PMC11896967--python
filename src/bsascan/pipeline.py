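"""End-to-end orchestration: simulate/load -> filter -> scan -> rank -> annotate.

Stage order: depth filter and shared-hom-alt filter, per-site statistics,
sliding-window scan, candidate region calling; then — for candidate ranking
only — the shared-het filter and functional-region restriction, followed by
ideal-frequency ranking and (when annotation inputs are available)
coding-consequence annotation.

The shared-het filter must run *after* the window scan: applying it first
removes nearly every unlinked site (both pools near 0.5) except the extreme
read-noise tail, which inflates distant windows' mean ED and destroys the
scan's contrast.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import consequence as csq
from . import filters, scan, simulate, stats, variants


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All tunables of the pipeline with the analysis defaults.

    Either ``vcf`` points at a two-pool variant file or ``simulate``/
    ``genetic_map`` describe a synthetic dataset to generate first.
    """

    out_dir: str = "bsascan_out"
    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    simulate: simulate.SimulationConfig | None = None
    genetic_map: simulate.GeneticMapSpec | None = None

    dp_min: int = 25
    dp_max: int = 250
    dp_mode: str = "combined"
    hom_ref_max: float = 0.1
    hom_alt_min: float = 0.9
    min_call_depth: int = 5
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    scan_stat: str = "ed"
    region_quantile: float = 0.99
    per_chromosome_quantile: bool = False
    top_fraction: float = 0.05
    promoter_len: int = 2000
    region_classes: list[str] | None = field(default_factory=lambda: ["exonic", "promoter"])
    multiallelic: str = "drop"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.genetic_map is not None:
            gm = d["genetic_map"]
            gm["chrom_names"] = list(gm["chrom_names"])
            gm["chrom_lengths_bp"] = list(gm["chrom_lengths_bp"])
            gm["suppressed_intervals"] = [list(iv) for iv in gm["suppressed_intervals"]]
            if not isinstance(gm["recomb_rate"], (int, float)):
                gm["recomb_rate"] = list(gm["recomb_rate"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = simulate.SimulationConfig(**d["simulate"])
        if d.get("genetic_map") is not None:
            gm = dict(d["genetic_map"])
            gm["chrom_names"] = tuple(gm["chrom_names"])
            gm["chrom_lengths_bp"] = tuple(gm["chrom_lengths_bp"])
            gm["suppressed_intervals"] = tuple(
                tuple(iv) for iv in gm.get("suppressed_intervals", ())
            )
            if not isinstance(gm.get("recomb_rate", 1.0), (int, float)):
                gm["recomb_rate"] = tuple(gm["recomb_rate"])
            d["genetic_map"] = simulate.GeneticMapSpec(**gm)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write all artifacts under ``config.out_dir``.

    Returns the machine-readable run summary (also written as
    ``summary.json``). Each stage's errors are re-raised as
    :class:`PipelineError` naming the stage; partially written artifacts are
    removed on failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    try:
        return _run_stages(config, out_dir, emit)
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError(name, str(exc)) from exc

    return wrap


def _run_stages(config: RunConfig, out_dir: Path, emit) -> dict[str, Any]:
    summary: dict[str, Any] = {"config": config.to_dict(), "stages": []}

    # --- obtain sites ------------------------------------------------------
    if config.vcf is None:
        if config.simulate is None or config.genetic_map is None:
            raise PipelineError("simulate", "config needs either 'vcf' or a simulate block")
        dataset = _stage("simulate")(simulate.simulate_dataset, config.simulate, config.genetic_map)
        paths = _stage("simulate")(
            simulate.write_dataset, dataset, config.simulate, config.genetic_map, out_dir
        )
        vcf_path = paths["vcf"]
        summary["simulated"] = {
            "vcf": str(vcf_path),
            "causal_chrom": config.simulate.causal_chrom,
            "causal_pos": config.simulate.causal_pos_bp,
        }
    else:
        vcf_path = Path(config.vcf)

    result = _stage("read_vcf")(variants.read_vcf, vcf_path, multiallelic=config.multiallelic)
    sites = result.sites
    if not sites:
        raise PipelineError("read_vcf", f"no usable biallelic sites in {vcf_path}")
    summary["input"] = {
        "vcf": str(vcf_path),
        "n_sites": len(sites),
        "n_multiallelic_dropped": result.n_multiallelic_dropped,
        "n_missing_ad": result.n_missing_ad,
    }

    # --- annotation (optional) --------------------------------------------
    models: list[variants.GeneModel] = []
    if config.gff3 is not None:
        models = _stage("read_gff3")(variants.read_gff3, config.gff3)
        sites = _stage("classify_regions")(
            variants.classify_regions, sites, models, config.promoter_len
        )

    # --- filters -----------------------------------------------------------
    thresholds = filters.GenotypeThresholds(
        config.hom_ref_max, config.hom_alt_min, config.min_call_depth
    )
    report = filters.FilterReport()
    sites = _stage("filter_depth")(
        filters.filter_depth, sites, config.dp_min, config.dp_max, config.dp_mode, report
    )
    sites = _stage("filter_shared_hom_alt")(
        filters.filter_shared_hom_alt, sites, thresholds, report
    )
    if not sites:
        raise PipelineError("filters", "no sites survive filtering")

    # --- statistics and scan ----------------------------------------------
    site_stats = _stage("site_stats")(stats.compute_site_stats, sites)
    emit("site_stats.tsv", lambda p: site_stats.to_csv(p, sep="\t", index=False))

    windows = _stage("scan")(
        scan.sliding_window_mean, site_stats, config.window_bp, config.step_bp, config.scan_stat
    )
    emit(
        "windows.tsv",
        lambda p: scan.windows_to_frame(windows).to_csv(p, sep="\t", index=False),
    )
    emit("windows.bed", lambda p: scan.write_windows_bed(windows, p))

    regions = _stage("call_regions")(
        scan.call_candidate_regions, windows, config.region_quantile,
        config.per_chromosome_quantile,
    )
    emit("regions.bed", lambda p: scan.write_regions_bed(regions, p))
    summary["regions"] = [
        {"chrom": r.chrom, "start": r.start, "end": r.end, "threshold": r.threshold,
         "peak_start": r.peak.start, "peak_mean": r.peak.mean_stat}
        for r in regions
    ]

    # --- ranking -----------------------------------------------------------
    # shared-het filter applies only to the candidate-ranking stage
    rank_sites = _stage("filter_shared_het")(
        filters.filter_shared_het, sites, thresholds, report
    )
    emit("filter_report.tsv", report.write_tsv)
    summary["filters"] = report.rows
    rank_stats = _stage("site_stats")(stats.compute_site_stats, rank_sites)
    region_classes = set(config.region_classes) if (config.region_classes and models) else None
    candidates = _stage("rank")(
        scan.rank_candidate_sites, rank_stats, regions, region_classes, config.top_fraction
    )
    emit(
        "candidates.tsv",
        lambda p: scan.candidates_to_frame(candidates).to_csv(p, sep="\t", index=False),
    )
    selected = [c for c in candidates if c.selected]
    summary["candidates"] = {
        "n_eligible": len(candidates),
        "n_selected": len(selected),
        "top": [
            {"chrom": c.chrom, "pos": c.pos, "ed_ideal": c.ed_ideal, "rank": c.rank}
            for c in selected[:10]
        ],
    }

    # --- consequences (optional) ------------------------------------------
    if models and config.fasta is not None:
        import pyfaidx

        genome = _stage("annotate")(pyfaidx.Fasta, str(config.fasta))
        rows = []
        site_by_key = {(s.chrom, s.pos): s for s in sites}
        for cand in selected:
            site = site_by_key.get((cand.chrom, cand.pos))
            if site is None:
                continue
            for model in models:
                if model.chrom == cand.chrom and model.contains_cds(cand.pos):
                    cons = _stage("annotate")(csq.annotate_consequence, model, genome, site)
                    rows.append(
                        {
                            "chrom": cand.chrom, "pos": cand.pos, "gene_id": model.gene_id,
                            "effect": cons.effect,
                            "original_protein_len": cons.original_protein_len,
                            "mutant_protein_len": cons.mutant_protein_len,
                            "stop_codon_index": cons.stop_codon_index,
                        }
                    )
        import pandas as pd

        emit(
            "consequences.tsv",
            lambda p: pd.DataFrame(
                rows,
                columns=["chrom", "pos", "gene_id", "effect", "original_protein_len",
                         "mutant_protein_len", "stop_codon_index"],
            ).to_csv(p, sep="\t", index=False),
        )
        summary["consequences"] = rows

    emit("config_resolved.yaml", lambda p: config.to_yaml(p))
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
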