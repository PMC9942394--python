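"""End-to-end scan orchestration: filter → window statistics → joint
top-quantile calling → XP-CLR / Dxy validation → gene annotation, with a run
manifest that makes every output reproducible from the config and seed."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .variants_io import (
    GenotypeTable, SiteFilterConfig, ValidationError,
    read_vcf, read_population_map, read_gene_annotations, apply_site_filters,
)
from .window_stats import WindowSpec, compute_window_table, write_window_table
from .xpclr import XPCLRConfig, xpclr_scores
from .sweep_caller import (
    compute_thresholds, call_joint_outliers, merge_windows_to_segments,
    annotate_genes, cross_method_concordance, allele_frequency_trajectory,
    xpclr_outlier_regions, dxy_outlier_windows,
)

log = logging.getLogger("sweepscan")

__all__ = ["Contrast", "RunConfig", "run_scan", "ContrastResult"]


@dataclass(frozen=True)
class Contrast:
    """One focal-vs-control comparison; names refer to populations or groups
    in the population map (e.g. focal='QH', control='low')."""

    name: str
    focal: str
    control: str


@dataclass
class RunConfig:
    vcf: str
    population_map: str
    genes: str = None
    contrasts: list = field(default_factory=list)
    window: WindowSpec = field(default_factory=WindowSpec)
    filters: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    xpclr: XPCLRConfig = field(default_factory=XPCLRConfig)
    quantile: float = 0.01
    trajectory_min_rise: float = 0.2
    output_dir: str = "sweepscan_out"
    seed: int = 0


@dataclass
class ContrastResult:
    name: str
    thresholds: object
    windows: pd.DataFrame
    segments: pd.DataFrame
    genes: set
    concordance: dict


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(cfg: RunConfig):
    d = asdict(cfg)
    d["window"] = asdict(cfg.window)
    d["filters"] = asdict(cfg.filters)
    x = asdict(cfg.xpclr)
    x["selection_grid"] = list(x["selection_grid"])
    d["xpclr"] = x
    d["contrasts"] = [asdict(c) for c in cfg.contrasts]
    d.pop("output_dir")  # where results land must not change what they are
    return d


def run_contrast(table, popmap, genes, contrast, cfg, chrom_lengths=None):
    """Window statistics, joint outliers, segments, gene set and concordance
    for one focal-vs-control contrast (library entry point; no files)."""
    control = popmap.samples_of(contrast.control)
    focal = popmap.samples_of(contrast.focal)
    if not control or not focal:
        raise ValidationError(
            f"contrast {contrast.name!r} references unknown population/group"
        )
    windows = compute_window_table(
        table, control, focal, chrom_lengths=chrom_lengths, spec=cfg.window
    )
    thresholds = compute_thresholds(windows, cfg.quantile)
    outliers = call_joint_outliers(windows, thresholds)
    segments = merge_windows_to_segments(outliers)
    concordance = {}
    gene_set = set()
    if genes is not None and len(segments):
        segments, gene_set = annotate_genes(segments, genes)
        scores = xpclr_scores(table, control, focal, cfg.xpclr,
                              chrom_lengths=chrom_lengths)
        xp_regions = xpclr_outlier_regions(scores, cfg.quantile)
        _, xp_genes = annotate_genes(xp_regions, genes) if len(xp_regions) else (None, set())
        dxy_hits = dxy_outlier_windows(windows, cfg.quantile)
        _, dxy_genes = annotate_genes(dxy_hits, genes) if len(dxy_hits) else (None, set())
        if gene_set:
            for label, vset in (("xpclr", xp_genes), ("dxy", dxy_genes)):
                frac, inter = cross_method_concordance(gene_set, vset)
                concordance[label] = {"fraction": frac, "n_candidate": len(gene_set),
                                      "n_overlap": len(inter)}
    return ContrastResult(contrast.name, thresholds, windows, segments,
                          gene_set, concordance)


def run_scan(cfg: RunConfig):
    """Run the full scan; writes per-contrast result files plus a manifest.

    Re-running with identical inputs and seed reproduces identical files
    (timestamps appear only in logs).  Returns the list of
    :class:`ContrastResult`.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    popmap = read_population_map(cfg.population_map)
    for c in cfg.contrasts:
        for name in (c.focal, c.control):
            if not popmap.samples_of(name):
                raise ValidationError(
                    f"contrast {c.name!r} references unknown population {name!r}"
                )

    table, skip = read_vcf(cfg.vcf)
    table, report = apply_site_filters(table, cfg.filters)
    log.info("filtered table: %d/%d sites kept (%s)", report.n_kept,
             report.n_input, report.rejected)
    genes = read_gene_annotations(cfg.genes) if cfg.genes else None

    if not cfg.contrasts:
        log.warning("empty contrast list; writing manifest only")

    results = []
    for contrast in cfg.contrasts:
        res = run_contrast(table, popmap, genes, contrast, cfg)
        prefix = out / contrast.name
        write_window_table(res.windows, f"{prefix}.windows.tsv")
        with open(f"{prefix}.thresholds.tsv", "w") as fh:
            fh.write("# top-quantile boundaries (value >= threshold qualifies)\n")
            fh.write("quantile\tfst_threshold\tpi_ratio_threshold\n")
            fh.write(f"{res.thresholds.quantile:.10g}\t"
                     f"{res.thresholds.fst_threshold:.10g}\t"
                     f"{res.thresholds.pi_ratio_threshold:.10g}\n")
        with open(f"{prefix}.segments.bed", "w") as fh:
            for i, row in enumerate(res.segments.itertuples(index=False)):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{contrast.name}_seg{i}\t{row.peak_fst:.6g}\n")
        with open(f"{prefix}.genes.tsv", "w") as fh:
            fh.write("# genes overlapping called segments (>=1 bp)\n")
            for g in sorted(res.genes):
                fh.write(g + "\n")
        with open(f"{prefix}.concordance.tsv", "w") as fh:
            fh.write("# fraction of candidate genes confirmed by each validator\n")
            fh.write("validator\tfraction\tn_candidate\tn_overlap\n")
            for label, d in sorted(res.concordance.items()):
                fh.write(f"{label}\t{d['fraction']:.6g}\t{d['n_candidate']}\t"
                         f"{d['n_overlap']}\n")
        _write_trajectory(table, popmap, res, cfg, f"{prefix}.trajectory.tsv")
        results.append(res)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {
            p: _sha256(p)
            for p in filter(None, [cfg.vcf, cfg.population_map, cfg.genes])
        },
        "skipped_records": skip,
        "filter_report": {"n_input": report.n_input, "n_kept": report.n_kept,
                          "rejected": report.rejected},
        "contrasts": [r.name for r in results],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results


def _write_trajectory(table, popmap, res, cfg, path):
    """Trajectory report for SNPs inside called segments; needs >= 3
    populations with altitudes, otherwise an empty commented file."""
    pops = [p for p in popmap.populations() if p in popmap.altitudes]
    with open(path, "w") as fh:
        fh.write("# allele-frequency-vs-altitude trajectories for segment SNPs\n")
        if len(pops) < 3 or not len(res.segments):
            fh.write("# (needs >=3 populations with altitudes and >=1 segment)\n")
            return
        sites = []
        for row in res.segments.itertuples(index=False):
            idx = table.range_query(row.chrom, row.start, row.end)
            sites.extend((row.chrom, int(table.pos[i])) for i in idx[:50])
        traj = allele_frequency_trajectory(table, popmap, sites,
                                           cfg.trajectory_min_rise)
        traj.to_csv(fh, sep="\t", index=False, float_format="%.6g")
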