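"""Outlier calling, segment merging, gene annotation and concordance.

A window is a sweep candidate when it sits simultaneously in the top
quantile (default 1%) of the F_ST distribution and of the log2 θπ-ratio
distribution.  Qualifying windows that overlap or share a boundary merge
into segments; segments pick up overlapping genes (≥ 1 bp); candidate gene
sets are then cross-validated against the genes flagged by an independent
scan (XP-CLR grid scores or windowed Dxy) and compared across population
contrasts.  Allele-frequency trajectories rank candidate SNPs by how their
focal-allele frequency tracks population altitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .variants_io import GenotypeTable, GeneAnnotation, PopulationMap, ValidationError

__all__ = [
    "OutlierThresholds",
    "empirical_quantile_threshold",
    "compute_thresholds",
    "call_joint_outliers",
    "merge_windows_to_segments",
    "annotate_genes",
    "cross_method_concordance",
    "contrast_overlap",
    "allele_frequency_trajectory",
    "xpclr_outlier_regions",
    "dxy_outlier_windows",
]


@dataclass(frozen=True)
class OutlierThresholds:
    """Realised top-quantile boundaries on a given window table."""

    fst_threshold: float
    pi_ratio_threshold: float
    quantile: float = 0.01


def empirical_quantile_threshold(values, quantile=0.01):
    """Nearest-rank top-quantile boundary.

    The top set is the ⌊quantile·n⌋ largest finite values (at least 1); the
    threshold is the smallest member, and windows qualify by value ≥
    threshold.  Masked (NaN) and infinite values never enter the ranking.
    """
    if not (0 < quantile < 0.5):
        raise ValidationError("quantile must be in (0, 0.5)")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("no unmasked values to rank")
    k = max(1, int(math.floor(quantile * v.size)))
    return float(np.sort(v)[-k])


def compute_thresholds(windows: pd.DataFrame, quantile=0.01) -> OutlierThresholds:
    """Top-quantile F_ST and log2 θπ-ratio boundaries over unmasked windows."""
    ok = ~windows["masked"]
    return OutlierThresholds(
        fst_threshold=empirical_quantile_threshold(windows.loc[ok, "fst"], quantile),
        pi_ratio_threshold=empirical_quantile_threshold(
            windows.loc[ok, "log2_pi_ratio"], quantile
        ),
        quantile=quantile,
    )


def call_joint_outliers(windows: pd.DataFrame, thresholds: OutlierThresholds):
    """Windows with F_ST ≥ its threshold AND log2 θπ ratio ≥ its threshold;
    masked windows never qualify."""
    ok = (
        ~windows["masked"]
        & (windows["fst"] >= thresholds.fst_threshold)
        & (windows["log2_pi_ratio"] >= thresholds.pi_ratio_threshold)
    )
    return windows[ok.fillna(False)].reset_index(drop=True)


def merge_windows_to_segments(outliers: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended outlier windows into segments.

    Peak statistics are maxima over the merged windows.  Returns a DataFrame
    with chrom, start, end, n_windows, peak_fst, peak_log2_pi_ratio.
    """
    if len(outliers) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows",
                                     "peak_fst", "peak_log2_pi_ratio"])
    df = outliers.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    segments = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            cur["n_windows"] += 1
            cur["peak_fst"] = max(cur["peak_fst"], row.fst)
            cur["peak_log2_pi_ratio"] = max(cur["peak_log2_pi_ratio"],
                                            row.log2_pi_ratio)
        else:
            if cur is not None:
                segments.append(cur)
            cur = {"chrom": row.chrom, "start": int(row.start), "end": int(row.end),
                   "n_windows": 1, "peak_fst": float(row.fst),
                   "peak_log2_pi_ratio": float(row.log2_pi_ratio)}
    segments.append(cur)
    return pd.DataFrame(segments)


def annotate_genes(segments: pd.DataFrame, genes: GeneAnnotation):
    """Attach overlapping genes (≥ 1 bp, half-open semantics) to segments.

    Returns ``(segments_with_genes, gene_set)``; the contrast-level gene set
    is deduplicated by gene_id.
    """
    from intervaltree import IntervalTree

    trees = {}
    for rec in genes.records.itertuples(index=False):
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            rec.start, rec.end, (rec.gene_id, rec.gene_name)
        )
    seg = segments.copy()
    gene_lists = []
    all_ids = {}
    for row in seg.itertuples(index=False):
        hits = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        ids = sorted({iv.data[0] for iv in hits})
        gene_lists.append(",".join(ids))
        for i in ids:
            all_ids[i] = None
    seg["genes"] = gene_lists
    return seg, set(all_ids)


def cross_method_concordance(candidate_genes, validator_genes):
    """|candidate ∩ validator| / |candidate| plus the sorted intersection."""
    candidate_genes = set(candidate_genes)
    if not candidate_genes:
        raise ValidationError("candidate gene set is empty")
    inter = sorted(candidate_genes & set(validator_genes))
    return len(inter) / len(candidate_genes), inter


def contrast_overlap(gene_sets: dict) -> pd.DataFrame:
    """Full inclusion–exclusion cell counts for a Venn diagram of ≥2 contrasts.

    Each row is one membership pattern (e.g. NMG=1, GS=1, QH=0) with the
    number of genes exactly in that pattern; rows sum to |union|.
    """
    names = list(gene_sets)
    if len(names) < 2:
        raise ValidationError("need at least two contrasts")
    union = set().union(*gene_sets.values())
    rows = []
    from itertools import product

    for pattern in product([1, 0], repeat=len(names)):
        if not any(pattern):
            continue
        cell = set(union)
        for name, bit in zip(names, pattern):
            cell = cell & gene_sets[name] if bit else cell - gene_sets[name]
        rows.append({**dict(zip(names, pattern)), "count": len(cell),
                     "genes": ",".join(str(g) for g in sorted(cell, key=str))})
    return pd.DataFrame(rows)


def allele_frequency_trajectory(
    table: GenotypeTable,
    popmap: PopulationMap,
    candidate_sites,
    min_rise=0.2,
) -> pd.DataFrame:
    """Per-site test of whether alt-allele frequency climbs with altitude.

    Populations are ordered by altitude; a site is flagged
    ``altitude_increasing`` iff its frequencies are non-decreasing along the
    order, the total rise is ≥ ``min_rise``, and the top population is
    strictly above the bottom one.  A Spearman rank correlation between
    altitude order and frequency is reported per site.  Sites with a
    population entirely missing are reported ``incomplete`` and never
    flagged.
    """
    pops = popmap.populations_by_altitude()
    if len(pops) < 3:
        raise ValidationError("need >= 3 populations with altitudes")
    idx_by_pop = {p: table.sample_indices(popmap.samples_of(p)) for p in pops}
    alts = [popmap.altitudes[p] for p in pops]
    rows = []
    for chrom, pos in candidate_sites:
        sites = table.range_query(chrom, pos, pos + 1)
        if len(sites) == 0:
            raise ValidationError(f"candidate site {chrom}:{pos} not in table")
        i = int(sites[0])
        freqs = []
        for p in pops:
            f = table.alt_frequency(idx_by_pop[p])[i]
            freqs.append(f)
        freqs = np.array(freqs, dtype=float)
        incomplete = bool(np.isnan(freqs).any())
        if incomplete:
            flagged, rho = False, np.nan
        else:
            nondecreasing = bool(np.all(np.diff(freqs) >= 0))
            rise = float(freqs[-1] - freqs[0])
            # epsilon guards float representation at the rise boundary
            flagged = (nondecreasing and rise >= min_rise - 1e-9
                       and freqs[-1] > freqs[0])
            rho = spearmanr(alts, freqs).statistic if len(set(freqs)) > 1 else 0.0
        rows.append({
            "chrom": chrom, "pos": pos,
            **{f"freq_{p}": freqs[j] for j, p in enumerate(pops)},
            "rank_correlation": rho,
            "altitude_increasing": flagged,
            "incomplete": incomplete,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Validator gene sets for concordance
# ---------------------------------------------------------------------------

def xpclr_outlier_regions(scores: pd.DataFrame, quantile=0.01,
                          region_halfwidth=20_000) -> pd.DataFrame:
    """Top-quantile XP-CLR grid points merged into regions.

    Each qualifying grid point becomes ±``region_halfwidth`` bp; overlapping
    or book-ended regions merge.  Returns chrom/start/end.
    """
    ok = ~scores["masked"]
    thr = empirical_quantile_threshold(scores.loc[ok, "score"], quantile)
    hits = scores[ok & (scores["score"] >= thr)]
    df = pd.DataFrame({
        "chrom": hits["chrom"],
        "start": np.maximum(hits["pos"] - region_halfwidth, 0),
        "end": hits["pos"] + region_halfwidth,
        "fst": np.nan, "log2_pi_ratio": np.nan, "masked": False,
    })
    merged = merge_windows_to_segments(df)
    return merged[["chrom", "start", "end"]]


def recovered_loci(segments: pd.DataFrame, truth: dict, tolerance=100_000):
    """Which planted loci are recovered by the called segments.

    ``truth`` maps chromosome → planted position (bp) or None.  A locus
    counts as recovered when a called segment lies within ``tolerance`` bp of
    it; each recovered locus maps into exactly one (merged, non-overlapping)
    segment.  Returns the dict of recovered chrom → position.
    """
    out = {}
    for chrom, pos in truth.items():
        if pos is None:
            continue
        hit = (
            (segments["chrom"] == chrom)
            & (segments["start"] < pos + tolerance)
            & (segments["end"] > pos - tolerance)
        )
        if hit.any():
            out[chrom] = pos
    return out


def dxy_outlier_windows(windows: pd.DataFrame, quantile=0.01) -> pd.DataFrame:
    """Top-quantile Dxy windows (the absolute-divergence validator)."""
    ok = ~windows["masked"]
    thr = empirical_quantile_threshold(windows.loc[ok, "dxy"], quantile)
    hits = windows[ok & (windows["dxy"] >= thr)]
    return hits[["chrom", "start", "end"]].reset_index(drop=True)
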