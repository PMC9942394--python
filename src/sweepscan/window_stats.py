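"""Sliding-window population-genetic statistics.

The scan works in 40-kb windows advanced in 20-kb steps and computes, per
window and per population contrast: the Weir–Cockerham F_ST (ratio of summed
variance components), nucleotide diversity π per bp in each group, the
log2 θπ ratio (control/focal, so a sweep in the focal group is large and
positive), absolute divergence Dxy per bp, and Tajima's D per group.

Conventions
-----------
* π and Dxy are normalised by the full window length in bp; monomorphic
  bases contribute 0 to the numerator and their full length to the
  denominator (the VCFtools convention).
* Windowed F_ST is the ratio of sums Σa / Σ(a+b+c) over usable sites
  ("weighted" estimate); a flag switches to the mean of per-site ratios.
* Negative window F_ST values are retained, not clamped.
* Windows with fewer than ``min_snps_per_window`` usable SNPs are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import MISSING, GenotypeTable, ValidationError

__all__ = [
    "WindowSpec",
    "enumerate_windows",
    "site_fst_components",
    "windowed_fst",
    "windowed_pi",
    "log2_pi_ratio",
    "windowed_dxy",
    "tajimas_d",
    "tajima_constants",
    "compute_window_table",
    "write_window_table",
    "read_window_table",
]

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps", "fst", "pi_low", "pi_focal",
    "log2_pi_ratio", "dxy", "tajd_low", "tajd_focal", "masked",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 40-kb windows, 20-kb steps by default."""

    window_size: int = 40_000
    step_size: int = 20_000
    min_snps_per_window: int = 10

    def __post_init__(self):
        if self.window_size <= 0 or self.step_size <= 0:
            raise ValidationError("window and step sizes must be positive")
        if self.step_size > self.window_size:
            raise ValidationError("step_size must not exceed window_size")


def enumerate_windows(chrom_lengths, spec: WindowSpec):
    """Ordered (chrom, start, end) triples covering every chromosome.

    Windows start at 0 and advance by ``step_size``; the final window is
    truncated at the chromosome end.  A start beyond ``length - step_size``
    would duplicate coverage of the trailing partial step and is not emitted,
    so a chromosome shorter than one window yields the single window
    ``[0, length)``.
    """
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom!r} has non-positive length")
        start = 0
        covered = 0
        while True:
            end = min(start + spec.window_size, length)
            windows.append((chrom, start, end))
            covered = max(covered, end)
            start += spec.step_size
            if start + spec.step_size <= length:
                continue
            if covered < length and start < length:
                continue  # window < 2·step can leave a trailing gap to fill
            break
    return windows


# ---------------------------------------------------------------------------
# Per-site building blocks (vectorised over sites)
# ---------------------------------------------------------------------------

def _group_counts(genotypes, idx):
    """(alt allele count, called chromosomes, observed het count) per site."""
    g = genotypes[:, idx]
    called = g != MISSING
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    het = (g == 1).sum(axis=1)
    return alt.astype(float), n_chrom.astype(float), het.astype(float)


def wc_fst_components(genotypes, idx1, idx2):
    """Weir–Cockerham (1984) two-population variance components per site.

    Returns arrays ``(a, b, c)`` — among-population, among-individual-within-
    population, and within-individual components — computed from observed
    allele frequencies and heterozygote counts with unequal sample sizes.
    Sites that are monomorphic across both groups, or have fewer than two
    called genotypes in either group, are NaN (excluded from sums).
    """
    alt1, m1, het1 = _group_counts(genotypes, idx1)
    alt2, m2, het2 = _group_counts(genotypes, idx2)
    n1, n2 = m1 / 2.0, m2 / 2.0           # called diploid individuals
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / m1
        p2 = alt2 / m2
        h1 = het1 / n1
        h2 = het2 / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    usable = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def site_fst_components(site, genotypes_group1, genotypes_group2):
    """Variance components for a single site given the two groups' dosages.

    Thin convenience wrapper over :func:`wc_fst_components`; returns the
    scalar ``(a, b, c)`` (NaN when undefined).
    """
    g = np.concatenate([genotypes_group1, genotypes_group2])[None, :]
    idx1 = np.arange(len(genotypes_group1))
    idx2 = np.arange(len(genotypes_group1), g.shape[1])
    a, b, c = wc_fst_components(g, idx1, idx2)
    return float(a[0]), float(b[0]), float(c[0])


def _site_pi_unbiased(genotypes, idx):
    """Per-site unbiased diversity (n/(n-1))·2p̂(1-p̂); NaN when < 2 calls."""
    alt, m, _ = _group_counts(genotypes, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / m
        val = (m / (m - 1)) * 2 * p * (1 - p)
    return np.where(m >= 2, val, np.nan)


def _window_slices(table, windows):
    for chrom, start, end in windows:
        yield (chrom, start, end), table.range_query(chrom, start, end)


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def windowed_fst(table, group1, group2, windows, ratio_of_sums=True):
    """Window F_ST = Σa / Σ(a+b+c) over usable sites (NaN when none).

    ``ratio_of_sums=False`` averages per-site ratios a/(a+b+c) instead.
    """
    idx1 = table.sample_indices(group1)
    idx2 = table.sample_indices(group2)
    a, b, c = wc_fst_components(table.genotypes, idx1, idx2)
    tot = a + b + c
    out = np.empty(len(windows))
    for w, ((chrom, start, end), sites) in enumerate(_window_slices(table, windows)):
        aa, tt = a[sites], tot[sites]
        use = ~np.isnan(aa)
        if not use.any():
            out[w] = np.nan
        elif ratio_of_sums:
            denom = tt[use].sum()
            out[w] = aa[use].sum() / denom if denom != 0 else np.nan
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios = aa[use] / tt[use]
            out[w] = np.nanmean(ratios)
    return out


def windowed_pi(table, group, windows):
    """Nucleotide diversity per bp: Σ per-site unbiased diversity / window bp."""
    idx = table.sample_indices(group)
    site_pi = _site_pi_unbiased(table.genotypes, idx)
    out = np.empty(len(windows))
    for w, ((chrom, start, end), sites) in enumerate(_window_slices(table, windows)):
        vals = site_pi[sites]
        use = ~np.isnan(vals)
        if len(sites) == 0:
            out[w] = 0.0  # monomorphic window: zero numerator, full length
        elif use.any():
            out[w] = vals[use].sum() / (end - start)
        else:
            out[w] = np.nan  # group entirely missing at every site
    return out


def log2_pi_ratio(pi_control, pi_focal):
    """log2(π_control / π_focal); +inf when the focal group has lost all
    diversity (reported but masked from quantile ranking downstream)."""
    pi_control = np.asarray(pi_control, dtype=float)
    pi_focal = np.asarray(pi_focal, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # difference of logs is exactly antisymmetric under group swap
        out = np.log2(pi_control) - np.log2(pi_focal)
    out = np.where((pi_focal == 0) & (pi_control > 0), np.inf, out)
    out = np.where((pi_focal == 0) & (pi_control == 0), np.nan, out)
    return out if out.ndim else float(out)


def windowed_dxy(table, group1, group2, windows):
    """Absolute divergence per bp: Σ [p̂₁(1-p̂₂)+p̂₂(1-p̂₁)] / window bp."""
    idx1 = table.sample_indices(group1)
    idx2 = table.sample_indices(group2)
    alt1, m1, _ = _group_counts(table.genotypes, idx1)
    alt2, m2, _ = _group_counts(table.genotypes, idx2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(m1 > 0, alt1 / np.maximum(m1, 1), np.nan)
        p2 = np.where(m2 > 0, alt2 / np.maximum(m2, 1), np.nan)
    d = p1 * (1 - p2) + p2 * (1 - p1)
    out = np.empty(len(windows))
    for w, ((chrom, start, end), sites) in enumerate(_window_slices(table, windows)):
        vals = d[sites]
        use = ~np.isnan(vals)
        if len(sites) == 0:
            out[w] = 0.0
        elif use.any():
            out[w] = vals[use].sum() / (end - start)
        else:
            out[w] = np.nan
    return out


def tajima_constants(n):
    """Tajima (1989) normalising constants for n sampled chromosomes."""
    if n < 2:
        raise ValidationError("Tajima's D requires n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(table, group, windows, min_segsites=3):
    """Tajima's D per window for one group.

    π here is the classical sum of per-site mean pairwise differences,
    k(n−k)/C(n,2); S counts sites segregating within the group.  Windows with
    fewer than ``min_segsites`` segregating sites are NaN.  Normalising
    constants use the group's full chromosome count; sites with missing calls
    use their own called count for the pairwise term.
    """
    idx = table.sample_indices(group)
    alt, m, _ = _group_counts(table.genotypes, idx)
    seg = (alt > 0) & (alt < m) & (m >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(seg, alt * (m - alt) / (m * (m - 1) / 2.0), 0.0)
    n = 2 * len(idx)
    const = tajima_constants(n)
    out = np.empty(len(windows))
    for w, (_, sites) in enumerate(_window_slices(table, windows)):
        S = int(seg[sites].sum())
        if S < max(min_segsites, 1):
            out[w] = np.nan
            continue
        pi_total = site_pi[sites].sum()
        var = const["e1"] * S + const["e2"] * S * (S - 1)
        out[w] = (pi_total - S / const["a1"]) / np.sqrt(var) if var > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Full per-window statistic vector
# ---------------------------------------------------------------------------

def compute_window_table(
    table: GenotypeTable,
    control_samples,
    focal_samples,
    windows=None,
    chrom_lengths=None,
    spec: WindowSpec = None,
    tajd_min_segsites=3,
) -> pd.DataFrame:
    """The full statistic vector per window as a DataFrame.

    ``control_samples`` is the low-altitude (reference) group, whose diversity
    forms the θπ-ratio numerator; ``focal_samples`` is the population scanned
    for sweeps.  Windows may be given directly or derived from
    ``chrom_lengths`` and ``spec``.  A window is ``masked`` when its usable
    SNP count falls below ``spec.min_snps_per_window``.
    """
    if spec is None:
        spec = WindowSpec()
    if windows is None:
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(table.pos[table._index[c][1] - 1]) + 1
                for c in table.chromosomes()
            }
        windows = enumerate_windows(chrom_lengths, spec)

    n_snps = np.array(
        [len(sites) for _, sites in _window_slices(table, windows)], dtype=int
    )
    fst = windowed_fst(table, control_samples, focal_samples, windows)
    pi_low = windowed_pi(table, control_samples, windows)
    pi_focal = windowed_pi(table, focal_samples, windows)
    ratio = log2_pi_ratio(pi_low, pi_focal)
    dxy = windowed_dxy(table, control_samples, focal_samples, windows)
    td_low = tajimas_d(table, control_samples, windows, tajd_min_segsites)
    td_focal = tajimas_d(table, focal_samples, windows, tajd_min_segsites)
    masked = n_snps < spec.min_snps_per_window

    return pd.DataFrame(
        {
            "chrom": [w[0] for w in windows],
            "start": [w[1] for w in windows],
            "end": [w[2] for w in windows],
            "n_snps": n_snps,
            "fst": fst,
            "pi_low": pi_low,
            "pi_focal": pi_focal,
            "log2_pi_ratio": ratio,
            "dxy": dxy,
            "tajd_low": td_low,
            "tajd_focal": td_focal,
            "masked": masked,
        }
    )


_WINDOW_TSV_HEADER = (
    "# sweepscan window table\n"
    "# chrom, start, end: 0-based half-open window (bp)\n"
    "# n_snps: biallelic SNPs in window; fst: Weir-Cockerham (unitless)\n"
    "# pi_low, pi_focal, dxy: per-bp; log2_pi_ratio, tajd_*: unitless\n"
    "# masked: 1 if n_snps below the per-window floor\n"
)


def write_window_table(df: pd.DataFrame, path):
    with open(path, "w") as fh:
        fh.write(_WINDOW_TSV_HEADER)
        out = df.copy()
        out["masked"] = out["masked"].astype(int)
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_window_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["masked"] = df["masked"].astype(bool)
    return df
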