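"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literal per-site loops, straight from the
published formulas, with no code shared with the package: these are the
second route in every dual-route check.
"""

import math

import numpy as np

MISSING = -1


def wc_components_literal(g1, g2):
    """Weir & Cockerham (1984) two-population variance components for one
    biallelic site, transcribed term by term (r = 2 populations).

    ``g1``/``g2`` are alt-dosage vectors with -1 for missing; returns
    (a, b, c) or (nan, nan, nan) when undefined.
    """
    g1 = [int(x) for x in g1 if x != MISSING]
    g2 = [int(x) for x in g2 if x != MISSING]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return (math.nan,) * 3
    r = 2
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for x in g1 if x == 1) / n1
    h2 = sum(1 for x in g2 if x == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar <= 0 or pbar >= 1:
        return (math.nan,) * 3
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def window_fst_literal(geno, idx1, idx2, site_idx):
    """Ratio-of-sums window F_ST from the literal per-site components."""
    num = den = 0.0
    for i in site_idx:
        a, b, c = wc_components_literal(geno[i][idx1], geno[i][idx2])
        if not math.isnan(a):
            num += a
            den += a + b + c
    return num / den if den != 0 else math.nan


def window_pi_literal(geno, idx, site_idx, length):
    """Window diversity per bp: per-site (n/(n-1))·2p(1-p) over called
    chromosomes, summed and divided by window length."""
    total = 0.0
    any_called = False
    for i in site_idx:
        calls = [int(x) for x in geno[i][idx] if x != MISSING]
        n = 2 * len(calls)
        if n < 2:
            continue
        any_called = True
        p = sum(calls) / n
        total += (n / (n - 1)) * 2 * p * (1 - p)
    if site_idx and not any_called:
        return math.nan
    return total / length


def window_dxy_literal(geno, idx1, idx2, site_idx, length):
    total = 0.0
    for i in site_idx:
        c1 = [int(x) for x in geno[i][idx1] if x != MISSING]
        c2 = [int(x) for x in geno[i][idx2] if x != MISSING]
        if not c1 or not c2:
            return math.nan
        p1 = sum(c1) / (2 * len(c1))
        p2 = sum(c2) / (2 * len(c2))
        total += p1 * (1 - p2) + p2 * (1 - p1)
    return total / length


def tajimas_d_literal(geno, idx, site_idx, min_segsites=3):
    """Tajima (1989) D with classical pairwise-difference π, literal sums."""
    n = 2 * len(idx)
    S = 0
    pi = 0.0
    for i in site_idx:
        calls = [int(x) for x in geno[i][idx] if x != MISSING]
        m = 2 * len(calls)
        if m < 2:
            continue
        k = sum(calls)
        if 0 < k < m:
            S += 1
            pi += k * (m - k) / (m * (m - 1) / 2)
    if S < max(min_segsites, 1):
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / a1) / math.sqrt(var) if var > 0 else 0.0


def interval_overlaps_literal(segments, genes):
    """All-pairs quadratic interval-overlap oracle.

    ``segments``: list of (chrom, start, end); ``genes``: list of
    (chrom, start, end, gene_id).  Returns per-segment sorted gene-id lists.
    """
    out = []
    for (sc, ss, se) in segments:
        hits = sorted(
            gid for (gc, gs, ge, gid) in genes
            if gc == sc and gs < se and ge > ss
        )
        out.append(hits)
    return out
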