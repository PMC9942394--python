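"""Reading, writing and site-level filtering of the variant formats the scan consumes.

The pipeline starts from a multi-sample VCF with per-site INFO/DP (total read
depth) and INFO/MQ (RMS mapping quality), a sample→population→altitude map,
and gene annotations in BED or GFF3.  Everything is normalised to a single
in-memory container, :class:`GenotypeTable`, which stores biallelic SNPs as an
alt-allele dosage matrix.  Internal coordinates are 0-based half-open
throughout; conversion from the 1-based VCF/GFF3 conventions happens at the
I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for a missing diploid genotype

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeTable",
    "SiteFilterConfig",
    "FilterReport",
    "PopulationMap",
    "GeneAnnotation",
    "read_vcf",
    "write_vcf",
    "apply_site_filters",
    "read_population_map",
    "read_gene_annotations",
    "read_ms_format",
    "write_ms_format",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP: position (0-based), alleles, quality fields, dosages.

    ``site_depth`` and ``rms_mapping_quality`` are ``nan`` when the VCF did not
    annotate them.  ``genotypes`` holds the per-sample alt-allele dosage
    (0/1/2) with :data:`MISSING` for uncalled samples.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    site_depth: float
    rms_mapping_quality: float
    genotypes: np.ndarray

    def __post_init__(self):
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValidationError("VariantSite is restricted to biallelic SNPs")
        if not math.isnan(self.site_depth) and self.site_depth < 0:
            raise ValidationError("site_depth must be >= 0")


class GenotypeTable:
    """Sites × samples dosage matrix with per-site quality fields.

    Sites are sorted by (chrom, pos) with no duplicates; a per-chromosome
    index supports range queries in O(log n).
    """

    def __init__(self, samples, chroms, pos, ref, alt, dp, mq, genotypes):
        self.samples = list(samples)
        self.chroms = np.asarray(chroms, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.dp = np.asarray(dp, dtype=float)
        self.mq = np.asarray(mq, dtype=float)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        n = len(self.pos)
        if self.genotypes.shape != (n, len(self.samples)):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )
        self._build_index()

    def _build_index(self):
        # contiguity + sortedness check, then one (start, stop) slice per chrom
        self._index = {}
        n = len(self.pos)
        start = 0
        for i in range(1, n + 1):
            if i == n or self.chroms[i] != self.chroms[start]:
                c = self.chroms[start]
                if c in self._index:
                    raise ValidationError(f"sites for chromosome {c!r} are not contiguous")
                block = self.pos[start:i]
                if np.any(np.diff(block) <= 0):
                    raise ValidationError(
                        f"sites on {c!r} are not strictly sorted by position"
                    )
                self._index[c] = (start, i)
                start = i

    # -- construction -------------------------------------------------------

    @classmethod
    def from_sites(cls, samples, sites):
        sites = sorted(sites, key=lambda s: (s.chrom, s.pos))
        return cls(
            samples,
            [s.chrom for s in sites],
            [s.pos for s in sites],
            [s.ref_allele for s in sites],
            [s.alt_allele for s in sites],
            [s.site_depth for s in sites],
            [s.rms_mapping_quality for s in sites],
            np.array([s.genotypes for s in sites], dtype=np.int8).reshape(
                len(sites), len(samples)
            ),
        )

    # -- accessors ----------------------------------------------------------

    @property
    def n_sites(self):
        return len(self.pos)

    @property
    def n_samples(self):
        return len(self.samples)

    def site(self, i) -> VariantSite:
        return VariantSite(
            self.chroms[i], int(self.pos[i]), self.ref[i], self.alt[i],
            float(self.dp[i]), float(self.mq[i]), self.genotypes[i],
        )

    def __iter__(self):
        return (self.site(i) for i in range(self.n_sites))

    def __len__(self):
        return self.n_sites

    def chromosomes(self):
        return list(self._index)

    def range_query(self, chrom, start, end):
        """Indices of sites with ``start <= pos < end`` on ``chrom``."""
        if chrom not in self._index:
            return np.arange(0)
        lo, hi = self._index[chrom]
        block = self.pos[lo:hi]
        return lo + np.arange(
            np.searchsorted(block, start, "left"),
            np.searchsorted(block, end, "left"),
        )

    def take(self, idx):
        """New table restricted to the given site indices (order preserved)."""
        idx = np.asarray(idx)
        return GenotypeTable(
            self.samples, self.chroms[idx], self.pos[idx], self.ref[idx],
            self.alt[idx], self.dp[idx], self.mq[idx], self.genotypes[idx],
        )

    def sample_indices(self, names):
        missing = [s for s in names if s not in self.samples]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in names], dtype=int)

    def alt_frequency(self, sample_idx=None):
        """Per-site alt-allele frequency over non-missing calls (nan if none)."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        called = g != MISSING
        n_chrom = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, samples=None):
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeTable`.

    Multiallelic and indel records are skipped (and counted); missing INFO/DP
    and INFO/MQ are stored as ``nan``.  Returns ``(table, skip_counts)`` where
    ``skip_counts`` has keys ``multiallelic`` and ``indel``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except OSError as e:  # pragma: no cover - message pass-through
        raise IOError(f"cannot open VCF {path}: {e}") from e
    if samples is not None:
        absent = [s for s in samples if s not in vcf.samples]
        if absent:
            raise ValidationError(f"samples not in VCF header: {absent}")
        vcf.set_samples(list(samples))
    names = list(vcf.samples)

    chroms, pos, ref, alt, dp, mq, geno = [], [], [], [], [], [], []
    skip = {"multiallelic": 0, "indel": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            skip["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skip["indel"] += 1
            continue
        chroms.append(v.CHROM)
        pos.append(v.POS - 1)  # to 0-based
        ref.append(v.REF)
        alt.append(v.ALT[0])
        d = v.INFO.get("DP")
        m = v.INFO.get("MQ")
        dp.append(np.nan if d is None else float(d))
        mq.append(np.nan if m is None else float(m))
        gt = v.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        geno.append(gt)
    vcf.close()
    n = len(pos)
    table = GenotypeTable(
        names, chroms, pos, ref, alt, dp, mq,
        np.array(geno, dtype=np.int8).reshape(n, len(names)),
    )
    return table, skip


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path):
    """Write the table back out as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in table.chromosomes():
            lo, hi = table._index[c]
            length = int(table.pos[hi - 1]) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples) + "\n"
        )
        for i in range(table.n_sites):
            info = []
            if not math.isnan(table.dp[i]):
                info.append(f"DP={int(table.dp[i])}")
            if not math.isnan(table.mq[i]):
                mqv = table.mq[i]
                info.append(f"MQ={int(mqv) if float(mqv).is_integer() else mqv}")
            gts = "\t".join(_GT_STR[int(g)] for g in table.genotypes[i])
            fh.write(
                f"{table.chroms[i]}\t{table.pos[i] + 1}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteFilterConfig:
    """Site-quality thresholds: keep a site iff DP in [min_depth, max_depth],
    RMS MQ >= min_rms_mq, minor-allele frequency >= min_maf (over non-missing
    calls) and missing-genotype fraction <= max_missing."""

    min_depth: float = 6
    max_depth: float = 100
    min_rms_mq: float = 20
    min_maf: float = 0.1
    max_missing: float = 0.1

    def __post_init__(self):
        if not (0 <= self.min_maf <= 0.5):
            raise ValidationError("min_maf must be in [0, 0.5]")
        if not (0 <= self.max_missing <= 1):
            raise ValidationError("max_missing must be in [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValidationError("min_depth must not exceed max_depth")


# first-failing-criterion attribution order
FILTER_CRITERIA = ("depth_low", "depth_high", "mq", "maf", "missing")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    rejected: dict = field(default_factory=dict)


def apply_site_filters(table: GenotypeTable, cfg: SiteFilterConfig = None):
    """Apply the site-quality filters; return ``(filtered_table, report)``.

    Each rejected site is attributed to its first failing criterion in the
    order depth-low, depth-high, MQ, MAF, missingness, so the per-criterion
    counts partition the rejected set.  A site with missing DP (or MQ) fails
    the corresponding criterion.
    """
    if cfg is None:
        cfg = SiteFilterConfig()
    if table.n_sites == 0:
        raise ValidationError("cannot filter an empty table")

    g = table.genotypes
    called = g != MISSING
    n_called = called.sum(axis=1)
    miss_frac = 1.0 - n_called / table.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=1) / np.maximum(2 * n_called, 1)
    p = np.where(n_called > 0, p, np.nan)
    maf = np.minimum(p, 1 - p)

    # nan comparisons are False, so ~(...) fails sites with missing DP/MQ —
    # but only when the corresponding threshold actually binds
    fail = {
        "depth_low": ~(table.dp >= cfg.min_depth) if cfg.min_depth > 0
        else np.nan_to_num(table.dp, nan=cfg.min_depth) < cfg.min_depth,
        "depth_high": ~(table.dp <= cfg.max_depth) & ~np.isnan(table.dp),
        "mq": ~(table.mq >= cfg.min_rms_mq) if cfg.min_rms_mq > 0
        else np.nan_to_num(table.mq, nan=cfg.min_rms_mq) < cfg.min_rms_mq,
        "maf": ~(maf >= cfg.min_maf),
        "missing": ~(miss_frac <= cfg.max_missing),
    }

    attributed = np.full(table.n_sites, -1)
    for k, name in enumerate(FILTER_CRITERIA):
        newly = (attributed == -1) & fail[name]
        attributed[newly] = k
    keep = attributed == -1

    report = FilterReport(
        n_input=table.n_sites,
        n_kept=int(keep.sum()),
        rejected={name: int((attributed == k).sum())
                  for k, name in enumerate(FILTER_CRITERIA)},
    )
    if report.n_kept == 0:
        warnings.warn("all sites removed by filters; returning empty table")
    return table.take(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """sample → population assignment, population altitudes (m.a.s.l.), and
    named groups (unions of populations, e.g. a pooled low-altitude group)."""

    assignments: dict
    altitudes: dict
    groups: dict = field(default_factory=dict)

    def populations(self):
        seen = {}
        for p in self.assignments.values():
            seen[p] = None
        return list(seen)

    def samples_of(self, name):
        """Samples belonging to population *name*, or to group *name*."""
        pops = self.groups.get(name, [name])
        return [s for s, p in self.assignments.items() if p in pops]

    def populations_by_altitude(self):
        pops = self.populations()
        absent = [p for p in pops if p not in self.altitudes]
        if absent:
            raise ValidationError(f"altitude missing for populations: {absent}")
        return sorted(pops, key=lambda p: self.altitudes[p])


def read_population_map(path):
    """Parse a whitespace-delimited map: ``sample pop altitude`` lines plus
    optional group lines ``name = P1,P2,...``."""
    assignments, altitudes, groups = {}, {}, {}
    n_data = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                name, members = line.split("=", 1)
                groups[name.strip()] = [m.strip() for m in members.split(",") if m.strip()]
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 'sample pop altitude'")
            sample, pop, alt = parts[0], parts[1], parts[2]
            try:
                alt = float(alt)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: altitude {alt!r} is not numeric"
                ) from None
            if sample in assignments:
                warnings.warn(f"duplicate sample {sample!r}; last assignment wins")
            assignments[sample] = pop
            altitudes[pop] = alt
            n_data += 1
    if n_data == 0:
        raise ValidationError(f"population map {path} contains no sample lines")
    return PopulationMap(assignments, altitudes, groups)


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene intervals as a DataFrame with columns chrom, start, end, strand,
    gene_id, gene_name — 0-based half-open, same assembly as the VCF."""

    records: pd.DataFrame

    def __len__(self):
        return len(self.records)


def read_gene_annotations(path, fmt=None) -> GeneAnnotation:
    """Read genes from BED (0-based half-open) or GFF3 (1-based inclusive,
    gene-type records only); both are normalised to 0-based half-open."""
    import pyranges as pr

    path = str(path)
    if fmt is None:
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    fmt = fmt.lower()
    if fmt == "bed":
        df = pr.read_bed(path).df
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "strand": df.get("Strand", pd.Series(["."] * len(df))).astype(str),
                "gene_id": df.get("Name", pd.Series([""] * len(df))).astype(str),
            }
        )
        out["gene_name"] = out["gene_id"]
    elif fmt == "gff3":
        df = pr.read_gff3(path).df  # pyranges already converts to 0-based
        df = df[df["Feature"] == "gene"].reset_index(drop=True)
        gene_id = df.get("ID", pd.Series([""] * len(df))).astype(str)
        name = df.get("Name")
        name = gene_id if name is None else name.astype(str).where(
            name.notna() & (name.astype(str) != ""), gene_id
        )
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "strand": df["Strand"].astype(str),
                "gene_id": gene_id,
                "gene_name": name,
            }
        )
    else:
        raise ValidationError(f"unknown annotation format {fmt!r}")

    bad = out["start"] >= out["end"]
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} gene records with start >= end")
        out = out[~bad].reset_index(drop=True)
    return GeneAnnotation(out)


# ---------------------------------------------------------------------------
# ms-format haplotype blocks
# ---------------------------------------------------------------------------

def write_ms_format(replicates, fh=None):
    """Write replicates in the standard ms dialect.

    ``replicates`` is an iterable of ``(haplotypes, positions)`` where
    ``haplotypes`` is an (n_hap, n_sites) 0/1 array and ``positions`` are
    sorted relative positions in [0, 1].  Returns the text when ``fh`` is
    None, else writes to the stream.
    """
    lines = []
    for hap, positions in replicates:
        hap = np.asarray(hap)
        positions = np.asarray(positions, dtype=float)
        if hap.ndim != 2:
            raise ValidationError("haplotype block must be 2-D")
        if hap.shape[1] != len(positions):
            raise ValidationError(
                f"row width {hap.shape[1]} does not match {len(positions)} positions"
            )
        lines.append("//")
        lines.append(f"segsites: {hap.shape[1]}")
        if hap.shape[1] > 0:
            lines.append("positions: " + " ".join(f"{p:.8f}" for p in positions))
            for row in hap:
                lines.append("".join("1" if x else "0" for x in row))
        lines.append("")
    text = "\n".join(lines)
    if fh is None:
        return text
    fh.write(text)
    return None


def read_ms_format(source):
    """Inverse of :func:`write_ms_format`; accepts text or a file object.

    Returns a list of ``(haplotypes, positions)`` blocks.
    """
    text = source if isinstance(source, str) else source.read()
    replicates = []
    lines = iter(text.splitlines())
    current = None
    for line in lines:
        line = line.strip()
        if line == "//":
            current = {"rows": [], "positions": np.array([]), "segsites": 0}
            replicates.append(current)
        elif line.startswith("segsites:"):
            current["segsites"] = int(line.split(":")[1])
        elif line.startswith("positions:"):
            current["positions"] = np.array(line.split(":")[1].split(), dtype=float)
        elif line and set(line) <= {"0", "1"} and current is not None:
            current["rows"].append([int(c) for c in line])
    out = []
    for rep in replicates:
        hap = np.array(rep["rows"], dtype=np.uint8)
        if hap.size == 0:
            hap = hap.reshape(len(rep["rows"]), rep["segsites"])
        if hap.shape[1] != rep["segsites"]:
            raise ValidationError("segsites does not match haplotype row width")
        out.append((hap, rep["positions"]))
    return out
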