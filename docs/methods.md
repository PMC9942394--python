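# Methods

This note documents the statistical models, estimators, numerical choices
and known limitations behind `sweepscan`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The scan

The scan contrasts a *focal* population (the one suspected of recent
adaptation) against a *control* group, which may pool several populations;
pooled groups are treated as a single population throughout.

**Site filters.** Starting from a VCF of biallelic SNPs, a site is kept iff
INFO/DP ∈ [6, 100], INFO/MQ ≥ 20, minor-allele frequency ≥ 0.1 and the
fraction of missing genotypes ≤ 0.1. All four comparisons are inclusive,
matching the conventional "≥ / ≤" phrasing of resequencing pipelines. MAF
is computed over non-missing called alleles of the whole cohort (a flag is
reserved for per-population filtering; the default is cohort-wide). A site
whose DP or MQ annotation is absent fails the corresponding criterion —
unless that criterion is configured to be vacuous (threshold 0), in which
case missing values pass. Rejected sites are attributed to the *first*
failing criterion in the fixed order depth-low, depth-high, MQ, MAF,
missingness, so the per-criterion counts partition the rejected set.

**Windows.** Statistics are computed in 40-kb windows advanced in 20-kb
steps (defaults; both configurable). Windows start at 0; a start s > 0 is
emitted only while s + step ≤ L, and the final window is truncated at the
chromosome end — every base is covered and a chromosome shorter than one
window yields the single window [0, L). Windows with fewer than
`min_snps_per_window` (default 10) SNPs are masked: they are reported but
excluded from quantile ranking and can never be outliers.

**Weir–Cockerham F_ST.** Per site, the two-population variance components
a (among populations), b (among individuals within populations) and c
(within individuals) are computed from observed allele frequencies and
heterozygote counts with the exact unequal-sample-size weights of the 1984
estimator; per-site sample sizes reflect missingness. Sites monomorphic
across both groups, or with fewer than two called genotypes in either
group, are excluded. The window estimate is the ratio of sums
Σa / Σ(a+b+c) (the "weighted" convention of the standard VCF tools); a
flag switches to the mean of per-site ratios. Negative estimates are
retained unclamped — they cannot enter a top-1% tail, and clamping would
bias genome-wide summaries.

**π and Dxy.** Per-site diversity uses the unbiased estimator
(n/(n−1))·2p̂(1−p̂) with n the called chromosomes at the site —
algebraically the mean pairwise difference k(n−k)/C(n,2). Window π is the
sum over sites divided by the *full window length in bp*: monomorphic
bases contribute zero to the numerator and their length to the denominator
(callable-site masking is out of scope; this matches the convention of the
standard windowed tools). Dxy sums p̂₁(1−p̂₂)+p̂₂(1−p̂₁) and divides by the
same length.

**log2 θπ ratio.** The ratio is π_control/π_focal, log2-transformed, so a
sweep in the focal population produces a large *positive* value. A window
where the focal group has lost all diversity while the control retains
some yields +∞: it is reported, automatically qualifies against any
threshold, but never participates in threshold *estimation*.

**Tajima's D.** The classical statistic with constants a₁…e₂ from the
group's full chromosome count; π here is the sum of per-site mean pairwise
differences and S counts sites segregating *within the group*. Windows
with S below `min_segsites` (default 3) are undefined. With missing data,
each site's pairwise term uses its own called count while the constants
use the nominal n — exact when data are complete, an approximation
otherwise. Note that the per-site mean pairwise difference equals the
"unbiased" form (n/(n−1))·2p̂(1−p̂); the two ways of writing π in this
package are the same quantity.

**Joint outlier calling.** Thresholds are nearest-rank top-quantile
boundaries: with n unmasked finite values and quantile q, the top set is
the ⌊qn⌋ largest (at least one), the threshold is the smallest member, and
windows qualify by value ≥ threshold. A candidate window must exceed
*both* the F_ST and log2-ratio thresholds. Thresholds are recomputed per
contrast, so different focal populations see different realised cutoffs.
Qualifying windows that overlap or share a boundary merge into segments
(step < window guarantees genuine sweep regions span overlapping
windows); segment peak statistics are maxima over members. Genes overlap
segments by ≥ 1 bp under half-open coordinates. Cross-method concordance
is |candidate ∩ validator| / |candidate|, with the F_ST/θπ gene set as
the denominator.

**XP-CLR-style scan.** At grid points every `grid_spacing` bp, SNPs within
`snp_radius` (evenly thinned to at most `max_snps_per_window`) contribute
composite log-likelihood terms. Neutrally, the focal frequency y given the
reference frequency p is Normal(p, ω·p(1−p)) truncated to (0,1), the
clipped mass becoming point masses at 0 and 1; ω is the genome-wide
method-of-moments drift scale mean[(p₂−p₁)²/(p₁(1−p₁))]. Under a sweep of
strength s at the grid point, a site at distance d escapes hitchhiking
with probability c = 1 − exp(−r·d/s); conditional on the pre-sweep
frequency x, the post-sweep frequency is 1−c+cx with probability x (the
beneficial mutation arose on the allele's background) and cx otherwise.
Observed focal counts enter through binomial sampling. The score is
2·(best composite log-likelihood over the selection grid − neutral);
with 0 in the grid the score is non-negative, and likelihood ties within
1e-9 prefer weaker selection, so frequency-identical data score exactly 0.
Numerics: the truncated-normal weights on a 201-point interior grid are
renormalised so each SNP's frequency law integrates to one, and the drift
s.d. is floored at 0.01 so the quadrature never straddles an unresolved
spike. This is a reimplementation of the model class, not a clone of any
released binary; the recombination rate is a data parameter (uniform by
default, map optional).

## The simulators

**Neutral IWM coalescent.** Hudson-style structured coalescent in ms
scaling: time in units of 4N₀ generations, within-deme pair coalescence at
rate 2/x for relative deme size x, per-lineage migration at the scaled
rate 4N₀m (uniform over other demes), all lineages merging into one
ancestral pool at the split time. Infinite-sites mutations fall on
branches at rate θ per unit total branch length. The scaling was verified
against msprime at matched parameters (site-frequency spectrum and mean
F_ST; see the cross-oracle test).

**Recombination** is approximated by partitioning the locus into freely
recombining, internally non-recombining blocks (θ divided evenly; one
block per ρ₀ = 20 units of scaled recombination by default, or an explicit
block count). This reproduces the aspect of recombination that matters
for windowed scans — many quasi-independent genealogies per 40-kb window,
hence realistic window-to-window sampling variance — but not within-block
linkage patterns or LD decay, so haplotype-structure statistics should not
be read off these simulations. Synthetic genomes use 5-kb blocks
(ρ per window ≫ 1, as in real data).

**Forward sweep simulator.** Discrete-generation diploid Wright–Fisher
with additive selection (fitnesses 1, 1+s, 1+2s) at one site in the focal
deme. The initial standing variation of all demes is one draw from the
IWM coalescent with 2N chromosomes per deme; the beneficial allele enters
as a single copy and runs are conditioned on fixation by restarting from
the same initial population on loss (capped at 10,000 restarts — if the
cap binds, 2Ns is too small to condition by rejection). Gametes recombine
with Poisson(r·L) crossovers; new mutations arise at μ per bp per
generation on infinite sites; columns lost or fixed metapopulation-wide
are pruned each generation. Sampling happens at fixation. Internally the
population matrix is double-buffered and columns are kept in arrival
order (crossover parity and pruning are order-independent), sorted once
at sampling.

**Calibration.** `calibrate_iwm_to_fst` simulates a grid of (split time,
migration rate) cells, scores each by the absolute difference of mean
F_ST to the target (or summed absolute quantile differences), and returns
the best cell, its full neutral F_ST distribution, and the nearest-rank
99th percentile — the neutral envelope that an observed top-1% tail must
exceed before being read as selection. A fit worse than `tolerance`
(default 0.05) is returned flagged as not converged.

## Synthetic study conditions

The default synthetic genome — used by the power tests and the acceptance
script — is 10 chromosomes of 1 Mb, two demes (split 0.05 × 4N₀
generations, migration 4N₀m = 1, giving background windowed F_ST ≈ 0.08),
θ/bp = 5×10⁻⁴, 15 + 15 sampled diploids, DP ~ Poisson(30) and MQ = 60,
with sweeps planted at the midpoints of three chromosomes: N = 500
diploids per deme, s = 0.1 (2Ns = 100), r = 5×10⁻⁷/bp (ρ/θ = 2). At
fixed 2Ns, slower sweeps in a larger deme accumulate more recombination
events and therefore leave more *consistent* hitchhiking troughs than
fast small-N sweeps, whose realised escape fraction is erratic.

What these conditions do and do not show: a sweep of 2Ns = 100 leaves a
diversity trough whose depth varies substantially between realisations —
roughly a quarter of sweeps at these settings produce a log2 θπ-ratio
peak below 1 and are near-invisible to any windowed scan. Power statements
are therefore made over replicates, and recovery of two of three planted
loci per genome is the realistic operating point; recovering all three
consistently would require stronger selection. The generator emulates
allele-frequency and diversity structure, not sequencing artefacts: no
base errors, no mapping bias, uniform depth, and DP/MQ fields that pass
the filters by construction unless degraded deliberately.

A planted locus counts as *recovered* when a called segment lies within
±100 kb of it, the same localisation radius used for the XP-CLR checks.
On neutral data the top-scoring XP-CLR grid point is roughly uniformly
placed, so ~20% of neutral 1-Mb regions put it within ±100 kb of the
midpoint by chance — the floor against which the sweep localisation rate
(~70–90%) and score separation should be judged.

## Determinism and reproducibility

Every simulator is a pure function of its inputs and a single integer
seed; derived seeds are spawned from one `numpy` Generator. `run_scan`
writes a manifest with the config hash (excluding the output directory),
input SHA-256 checksums, seed and package version; re-running with
identical inputs reproduces byte-identical result files. Test problem
sizes (replicate counts, locus lengths) are chosen so the whole suite
runs in minutes on one CPU while keeping Monte-Carlo standard errors
well inside the asserted tolerances; the acceptance script reports the
problem size alongside every quantity.

## Known limitations

* Biallelic SNPs only; multiallelic records are skipped, not decomposed.
* π/Dxy denominators assume every base of a window is callable.
* Tajima's D constants ignore per-site missingness (exact for complete
  data).
* The block-recombination approximation carries no within-block LD; the
  coalescent has one split event and no post-split size changes.
* The XP-CLR reimplementation omits LD-based SNP down-weighting and makes
  no claim of numerical parity with any released binary.
* Windowed F_ST quantiles are computed over possibly correlated windows
  (overlapping steps), as is standard for this scan design.
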