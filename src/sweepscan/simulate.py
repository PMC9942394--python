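"""Coalescent and forward simulation of multi-population genotype data.

Two generators live here:

* a Hudson-style structured coalescent under an isolation-with-migration
  (IWM) demography — demes exchanging migrants back to a split time, a single
  ancestral pool before it — with infinite-sites mutation.  Scaling follows
  the ms conventions: time in units of 4N₀ generations, θ = 4N₀μ per locus,
  migration as the scaled rate 4N₀m.  Recombination is approximated by
  partitioning the locus into freely recombining, internally non-recombining
  blocks (see :func:`resolve_blocks`).
* a forward-time diploid Wright–Fisher simulator that plants a selective
  sweep: a beneficial allele (genotype fitnesses 1, 1+s, 1+2s) introduced as
  a single copy in a focal deme and conditioned on fixation by restarting on
  loss.  Neutral variation is seeded from the coalescent and evolves with
  crossover recombination and new mutation.

Both are pure functions of their inputs and a seed.  A grid-search
calibrator fits split time and migration rate to a target F_ST summary and
returns the fitted model's neutral F_ST distribution and its top-1%
"neutral envelope", mirroring how observed F_ST distributions are matched by
neutral IWM simulation before declaring the top tail selective.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .variants_io import GenotypeTable, PopulationMap, GeneAnnotation, ValidationError
from .window_stats import wc_fst_components

__all__ = [
    "IWMModel",
    "SweepSimConfig",
    "HaplotypeSample",
    "simulate_neutral_iwm",
    "simulate_sweep",
    "calibrate_iwm_to_fst",
    "CalibrationResult",
    "haplotypes_to_vcf",
    "haplotype_sample_to_table",
    "make_sweep_genome",
    "synthetic_gene_annotations",
]


@dataclass(frozen=True)
class IWMModel:
    """Isolation-with-migration demography in ms scaling.

    ``deme_sizes`` are per-deme effective sizes relative to the reference N₀;
    ``split_time`` (units of 4N₀ generations) is when demes merge into one
    ancestral pool of relative size ``ancestral_size``; ``migration_rate`` is
    the scaled rate 4N₀m at which each lineage migrates (split uniformly over
    the other demes).  ``theta`` and ``rho`` are 4N₀μ and 4N₀r per locus.
    """

    sample_sizes: tuple = (20, 20)      # chromosomes per deme
    deme_sizes: tuple = None            # default: all 1.0
    split_time: float = 0.05
    migration_rate: float = 1.0
    theta: float = 500.0
    rho: float = 0.0
    locus_length: int = 1_000_000
    ancestral_size: float = 1.0
    recomb_blocks: int = None           # override block approximation of rho

    def __post_init__(self):
        if self.deme_sizes is None:
            object.__setattr__(self, "deme_sizes", tuple([1.0] * len(self.sample_sizes)))
        if len(self.deme_sizes) != len(self.sample_sizes):
            raise ValidationError("deme_sizes and sample_sizes must align")
        if self.split_time < 0 or self.migration_rate < 0:
            raise ValidationError("split_time and migration_rate must be >= 0")
        if sum(self.sample_sizes) < 2:
            raise ValidationError("need at least 2 sampled chromosomes")
        if self.theta <= 0:
            raise ValidationError("theta must be > 0")
        if any(s <= 0 for s in self.deme_sizes) or self.ancestral_size <= 0:
            raise ValidationError("deme sizes must be > 0")


def resolve_blocks(model: IWMModel) -> int:
    """Number of freely recombining blocks approximating ``rho``.

    One block per ρ₀ = 20 units of scaled recombination (capped at 200); an
    explicit ``recomb_blocks`` wins.  ρ = 0 means a single non-recombining
    locus.
    """
    if model.recomb_blocks is not None:
        return max(1, int(model.recomb_blocks))
    if model.rho <= 0:
        return 1
    return int(np.clip(round(model.rho / 20.0), 1, 200))


@dataclass
class HaplotypeSample:
    """One replicate: 0/1 haplotypes (rows grouped by deme), sorted relative
    positions in [0,1], per-deme row counts, and the seed that produced it."""

    haplotypes: np.ndarray
    positions: np.ndarray
    sample_sizes: tuple
    seed: int
    sweep_position: float = None        # relative position of a planted sweep

    @property
    def segsites(self):
        return self.haplotypes.shape[1]

    def deme_rows(self, d):
        lo = sum(self.sample_sizes[:d])
        return slice(lo, lo + self.sample_sizes[d])

    def pairwise_diversity(self):
        """Mean pairwise difference summed over sites (per locus, not per bp)."""
        n = self.haplotypes.shape[0]
        k = self.haplotypes.sum(axis=0)
        return float(np.sum(k * (n - k)) / (n * (n - 1) / 2.0))


# ---------------------------------------------------------------------------
# Structured coalescent
# ---------------------------------------------------------------------------

class _RandStream:
    """Buffered draws from a Generator: cuts per-event call overhead in the
    coalescent loop while staying a pure function of the generator state."""

    def __init__(self, rng, chunk=4096):
        self.rng = rng
        self.chunk = chunk
        self._exp = np.empty(0)
        self._uni = np.empty(0)
        self._ie = 0
        self._iu = 0

    def exponential(self):
        if self._ie >= len(self._exp):
            self._exp = self.rng.exponential(1.0, size=self.chunk)
            self._ie = 0
        v = self._exp[self._ie]
        self._ie += 1
        return v

    def uniform(self):
        if self._iu >= len(self._uni):
            self._uni = self.rng.uniform(0.0, 1.0, size=self.chunk)
            self._iu = 0
        v = self._uni[self._iu]
        self._iu += 1
        return v

    def integer(self, n):
        return int(self.uniform() * n)


def _simulate_tree(rng, sample_sizes, deme_sizes, split_time, migration_rate,
                   ancestral_size, stream=None):
    """One genealogy: returns (parent, node_time) arrays; leaves 0..n-1 are
    grouped by deme in sample order.  Per-deme lineage lists with swap-pop
    removal keep every event O(1)."""
    n = sum(sample_sizes)
    n_demes = len(sample_sizes)
    rs = stream if stream is not None else _RandStream(rng)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    demes = [[] for _ in range(n_demes)]
    node = 0
    for d, k in enumerate(sample_sizes):
        for _ in range(k):
            demes[d].append(node)
            node += 1
    next_node = n
    t = 0.0
    merged = n_demes == 1 or split_time == 0.0
    if merged and n_demes > 1:
        pool = [x for dd in demes for x in dd]
        demes = [pool]

    def pop_random(lst):
        i = rs.integer(len(lst))
        lst[i], lst[-1] = lst[-1], lst[i]
        return lst.pop()

    n_live = n
    while n_live > 1:
        if merged:
            pool = demes[0]
            pool_size = deme_sizes[0] if n_demes == 1 else ancestral_size
            k = len(pool)
            t += rs.exponential() * pool_size / (k * (k - 1))
            a, b = pop_random(pool), pop_random(pool)
            parent[a] = parent[b] = next_node
            node_time[next_node] = t
            pool.append(next_node)
            next_node += 1
            n_live -= 1
            continue

        coal_rates = [len(demes[d]) * (len(demes[d]) - 1) / deme_sizes[d]
                      for d in range(n_demes)]
        mig_rate = migration_rate * n_live
        total = sum(coal_rates) + mig_rate
        if total == 0.0:
            t = split_time
        else:
            dt = rs.exponential() / total
            if t + dt >= split_time:
                t = split_time
            else:
                t += dt
                u = rs.uniform() * total
                if u < mig_rate:
                    # migrating lineage uniform over live lineages
                    pick = rs.integer(n_live)
                    src = 0
                    while pick >= len(demes[src]):
                        pick -= len(demes[src])
                        src += 1
                    others = [d for d in range(n_demes) if d != src]
                    dst = others[rs.integer(len(others))]
                    demes[dst].append(pop_random(demes[src]))
                else:
                    u -= mig_rate
                    for d in range(n_demes):
                        if u < coal_rates[d]:
                            a, b = pop_random(demes[d]), pop_random(demes[d])
                            parent[a] = parent[b] = next_node
                            node_time[next_node] = t
                            demes[d].append(next_node)
                            next_node += 1
                            n_live -= 1
                            break
                        u -= coal_rates[d]
                continue
        # reached the split: merge every lineage into the ancestral pool
        merged = True
        pool = [x for dd in demes for x in dd]
        demes = [pool] + [[] for _ in range(n_demes - 1)]

    return parent[:next_node], node_time[:next_node]


def _drop_mutations(rng, parent, node_time, n_leaves, theta):
    """Infinite-sites mutations at rate theta per unit total branch length;
    returns (haplotype matrix, sorted positions in [0,1])."""
    n_nodes = len(parent)
    branch = np.zeros(n_nodes)
    has_parent = parent >= 0
    branch[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    total = branch.sum()
    n_mut = rng.poisson(theta * total)
    if n_mut == 0:
        return np.zeros((n_leaves, 0), dtype=np.uint8), np.array([])
    carriers = rng.choice(n_nodes, size=n_mut, p=branch / total)
    positions = rng.uniform(0, 1, size=n_mut)
    order = np.argsort(positions)
    carriers = carriers[order]
    # descendant leaves per mutated branch, gathered by explicit-stack DFS
    # (cheaper than full per-node mask tables for large samples)
    first_child = np.full(n_nodes, -1, dtype=np.int64)
    sibling = np.full(n_nodes, -1, dtype=np.int64)
    for child in range(n_nodes):
        p = parent[child]
        if p >= 0:
            sibling[child] = first_child[p]
            first_child[p] = child
    hap = np.zeros((n_leaves, n_mut), dtype=np.uint8)
    cache = {}
    for m, node in enumerate(carriers):
        leaves = cache.get(node)
        if leaves is None:
            stack = [node]
            acc = []
            while stack:
                v = stack.pop()
                if v < n_leaves:
                    acc.append(v)
                c = first_child[v]
                while c >= 0:
                    stack.append(c)
                    c = sibling[c]
            leaves = np.array(acc, dtype=np.int64)
            cache[node] = leaves
        hap[leaves, m] = 1
    return hap, positions[order]


def simulate_neutral_iwm(model: IWMModel, n_replicates, seed):
    """Neutral IWM coalescent samples; reproducible given ``seed``.

    Returns a list of :class:`HaplotypeSample`, one per replicate.  With
    ρ > 0 the locus is split into independent blocks (θ divided evenly,
    block positions mapped into their sub-interval of [0,1]).
    """
    rng = np.random.default_rng(seed)
    stream = _RandStream(rng)
    blocks = resolve_blocks(model)
    out = []
    for rep in range(n_replicates):
        haps, poss = [], []
        for b in range(blocks):
            parent, node_time = _simulate_tree(
                rng, model.sample_sizes, model.deme_sizes, model.split_time,
                model.migration_rate, model.ancestral_size, stream=stream,
            )
            h, p = _drop_mutations(rng, parent, node_time,
                                   sum(model.sample_sizes), model.theta / blocks)
            haps.append(h)
            poss.append((b + p) / blocks)
        out.append(
            HaplotypeSample(
                np.hstack(haps), np.concatenate(poss), tuple(model.sample_sizes),
                seed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Forward Wright–Fisher sweep simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepSimConfig:
    """Forward sweep simulation settings.

    ``n_diploid`` is the per-deme diploid size N; selection is additive with
    per-copy coefficient ``s`` acting in ``focal_deme`` only.  ``mu_per_bp``
    and ``recomb_per_bp`` are per-generation rates.  Sampling happens at
    fixation of the beneficial allele in the focal deme (or at
    ``max_generations``, whichever comes first).
    """

    n_diploid: int = 500
    s: float = 0.1
    sweep_position: int = 500_000
    locus_length: int = 1_000_000
    mu_per_bp: float = 2.5e-7
    recomb_per_bp: float = 5e-7
    focal_deme: int = 0
    sample_sizes: tuple = (15, 15)      # diploids per deme to sample
    max_generations: int = 100_000
    max_restarts: int = 10_000

    def __post_init__(self):
        if self.s < 0:
            raise ValidationError("s must be >= 0")
        if not (0 < self.sweep_position < self.locus_length):
            raise ValidationError("sweep_position must lie inside the locus")


def _init_forward_population(cfg, background, rng):
    """Initial 2N-per-deme haplotype matrix seeded from the neutral coalescent."""
    n_demes = 1 if background is None else len(background.sample_sizes)
    rows_per_deme = 2 * cfg.n_diploid
    if background is None:
        matrix = np.zeros((n_demes * rows_per_deme, 0), dtype=np.uint8)
        positions = np.array([], dtype=np.int64)
    else:
        model = replace(background, sample_sizes=tuple([rows_per_deme] * n_demes),
                        locus_length=cfg.locus_length)
        sample = simulate_neutral_iwm(model, 1, int(rng.integers(2**31)))[0]
        positions = _relative_to_bp(sample.positions, cfg.locus_length)
        matrix = sample.haplotypes.astype(np.uint8)
    return matrix, positions, n_demes


def _crossover_gamete(rng, h1, h2, positions, n_cross, locus_length):
    breaks = np.sort(rng.uniform(0, locus_length, size=n_cross))
    parity = np.searchsorted(breaks, positions) % 2
    first = rng.integers(2)
    a, b = (h1, h2) if first == 0 else (h2, h1)
    return np.where(parity == 0, a, b)


def simulate_sweep(cfg: SweepSimConfig, background: IWMModel = None, seed=0,
                   condition_on_fixation=True):
    """Forward Wright–Fisher simulation of a selective sweep.

    Returns ``(sample, info)``: a :class:`HaplotypeSample` drawn at the end
    (positions relative, sweep site recorded) and a dict with the fixation
    outcome, restart count and generations elapsed.  With
    ``condition_on_fixation`` the run restarts from the same initial
    population whenever the beneficial allele is lost (capped at
    ``max_restarts``); without it, a single trajectory is run to absorption
    — the branch used to check the neutral fixation probability 1/(2N).
    """
    rng = np.random.default_rng(seed)
    matrix0, positions0, n_demes = _init_forward_population(cfg, background, rng)
    if cfg.focal_deme >= n_demes:
        raise ValidationError("focal_deme outside the demography")
    N = cfg.n_diploid
    rows = 2 * N
    L = cfg.locus_length
    mu_total = cfg.mu_per_bp * L
    r_total = cfg.recomb_per_bp * L
    fast_path = matrix0.shape[1] == 0 and mu_total == 0.0

    restarts = 0
    while True:
        if fast_path:
            fixed, gens = _fast_trajectory(rng, N, cfg.s, cfg.max_generations)
            matrix = np.zeros((n_demes * rows, 1), dtype=np.uint8)
            positions = np.array([cfg.sweep_position], dtype=np.int64)
            if fixed:
                matrix[cfg.focal_deme * rows:(cfg.focal_deme + 1) * rows, 0] = 1
        else:
            fixed, gens, matrix, positions = _forward_run(
                rng, cfg, matrix0, positions0, n_demes, mu_total, r_total
            )
        if fixed or not condition_on_fixation:
            break
        restarts += 1
        if restarts >= cfg.max_restarts:
            raise ValidationError(
                "conditioning on fixation exceeded max_restarts; "
                "increase s (larger 2Ns) or max_restarts"
            )

    sample, sweep_rel = _sample_from_population(
        rng, cfg, matrix, positions, n_demes, seed
    )
    info = {"fixed": bool(fixed), "restarts": restarts, "generations": gens}
    return sample, info


def _fast_trajectory(rng, N, s, max_gen):
    """Allele-count-only WF dynamics (no linked variation)."""
    count = 1
    for gen in range(1, max_gen + 1):
        p = count / (2.0 * N)
        pw = p * (1 + s) / (1 + s * p) if s > 0 else p  # additive selection
        count = rng.binomial(2 * N, pw)
        if count == 0:
            return False, gen
        if count == 2 * N:
            return True, gen
    return False, max_gen


def _forward_run(rng, cfg, matrix0, positions0, n_demes, mu_total, r_total):
    """One conditioning attempt.  Columns are kept in arrival (not genomic)
    order for speed — crossover parity and pruning are order-independent —
    and sorted once at sampling time.  Returns (fixed, generations, matrix,
    positions) with positions sorted."""
    N = cfg.n_diploid
    rows = 2 * N
    L = cfg.locus_length
    positions = positions0.copy()
    matrix = matrix0.copy()
    # append the beneficial allele as one new column on a random focal haplotype
    sweep_pos = cfg.sweep_position
    while np.any(positions == sweep_pos):  # infinite-sites collision shift
        sweep_pos += 1
    col = np.zeros((matrix.shape[0], 1), dtype=np.uint8)
    col[cfg.focal_deme * rows + rng.integers(rows), 0] = 1
    matrix = np.hstack([matrix, col])
    positions = np.append(positions, sweep_pos)
    sweep_col = matrix.shape[1] - 1

    # double-buffered column store: generations alternate reading one buffer
    # and writing the other, so mutation appends and pruning never reallocate
    total_rows = matrix.shape[0]
    S = matrix.shape[1]
    headroom = max(int(4 * max(total_rows * mu_total, 1) * 8), 512)
    cap = S + headroom
    bufs = [np.zeros((total_rows, cap), dtype=np.uint8),
            np.zeros((total_rows, cap), dtype=np.uint8)]
    posbuf = np.zeros(cap, dtype=np.int64)
    bufs[0][:, :S] = matrix
    posbuf[:S] = positions
    cur = 0

    fixed = None
    for gen in range(1, cfg.max_generations + 1):
        A, B = bufs[cur], bufs[1 - cur]
        pos = posbuf[:S]
        for d in range(n_demes):
            sl = slice(d * rows, (d + 1) * rows)
            dosage = A[sl, sweep_col].reshape(N, 2).sum(axis=1)
            if d == cfg.focal_deme and cfg.s > 0:
                w = 1.0 + cfg.s * dosage
                w = w / w.sum()
                parents = rng.choice(N, size=rows, p=w)   # one gamete per child row
            else:
                parents = rng.integers(0, N, size=rows)
            which = rng.integers(0, 2, size=rows)
            n_cross = rng.poisson(r_total, size=rows)
            first = d * rows + 2 * parents + which
            np.take(A[:, :S], first, axis=0, out=B[sl, :S])
            xg = np.flatnonzero(n_cross)
            if len(xg):
                # batched crossovers: XOR parity of breakpoints along the locus
                max_k = int(n_cross[xg].max())
                parity = np.zeros((len(xg), S), dtype=bool)
                for k in range(max_k):
                    active = n_cross[xg] > k
                    breaks = rng.uniform(0, L, size=len(xg))
                    parity[active] ^= pos[None, :] >= breaks[active, None]
                other = d * rows + 2 * parents[xg] + (1 - which[xg])
                B[sl, :S][xg] = np.where(parity, A[other, :S], B[sl, :S][xg])

        if mu_total > 0:
            n_new = rng.poisson(total_rows * mu_total)
            if n_new:
                new_pos = rng.integers(0, L, size=n_new).astype(np.int64)
                new_pos = np.unique(new_pos[~np.isin(new_pos, pos)])
                k = len(new_pos)
                if S + k > cap:  # rare: grow both buffers
                    cap = S + k + headroom
                    for i in (0, 1):
                        grown = np.zeros((total_rows, cap), dtype=np.uint8)
                        grown[:, :S] = bufs[i][:, :S]
                        bufs[i] = grown
                    posbuf = np.concatenate(
                        [posbuf[:S], np.zeros(cap - S, dtype=np.int64)])
                    A, B = bufs[cur], bufs[1 - cur]
                if k:
                    B[:, S:S + k] = 0
                    B[rng.integers(0, total_rows, size=k),
                      S + np.arange(k)] = 1
                    posbuf[S:S + k] = new_pos
                    S += k

        # prune columns lost or fixed metapopulation-wide (sweep column kept),
        # compacting from B back into A (whose contents are now dead)
        freq = B[:, :S].sum(axis=0, dtype=np.int64)
        keep = (freq > 0) & (freq < total_rows)
        keep[sweep_col] = True
        if not keep.all():
            idx = np.flatnonzero(keep)
            sweep_col = int(keep[:sweep_col].sum())
            np.take(B[:, :S], idx, axis=1, out=A[:, :len(idx)])
            posbuf[:len(idx)] = posbuf[:S][idx]
            S = len(idx)
            cur = cur  # A holds the compacted generation
        else:
            cur = 1 - cur  # B holds the generation unchanged

        live = bufs[cur]
        focal = live[cfg.focal_deme * rows:(cfg.focal_deme + 1) * rows, sweep_col]
        f = int(focal.sum())
        if f == 0:
            fixed = False
            break
        if f == rows:
            fixed = True
            break
    if fixed is None:
        fixed, gen = False, cfg.max_generations
    matrix = bufs[cur][:, :S].copy()
    positions = posbuf[:S].copy()
    order = np.argsort(positions, kind="stable")
    return fixed, gen, matrix[:, order], positions[order]


def _sample_from_population(rng, cfg, matrix, positions, n_demes, seed):
    rows = 2 * cfg.n_diploid
    picks = []
    sizes = []
    for d in range(n_demes):
        k = 2 * cfg.sample_sizes[d] if d < len(cfg.sample_sizes) else 0
        if k:
            # sample whole individuals so haplotype pairs stay intact
            inds = rng.choice(cfg.n_diploid, size=k // 2, replace=False)
            chosen = np.column_stack([2 * inds, 2 * inds + 1]).ravel()
            picks.append(d * rows + chosen)
            sizes.append(k)
    hap = matrix[np.concatenate(picks)]
    seg = (hap.sum(axis=0) > 0) & (hap.sum(axis=0) < hap.shape[0])
    sweep_rel = cfg.sweep_position / cfg.locus_length
    sample = HaplotypeSample(
        hap[:, seg].astype(np.uint8), positions[seg] / cfg.locus_length,
        tuple(sizes), seed, sweep_position=sweep_rel,
    )
    return sample, sweep_rel


# ---------------------------------------------------------------------------
# Calibration of the IWM model to a target F_ST summary
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    model: IWMModel
    grid_report: pd.DataFrame
    fst_distribution: np.ndarray
    envelope_99: float
    discrepancy: float
    converged: bool


def per_locus_fst(sample: HaplotypeSample):
    """Weir–Cockerham F_ST over the whole locus, pairing consecutive
    haplotypes into diploids (ratio of summed components)."""
    table, names = haplotype_sample_to_table(sample, locus_length=1, chrom="sim")
    idx1 = table.sample_indices(names[0])
    idx2 = table.sample_indices(names[1])
    a, b, c = wc_fst_components(table.genotypes, idx1, idx2)
    use = ~np.isnan(a)
    denom = (a + b + c)[use].sum()
    return float(a[use].sum() / denom) if use.any() and denom != 0 else np.nan


def calibrate_iwm_to_fst(
    target,
    split_grid,
    migration_grid,
    template: IWMModel = None,
    n_replicates=100,
    seed=0,
    quantiles=None,
    tolerance=0.05,
):
    """Grid-search fit of (split_time, migration_rate) to a target F_ST summary.

    ``target`` is either an array of observed per-window F_ST values or a
    precomputed mean (float).  Each grid cell simulates ``n_replicates``
    neutral loci and scores the absolute difference of means (or, when
    ``quantiles`` is given, the summed absolute quantile differences).  The
    best cell is returned with its full neutral F_ST distribution and the
    nearest-rank 99th percentile — the neutral envelope against which an
    observed top-1% tail is judged.  ``converged`` is False when even the
    best cell misses the target by more than ``tolerance``.
    """
    from .sweep_caller import empirical_quantile_threshold

    if template is None:
        template = IWMModel()
    target = np.asarray(target, dtype=float).ravel()
    target_mean = float(np.nanmean(target))
    rng = np.random.default_rng(seed)
    rows = []
    best = None
    for st, mig in itertools.product(split_grid, migration_grid):
        model = replace(template, split_time=float(st), migration_rate=float(mig))
        reps = simulate_neutral_iwm(model, n_replicates, int(rng.integers(2**31)))
        fst = np.array([per_locus_fst(s) for s in reps])
        fst = fst[~np.isnan(fst)]
        if quantiles is not None:
            disc = float(np.sum(np.abs(
                np.quantile(fst, quantiles) - np.quantile(target, quantiles)
            )))
        else:
            disc = abs(float(fst.mean()) - target_mean)
        rows.append({"split_time": st, "migration_rate": mig,
                     "mean_fst": float(fst.mean()), "discrepancy": disc})
        if best is None or disc < best[0]:
            best = (disc, model, fst)
    disc, model, fst = best
    return CalibrationResult(
        model=model,
        grid_report=pd.DataFrame(rows),
        fst_distribution=fst,
        envelope_99=float(empirical_quantile_threshold(fst, 0.01)),
        discrepancy=disc,
        converged=disc <= tolerance,
    )


# ---------------------------------------------------------------------------
# Haplotypes → diploid genotype table / VCF
# ---------------------------------------------------------------------------

def _relative_to_bp(positions, locus_length):
    """Scale relative positions to unique sorted integer bp (collisions are
    shifted to the next free bp)."""
    bp = np.floor(np.asarray(positions) * locus_length).astype(np.int64)
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


def _pair_to_dosage(hap):
    if hap.shape[0] % 2:
        raise ValidationError("odd haplotype count cannot be paired into diploids")
    return hap.reshape(hap.shape[0] // 2, 2, -1).sum(axis=1).astype(np.int8)


def haplotype_sample_to_table(sample: HaplotypeSample, locus_length=None,
                              chrom="chr1", pop_names=None):
    """Pair consecutive haplotypes into diploids and build a GenotypeTable.

    Returns ``(table, per_deme_sample_names)``.  DP/MQ are left missing; use
    :func:`haplotypes_to_vcf` when the site-quality filters are in play.
    """
    if locus_length is None:
        locus_length = max(len(sample.positions), 1)
    bp = _relative_to_bp(sample.positions, locus_length)
    names, dosages = [], []
    for d, k in enumerate(sample.sample_sizes):
        pop = pop_names[d] if pop_names else f"pop{d}"
        hap = sample.haplotypes[sample.deme_rows(d)]
        dosages.append(_pair_to_dosage(hap))
        names.append([f"{pop}_{i}" for i in range(k // 2)])
    geno = np.concatenate(dosages, axis=0).T.astype(np.int8)  # (sites, samples)
    flat_names = [n for grp in names for n in grp]
    n_sites = len(bp)
    table = GenotypeTable(
        flat_names, [chrom] * n_sites, bp,
        ["A"] * n_sites, ["T"] * n_sites,
        [np.nan] * n_sites, [np.nan] * n_sites, geno,
    )
    return table, names


def haplotypes_to_vcf(sample: HaplotypeSample, locus_length, chrom="chr1",
                      seed=0, dp_mean=30.0, mq_value=60.0, pop_names=None,
                      dp_override=None, mq_override=None):
    """Render a replicate as VCF text plus a truth table.

    Consecutive haplotype rows within each deme pair into one diploid sample.
    INFO/DP is Poisson(``dp_mean``) and INFO/MQ constant ``mq_value`` unless
    per-site override arrays are given (used to inject degraded-quality sites
    that exercise the filters).  Returns ``(vcf_text, truth_df)``.
    """
    rng = np.random.default_rng(seed)
    table, names = haplotype_sample_to_table(sample, locus_length, chrom, pop_names)
    dp = rng.poisson(dp_mean, size=table.n_sites).astype(float)
    mq = np.full(table.n_sites, float(mq_value))
    if dp_override is not None:
        dp = np.asarray(dp_override, dtype=float)
    if mq_override is not None:
        mq = np.asarray(mq_override, dtype=float)
    table = GenotypeTable(table.samples, table.chroms, table.pos, table.ref,
                          table.alt, dp, mq, table.genotypes)
    text = _render_vcf_text(table)
    rows = []
    for d, grp in enumerate(names):
        pop = pop_names[d] if pop_names else f"pop{d}"
        for s in grp:
            rows.append({"sample": s, "population": pop})
    truth = pd.DataFrame(rows)
    if sample.sweep_position is not None:
        truth.attrs["sweep_position_bp"] = int(sample.sweep_position * locus_length)
    return text, truth


def _render_vcf_text(table: GenotypeTable) -> str:
    import io
    import tempfile
    import os

    from .variants_io import write_vcf

    fd, path = tempfile.mkstemp(suffix=".vcf")
    os.close(fd)
    try:
        write_vcf(table, path)
        with open(path) as fh:
            return fh.read()
    finally:
        os.unlink(path)


# ---------------------------------------------------------------------------
# Whole synthetic genome with planted sweeps
# ---------------------------------------------------------------------------

def make_sweep_genome(
    seed,
    n_chrom=10,
    chrom_length=1_000_000,
    sweep_chroms=(1, 4, 8),
    iwm: IWMModel = None,
    sweep: SweepSimConfig = None,
    sample_diploids=(15, 15),
    pop_names=("low", "high"),
):
    """Two-population genome with planted sweeps in the focal population.

    Neutral chromosomes come from the IWM coalescent; each chromosome listed
    in ``sweep_chroms`` (0-based index) is instead produced by the forward
    simulator with the sweep at the chromosome midpoint.  Returns
    ``(table, popmap, truth)`` where ``truth`` maps chromosome name to the
    planted sweep position (bp) or None.
    """
    rng = np.random.default_rng(seed)
    if iwm is None:
        iwm = IWMModel(
            sample_sizes=tuple(2 * k for k in sample_diploids),
            split_time=0.05, migration_rate=1.0,
            theta=5e-4 * chrom_length, rho=0.0,
            locus_length=chrom_length,
            recomb_blocks=max(1, chrom_length // 5_000),
        )
    if sweep is None:
        n_dip = 500
        sweep = SweepSimConfig(
            n_diploid=n_dip, s=0.1, sweep_position=chrom_length // 2,
            locus_length=chrom_length,
            mu_per_bp=iwm.theta / chrom_length / (4 * n_dip),
            recomb_per_bp=5e-7,
            focal_deme=1, sample_sizes=tuple(sample_diploids),
        )

    tables = []
    truth = {}
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        sub_seed = int(rng.integers(2**31))
        if c in sweep_chroms:
            hap, info = simulate_sweep(sweep, background=iwm, seed=sub_seed)
            truth[chrom] = int(hap.sweep_position * chrom_length)
        else:
            hap = simulate_neutral_iwm(iwm, 1, sub_seed)[0]
            # reduce to the sampled individuals (coalescent already sampled n)
            truth[chrom] = None
        t, _ = haplotype_sample_to_table(hap, chrom_length, chrom, pop_names)
        # site-quality fields as a clean sequencing run would produce them
        t = GenotypeTable(
            t.samples, t.chroms, t.pos, t.ref, t.alt,
            rng.poisson(30.0, size=t.n_sites).astype(float),
            np.full(t.n_sites, 60.0), t.genotypes,
        )
        tables.append(t)

    samples = tables[0].samples
    table = GenotypeTable(
        samples,
        np.concatenate([t.chroms for t in tables]),
        np.concatenate([t.pos for t in tables]),
        np.concatenate([t.ref for t in tables]),
        np.concatenate([t.alt for t in tables]),
        np.concatenate([t.dp for t in tables]),
        np.concatenate([t.mq for t in tables]),
        np.concatenate([t.genotypes for t in tables], axis=0),
    )
    assignments = {}
    for s in samples:
        assignments[s] = s.rsplit("_", 1)[0]
    altitudes = {pop_names[0]: 100.0, pop_names[1]: 2600.0}
    popmap = PopulationMap(assignments, altitudes)
    return table, popmap, truth


def synthetic_gene_annotations(n_chrom=10, chrom_length=1_000_000,
                               spacing=50_000, gene_length=20_000):
    """Evenly spaced synthetic gene models for annotating called segments."""
    rows = []
    gid = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        for start in range(0, chrom_length - gene_length, spacing):
            rows.append({"chrom": chrom, "start": start,
                         "end": start + gene_length, "strand": "+",
                         "gene_id": f"g{gid:05d}", "gene_name": f"g{gid:05d}"})
            gid += 1
    return GeneAnnotation(pd.DataFrame(rows))
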