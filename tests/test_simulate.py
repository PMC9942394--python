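import numpy as np
import pytest
from scipy.stats import chi2_contingency

import sweepscan as ss
from sweepscan.simulate import per_locus_fst, _relative_to_bp
from sweepscan.variants_io import ValidationError, read_vcf


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


class TestNeutralCoalescent:
    def test_watterson_and_pairwise_expectations(self):
        # n=10, theta=5: E[S] = theta*a9 = 14.145, E[pi] = theta = 5
        model = ss.IWMModel(sample_sizes=(10,), split_time=0.0,
                            migration_rate=0.0, theta=5.0, locus_length=1000)
        reps = ss.simulate_neutral_iwm(model, 800, seed=101)
        S = np.array([r.segsites for r in reps])
        pi = np.array([r.pairwise_diversity() for r in reps])
        for obs, expect in ((S, 5 * harmonic(10)), (pi, 5.0)):
            se = obs.std(ddof=1) / np.sqrt(len(obs))
            assert abs(obs.mean() - expect) < 3 * se

    def test_degenerate_demography_is_panmictic(self):
        model = ss.IWMModel(sample_sizes=(20, 20), split_time=0.0,
                            migration_rate=0.0, theta=20.0)
        fst = np.array([per_locus_fst(s)
                        for s in ss.simulate_neutral_iwm(model, 150, seed=7)])
        assert abs(np.nanmean(fst)) < 0.02

    def test_reproducible_given_seed(self):
        model = ss.IWMModel(sample_sizes=(6, 6), theta=10.0)
        a = ss.simulate_neutral_iwm(model, 3, seed=42)
        b = ss.simulate_neutral_iwm(model, 3, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.haplotypes, y.haplotypes)
            np.testing.assert_array_equal(x.positions, y.positions)

    def test_invalid_demography_rejected(self):
        with pytest.raises(ValidationError):
            ss.IWMModel(sample_sizes=(4, 4), split_time=-1.0)
        with pytest.raises(ValidationError):
            ss.IWMModel(sample_sizes=(4, 4), theta=0.0)


class TestMsprimeCrossOracle:
    """The simulator against msprime at matched parameters (ms scaling:
    time in 4N0 generations, theta = 4N0*mu*L, migration = 4N0*m)."""

    def _msprime_sfs_and_fst(self, n_reps, pick):
        import msprime

        N, M, st, theta, L = 1000, 1.0, 0.25, 10.0, 10_000
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=N)
        dem.add_population(name="B", initial_size=N)
        dem.add_population(name="anc", initial_size=N)
        dem.set_symmetric_migration_rate(["A", "B"], M / (4 * N))
        dem.add_population_split(time=st * 4 * N, derived=["A", "B"],
                                 ancestral="anc")
        sfs = np.zeros(19)
        fsts = []
        for seed in range(1, n_reps + 1):
            ts = msprime.sim_ancestry(samples={"A": 5, "B": 5}, demography=dem,
                                      sequence_length=L, random_seed=seed,
                                      ploidy=2)
            ts = msprime.sim_mutations(ts, rate=theta / (4 * N * L),
                                       random_seed=seed + 10**6,
                                       discrete_genome=False)
            g = ts.genotype_matrix()
            counts = g.sum(axis=1)
            counts = counts[(counts > 0) & (counts < 20)]
            if len(counts):
                sfs[pick(counts) - 1] += 1
            samp = ss.HaplotypeSample(g.T.astype(np.uint8),
                                      ts.sites_position / L, (10, 10), seed)
            fsts.append(per_locus_fst(samp))
        return sfs, np.nanmean(fsts)

    def test_sfs_and_fst_match(self):
        # SNP counts within one replicate share a genealogy, so the SFS is
        # compared on one randomly chosen segregating site per replicate —
        # independent draws, as the chi-square homogeneity test requires
        n_reps = 800
        pick_rng = np.random.default_rng(99)

        def pick(counts):
            return counts[pick_rng.integers(len(counts))]

        model = ss.IWMModel(sample_sizes=(10, 10), split_time=0.25,
                            migration_rate=1.0, theta=10.0, locus_length=10_000)
        reps = ss.simulate_neutral_iwm(model, n_reps, seed=5)
        sfs_mine = np.zeros(19)
        for r in reps:
            counts = r.haplotypes.sum(axis=0)
            counts = counts[(counts > 0) & (counts < 20)]
            if len(counts):
                sfs_mine[pick(counts) - 1] += 1
        fst_mine = np.nanmean([per_locus_fst(s) for s in reps])
        sfs_ref, fst_ref = self._msprime_sfs_and_fst(n_reps, pick)
        # pool tail bins so expected counts stay comfortably above 5
        bins = [0, 1, 2, 4, 7, 11, 19]
        mine = np.add.reduceat(sfs_mine, bins[:-1])
        ref = np.add.reduceat(sfs_ref, bins[:-1])
        _, p, _, _ = chi2_contingency(np.vstack([mine, ref]))
        assert p > 0.01
        assert fst_mine == pytest.approx(fst_ref, abs=0.03)


class TestSweepSimulator:
    def test_neutral_fixation_probability(self):
        # allele tracked without selection: P(fix) ~ 1/(2N), binomial 3-SE band
        N, runs = 50, 4000
        cfg = ss.SweepSimConfig(n_diploid=N, s=0.0, mu_per_bp=0.0,
                                locus_length=1000, sweep_position=500,
                                sample_sizes=(2,))
        fixed = 0
        for seed in range(runs):
            _, info = ss.simulate_sweep(cfg, background=None, seed=seed,
                                        condition_on_fixation=False)
            fixed += info["fixed"]
        p = 1.0 / (2 * N)
        se = np.sqrt(p * (1 - p) / runs)
        assert abs(fixed / runs - p) < 3 * se

    def test_same_seed_same_haplotypes(self):
        model = ss.IWMModel(sample_sizes=(20,), theta=50.0,
                            locus_length=100_000, recomb_blocks=10)
        cfg = ss.SweepSimConfig(n_diploid=50, s=0.5, locus_length=100_000,
                                sweep_position=50_000, mu_per_bp=1e-6,
                                recomb_per_bp=5e-7, sample_sizes=(8,))
        a, _ = ss.simulate_sweep(cfg, background=model, seed=9)
        b, _ = ss.simulate_sweep(cfg, background=model, seed=9)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_allclose(a.positions, b.positions)

    def test_diversity_trough_at_sweep_site(self):
        # hitchhiking: central 40 kb diversity below the outer 40 kb flanks
        L = 1_000_000
        model = ss.IWMModel(sample_sizes=(30,), split_time=0.0,
                            migration_rate=0.0, theta=5e-4 * L,
                            locus_length=L, recomb_blocks=200)
        cfg = ss.SweepSimConfig(n_diploid=500, s=0.1, locus_length=L,
                                sweep_position=L // 2, mu_per_bp=2.5e-7,
                                recomb_per_bp=5e-7, focal_deme=0,
                                sample_sizes=(15,))
        n_reps, trough = 12, 0
        for seed in range(n_reps):
            hap, info = ss.simulate_sweep(cfg, background=model, seed=seed)
            assert info["fixed"]
            bp = hap.positions * L
            n = hap.haplotypes.shape[0]

            def pi_in(lo, hi):
                cols = (bp >= lo) & (bp < hi)
                k = hap.haplotypes[:, cols].sum(axis=0)
                return np.sum(k * (n - k)) / (n * (n - 1) / 2) / (hi - lo)

            center = pi_in(L // 2 - 20_000, L // 2 + 20_000)
            flanks = (pi_in(0, 40_000) + pi_in(L - 40_000, L)) / 2
            trough += center < flanks
        assert trough >= 10  # ≥ ~90% of replicates show the trough

    def test_restart_cap_raises(self):
        cfg = ss.SweepSimConfig(n_diploid=200, s=1e-6, mu_per_bp=0.0,
                                locus_length=1000, sweep_position=500,
                                max_restarts=5, max_generations=10_000,
                                sample_sizes=(2,))
        with pytest.raises(ValidationError, match="max_restarts"):
            ss.simulate_sweep(cfg, background=None, seed=3)


class TestHaplotypesToVcf:
    def test_pairing_and_truth_table(self):
        hap = np.array([[1, 0], [1, 1], [0, 0], [0, 1]], dtype=np.uint8)
        sample = ss.HaplotypeSample(hap, np.array([0.2, 0.6]), (2, 2), 0)
        text, truth = ss.haplotypes_to_vcf(sample, locus_length=100, seed=1)
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(lines) == 2
        assert list(truth["population"]) == ["pop0", "pop1"]
        # first diploid pairs rows 0+1 -> dosages 2 then 1
        assert lines[0].split("\t")[9] == "1/1"
        assert lines[1].split("\t")[9] == "0/1"

    def test_position_collision_shifts_to_next_free_bp(self):
        bp = _relative_to_bp(np.array([0.51, 0.514, 0.518]), 100)
        assert list(bp) == [51, 52, 53]

    def test_full_loop_diversity_identity(self, tmp_path):
        # simulate -> VCF -> read_vcf -> windowed_pi equals the diversity
        # computed directly on the haplotypes, same denominator
        L = 10_000
        model = ss.IWMModel(sample_sizes=(12,), split_time=0.0,
                            migration_rate=0.0, theta=8.0, locus_length=L)
        hap = ss.simulate_neutral_iwm(model, 1, seed=33)[0]
        text, _ = ss.haplotypes_to_vcf(hap, locus_length=L, seed=4)
        path = tmp_path / "sim.vcf"
        path.write_text(text)
        table, _ = read_vcf(path)
        pi = ss.windowed_pi(table, table.samples, [("chr1", 0, L)])[0]
        n = hap.haplotypes.shape[0]
        k = hap.haplotypes.sum(axis=0)
        direct = np.sum(k * (n - k)) / (n * (n - 1) / 2) / L
        assert pi == pytest.approx(direct, abs=1e-10)


class TestCalibration:
    def test_degenerate_target_selects_panmixia(self):
        res = ss.calibrate_iwm_to_fst(
            np.zeros(50), split_grid=[0.0, 0.5], migration_grid=[0.0],
            template=ss.IWMModel(sample_sizes=(20, 20), theta=20.0),
            n_replicates=60, seed=2)
        assert res.model.split_time == 0.0
        assert abs(res.grid_report.iloc[0]["mean_fst"]) < 0.02
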