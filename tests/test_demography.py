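"""Migration topologies, prior sampling, and coalescent simulator behaviour,
including an independent msprime oracle for the structured coalescent."""

import numpy as np
import pytest

from slopeflow._coalescent import simulate_counts
from slopeflow.demography import (
    DemographicModel,
    PriorSpec,
    build_migration_matrix,
    dataset_sumstats,
    sample_prior,
    simulate_counts_dataset,
    simulate_dataset,
    sumstat_names,
    sumstats_from_counts,
)


class TestMigrationMatrix:
    def test_stepping_stone_adjacency(self):
        M = build_migration_matrix("ss", 3, 0.01)
        nonzero = {(i, j) for i, j in zip(*np.nonzero(M))}
        assert nonzero == {(0, 1), (1, 0), (1, 2), (2, 1)}
        assert np.allclose(M[M > 0], 0.01)

    def test_island_all_pairs(self):
        M = build_migration_matrix("am", 4, 0.02)
        off = M[~np.eye(4, dtype=bool)]
        assert len(off) == 12 and np.allclose(off, 0.02)

    def test_source_sink_doubles_top_edges(self):
        m = 0.01
        M = build_migration_matrix("sk", 5, m)
        A = build_migration_matrix("am", 5, m)
        # backward: lineages sampled in the top deme jump to each donor at 2m
        np.testing.assert_allclose(M[4, :4], 2 * m)
        np.testing.assert_allclose(M[:4, :], A[:4, :])

    def test_downslope_reverses_to_upward_lineage_movement(self):
        M = build_migration_matrix("dn", 4, 0.01)
        nonzero = {(i, j) for i, j in zip(*np.nonzero(M))}
        assert nonzero == {(0, 1), (1, 2), (2, 3)}

    def test_upslope_reverses_to_downward_lineage_movement(self):
        M = build_migration_matrix("up", 4, 0.01)
        nonzero = {(i, j) for i, j in zip(*np.nonzero(M))}
        assert nonzero == {(1, 0), (2, 1), (3, 2)}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_migration_matrix("xx", 3, 0.01)
        with pytest.raises(ValueError):
            build_migration_matrix("sk", 2, 0.01)
        with pytest.raises(ValueError):
            build_migration_matrix("ss", 3, 0.0)


class TestPrior:
    def test_support(self, rng):
        prior = PriorSpec()
        for _ in range(1000):
            m, Ne = sample_prior(prior, 4, rng)
            assert 0.001 <= m <= 0.05
            assert np.all((200 <= Ne) & (Ne <= 10_000))

    def test_log_uniform_median(self):
        rng = np.random.default_rng(5)
        draws = np.concatenate(
            [sample_prior(PriorSpec(), 5, rng)[1] for _ in range(20_000)]
        )
        assert np.median(draws) == pytest.approx(np.sqrt(200 * 10_000), rel=0.02)

    def test_seeded_reproducibility(self):
        a = sample_prior(PriorSpec(), 3, np.random.default_rng(7))
        b = sample_prior(PriorSpec(), 3, np.random.default_rng(7))
        assert a[0] == b[0] and np.array_equal(a[1], b[1])


class TestSimulator:
    def test_single_deme_all_polymorphic(self, rng):
        model = DemographicModel("ss", Ne=np.array([500.0, 500.0]), m=0.01)
        # single-deme case via a 1-deme island is disallowed (d>=2); check
        # polymorphism conditioning on the pooled sample instead
        counts, het = simulate_counts_dataset(model, np.array([5, 5]), 100, rng)
        total = counts.sum(axis=1)
        assert np.all((total >= 1) & (total <= 19))

    def test_true_single_deme_counts(self, rng):
        counts, het = simulate_counts(
            1, 150, np.array([12]), np.array([800.0]), np.zeros((1, 1))
        )
        assert counts.shape == (150, 1)
        assert np.all((counts[:, 0] >= 1) & (counts[:, 0] < 12))

    def test_seeded_reproducibility(self):
        args = (np.array([6, 6]), np.array([400.0, 900.0]))
        model = DemographicModel("ss", Ne=args[1], m=0.02)
        c1, h1 = simulate_counts_dataset(model, args[0], 50, np.random.default_rng(3))
        c2, h2 = simulate_counts_dataset(model, args[0], 50, np.random.default_rng(3))
        assert np.array_equal(c1, c2) and np.array_equal(h1, h2)

    def test_non_communicating_demes_error(self):
        with pytest.raises(RuntimeError, match="common ancestor"):
            simulate_counts(
                1, 5, np.array([4, 4]), np.array([100.0, 100.0]), np.zeros((2, 2))
            )

    def test_island_matches_pairwise_closed_form(self, rng):
        # d-island coalescent with per-edge backward rate m: pairwise
        # (two-deme Nei) F_ST = 1/(1 + 8 N d m)
        N, d, m = 1000.0, 4, 0.005
        model = DemographicModel("am", Ne=np.full(d, N), m=m)
        samples = np.full(d, 10)
        vals = []
        for _ in range(20):
            c, h = simulate_counts_dataset(model, samples, 200, rng)
            s = sumstats_from_counts(c, h, samples)
            vals.append(np.mean(s[-6:]))
        expected = 1.0 / (1.0 + 8.0 * N * d * m)
        assert np.mean(vals) == pytest.approx(expected, rel=0.25)

    def test_doubling_ne_at_fixed_nem_leaves_fst_stable(self, rng):
        samples = np.full(3, 8)

        def mean_fst(ne, m, reps=25):
            model = DemographicModel("ss", Ne=np.full(3, ne), m=m)
            out = []
            for _ in range(reps):
                c, h = simulate_counts_dataset(model, samples, 200, rng)
                out.append(np.mean(sumstats_from_counts(c, h, samples)[-3:]))
            return np.mean(out), np.std(out) / np.sqrt(reps)

        f1, se1 = mean_fst(1000.0, 0.01)
        f2, se2 = mean_fst(2000.0, 0.005)
        assert abs(f1 - f2) < 4.0 * (se1 + se2)


class TestSumstats:
    def test_names_and_length(self):
        names = sumstat_names(4)
        assert len(names) == 2 + 4 + 6 + 6
        assert names[0] == "H_total"

    def test_hand_computed_vector(self):
        # 2 demes x 2 diploids; loci: [fixed diff, shared singleton, monomorphic]
        counts = np.array([[4, 0], [1, 1], [0, 0]])
        het = np.array([[0, 0], [1, 1], [0, 0]])
        samples = np.array([2, 2])
        s = sumstats_from_counts(counts, het, samples)
        names = sumstat_names(2)
        vec = dict(zip(names, s))
        assert vec["S_total"] == 2.0  # locus 3 is monomorphic
        assert vec["S_pop1"] == 1.0 and vec["S_pop2"] == 1.0
        # pi: locus1 contributes (4*4+0)/16 = 1, locus2 (1*3+1*3)/16 = .375
        assert vec["pi_1_2"] == pytest.approx(1.0 + 0.375)

    def test_order_invariance(self, rng):
        model = DemographicModel("ss", Ne=np.array([500.0, 500.0, 500.0]), m=0.02)
        g, hap, pm = simulate_dataset(model, np.array([4, 4, 4]), 60, rng)
        s1 = dataset_sumstats(g, pm)
        perm = rng.permutation(g.n_samples)
        from slopeflow.genotype_io import GenotypeMatrix

        g2 = GenotypeMatrix(
            sample_ids=[g.sample_ids[i] for i in perm],
            locus_ids=list(g.locus_ids),
            calls=g.calls[perm, :],
        )
        np.testing.assert_allclose(dataset_sumstats(g2, pm), s1, atol=1e-12)

    def test_monomorphic_matrix(self):
        from conftest import make_matrix

        g, pm = make_matrix({"A": 3, "B": 3}, np.zeros((6, 4), dtype=np.int8))
        s = dataset_sumstats(g, pm)
        vec = dict(zip(sumstat_names(2), s))
        assert vec["S_total"] == 0 and vec["pi_1_2"] == 0

    def test_simulated_genotypes_consistent_with_counts(self, rng):
        model = DemographicModel("am", Ne=np.full(3, 800.0), m=0.01)
        g, hap, pm = simulate_dataset(model, np.array([5, 5, 5]), 40, rng)
        assert g.n_loci == 40
        assert np.array_equal(g.calls, (hap[0::2] + hap[1::2]))
        s = dataset_sumstats(g, pm)
        assert np.all(np.isfinite(s))


class TestStructuredOracle:
    """Cross-check counts against msprime's structured coalescent."""

    @staticmethod
    def _msprime_counts(n_loci, samples, Ne, M, seed):
        import msprime

        d = len(samples)
        demography = msprime.Demography()
        for k in range(d):
            demography.add_population(name=f"p{k}", initial_size=Ne[k])
        demography.migration_matrix = np.asarray(M)
        rng = np.random.default_rng(seed)
        reps = msprime.sim_ancestry(
            samples={f"p{k}": int(samples[k]) for k in range(d)},
            demography=demography,
            sequence_length=1,
            num_replicates=n_loci,
            random_seed=seed,
        )
        counts = np.zeros((n_loci, d), dtype=int)
        pop_of = None
        for i, ts in enumerate(reps):
            tree = ts.first()
            if pop_of is None:
                pop_of = np.array(
                    [ts.node(u).population for u in ts.samples()]
                )
            nodes = [
                (u, tree.branch_length(u))
                for u in tree.nodes()
                if tree.parent(u) != -1
            ]
            lens = np.array([b for _, b in nodes])
            pick = rng.choice(len(nodes), p=lens / lens.sum())
            below = list(tree.samples(nodes[pick][0]))
            for u in below:
                counts[i, pop_of[u]] += 1
        return counts

    def test_island_summaries_match_msprime(self, rng):
        samples = np.array([6, 6, 6])
        Ne = np.array([800.0, 800.0, 800.0])
        M = build_migration_matrix("am", 3, 0.004)
        n = 800
        ours, _ = simulate_counts_dataset(
            DemographicModel("am", Ne=Ne, m=0.004), samples, n, rng
        )
        theirs = self._msprime_counts(n, samples, Ne, M, seed=11)
        for k in range(3):
            fo = np.minimum(ours[:, k], 12 - ours[:, k])
            ft = np.minimum(theirs[:, k], 12 - theirs[:, k])
            # compare folded per-deme spectra means and monomorphic shares
            se = np.sqrt(fo.var() / n + ft.var() / n)
            assert abs(fo.mean() - ft.mean()) < 4 * se + 1e-9
            p0o, p0t = np.mean(fo == 0), np.mean(ft == 0)
            se0 = np.sqrt(p0o * (1 - p0o) / n + p0t * (1 - p0t) / n)
            assert abs(p0o - p0t) < 4 * se0 + 1e-9


class TestModelInvariants:
    def test_stepping_stone_fst_increases_with_separation(self, rng):
        model = DemographicModel("ss", Ne=np.full(4, 1000.0), m=0.01)
        samples = np.full(4, 8)
        names = sumstat_names(4)
        idx = {nm: i for i, nm in enumerate(names)}
        by_step = {1: [], 2: [], 3: []}
        for _ in range(20):
            c, h = simulate_counts_dataset(model, samples, 200, rng)
            s = sumstats_from_counts(c, h, samples)
            for a in range(4):
                for b in range(a + 1, 4):
                    by_step[b - a].append(s[idx[f"fst_{a + 1}_{b + 1}"]])
        m1, m2, m3 = (np.mean(by_step[k]) for k in (1, 2, 3))
        assert m1 < m2 < m3

    def test_source_sink_low_divergence_to_sink(self, rng):
        model = DemographicModel("sk", Ne=np.full(4, 1000.0), m=0.005)
        samples = np.full(4, 8)
        names = sumstat_names(4)
        idx = {nm: i for i, nm in enumerate(names)}
        sink, donors = [], []
        for _ in range(20):
            c, h = simulate_counts_dataset(model, samples, 200, rng)
            s = sumstats_from_counts(c, h, samples)
            for a in range(4):
                for b in range(a + 1, 4):
                    val = s[idx[f"fst_{a + 1}_{b + 1}"]]
                    (sink if b == 3 else donors).append(val)
        assert np.mean(sink) < np.mean(donors)

    def test_island_fst_decreases_with_m(self, rng):
        samples = np.full(4, 8)
        means = []
        for m in (0.001, 0.01, 0.05):
            model = DemographicModel("am", Ne=np.full(4, 1000.0), m=m)
            vals = []
            for _ in range(20):
                c, h = simulate_counts_dataset(model, samples, 200, rng)
                vals.append(np.mean(sumstats_from_counts(c, h, samples)[-6:]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_simulated_data_reenter_pipeline(self, rng):
        from slopeflow.popgen_stats import locus_stats, overall_stats, pairwise_fst

        model = DemographicModel("ss", Ne=np.full(3, 600.0), m=0.01)
        g, _hap, pm = simulate_dataset(model, np.array([6, 6, 6]), 80, rng)
        ov = overall_stats(locus_stats(g, pm))
        assert -0.05 <= ov.F_ST <= 1.0
        assert np.all(np.isfinite(pairwise_fst(g, pm).fst.to_numpy()))
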