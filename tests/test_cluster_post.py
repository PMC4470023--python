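import numpy as np
import pytest

from msatpop import (
    SimConfig,
    allele_frequencies,
    assign_breeds,
    breed_pca,
    mean_q_matrix,
    read_q_runs,
    run_similarity,
    select_consensus_runs,
    simulate_breeds,
    simulate_q_runs,
    write_q_runs,
)
from msatpop.simulate import QRunSet


def runset(*mats):
    mats = [np.asarray(m, dtype=float) for m in mats]
    n, K = mats[0].shape
    return QRunSet(mats, [f"i{k}" for k in range(n)], K)


class TestRunSimilarity:
    def test_identical_runs_score_one(self):
        q = np.random.default_rng(0).dirichlet(np.ones(3), size=12)
        sim = run_similarity(runset(q, q.copy()), method="exact")
        assert sim.ssc[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["exact", "greedy"])
    def test_column_permutation_invariance(self, method):
        rng = np.random.default_rng(1)
        q = rng.dirichlet(np.ones(4), size=20)
        for _ in range(5):
            perm = rng.permutation(4)
            sim = run_similarity(runset(q, q[:, perm]), method=method)
            assert sim.ssc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_greedy_bounded_by_exact(self):
        """On replicate-run pairs (shared structure, label switching,
        run-to-run noise) the greedy alignment almost always attains the
        exact K!-enumeration optimum, and never exceeds it."""
        agree = 0
        for seed in range(100):
            runs, _, _ = simulate_q_runs(
                2, 20, 4, noise=0.4, label_shuffle=True, seed=seed)
            e = run_similarity(runs, method="exact").ssc[0, 1]
            g = run_similarity(runs, method="greedy").ssc[0, 1]
            assert g <= e + 1e-12
            agree += np.isclose(g, e)
        assert agree >= 95

    def test_exact_limited_to_small_k(self):
        rng = np.random.default_rng(3)
        q = rng.dirichlet(np.ones(9), size=10)
        with pytest.raises(ValueError, match="K <= 8"):
            run_similarity(runset(q, q), method="exact")

    def test_half_mismatch_hand_value(self):
        # one of two hard-assigned rows disagrees under the best alignment:
        # ||diff||_F = sqrt(2), SSC = 1 - sqrt(2)/sqrt(2 * 2) = 1 - 1/sqrt(2)
        a = np.array([[1.0, 0.0], [1.0, 0.0]])
        b = np.array([[1.0, 0.0], [0.0, 1.0]])
        sim = run_similarity(runset(a, b), method="exact")
        assert sim.ssc[0, 1] == pytest.approx(1 - 1 / np.sqrt(2))


class TestConsensusSelection:
    def test_all_identical_selects_everything(self):
        runs, _, _ = simulate_q_runs(8, 25, 3, noise=0.0, seed=4)
        sim = run_similarity(runs, method="exact")
        assert select_consensus_runs(sim) == list(range(8))

    def test_outlier_excluded(self):
        rng = np.random.default_rng(5)
        q = rng.dirichlet(np.ones(3) * 0.2, size=30)
        outlier = rng.dirichlet(np.ones(3), size=30)
        runs = runset(*([q] * 6 + [outlier]))
        sim = run_similarity(runs, method="exact")
        assert select_consensus_runs(sim) == [0, 1, 2, 3, 4, 5]

    def test_mutually_dissimilar_gives_singleton(self):
        rng = np.random.default_rng(6)
        mats = [rng.dirichlet(np.ones(4), size=25) for _ in range(5)]
        sim = run_similarity(runset(*mats), method="exact")
        assert len(select_consensus_runs(sim)) == 1


class TestMeanQMatrix:
    def test_singleton_subset_identity(self):
        runs, _, _ = simulate_q_runs(3, 15, 3, noise=0.5, seed=7)
        sim = run_similarity(runs, method="exact")
        mq = mean_q_matrix(runs, [1], sim)
        assert np.allclose(mq, runs.runs[1])

    def test_permuted_pair_recovers_original(self):
        rng = np.random.default_rng(8)
        q = rng.dirichlet(np.ones(4), size=20)
        rs = runset(q, q[:, [2, 0, 3, 1]])
        sim = run_similarity(rs, method="exact")
        mq = mean_q_matrix(rs, [0, 1], sim)
        assert np.allclose(mq, q, atol=1e-12)

    def test_mean_beats_single_runs(self):
        """Averaging aligned noisy replicates lands closer to the truth
        (Frobenius) than the typical individual run."""
        wins = 0
        for seed in range(10):
            runs, truth, _ = simulate_q_runs(
                10, 40, 4, noise=0.1, label_shuffle=True, seed=100 + seed)
            sim = run_similarity(runs, method="exact")
            subset = select_consensus_runs(sim)
            mq = mean_q_matrix(runs, subset, sim)
            ref = subset[0]
            # align the truth onto the reference run's label order
            tr = run_similarity(
                runset(runs.runs[ref], truth), method="exact")
            truth_aligned = truth[:, tr.permutations[(0, 1)]]
            d_mean = np.linalg.norm(mq - truth_aligned)
            d_single = [np.linalg.norm(runs.runs[j][:, sim.permutations[(ref, j)]]
                                       - truth_aligned) for j in subset]
            wins += d_mean <= min(d_single) + 1e-9 or d_mean < np.median(d_single)
        assert wins >= 9


class TestAssignBreeds:
    def test_block_diagonal_perfect_assignment(self):
        K = 4
        breed_of = np.repeat([f"B{k}" for k in range(K)], 10)
        q = np.zeros((40, K))
        q[np.arange(40), np.repeat(np.arange(K), 10)] = 1.0
        rep = assign_breeds(q, breed_of)
        assert rep.overall_pct == pytest.approx(100.0)
        assert all(v == 100.0 for v in rep.pct_assigned.values())
        assert rep.shared_clusters == []
        assert rep.unassignable == []

    def test_two_breeds_sharing_a_cluster(self):
        breed_of = np.array(["X"] * 10 + ["Y"] * 10 + ["Z"] * 10, dtype=object)
        q = np.zeros((30, 3))
        q[:20, 0] = 1.0   # X and Y pile into cluster 0
        q[20:, 2] = 1.0
        rep = assign_breeds(q, breed_of)
        assert rep.shared_clusters == [(0, ["X", "Y"])]

    def test_uniform_q_scattered_and_deterministic(self):
        breed_of = np.array(["X"] * 6, dtype=object)
        q = np.full((6, 3), 1 / 3)
        rep = assign_breeds(q, breed_of)
        # argmax ties resolve to cluster 0: all six land there -> assigned
        assert rep.cluster_of_breed["X"] == 0
        rep2 = assign_breeds(q, breed_of)
        assert rep.cluster_of_breed == rep2.cluster_of_breed

    def test_scattered_breed_unassignable(self):
        breed_of = np.array(["X"] * 4, dtype=object)
        q = np.eye(4)
        rep = assign_breeds(q, breed_of)
        assert rep.unassignable == ["X"]

    def test_label_invariance_end_to_end(self):
        rng = np.random.default_rng(9)
        breed_of = np.repeat([f"B{k}" for k in range(3)], 12)
        q = rng.dirichlet(np.ones(3) * 0.3, size=36)
        perm = np.array([2, 0, 1])
        r1 = assign_breeds(q, breed_of)
        r2 = assign_breeds(q[:, perm], breed_of)
        assert r1.pct_assigned == r2.pct_assigned
        assert r1.overall_pct == r2.overall_pct

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_breeds(np.full((4, 3), 1 / 3),
                          np.array(["X"] * 4, dtype=object), K=5)


class TestQRunIO:
    def test_round_trip(self, tmp_path):
        runs, _, _ = simulate_q_runs(3, 10, 3, noise=0.1, seed=10)
        paths = write_q_runs(runs, tmp_path)
        back = read_q_runs(paths)
        assert back.K == 3
        for a, b in zip(runs.runs, back.runs):
            assert np.allclose(a, b, atol=1e-6)


class TestBreedPca:
    def test_inertia_sums_to_100(self, small_sim_freq):
        res = breed_pca(small_sim_freq, n_axes=2, n_perm=0)
        assert res.attrs["all_inertia_pct"].sum() == pytest.approx(100.0)

    def test_two_clusters_separate_on_axis_one(self):
        div = [0.02] * 4 + [0.35] * 4
        cfg = SimConfig(n_breeds=8, n_loci=12, alleles_per_locus=(6, 12),
                        sample_sizes=[25] * 8, divergence=div, seed=23)
        ds, _ = simulate_breeds(cfg)
        freq = allele_frequencies(ds)
        res = breed_pca(freq, ds, n_axes=1, n_perm=199, seed=3)
        assert res.p.iloc[0] <= 0.01
        scores = res.attrs["scores"]["axis1"].to_numpy()
        # low-drift breeds cluster tightly, the drifted ones scatter:
        # axis 1 splits the drifted group away from the tight core
        assert np.std(scores[4:]) > np.std(scores[:4])

    def test_panmictic_pool_axis_not_significant(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_breeds=8, n_loci=6, alleles_per_locus=(4, 8),
                            sample_sizes=[15] * 8, divergence=[1e-12] * 8,
                            seed=400 + seed)
            ds, _ = simulate_breeds(cfg)
            freq = allele_frequencies(ds)
            res = breed_pca(freq, ds, n_axes=1, n_perm=99, seed=seed)
            hits += res.p.iloc[0] > 0.05
        assert hits >= 9

    def test_too_few_breeds_rejected(self):
        cfg = SimConfig(n_breeds=2, n_loci=3, sample_sizes=[10] * 2,
                        divergence=[0.1] * 2, seed=1)
        ds, _ = simulate_breeds(cfg)
        with pytest.raises(ValueError):
            breed_pca(allele_frequencies(ds), n_perm=0)
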