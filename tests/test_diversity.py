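import itertools

import numpy as np
import pytest
from scipy import stats as sps

from msatpop import (
    SimConfig,
    allele_frequencies,
    allelic_richness,
    breed_summary,
    estimate_null_allele_freq,
    genic_differentiation_test,
    hwe_test,
    inject_null_alleles,
    sequential_bonferroni,
    simulate_breeds,
)
from msatpop.diversity import _rarefied_richness

from conftest import make_dataset


def enumerate_richness(counts, g):
    """Exhaustive oracle: mean distinct alleles over all g-subsets of the
    allele-copy multiset."""
    copies = [k for k, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(copies)), g))
    distinct = [len({copies[i] for i in sub}) for sub in subsets]
    return sum(distinct) / len(distinct)


class TestBreedSummary:
    def test_closed_form_toy(self):
        ds = make_dataset({"X": [((1, 1),), ((1, 2),)], "Y": [((2, 2),), ((2, 2),)]})
        s = breed_summary(allele_frequencies(ds), ds).per_breed.set_index("breed")
        assert s.loc["X", "ho"] == pytest.approx(0.5)
        assert s.loc["X", "he"] == pytest.approx(0.5)      # (4/3)(1 - 0.625)
        assert s.loc["X", "ae"] == pytest.approx(1.6)

    def test_monomorphic_breed(self):
        ds = make_dataset({"X": [((1, 1),)] * 5, "Y": [((1, 2),)] * 5})
        s = breed_summary(allele_frequencies(ds), ds).per_breed.set_index("breed")
        assert s.loc["X", "he"] == 0.0
        assert s.loc["X", "ho"] == 0.0
        assert s.loc["X", "ae"] == 1.0
        assert s.loc["X", "mna"] == 1.0

    def test_all_missing_locus_excluded_from_means(self):
        ds = make_dataset({
            "X": [((1, 2), (0, 0)), ((1, 2), (0, 0))],
            "Y": [((1, 2), (3, 4)), ((1, 2), (3, 4))],
        })
        s = breed_summary(allele_frequencies(ds), ds)
        x_cells = s.per_cell[s.per_cell.breed == "X"]
        assert len(x_cells) == 1  # locus 2 dropped for X

    def test_unbiased_correction_shrinks_with_n(self):
        """He_unbiased exceeds 1 - sum p^2 and approaches it as n grows."""
        excesses = []
        for n in (5, 50, 500):
            ds = make_dataset({"X": [((1, 2),)] * n, "Y": [((1, 2),)] * n})
            s = breed_summary(allele_frequencies(ds), ds).per_breed
            excesses.append(s.he.iloc[0] - 0.5)
        assert all(e > 0 for e in excesses)
        assert excesses[0] > excesses[1] > excesses[2]

    def test_he_range_tracks_drift_range(self):
        """Wider simulated drift ranges widen the spread of breed He, and
        the least-drifted breed attains the top He."""
        spreads = []
        for fmax in (0.10, 0.45):
            div = np.linspace(0.03, fmax, 8)
            cfg = SimConfig(n_breeds=8, n_loci=12, alleles_per_locus=(10, 15),
                            sample_sizes=[30] * 8, divergence=div, seed=60)
            ds, truth = simulate_breeds(cfg)
            s = breed_summary(allele_frequencies(ds), ds).per_breed
            spreads.append(s.he.max() - s.he.min())
            if fmax == 0.45:
                assert s.he.idxmax() == 0  # breed B01 has the least drift
        assert spreads[1] > spreads[0]


class TestAllelicRichness:
    def test_pair_counts_closed_form(self):
        # counts {A:3, B:1}, g=2: Ar = 1 + (1 - C(3,2)/C(4,2)) = 1.5
        assert _rarefied_richness(np.array([3, 1]), 2) == pytest.approx(1.5)

    def test_full_sample_equals_observed_count(self):
        counts = np.array([4, 3, 2, 1])
        assert _rarefied_richness(counts, 10) == pytest.approx(4.0)

    def test_monomorphic_cell_is_one(self):
        assert _rarefied_richness(np.array([12]), 6) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            k = rng.integers(2, 5)
            counts = rng.integers(1, 5, size=k)
            while counts.sum() > 12:
                counts = rng.integers(1, 5, size=k)
            total = int(counts.sum())
            for g in range(2, total + 1):
                assert _rarefied_richness(counts, g) == pytest.approx(
                    enumerate_richness(counts, g), abs=1e-12
                )

    def test_min_n_exclusion_and_default_g(self):
        ds = make_dataset({
            "big": [((1, 2),)] * 20,
            "small": [((1, 3),)] * 5,
        })
        per_breed, per_cell = allelic_richness(ds, min_n=18)
        assert per_breed.breed.tolist() == ["big"]
        assert per_cell.g.iloc[0] == 40  # defaults to min 2N among included

    def test_invalid_g_rejected(self):
        ds = make_dataset({"big": [((1, 2),)] * 20})
        with pytest.raises(ValueError):
            allelic_richness(ds, g=1, min_n=18)
        with pytest.raises(ValueError):
            allelic_richness(ds, g=41, min_n=18)


class TestNullAlleleEM:
    def test_exact_hwe_data_gives_near_zero(self):
        geno = [((1, 1),)] * 25 + [((1, 2),)] * 50 + [((2, 2),)] * 25
        ds = make_dataset({"X": geno})
        est = estimate_null_allele_freq(ds)
        assert est.table.r_hat.iloc[0] < 0.01
        assert not est.table.flag.iloc[0]

    def test_recovers_injected_null(self):
        cfg = SimConfig(n_breeds=1, n_loci=1, alleles_per_locus=(8, 8),
                        sample_sizes=[200], divergence=[0.05], seed=7)
        ds, _ = simulate_breeds(cfg)
        noisy = inject_null_alleles(ds, 0.3, loci=[0], seed=42)
        est = estimate_null_allele_freq(noisy)
        r_hat = est.table.r_hat.iloc[0]
        assert 0.25 <= r_hat <= 0.35
        assert est.table.flag.iloc[0]
        assert est.table.converged.iloc[0]

    def test_all_blank_locus_degenerate_boundary(self):
        ds = make_dataset({"X": [((0, 0), (1, 2))] * 4})
        est = estimate_null_allele_freq(ds)
        row = est.table.set_index("locus").loc["L1"]
        assert row.r_hat == pytest.approx(1.0)
        assert row.flag
        assert not row.converged


class TestHweTest:
    def test_complete_excess_matches_enumeration_oracle(self):
        """Four A/B heterozygotes: the exhaustive null over orderings of the
        4+4 allele copies has P(all pairs heterozygous) = 16/70, which is
        the exact lower bound of the excess p-value."""
        ds = make_dataset({"X": [((1, 2),)] * 4, "Y": [((1, 2),)] * 4})
        res = hwe_test(ds, n_perm=4999, seed=1)
        row = res[res.breed == "X"].iloc[0]
        assert row.p_excess == pytest.approx(16 / 70, abs=0.02)
        assert row.p_deficit > 0.95
        assert row.direction == "excess"

    def test_large_excess_significant(self):
        ds = make_dataset({"X": [((1, 2),)] * 20, "Y": [((1, 2),)] * 20})
        res = hwe_test(ds, n_perm=999, seed=2)
        row = res[res.breed == "X"].iloc[0]
        assert row.p_excess < 0.05
        assert row.p_deficit > 0.9

    def test_monomorphic_cell_is_na(self):
        ds = make_dataset({"X": [((1, 1),)] * 6, "Y": [((1, 2),)] * 6})
        res = hwe_test(ds, n_perm=99, seed=3)
        row = res[res.breed == "X"].iloc[0]
        assert np.isnan(row.p_deficit)
        assert row.direction == "NA"

    def test_seeded_determinism(self, small_sim):
        ds, _ = small_sim
        r1 = hwe_test(ds, n_perm=49, seed=11)
        r2 = hwe_test(ds, n_perm=49, seed=11)
        assert r1.equals(r2)


class TestGenicDifferentiation:
    def test_identical_breeds_p_near_one(self):
        ds = make_dataset({"A": [((1, 2),)] * 10, "B": [((1, 2),)] * 10})
        res = genic_differentiation_test(ds, "A", "B", n_perm=199, seed=4)
        p_comb = res[res.locus == "__combined__"].p.iloc[0]
        assert p_comb == pytest.approx(1.0)

    def test_fixed_different_breeds_significant(self):
        ds = make_dataset({"A": [((1, 1),)] * 20, "B": [((2, 2),)] * 20})
        res = genic_differentiation_test(ds, "A", "B", n_perm=1999, seed=5)
        p_comb = res[res.locus == "__combined__"].p.iloc[0]
        assert p_comb < 1e-3

    def test_null_split_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for rep in range(30):
            calls = rng.integers(1, 5, size=(30, 1, 2))
            labels = np.array(["A"] * 15 + ["B"] * 15, dtype=object)
            ds = make_dataset({"Z": [((1, 1),)]})  # placeholder, rebuilt below
            from msatpop import GenotypeDataset
            ds = GenotypeDataset([f"i{k}" for k in range(30)],
                                 labels[rng.permutation(30)], ["L1"],
                                 calls.astype(np.int32))
            res = genic_differentiation_test(ds, "A", "B", n_perm=99,
                                             seed=1000 + rep)
            pvals.append(res[res.locus == "L1"].p.iloc[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.001

    def test_untyped_locus_skipped(self):
        ds = make_dataset({
            "A": [((1, 2), (0, 0))] * 5,
            "B": [((1, 1), (3, 3))] * 5,
        })
        res = genic_differentiation_test(ds, "A", "B", n_perm=99, seed=7)
        assert bool(res[res.locus == "L2"].skipped.iloc[0])


class TestSequentialBonferroni:
    @pytest.mark.parametrize(
        "pvals, alpha, expected_reject, expected_adj",
        [
            ([0.01, 0.04], 0.05, [True, True], [0.02, 0.04]),
            ([0.04], 0.05, [True], [0.04]),
            ([0.03, 0.03], 0.05, [False, False], [0.06, 0.06]),
            ([], 0.05, [], []),
        ],
    )
    def test_hand_worked_examples(self, pvals, alpha, expected_reject,
                                  expected_adj):
        reject, adj = sequential_bonferroni(pvals, alpha)
        assert reject.tolist() == expected_reject
        assert adj.tolist() == pytest.approx(expected_adj)

    def test_between_bonferroni_and_unadjusted(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(12) ** 2
            alpha = 0.05
            holm, _ = sequential_bonferroni(p, alpha)
            bonf = p < alpha / len(p)
            raw = p < alpha
            assert np.all(holm >= bonf)   # Holm rejects everything Bonferroni does
            assert np.all(raw >= holm)    # and nothing the raw test keeps

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.5, 1.2])
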