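import numpy as np
import pytest
from scipy import stats

from trihybrid import (
    MISSING,
    SimConfig,
    build_triangle_table,
    class_expectations,
    cross,
    downsample_depth,
    make_hybrid_classes,
    select_aims,
    simulate_parental_pools,
    subsample_parentals,
)
from trihybrid.aims import allele_frequencies
from trihybrid.errors import ParameterError

from conftest import matrix_from_rows


class TestParentalPools:
    def test_fixed_difference_count_and_sample_delta(self):
        cfg = SimConfig(n_sites=100, n_fixed_diff=15, n_per_parental=10, seed=3)
        G, pm = simulate_parental_pools(cfg)
        assert (G.sites["true_delta"] == 1.0).sum() == 15
        f1 = allele_frequencies(G, pm.p1_individuals)
        f2 = allele_frequencies(G, pm.p2_individuals)
        # with every individual sampled, fixed sites are fixed in the sample
        fixed = G.sites["true_delta"] == 1.0
        np.testing.assert_array_equal(f1.freq[fixed], 0.0)
        np.testing.assert_array_equal(f2.freq[fixed], 1.0)

    def test_seed_determinism(self):
        cfg = SimConfig(n_sites=50, n_fixed_diff=5, n_per_parental=4, seed=11)
        G1, _ = simulate_parental_pools(cfg)
        G2, _ = simulate_parental_pools(cfg)
        np.testing.assert_array_equal(G1.genotypes, G2.genotypes)

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ParameterError):
            SimConfig(spectrum=("beta", -1.0, 0.5))
        with pytest.raises(ParameterError):
            SimConfig(spectrum=("gamma", 1.0))

    def test_genotype_frequencies_track_true_frequencies(self):
        """Binomial sampling oracle: sample alt frequency at each site is
        within 4 binomial SE of truth for a large pool."""
        cfg = SimConfig(
            n_sites=200, n_fixed_diff=0, n_per_parental=250,
            spectrum=("uniform",), seed=7,
        )
        G, pm = simulate_parental_pools(cfg)
        f = allele_frequencies(G, pm.p1_individuals)
        p = G.sites["true_freq_p1"].to_numpy()
        se = np.sqrt(p * (1 - p) / (2 * 250))
        assert (np.abs(f.freq - p) <= 4 * se + 1e-12).mean() > 0.98


class TestCross:
    def test_forced_outcomes(self):
        rng = np.random.default_rng(0)
        assert list(cross([2, 0], [2, 0], rng)) == [2, 0]
        # opposite homozygotes force a heterozygote (the F1 definition)
        assert list(cross([0] * 5, [2] * 5, rng)) == [1] * 5

    def test_missing_parent_site_propagates(self):
        rng = np.random.default_rng(0)
        assert cross([MISSING], [2], rng)[0] == MISSING

    def test_mendelian_probability_het_by_homref(self):
        rng = np.random.default_rng(42)
        n = 10_000
        child = cross(np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8), rng)
        assert set(np.unique(child)) <= {0, 1}
        k = int((child == 1).sum())
        lo, hi = stats.binom.interval(0.9999, n, 0.5)
        assert lo <= k <= hi

    def test_site_mismatch(self):
        with pytest.raises(ParameterError):
            cross([0, 1], [0], np.random.default_rng(0))


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(n_sites=300, n_fixed_diff=300, n_per_parental=20, seed=5)
    G, pm = simulate_parental_pools(cfg)
    return make_hybrid_classes(G, pm, n_per_class=20, rng=np.random.default_rng(6))


class TestHybridClasses:

    def test_counts_and_labels(self, sim):
        G, pm = sim
        assert G.n_individuals == 40 + 80
        for label in ("F1", "F2", "BC1_P1", "BC1_P2"):
            assert len(pm.individuals(label)) == 20

    def test_f1_heterozygosity_forced_at_fixed_differences(self, sim):
        G, pm = sim
        aims = select_aims(G, pm, threshold=1.0)
        table = build_triangle_table(aims, pm).set_index("id")
        f1 = table.loc[[f"F1_{k:03d}" for k in range(20)]]
        assert (f1["heterozygosity"] == 1.0).all()
        assert (f1["hybrid_index"] == 0.5).all()

    def test_class_means_match_expectations(self, sim):
        """Triangle-plot parameter recovery: class means within 3 MC SE."""
        G, pm = sim
        aims = select_aims(G, pm, threshold=1.0)
        table = build_triangle_table(aims, pm)
        exp = {c.label: c for c in class_expectations(1)}
        n_sites, n_ind = 300, 20
        for label in ("P1", "P2", "F1", "F2", "BC1_P1", "BC1_P2"):
            grp = table[table["pop"] == label]
            ce = exp[label]
            for col, mean in [("hybrid_index", ce.hybrid_index),
                              ("heterozygosity", ce.heterozygosity)]:
                se = np.sqrt(max(mean * (1 - mean), 1e-12) / (n_sites * n_ind))
                assert abs(grp[col].mean() - mean) <= 3 * se + 1e-9, (label, col)

    def test_determinism_under_seed(self):
        cfg = SimConfig(n_sites=50, n_fixed_diff=50, n_per_parental=4, seed=9)
        G, pm = simulate_parental_pools(cfg)
        A, _ = make_hybrid_classes(G, pm, 5, rng=np.random.default_rng(1))
        B, _ = make_hybrid_classes(G, pm, 5, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(A.genotypes, B.genotypes)


class TestDepthDownsampling:
    def test_homozygotes_and_missing_unchanged(self):
        G = matrix_from_rows([[0, 2, MISSING]])
        D = downsample_depth(G, depth=1, rng=0)
        np.testing.assert_array_equal(D.genotypes, G.genotypes)

    def test_depth_one_always_recodes_heterozygotes(self):
        G = matrix_from_rows([[1] * 200])
        D = downsample_depth(G, depth=1, rng=0)
        assert not (D.genotypes == 1).any()
        # both homozygous recodings occur
        assert (D.genotypes == 0).any() and (D.genotypes == 2).any()

    def test_het_survival_probability_at_depth_six(self):
        rng = np.random.default_rng(123)
        n = 100_000
        G = matrix_from_rows([np.ones(n, dtype=np.int8)])
        D = downsample_depth(G, depth=6, rng=rng)
        k = int((D.genotypes == 1).sum())
        lo, hi = stats.binom.interval(0.9999, n, 1 - 2 ** (1 - 6))
        assert lo <= k <= hi

    def test_attenuation_law_across_depths(self):
        """E[observed het] = true het * (1 - 2**(1-d)), exact binomial."""
        rng = np.random.default_rng(7)
        n = 50_000
        G = matrix_from_rows([np.ones(n, dtype=np.int8)])
        for depth in (2, 4, 8):
            D = downsample_depth(G, depth=depth, rng=rng)
            obs = (D.genotypes == 1).mean()
            expected = 1 - 2 ** (1 - depth)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(obs - expected) <= 4 * se

    def test_hybrid_index_unbiased_by_depth(self):
        """Recoded hets split evenly to either homozygote, so the mean
        dosage (hence hybrid index) is depth-invariant."""
        rng = np.random.default_rng(77)
        n = 100_000
        G = matrix_from_rows([np.ones(n, dtype=np.int8)])
        D = downsample_depth(G, depth=2, rng=rng)
        mean_dos = D.genotypes[D.genotypes != MISSING].mean()
        assert abs(mean_dos - 1.0) < 0.02  # ~4 SE

    def test_individual_subset_restricts_recoding(self):
        G = matrix_from_rows([[1] * 50, [1] * 50], ["a", "b"])
        D = downsample_depth(G, depth=1, rng=0, individuals=["b"])
        assert (D.genotypes[0] == 1).all()
        assert not (D.genotypes[1] == 1).any()

    def test_depth_domain(self):
        with pytest.raises(ParameterError):
            downsample_depth(matrix_from_rows([[1]]), depth=0, rng=0)


class TestSubsampleParentals:
    @pytest.fixture()
    def pm(self):
        cfg = SimConfig(n_sites=10, n_fixed_diff=10, n_per_parental=8, seed=2)
        _, pm = simulate_parental_pools(cfg)
        return pm

    def test_full_size_keeps_everyone(self, pm):
        reps = subsample_parentals(pm, n=8, replicates=3, rng=0)
        for rep in reps:
            assert rep.assignments == pm.assignments

    def test_replicates_keep_n_and_exclude_the_rest(self, pm):
        reps = subsample_parentals(pm, n=3, replicates=200, rng=1)
        assert len(reps) == 200
        originals = set(pm.p1_individuals) | set(pm.p2_individuals)
        for rep in reps[:20]:
            assert len(rep.p1_individuals) == 3
            assert len(rep.p2_individuals) == 3
            assert set(rep.p1_individuals) <= originals
            excluded = [i for i, lab in rep.assignments.items()
                        if lab.endswith("_excluded")]
            assert len(excluded) == 10
        # replicates differ (almost surely for 200 draws of 3 from 8)
        assert len({tuple(sorted(r.p1_individuals)) for r in reps}) > 1

    def test_oversized_request_rejected(self, pm):
        with pytest.raises(ParameterError):
            subsample_parentals(pm, n=9, replicates=1, rng=0)


class TestFalseFixedDifferences:
    def test_true_delta_at_sample_fixed_sites_is_left_skewed(self):
        """With 5 individuals per pool, sites that look fixed in the sample
        have true delta concentrated near 1 (left-skewed, mode at top)."""
        cfg = SimConfig(
            n_sites=4000, n_fixed_diff=0, n_per_parental=30,
            spectrum=("beta", 0.5, 0.5), seed=13,
        )
        G, pm = simulate_parental_pools(cfg)
        true_delta = G.sites["true_delta"].to_numpy()
        collected = []
        for rep in subsample_parentals(pm, n=5, replicates=20, rng=14):
            f1 = allele_frequencies(G, rep.p1_individuals)
            f2 = allele_frequencies(G, rep.p2_individuals)
            sample_fixed = np.abs(f1.freq - f2.freq) >= 1.0 - 1e-12
            collected.append(true_delta[sample_fixed])
        d = np.concatenate(collected)
        assert d.size > 100
        assert stats.skew(d) < 0  # left-skewed
        hist, _ = np.histogram(d, bins=10, range=(0, 1))
        assert hist.argmax() == 9  # mode in the top bin, near delta = 1
        assert np.median(d) > 0.8
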