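"""Statistics: hand-checked values, closed forms, estimator oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snppanel as sp
from snppanel import MISSING, ConfigError, Population

from conftest import make_matrix


# -- independent Weir-Cockerham oracle (scalar, per site) ------------------


def wc_theta_reference(geno_by_group):
    """Scalar Weir & Cockerham (1984) theta for one site, two groups.

    Independent of the vectorized production path: plain Python loops over
    the genotype lists, following the variance-component definitions.
    """
    r = len(geno_by_group)
    n = []
    p = []
    h = []
    for genos in geno_by_group:
        genos = [g for g in genos if g != MISSING]
        n_i = len(genos)
        n.append(n_i)
        p.append(sum(genos) / (2 * n_i))
        h.append(sum(1 for g in genos if g == 1) / n_i)
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(n[i] * p[i] for i in range(r)) / (r * nbar)
    s2 = sum(n[i] * (p[i] - pbar) ** 2 for i in range(r)) / ((r - 1) * nbar)
    hbar = sum(n[i] * h[i] for i in range(r)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return float("nan") if denom == 0 else a / denom


def two_group_matrix(g1, g2):
    calls = np.array([list(g1) + list(g2)]).T
    pops = [Population.TEMPERATE] * len(g1) + [Population.TROPICAL] * len(g2)
    return make_matrix(calls, populations=pops)


class TestAlleleFrequencies:
    def test_hand_count(self):
        m = make_matrix(np.array([[2], [2], [1], [0]]), populations=[Population.TEMPERATE] * 4)
        freqs = sp.allele_frequencies(m)
        assert freqs["temperate"].iloc[0] == pytest.approx(0.625)
        assert sp.minor_allele_frequency(freqs["overall"])[0] == pytest.approx(0.375)

    def test_all_reference(self):
        m = make_matrix(np.zeros((3, 1)), populations=[Population.TROPICAL] * 3)
        assert sp.allele_frequencies(m)["tropical"].iloc[0] == 0.0

    def test_all_missing_undefined(self):
        m = make_matrix(np.full((3, 1), MISSING), populations=[Population.TROPICAL] * 3)
        assert math.isnan(sp.allele_frequencies(m)["tropical"].iloc[0])

    def test_missing_excluded_from_both_sides(self):
        m = make_matrix(np.array([[2], [MISSING], [0]]), populations=[Population.TEMPERATE] * 3)
        assert sp.allele_frequencies(m)["temperate"].iloc[0] == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        m = make_matrix(np.zeros((2, 1)))
        with pytest.raises(ConfigError):
            sp.allele_frequencies(m)


class TestPic:
    @pytest.mark.parametrize(
        "freqs,expected",
        [((1.0,), 0.0), ((0.5, 0.5), 0.375), ((0.9, 0.1), 0.1638)],
    )
    def test_printed_equation(self, freqs, expected):
        assert sp.pic(freqs) == pytest.approx(expected, abs=1e-12)

    def test_sum_validation(self):
        with pytest.raises(ConfigError):
            sp.pic((0.6, 0.6))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_biallelic_bounds_and_maximum(self, p):
        v = sp.pic_biallelic(p)
        assert -1e-12 <= v <= 0.375 + 1e-12
        assert sp.pic((p, 1.0 - p)) == pytest.approx(v, abs=1e-12)


class TestAfd:
    @pytest.mark.parametrize(
        "tem,tro,expected",
        [(0.886, 0.124, 0.762), (0.267, 0.946, 0.679), (0.3, 0.3, 0.0)],
    )
    def test_values(self, tem, tro, expected):
        assert sp.afd(tem, tro) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self):
        assert sp.afd(0.2, 0.9) == sp.afd(0.9, 0.2)

    def test_range_validated(self):
        with pytest.raises(ConfigError):
            sp.afd(1.2, 0.5)


class TestWeirCockerham:
    def test_fixed_opposite_alleles_is_one(self):
        m = two_group_matrix([2] * 10, [0] * 10)
        assert sp.fst_weir_cockerham(m)[0] == pytest.approx(1.0)

    def test_identical_groups_nonpositive(self):
        g = [0, 0, 2, 2, 1, 0, 2, 1, 0, 2]
        m = two_group_matrix(g, list(g))
        assert sp.fst_weir_cockerham(m)[0] <= 0

    def test_monomorphic_both_undefined(self):
        m = two_group_matrix([0, 0, 0], [0, 0, 0])
        assert math.isnan(sp.fst_weir_cockerham(m)[0])

    def test_known_frequencies_vs_oracle(self):
        g1 = [2] * 16 + [0] * 4  # freq 0.8
        g2 = [2] * 4 + [0] * 16  # freq 0.2
        m = two_group_matrix(g1, g2)
        assert sp.fst_weir_cockerham(m)[0] == pytest.approx(wc_theta_reference([g1, g2]), abs=1e-12)

    def test_dual_implementation_on_random_tables(self):
        """Vectorized theta equals the scalar reference to 1e-10 on 100 tables."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            n1, n2 = rng.integers(2, 12, size=2)
            g1 = rng.choice([0, 1, 2, MISSING], size=n1, p=[0.4, 0.1, 0.4, 0.1]).tolist()
            g2 = rng.choice([0, 1, 2, MISSING], size=n2, p=[0.4, 0.1, 0.4, 0.1]).tolist()
            if sum(g != MISSING for g in g1) < 2 or sum(g != MISSING for g in g2) < 2:
                continue
            expected = wc_theta_reference([g1, g2])
            got = sp.fst_weir_cockerham(two_group_matrix(g1, g2))[0]
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)
            checked += 1

    def test_global_estimator_sums_components(self):
        g1a, g2a = [2] * 8 + [0] * 2, [2] * 2 + [0] * 8
        m = make_matrix(
            np.array([g1a + g2a, g1a + g2a]).T,
            populations=[Population.TEMPERATE] * 10 + [Population.TROPICAL] * 10,
        )
        # identical sites: multi-locus estimate equals the per-site value
        assert sp.fst_weir_cockerham_global(m) == pytest.approx(sp.fst_weir_cockerham(m)[0], abs=1e-12)

    def test_more_than_two_groups_rejected(self, two_pop_matrix):
        groups = {"a": np.array([0, 1]), "b": np.array([2, 3]), "c": np.array([4, 5])}
        with pytest.raises(ConfigError):
            sp.fst_weir_cockerham(two_pop_matrix, groups)


class TestFoldedSfs2d:
    def test_all_monomorphic_in_corner(self):
        m = make_matrix(np.zeros((4, 5)), populations=[Population.TEMPERATE] * 2 + [Population.TROPICAL] * 2)
        counts = sp.folded_sfs_2d(m, n_bins=5)
        assert counts[0, 0] == 5 and counts.sum() == 5

    def test_count_conservation(self, small_sim):
        _, m, _ = small_sim
        counts = sp.folded_sfs_2d(m, n_bins=10)
        retained = (~sp.allele_frequencies(m)[["temperate", "tropical"]].isna().any(axis=1)).sum()
        assert counts.sum() == retained

    def test_undifferentiated_mass_near_diagonal(self):
        cfg = sp.SimConfig(
            n_temperate=60, n_tropical=60, n_variants=500, n_chromosomes=2,
            chrom_length=1_000_000, target_fst=0.0, seed=8,
        )
        m, _ = sp.simulate_panel(cfg)
        counts = sp.folded_sfs_2d(m, n_bins=10)
        band = sum(
            counts[i, j] for i in range(10) for j in range(10) if abs(i - j) <= 1
        )
        off = counts.sum() - band
        assert band > off


class TestSampleRates:
    def test_no_missing(self, two_pop_matrix):
        per_sample, per_variant = sp.sample_rates(two_pop_matrix)
        assert (per_sample["missing_rate"] == 0).all()
        assert (per_variant["missing_rate"] == 0).all()

    def test_het_rate_among_nonmissing(self):
        m = make_matrix(np.array([[1, 1, 0, 2]]))
        per_sample, _ = sp.sample_rates(m)
        assert per_sample["het_rate"].iloc[0] == pytest.approx(0.5)

    def test_hand_counted_missing(self):
        calls = np.array([[MISSING, 0, 1, 2, MISSING], [0, 2, MISSING, 0, 1]])
        per_sample, _ = sp.sample_rates(make_matrix(calls))
        assert per_sample["missing_rate"].tolist() == pytest.approx([0.4, 0.2])


class TestIbsDistance:
    def test_identical_samples_zero(self):
        m = make_matrix(np.array([[0, 2, 1], [0, 2, 1]]))
        assert sp.ibs_distance_matrix(m).values[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        m = make_matrix(np.array([[0, 0, 0], [2, 2, 2]]))
        assert sp.ibs_distance_matrix(m).values[0, 1] == 1.0

    def test_half_shared_allele(self):
        m = make_matrix(np.array([[0, 2, 1], [0, 0, 1]]))
        assert sp.ibs_distance_matrix(m).values[0, 1] == pytest.approx(1 / 3)

    def test_pairwise_complete_missing(self):
        m = make_matrix(np.array([[0, MISSING, 2], [0, 2, 2]]))
        assert sp.ibs_distance_matrix(m).values[0, 1] == 0.0

    def test_no_shared_variant_flagged(self):
        m = make_matrix(np.array([[0, MISSING], [MISSING, 2]]))
        with pytest.warns(UserWarning, match="share no genotyped"):
            dm = sp.ibs_distance_matrix(m)
        assert math.isnan(dm.values[0, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, 2], size=(3, 12))
        d = sp.ibs_distance_matrix(make_matrix(calls)).values
        assert np.allclose(d, d.T)
        assert d[0, 0] == d[1, 1] == d[2, 2] == 0.0
        for i, j, k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestDiversity:
    def test_clones_zero(self):
        m = make_matrix(np.tile([0, 2, 1, 2], (3, 1)), populations=[Population.TEMPERATE] * 3)
        assert sp.nucleotide_diversity_within(m, "temperate") == 0.0

    def test_two_samples_equals_pair_distance(self):
        m = make_matrix(np.array([[0, 2], [2, 2]]), populations=[Population.TROPICAL] * 2)
        d = sp.ibs_distance_matrix(m).values[0, 1]
        assert sp.nucleotide_diversity_within(m, "tropical") == pytest.approx(d)

    def test_three_sample_enumeration(self):
        calls = np.array([[0, 0, 2], [2, 0, 2], [1, 2, 0]])
        m = make_matrix(calls, populations=[Population.TEMPERATE] * 3)
        d = sp.ibs_distance_matrix(m).values
        expected = (d[0, 1] + d[0, 2] + d[1, 2]) / 3
        assert sp.nucleotide_diversity_within(m, "temperate") == pytest.approx(expected)

    def test_singleton_group_rejected(self):
        m = make_matrix(np.zeros((2, 2)), populations=[Population.TEMPERATE, Population.TROPICAL])
        with pytest.raises(ConfigError):
            sp.nucleotide_diversity_within(m, "temperate")

    def test_between_group_mean(self, two_pop_matrix):
        d = sp.ibs_distance_matrix(two_pop_matrix).values
        expected = d[np.ix_(range(4), range(4, 8))].mean()
        got = sp.nucleotide_diversity_between(
            two_pop_matrix,
            [s.id for s in two_pop_matrix.samples[:4]],
            [s.id for s in two_pop_matrix.samples[4:]],
        )
        assert got == pytest.approx(expected)


class TestKinship:
    def test_clone_pair_scores_maximum(self, small_sim):
        _, m, _ = small_sim
        clone = sp.SampleRecord("clone_of_first", m.samples[0].population)
        m2 = sp.GenotypeMatrix(
            variants=m.variants,
            samples=m.samples + [clone],
            calls=np.vstack([m.calls, m.calls[:1]]),
        )
        k = sp.kinship_matrix(m2)
        off = k.values.copy()
        np.fill_diagonal(off, -1)
        i, j = np.unravel_index(off.argmax(), off.shape)
        assert {m2.sample_ids[i], m2.sample_ids[j]} == {m2.sample_ids[0], "clone_of_first"}

    def test_values_in_unit_interval(self, small_sim):
        _, m, _ = small_sim
        k = sp.kinship_matrix(m).values
        assert k.min() >= 0 and k.max() <= 1 + 1e-12

    def test_within_population_exceeds_between(self):
        cfg = sp.SimConfig(
            n_temperate=40, n_tropical=40, n_variants=600, n_chromosomes=2,
            chrom_length=1_000_000, target_fst=0.3, seed=17,
        )
        m, _ = sp.simulate_panel(cfg)
        k = sp.kinship_matrix(m).values
        tem = np.arange(40)
        tro = np.arange(40, 80)
        within = np.concatenate(
            [k[np.triu_indices(40, 1)], k[np.ix_(tro, tro)][np.triu_indices(40, 1)]]
        )
        between = k[np.ix_(tem, tro)].ravel()
        assert np.median(between) < np.median(within)

    def test_degenerate_all_identical_rejected(self):
        m = make_matrix(np.zeros((4, 5)))
        with pytest.raises(ConfigError):
            sp.kinship_matrix(m)


class TestLdR2:
    def test_identical_vectors(self):
        assert sp.ld_r2([0, 0, 2, 2], [0, 0, 2, 2]) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        assert math.isnan(sp.ld_r2([0, 0, 0, 0], [0, 2, 0, 2]))

    def test_orthogonal_vectors(self):
        assert sp.ld_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(ConfigError):
            sp.ld_r2([0, 2], [0, 2, 2])

    def test_pairwise_complete(self):
        # after dropping the missing pair the vectors are identical
        assert sp.ld_r2([0, 2, MISSING, 2], [0, 2, 2, 2]) == pytest.approx(1.0)


class TestLdDecay:
    def test_pair_count_conservation(self, small_sim):
        _, m, _ = small_sim
        curve = sp.ld_decay_curve(m, max_distance=400_000, bin_width=50_000)
        chroms, positions = m.chroms, m.positions
        freqs = sp.allele_frequencies(m)["overall"].values
        maf = np.minimum(freqs, 1 - freqs)
        expected = 0
        for j in range(m.n_variants):
            for l in range(j + 1, m.n_variants):
                if chroms[j] != chroms[l] or not (maf[j] > 0.05 and maf[l] > 0.05):
                    continue
                if abs(positions[l] - positions[j]) < 400_000:
                    r2 = sp.ld_r2(m.calls[:, j], m.calls[:, l])
                    if not math.isnan(r2):
                        expected += 1
        assert curve.n_pairs.sum() == expected

    def test_single_block_never_decays(self):
        cfg = sp.SimConfig(
            n_temperate=40, n_tropical=0, n_variants=200, n_chromosomes=1,
            chrom_length=500_000, ld_block_mean_length=float("inf"), n_founders=2,
            het_rate=0.0, missing_rate=0.0, seed=3,
        )
        m, _ = sp.simulate_panel(cfg, linkage=True)
        curve = sp.ld_decay_curve(m, max_distance=400_000, bin_width=50_000)
        assert curve.mean_r2[0] > 0.9
        assert sp.decay_distance(curve, threshold=0.1) is None

    def test_unlinked_decays_in_first_bin(self):
        cfg = sp.SimConfig(
            n_temperate=100, n_tropical=100, n_variants=400, n_chromosomes=1,
            chrom_length=500_000, het_rate=0.0, missing_rate=0.0, seed=4,
        )
        m, _ = sp.simulate_panel(cfg)
        curve = sp.ld_decay_curve(m, max_distance=400_000, bin_width=50_000)
        # under independence r^2 ~ 1/n, far below 0.1
        assert sp.decay_distance(curve, threshold=0.1) == (0, 50_000)

    def test_no_pairs_is_error(self):
        m = make_matrix(np.array([[0], [2], [0], [2]]))
        with pytest.raises(sp.SnpPanelError):
            sp.ld_decay_curve(m)


def test_variant_stats_assembles_columns(small_sim):
    _, m, _ = small_sim
    df = sp.variant_stats(m)
    for col in ("freq_temperate", "freq_tropical", "maf", "pic", "afd", "fst", "missing_rate", "het_rate"):
        assert col in df.columns
    assert np.allclose(
        df["afd"].dropna(),
        (df["freq_temperate"] - df["freq_tropical"]).abs().dropna(),
    )
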