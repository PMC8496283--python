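"""Pairwise-difference statistics, Hudson FST, 2D-SFS, typing data."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from snpascert.ascertainment import AscertainmentConfig, select_markers
from snpascert.stats import (
    TypingData,
    aggregate_deviations,
    fst_hudson,
    make_typing_data,
    pairwise_stats,
    pi_between,
    pi_within,
    random_marker_baseline,
    reseq_typing_view,
    sfs_2d,
)


def typing(matrix, pop_labels):
    matrix = np.asarray(matrix, dtype=np.int8)
    return TypingData(
        matrix=matrix,
        pop_labels=np.asarray(pop_labels),
        marker_sites=np.arange(matrix.shape[1]),
    )


def brute_pi_within(matrix):
    """Oracle: mean Hamming distance over all haplotype pairs."""
    pairs = list(itertools.combinations(range(matrix.shape[0]), 2))
    return np.mean([np.sum(matrix[i] != matrix[j]) for i, j in pairs])


def brute_pi_between(ma, mb):
    return np.mean([np.sum(a != b) for a in ma for b in mb])


class TestPiHandExamples:
    def test_single_pair_one_difference(self):
        data = typing([[0, 0], [0, 1]], [0, 0])
        assert pi_within(data, 0) == 1.0

    def test_identical_haplotypes_zero(self):
        data = typing([[1, 0, 1]] * 4, [0] * 4)
        assert pi_within(data, 0) == 0.0

    def test_between_hand_enumeration(self):
        # cross distances: 2, 1, 1, 2 -> mean 1.5
        data = typing([[0, 0], [0, 1], [1, 1], [1, 0]], [0, 0, 1, 1])
        assert pi_between(data, 0, 1) == 1.5

    def test_fst_from_hand_values(self):
        data = typing([[0, 0], [0, 1], [1, 1], [1, 0]], [0, 0, 1, 1])
        fst, defined = fst_hudson(data, 0, 1)
        assert defined
        assert fst == pytest.approx(1 - 1.0 / 1.5)

    def test_identical_multisets_give_fst_of_self_pair_correction(self):
        # pi_w excludes self-pairs while pi_b includes the identical cross
        # pairs, so two copies of the same multiset give exactly -1/(n-1);
        # the value vanishes as n grows (see the panmictic-halves check).
        block = [[0, 1, 0], [1, 0, 0], [0, 0, 1]]
        data = typing(block + block, [0, 0, 0, 1, 1, 1])
        fst, defined = fst_hudson(data, 0, 1)
        assert defined
        assert fst == pytest.approx(-1 / 2)
        big = block * 20
        data = typing(big + big, [0] * 60 + [1] * 60)
        fst, _ = fst_hudson(data, 0, 1)
        assert fst == pytest.approx(-1 / 59)

    def test_undefined_when_no_between_variation(self):
        data = typing([[0], [0], [0], [0]], [0, 0, 1, 1])
        fst, defined = fst_hudson(data, 0, 1)
        assert not defined
        assert np.isnan(fst)

    def test_requires_two_haplotypes_per_population(self):
        data = typing([[0], [1]], [0, 1])
        with pytest.raises(ValueError):
            pi_within(data, 0)


class TestPiOracle:
    @given(
        matrix=arrays(np.int8, st.tuples(st.integers(4, 12), st.integers(1, 20)),
                      elements=st.integers(0, 1)),
        split=st.floats(0.3, 0.7),
    )
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_frequency_formula_equals_pair_enumeration(self, matrix, split):
        na = max(2, min(matrix.shape[0] - 2, int(matrix.shape[0] * split)))
        labels = np.array([0] * na + [1] * (matrix.shape[0] - na))
        data = typing(matrix, labels)
        assert pi_within(data, 0) == pytest.approx(brute_pi_within(matrix[:na]))
        assert pi_within(data, 1) == pytest.approx(brute_pi_within(matrix[na:]))
        assert pi_between(data, 0, 1) == pytest.approx(
            brute_pi_between(matrix[:na], matrix[na:])
        )

    def test_doubling_every_haplotype_preserves_pi_between(self):
        rng = np.random.default_rng(5)
        ma = rng.integers(0, 2, (4, 12), dtype=np.int8)
        mb = rng.integers(0, 2, (5, 12), dtype=np.int8)
        single = typing(np.vstack([ma, mb]), [0] * 4 + [1] * 5)
        doubled = typing(
            np.vstack([ma, ma, mb, mb]), [0] * 8 + [1] * 10
        )
        assert pi_between(doubled, 0, 1) == pytest.approx(pi_between(single, 0, 1))


class TestSfs2d:
    def test_hand_tabulation(self):
        data = typing([[0, 1], [0, 1], [1, 0], [1, 1]], [0, 0, 1, 1])
        spec = sfs_2d(data, 0, 1)
        # site 0: counts (0 in A, 2 in B); site 1: (2 in A, 1 in B)
        assert spec.counts[0, 2] == 1
        assert spec.counts[2, 1] == 1
        assert spec.counts.sum() == 2

    def test_cells_sum_to_site_count_and_include_corners(self):
        rng = np.random.default_rng(2)
        matrix = rng.integers(0, 2, (8, 30), dtype=np.int8)
        matrix[:, 0] = 0  # monomorphic ancestral column stays in the corner cell
        data = typing(matrix, [0] * 4 + [1] * 4)
        spec = sfs_2d(data, 0, 1)
        assert spec.counts.shape == (5, 5)
        assert spec.counts.sum() == 30
        assert spec.counts[0, 0] >= 1

    def test_swapping_populations_transposes(self):
        rng = np.random.default_rng(3)
        data = typing(rng.integers(0, 2, (9, 25), dtype=np.int8), [0] * 4 + [1] * 5)
        ab = sfs_2d(data, 0, 1).counts
        ba = sfs_2d(data, 1, 0).counts
        assert np.array_equal(ab, ba.T)

    def test_marginals_match_1d_spectra(self):
        rng = np.random.default_rng(4)
        matrix = rng.integers(0, 2, (10, 40), dtype=np.int8)
        data = typing(matrix, [0] * 5 + [1] * 5)
        spec = sfs_2d(data, 0, 1)
        da = matrix[:5].sum(axis=0)
        sfs_a = np.bincount(da, minlength=6)
        assert np.array_equal(spec.counts.sum(axis=1), sfs_a)


class TestTypingData:
    def test_restricts_to_typing_rows_and_marker_columns(self, dataset_factory):
        rng = np.random.default_rng(6)
        ds = dataset_factory(rng.integers(0, 2, (30, 60), dtype=np.int8), [10, 10, 10],
                             n_discovery=4)
        cfg = AscertainmentConfig(n_markers=20, seed=0)
        sel = select_markers(np.arange(60), cfg)
        typ = make_typing_data(ds, sel)
        assert typ.matrix.shape == (18, 20)  # 6 typing rows x 3 populations
        assert np.array_equal(typ.marker_sites, np.sort(sel.selected_markers))

    def test_monomorphic_marker_column_retained(self, dataset_factory):
        matrix = np.zeros((8, 3), dtype=np.int8)
        matrix[0:2, 0] = 1  # variable only among discovery rows of population 0
        matrix[:4, 1] = 1
        matrix[1::2, 2] = 1
        ds = dataset_factory(matrix, [4, 4], n_discovery=2)
        cfg = AscertainmentConfig(n_markers=3, seed=0)
        typ = make_typing_data(ds, select_markers(np.arange(3), cfg))
        assert typ.matrix.shape[1] == 3
        assert (typ.matrix[:, 0] == 0).all()  # all-zero column kept

    def test_excluded_selection_refused_with_context(self, dataset_factory):
        ds = dataset_factory(np.eye(4, dtype=np.int8), [4], n_discovery=2)
        sel = select_markers(np.arange(2), AscertainmentConfig(n_markers=50))
        with pytest.raises(ValueError, match="excluded"):
            make_typing_data(ds, sel)

    def test_reuse_design_types_discovery_rows(self, dataset_factory):
        rng = np.random.default_rng(7)
        matrix = rng.integers(0, 2, (8, 10), dtype=np.int8)
        ds = dataset_factory(matrix, [4, 4], n_discovery=4, reuse=True)
        typ = reseq_typing_view(ds)
        assert typ.matrix.shape == (8, 10)  # discovery haplotypes themselves are typed

    def test_reseq_view_uses_typing_rows_at_all_sites(self, dataset_factory):
        rng = np.random.default_rng(8)
        matrix = rng.integers(0, 2, (8, 10), dtype=np.int8)
        ds = dataset_factory(matrix, [4, 4], n_discovery=2)
        typ = reseq_typing_view(ds)
        assert typ.matrix.shape == (4, 10)
        assert np.array_equal(typ.marker_sites, np.arange(10))


class TestRandomBaseline:
    def test_samples_from_all_segregating_sites(self, dataset_factory):
        rng = np.random.default_rng(9)
        ds = dataset_factory(rng.integers(0, 2, (12, 140), dtype=np.int8), [6, 6],
                             n_discovery=3)
        sel = random_marker_baseline(ds, 50, seed=1)
        assert not sel.excluded
        assert sel.selected_markers.size == 50
        assert sel.candidate_sites.size == 140

    def test_too_few_sites_excluded(self, dataset_factory):
        ds = dataset_factory(np.eye(6, dtype=np.int8), [6], n_discovery=3)
        assert random_marker_baseline(ds, 50, seed=1).excluded

    def test_subsampling_unbiased_for_pi(self, dataset_factory):
        rng = np.random.default_rng(10)
        matrix = rng.integers(0, 2, (12, 200), dtype=np.int8)
        ds = dataset_factory(matrix, [12], n_discovery=4)
        full = pi_within(reseq_typing_view(ds), 0) / 200  # per-site
        sub = np.mean(
            [
                pi_within(make_typing_data(ds, random_marker_baseline(ds, 50, seed=s)), 0) / 50
                for s in range(200)
            ]
        )
        assert sub == pytest.approx(full, rel=0.02)


class TestAggregateDeviations:
    def test_paired_and_unpaired_deviation_agree_on_shared_replicates(self):
        rng = np.random.default_rng(11)
        ft = rng.normal(0.5, 0.05, 50)
        fr = rng.normal(0.6, 0.05, 50)
        ones = np.ones(50)
        rec = aggregate_deviations("merged_panel", 0.05, (0, 1), ft, fr, ones, ones, ones,
                                   ones, n_excluded=3)
        assert rec.deviation == pytest.approx(rec.deviation_paired)
        assert rec.deviation == pytest.approx(ft.mean() - fr.mean())
        assert rec.n_replicates_used == 50
        assert rec.n_excluded == 3

    def test_undefined_fst_dropped_and_counted(self):
        ft = np.array([0.5, np.nan, 0.6])
        fr = np.array([0.5, 0.5, 0.7])
        ones = np.ones(3)
        rec = aggregate_deviations("s", 0.0, (0, 1), ft, fr, ones, ones, ones, ones, 0)
        assert rec.n_fst_undefined == 1
        assert rec.n_replicates_used == 2

    def test_empty_cell_yields_nan_record(self):
        empty = np.zeros(0)
        rec = aggregate_deviations("s", 0.0, (0, 1), empty, empty, empty, empty, empty,
                                   empty, n_excluded=10)
        assert np.isnan(rec.deviation)
        assert rec.n_excluded == 10

    def test_relative_pi_is_ratio_of_means(self):
        ones = np.ones(4)
        rec = aggregate_deviations(
            "s", 0.0, (0, 1), ones * 0.5, ones * 0.5,
            np.array([2.0, 2.0, 4.0, 4.0]), np.array([1.0, 3.0, 1.0, 3.0]),
            ones * 6.0, ones * 2.0, 0,
        )
        assert rec.relative_pi_within == pytest.approx(3.0 / 2.0)
        assert rec.relative_pi_between == pytest.approx(3.0)


class TestPairwiseStats:
    def test_all_pairs_present_for_three_populations(self):
        rng = np.random.default_rng(12)
        data = typing(rng.integers(0, 2, (9, 30), dtype=np.int8), [0] * 3 + [1] * 3 + [2] * 3)
        st_ = pairwise_stats(data)
        assert set(st_.pi_w) == {0, 1, 2}
        assert set(st_.pi_b) == {(0, 1), (0, 2), (1, 2)}
        for pair, fst in st_.fst.items():
            if st_.fst_defined[pair]:
                assert fst <= 1.0
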