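"""Occurrence scanning, distance samples and empirical CCDFs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qword.occurrences import (
    DistanceSample,
    InsufficientSampleError,
    Word,
    distances_from_positions,
    distances_in_regions,
    element_distances,
    empirical_ccdf,
    find_occurrences,
    word_distances,
)
from qword.ranking import enumerate_kmers
from qword.sequence_io import GenomicInterval, SequenceRecord
from qword.synthetic import random_genome


def naive_scan(text: str, word: str) -> list[int]:
    """Independent oracle: O(N*L) sliding-window comparison."""
    L = len(word)
    return [i for i in range(len(text) - L + 1) if text[i : i + L] == word]


class TestFindOccurrences:
    @pytest.mark.parametrize(
        "seq, word, expected",
        [
            ("CGCGACG", "CG", [0, 2, 5]),
            ("AAAA", "AA", [0, 1, 2]),  # overlaps counted
            ("ACGT", "TT", []),
            ("ACG", "ACGT", []),  # word longer than sequence
            ("ANAA", "AA", [2]),  # N never matches
        ],
    )
    def test_examples(self, seq, word, expected):
        assert list(find_occurrences(SequenceRecord("t", seq), word)) == expected

    def test_oracle_equivalence_all_di_and_trinucleotides(self):
        seq = random_genome(10_000, seed=77).sequence
        for word in enumerate_kmers(2) + enumerate_kmers(3):
            assert list(find_occurrences(seq, word)) == naive_scan(seq, word), word

    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=60),
        st.text(alphabet="ACGT", min_size=1, max_size=4),
    )
    def test_oracle_equivalence_random(self, seq, word):
        assert list(find_occurrences(seq, word)) == naive_scan(seq, word)

    def test_count_identity(self):
        seq = random_genome(5_000, seed=3).sequence
        for word in ("CG", "AA", "TAT"):
            positions = find_occurrences(seq, word)
            count = sum(seq[i:].startswith(word) for i in range(len(seq)))
            assert positions.size == count

    def test_invalid_word_rejected(self):
        with pytest.raises(ValueError):
            Word("CN")
        with pytest.raises(ValueError):
            Word("")


class TestDistances:
    @pytest.mark.parametrize(
        "positions, expected",
        [([0, 2, 5], [2, 3]), ([7], []), ([], []), ([0, 1, 2], [1, 1])],
    )
    def test_from_positions(self, positions, expected):
        assert list(distances_from_positions(positions)) == expected

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            distances_from_positions([5, 2, 9])

    def test_regions_never_bridge(self):
        seq = SequenceRecord("chr1", "CGCGAAAAAACGCG")
        regions = [GenomicInterval("chr1", 0, 4), GenomicInterval("chr1", 10, 14)]
        sample = distances_in_regions(seq, "CG", regions)
        assert sorted(sample.distances.tolist()) == [2, 2]
        assert sample.n_occurrences == 4

    def test_single_region_equals_whole_sequence(self):
        seq = SequenceRecord("chr1", random_genome(2_000, seed=5).sequence)
        whole = word_distances(seq, "CG", n_split_threshold=None)
        region = distances_in_regions(seq, "CG", [GenomicInterval("chr1", 0, len(seq))])
        assert np.array_equal(whole.distances, region.distances)

    def test_region_with_single_occurrence_contributes_nothing(self):
        seq = SequenceRecord("chr1", "AACGAA")
        sample = distances_in_regions(seq, "CG", [GenomicInterval("chr1", 0, 6)])
        assert sample.n == 0
        assert sample.n_occurrences == 1

    def test_region_out_of_bounds_errors(self):
        seq = SequenceRecord("chr1", "ACGT")
        with pytest.raises(ValueError):
            distances_in_regions(seq, "CG", [GenomicInterval("chr1", 0, 10)])

    def test_match_must_lie_entirely_within_region(self):
        seq = SequenceRecord("chr1", "ACGT")
        # CG straddles the region boundary at 2: not an occurrence
        sample = distances_in_regions(seq, "CG", [GenomicInterval("chr1", 0, 2)])
        assert sample.n_occurrences == 0

    def test_long_n_runs_split_the_scope(self):
        seq = SequenceRecord("x", "CGCG" + "N" * 30 + "CGCG")
        split = word_distances(seq, "CG", n_split_threshold=20)
        assert sorted(split.distances.tolist()) == [2, 2]
        unsplit = word_distances(seq, "CG", n_split_threshold=None)
        assert sorted(unsplit.distances.tolist()) == [2, 2, 32]


class TestElementDistances:
    def test_single_chrom(self):
        ivs = [GenomicInterval("chr1", s, s + 40) for s in (100, 250, 400)]
        assert list(element_distances(ivs).distances) == [150, 150]

    def test_two_chroms_pooled(self):
        ivs = [
            GenomicInterval("chr1", 0, 3),
            GenomicInterval("chr1", 10, 13),
            GenomicInterval("chr2", 5, 8),
            GenomicInterval("chr2", 9, 12),
        ]
        assert sorted(element_distances(ivs).distances.tolist()) == [4, 10]

    def test_single_interval_per_chrom_yields_nothing(self):
        ivs = [GenomicInterval("chr1", 0, 5), GenomicInterval("chr2", 0, 5)]
        assert element_distances(ivs).n == 0

    def test_duplicate_starts_collapsed_with_warning(self):
        ivs = [
            GenomicInterval("chr1", 0, 5),
            GenomicInterval("chr1", 0, 9),
            GenomicInterval("chr1", 4, 9),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            sample = element_distances(ivs)
        assert list(sample.distances) == [4]

    def test_gap_mode(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 25, 30)]
        assert list(element_distances(ivs, mode="gap").distances) == [15]


class TestEmpiricalCCDF:
    def test_brute_force_example(self):
        sample = DistanceSample("w", [1, 1, 2], 4)
        c = empirical_ccdf(sample, min_occurrences=1)
        assert list(c.distances) == [1, 2]
        assert c.values[0] == 1.0
        assert c.values[1] == pytest.approx(1 / 3)

    def test_degenerate_single_distance(self):
        c = empirical_ccdf(DistanceSample("w", [5, 5, 5], 4), min_occurrences=1)
        assert list(c.distances) == [5]
        assert list(c.values) == [1.0]

    def test_values_decreasing_and_positive(self):
        rng = np.random.default_rng(1)
        sample = DistanceSample("w", rng.integers(1, 500, size=2_000), 2_001)
        c = empirical_ccdf(sample)
        assert c.values[0] == 1.0
        assert np.all(np.diff(c.values) < 0)
        assert np.all(c.values > 0)

    def test_insufficient_sample_signals_n(self):
        with pytest.raises(InsufficientSampleError) as err:
            empirical_ccdf(DistanceSample("w", [3, 4], 3), min_occurrences=50)
        assert err.value.n == 2
        assert err.value.minimum == 50

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            DistanceSample("w", [0, 1], 3)
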