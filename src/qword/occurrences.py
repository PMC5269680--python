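"""Word occurrence scanning, inter-occurrence distances and empirical CCDFs.

Occurrence scanning is overlap-inclusive: tandem and overlapping matches all
count (``AAAA`` contains ``AA`` at 0, 1 and 2).  A distance is the
start-to-start difference in bp between consecutive occurrences; the minimal
possible distance is therefore 1.  The empirical complementary cumulative
distribution P(D >= d) over those distances is the object the q-exponential
is fitted to.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_math import DNA_LETTERS
from .sequence_io import GenomicInterval, SequenceRecord

__all__ = [
    "Word",
    "DistanceSample",
    "EmpiricalCCDF",
    "InsufficientSampleError",
    "find_occurrences",
    "distances_from_positions",
    "word_distances",
    "distances_in_regions",
    "element_distances",
    "empirical_ccdf",
]

#: minimal number of distances required to build a CCDF worth fitting
DEFAULT_MIN_OCCURRENCES = 50

#: runs of N at least this long split the scope into independent segments
DEFAULT_N_SPLIT = 1000


@dataclass(frozen=True)
class Word:
    """A fixed DNA word over {A,C,G,T}; N is not allowed inside a word."""

    letters: str

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("word must be non-empty")
        bad = set(self.letters) - set(DNA_LETTERS)
        if bad:
            raise ValueError(f"word {self.letters!r} contains invalid letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters


@dataclass
class DistanceSample:
    """Distances between consecutive occurrences of one word in one scope."""

    word: str
    distances: np.ndarray
    n_occurrences: int
    scope: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        if self.distances.size and self.distances.min() < 1:
            raise ValueError("all distances must be >= 1")

    @property
    def n(self) -> int:
        return int(self.distances.size)


@dataclass
class EmpiricalCCDF:
    """Distinct observed distances d_i with values P(D >= d_i).

    Values are strictly decreasing, the first is exactly 1 and all are
    positive (the largest observed distance always has mass above it).
    """

    distances: np.ndarray
    values: np.ndarray
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances.size == 0:
            raise ValueError("CCDF needs at least one point")
        if self.values[0] != 1.0:
            raise ValueError("first CCDF value must be exactly 1")
        if np.any(np.diff(self.values) >= 0):
            raise ValueError("CCDF values must be strictly decreasing")
        if self.values[-1] <= 0:
            raise ValueError("CCDF values must be positive")


class InsufficientSampleError(ValueError):
    """Raised when a distance sample is too small for a stable fit."""

    def __init__(self, n: int, minimum: int, label: str = ""):
        self.n = n
        self.minimum = minimum
        super().__init__(
            f"{label or 'sample'}: {n} distances < required minimum {minimum}"
        )


def find_occurrences(seq: SequenceRecord | str, word: Word | str) -> np.ndarray:
    """All 0-based start positions of ``word`` in ``seq``, overlaps included.

    Matching is exact over A/C/G/T; windows containing N never match.
    A word longer than the sequence yields an empty result.
    """
    text = seq.sequence if isinstance(seq, SequenceRecord) else seq
    letters = word.letters if isinstance(word, Word) else str(Word(word))
    # lookahead makes re report overlapping matches
    pattern = re.compile("(?=" + letters + ")")
    return np.fromiter(
        (m.start() for m in pattern.finditer(text)), dtype=np.int64
    )


def distances_from_positions(positions) -> np.ndarray:
    """Start-to-start differences between consecutive sorted positions."""
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be sorted and distinct")
    if pos.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.diff(pos)


def _n_split_segments(text: str, threshold: int | None) -> list[tuple[int, int]]:
    """Segment boundaries after cutting at N-runs of length >= threshold."""
    if threshold is None:
        return [(0, len(text))]
    segments = []
    prev = 0
    for m in re.finditer("N{%d,}" % threshold, text):
        if m.start() > prev:
            segments.append((prev, m.start()))
        prev = m.end()
    if prev < len(text):
        segments.append((prev, len(text)))
    return segments


def word_distances(
    seq: SequenceRecord,
    word: Word | str,
    n_split_threshold: int | None = DEFAULT_N_SPLIT,
) -> DistanceSample:
    """Whole-sequence distance sample for one word.

    Assembly-gap style runs of N at least ``n_split_threshold`` long act as
    segment boundaries: no distance bridges them.  Shorter N stretches keep
    their bp width, so real coordinates are preserved.
    """
    word = word if isinstance(word, Word) else Word(str(word))
    all_dists = []
    n_occ = 0
    for s, e in _n_split_segments(seq.sequence, n_split_threshold):
        positions = find_occurrences(seq.sequence[s:e], word)
        n_occ += positions.size
        if positions.size >= 2:
            all_dists.append(np.diff(positions))
    dists = np.concatenate(all_dists) if all_dists else np.empty(0, dtype=np.int64)
    return DistanceSample(
        word=str(word), distances=dists, n_occurrences=n_occ, scope=seq.id
    )


def distances_in_regions(
    seq: SequenceRecord,
    word: Word | str,
    regions: Sequence[GenomicInterval],
) -> DistanceSample:
    """Region-restricted distance sample.

    Occurrences are located independently inside each region (a match must lie
    entirely within it); distances never bridge two regions.  All regions'
    distances are pooled into one sample.
    """
    word = word if isinstance(word, Word) else Word(str(word))
    all_dists = []
    n_occ = 0
    for iv in regions:
        if iv.end > len(seq):
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} exceeds sequence "
                f"{seq.id} of length {len(seq)}"
            )
        positions = find_occurrences(seq.sequence[iv.start : iv.end], word)
        n_occ += positions.size
        if positions.size >= 2:
            all_dists.append(np.diff(positions))
    dists = np.concatenate(all_dists) if all_dists else np.empty(0, dtype=np.int64)
    return DistanceSample(
        word=str(word),
        distances=dists,
        n_occurrences=n_occ,
        scope=f"{seq.id}:regions[{len(regions)}]",
    )


def element_distances(
    intervals: Sequence[GenomicInterval],
    label: str = "element",
    mode: str = "start",
) -> DistanceSample:
    """Distances between consecutive genome elements (variable-length words).

    Intervals are grouped by chromosome and sorted by start; successive
    start-to-start differences are pooled across chromosomes.  With
    ``mode='gap'`` the end-to-next-start gap is used instead (negative gaps
    from overlapping elements are dropped).  Duplicate starts are collapsed
    with a warning.
    """
    if mode not in ("start", "gap"):
        raise ValueError("mode must be 'start' or 'gap'")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    all_dists = []
    n_used = 0
    n_dupes = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        seen = set()
        unique = []
        for iv in ivs:
            if iv.start in seen:
                n_dupes += 1
                continue
            seen.add(iv.start)
            unique.append(iv)
        n_used += len(unique)
        if len(unique) < 2:
            continue
        if mode == "start":
            starts = np.array([iv.start for iv in unique], dtype=np.int64)
            all_dists.append(np.diff(starts))
        else:
            gaps = np.array(
                [b.start - a.end for a, b in zip(unique, unique[1:])], dtype=np.int64
            )
            all_dists.append(gaps[gaps >= 1])
    if n_dupes:
        warnings.warn(f"collapsed {n_dupes} intervals with duplicate starts")
    dists = np.concatenate(all_dists) if all_dists else np.empty(0, dtype=np.int64)
    return DistanceSample(
        word=label, distances=dists, n_occurrences=n_used, scope="elements"
    )


def empirical_ccdf(
    sample: DistanceSample, min_occurrences: int = DEFAULT_MIN_OCCURRENCES
) -> EmpiricalCCDF:
    """Empirical P(D >= d) at each distinct observed distance.

    The first point is exactly 1 by construction.  Samples with fewer than
    ``min_occurrences`` distances are refused rather than fitted unstably.
    """
    n = sample.n
    if n < min_occurrences:
        raise InsufficientSampleError(n, min_occurrences, sample.word)
    distinct, counts = np.unique(sample.distances, return_counts=True)
    # P(D >= d_i) = (number of distances >= d_i) / n
    geq = np.cumsum(counts[::-1])[::-1]
    return EmpiricalCCDF(
        distances=distinct, values=geq / n, n=n, label=sample.word
    )
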