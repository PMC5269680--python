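"""Synthetic sequence and distance-sample generators.

Everything the analysis chain consumes can be generated here with known
ground truth, so the whole tool is testable without any genome download:

* i.i.d. random sequences with chosen letter probabilities — the regime in
  which every word's inter-occurrence distances follow the geometric null;
* q-exponential distance samples with known (q, x0) — drawn by inverse
  transform through the q-logarithm;
* sequences with one planted word whose inter-occurrence distances realise
  such a sample exactly, against a filler background that provably cannot
  create spurious occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_math import DNA_LETTERS, QParams, q_logarithm
from .occurrences import DistanceSample, Word, find_occurrences
from .sequence_io import SequenceRecord

__all__ = [
    "PlantSpec",
    "PlantedSequence",
    "random_genome",
    "sample_q_exponential_distances",
    "planted_cluster_sequence",
]


def _as_prob_array(probs) -> np.ndarray:
    if probs is None:
        arr = np.full(4, 0.25)
    elif isinstance(probs, dict):
        arr = np.array([probs.get(x, 0.0) for x in DNA_LETTERS], dtype=float)
    else:
        arr = np.asarray(probs, dtype=float)
    if arr.shape != (4,) or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be 4 non-negative values for A,C,G,T summing to 1")
    return arr


def random_genome(length: int, probs=None, seed: int = 0, id: str = "random") -> SequenceRecord:
    """I.i.d. random sequence of the given length.

    ``probs`` are the A,C,G,T probabilities (uniform by default); accepts a
    length-4 sequence or a dict.  Deterministic per seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    arr = _as_prob_array(probs)
    rng = np.random.default_rng(seed)
    letters = np.frombuffer("".join(DNA_LETTERS).encode("ascii"), dtype=np.uint8)
    draw = rng.choice(letters, size=length, p=arr)
    return SequenceRecord(id=id, sequence=draw.tobytes().decode("ascii"))


def sample_q_exponential_distances(
    params: QParams, n: int, seed: int, label: str = "synthetic"
) -> DistanceSample:
    """Draw n integer distances whose CCDF converges to the Tsallis curve.

    Inverse transform: u ~ Uniform(0,1], d = max(1, ceil(-x0 * ln_q(u))).
    With the ceiling discretisation, P(D >= d) = e_q(-(d-1)/x0) exactly —
    the same offset convention the fitter uses.  For q <= 1 the exponential
    branch is used.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = 1.0 - rng.random(n)  # (0, 1]
    if params.q <= 1.0 + 1e-12:
        x = -params.x0 * np.log(u)
    else:
        x = -params.x0 * np.asarray(q_logarithm(u, params.q))
    d = np.maximum(1, np.ceil(x)).astype(np.int64)
    return DistanceSample(word=label, distances=d, n_occurrences=n + 1, scope="synthetic")


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a sequence with one clustered word planted in it."""

    word: str
    q_target: float
    x0_target: float
    n_occurrences: int
    background_probs: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        Word(self.word)  # validates the alphabet
        if self.q_target <= 1.0:
            raise ValueError("q_target must exceed 1 (clustered regime)")
        if self.x0_target <= 0:
            raise ValueError("x0_target must be positive")
        if self.n_occurrences < 2:
            raise ValueError("need at least 2 occurrences to have distances")


@dataclass
class PlantedSequence:
    """A planted sequence with its ground-truth positions and distances."""

    record: SequenceRecord
    positions: np.ndarray
    distances: np.ndarray
    spec: PlantSpec


def _clean_small_distances(word: str) -> list[int]:
    """Distances d <= L at which two copies of the word can be placed
    without creating any third, accidental occurrence between them."""
    L = len(word)
    clean = []
    for d in range(1, L + 1):
        if d < L and word[d:] != word[: L - d]:
            continue  # inconsistent overlap: not realisable at all
        # realisable: build the two-copy string and scan it
        two = word[:d] + word
        hits = find_occurrences(two, Word(word))
        if list(hits) == [0, d]:
            clean.append(d)
    return clean


def _clamp_distances(distances: np.ndarray, word: str) -> np.ndarray:
    """Raise each sampled distance to the nearest not-smaller clean one."""
    L = len(word)
    clean_small = _clean_small_distances(word)
    out = distances.copy()
    for i, d in enumerate(out):
        if d > L:
            continue
        bumped = next((c for c in clean_small if c >= d), L + 1)
        out[i] = bumped
    return out


def planted_cluster_sequence(spec: PlantSpec, mode: str = "exact") -> PlantedSequence:
    """Construct a sequence whose planted word is clustered by design.

    Start-to-start distances between consecutive copies of the word are drawn
    from the q-exponential with (q_target, x0_target); copies are separated
    (or overlapped, where the word's structure permits) accordingly, with the
    gaps filled by random letters.

    In ``mode='exact'`` the filler alphabet is the complement of the word's
    letters, so no window containing a filler letter can match the word, and
    sampled distances are clamped up to the nearest "clean" value at which
    two copies create no accidental third occurrence; scanning the result
    reproduces the planted positions exactly.  Words using all four letters
    have no safe filler; for those, ``mode='contaminated'`` fills gaps from
    the full alphabet and accepts chance occurrences as real.
    """
    if mode not in ("exact", "contaminated"):
        raise ValueError("mode must be 'exact' or 'contaminated'")
    word = spec.word
    L = len(word)
    rng = np.random.default_rng(spec.seed)

    sample = sample_q_exponential_distances(
        QParams(q=spec.q_target, x0=spec.x0_target),
        n=spec.n_occurrences - 1,
        seed=int(rng.integers(2**31)),
        label=word,
    )
    distances = sample.distances

    if mode == "exact":
        filler_letters = sorted(set(DNA_LETTERS) - set(word))
        if not filler_letters:
            raise ValueError(
                f"word {word!r} uses all four letters: no filler alphabet can "
                "exclude accidental occurrences; use mode='contaminated'"
            )
        distances = _clamp_distances(distances, word)
        if spec.background_probs is not None:
            p = np.array([spec.background_probs.get(x, 0.0) for x in filler_letters])
            if p.sum() <= 0:
                raise ValueError("background_probs assign no mass to the filler alphabet")
            p = p / p.sum()
        else:
            p = np.full(len(filler_letters), 1.0 / len(filler_letters))
        filler_bytes = np.frombuffer("".join(filler_letters).encode("ascii"), dtype=np.uint8)
    else:
        p = _as_prob_array(spec.background_probs)
        filler_bytes = np.frombuffer("".join(DNA_LETTERS).encode("ascii"), dtype=np.uint8)
        distances = np.maximum(distances, L)  # overlaps need structure; keep copies apart

    positions = np.concatenate([[0], np.cumsum(distances)])
    total = int(positions[-1]) + L
    arr = rng.choice(filler_bytes, size=total, p=p)
    wbytes = np.frombuffer(word.encode("ascii"), dtype=np.uint8)
    for pos in positions:
        arr[pos : pos + L] = wbytes
    record = SequenceRecord(
        id=f"planted_{word}_q{spec.q_target:g}", sequence=arr.tobytes().decode("ascii")
    )
    if mode == "exact":
        found = find_occurrences(record, Word(word))
        if not np.array_equal(found, positions):
            raise AssertionError(
                "planted construction produced unexpected occurrences; "
                "this indicates an unhandled self-overlap structure"
            )
    return PlantedSequence(record=record, positions=positions, distances=distances, spec=spec)
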