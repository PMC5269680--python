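"""Batch scan -> CCDF -> fit pipeline and q-based word ranking.

Each word in each scope (a whole sequence, or a set of regions on it) gets
one q-exponential fit; words are then ranked by fitted q, descending — the
larger the entropic index, the stronger the word's spatial clustering and,
by the method's premise, its functional importance.  Words whose fit failed
or whose sample is too small are never interleaved into the q ordering; they
are appended at the bottom with the reason.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .occurrences import (
    DEFAULT_MIN_OCCURRENCES,
    DEFAULT_N_SPLIT,
    InsufficientSampleError,
    Word,
    distances_in_regions,
    empirical_ccdf,
    word_distances,
)
from .qfit import fit_q_exponential
from .sequence_io import GenomicInterval, SequenceRecord

__all__ = ["WordRanking", "enumerate_kmers", "rank_words", "compare_scopes"]

_COLUMNS = ["word", "scope", "n", "q", "x0", "r_squared", "rms", "converged", "status"]


@dataclass
class WordRanking:
    """Ranked fit results; ``table`` is a DataFrame sorted by q descending,
    with failed/insufficient rows segregated at the bottom."""

    table: pd.DataFrame

    @property
    def ok(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "ok"]

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.ok.head(n)

    def q_of(self, word: str, scope: str | None = None) -> float:
        rows = self.table[self.table["word"] == word]
        if scope is not None:
            rows = rows[rows["scope"] == scope]
        if rows.empty:
            raise KeyError(f"word {word!r} not in ranking")
        return float(rows.iloc[0]["q"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enumerate_kmers(k: int) -> list[str]:
    """All 4**k DNA words of length k, lexicographic (1 <= k <= 12)."""
    if not (1 <= k <= 12):
        raise ValueError(f"k must be in [1, 12], got {k}")
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def _sort_ranking(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_COLUMNS)
    good = df[df["status"] == "ok"].sort_values(
        ["q", "word"], ascending=[False, True], kind="mergesort"
    )
    bad = df[df["status"] != "ok"].sort_values("word", kind="mergesort")
    return pd.concat([good, bad], ignore_index=True)


def rank_words(
    seqs: Sequence[SequenceRecord],
    words: Sequence[Word | str],
    regions: Sequence[GenomicInterval] | None = None,
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    fit_space: str = "linear",
    n_split_threshold: int | None = DEFAULT_N_SPLIT,
) -> WordRanking:
    """Fit every word in every scope and rank by q.

    Each sequence record is a whole-sequence scope; when ``regions`` is
    given, every record additionally gets a region-restricted scope over the
    intervals whose chrom matches the record id.  Deterministic for fixed
    inputs and configuration.
    """
    rows = []
    for seq in seqs:
        scopes = [("whole", None)]
        if regions is not None:
            scopes.append(
                ("regions", [iv for iv in regions if iv.chrom == seq.id])
            )
        for kind, ivs in scopes:
            for w in words:
                w = w if isinstance(w, Word) else Word(str(w))
                if kind == "whole":
                    sample = word_distances(seq, w, n_split_threshold)
                    scope_label = seq.id
                else:
                    sample = distances_in_regions(seq, w, ivs)
                    scope_label = f"{seq.id}:regions"
                row = {
                    "word": str(w),
                    "scope": scope_label,
                    "n": sample.n,
                    "q": float("nan"),
                    "x0": float("nan"),
                    "r_squared": float("nan"),
                    "rms": float("nan"),
                    "converged": False,
                }
                try:
                    ccdf = empirical_ccdf(sample, min_occurrences)
                except InsufficientSampleError:
                    row["status"] = "insufficient_sample"
                    rows.append(row)
                    continue
                fit = fit_q_exponential(ccdf, fit_space=fit_space)
                row.update(
                    q=fit.q,
                    x0=fit.x0,
                    r_squared=fit.r_squared,
                    rms=fit.rms,
                    converged=fit.converged,
                    status="ok" if fit.converged else "not_converged",
                )
                rows.append(row)
    return WordRanking(table=_sort_ranking(rows))


def compare_scopes(
    rankings: Mapping[str, WordRanking], word: str
) -> pd.DataFrame:
    """Pull one word's fit out of several rankings (e.g. several genomes).

    Pure reshaping: rows of (scope, q, x0, n, r_squared, status) sorted by q
    descending among present entries; scopes where the word is absent or
    unfit are flagged, never dropped.
    """
    out = []
    for label, ranking in rankings.items():
        rows = ranking.table[ranking.table["word"] == word]
        if rows.empty:
            out.append(
                {"scope": label, "q": float("nan"), "x0": float("nan"),
                 "n": 0, "r_squared": float("nan"), "status": "absent"}
            )
            continue
        r = rows.iloc[0]
        out.append(
            {"scope": label, "q": r["q"], "x0": r["x0"], "n": r["n"],
             "r_squared": r["r_squared"], "status": r["status"]}
        )
    df = pd.DataFrame(out, columns=["scope", "q", "x0", "n", "r_squared", "status"])
    present = df[df["status"] == "ok"].sort_values("q", ascending=False, kind="mergesort")
    rest = df[df["status"] != "ok"]
    return pd.concat([present, rest], ignore_index=True)
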