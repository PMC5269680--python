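"""Sequence and interval IO, shuffled baselines and upstream windows.

FASTA is read through Bio.SeqIO (gzip-transparent); BED3/BED6 through pandas.
Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_LETTERS = frozenset("ACGTN")

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "shuffle_sequence",
    "upstream_windows",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercased on construction."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand and label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _clean_sequence(raw: str, record_id: str, on_invalid: str = "reject") -> str:
    seq = raw.upper()
    invalid = set(seq) - VALID_LETTERS
    if invalid:
        if on_invalid == "map_to_n":
            seq = "".join(ch if ch in VALID_LETTERS else "N" for ch in seq)
        else:
            raise ValueError(
                f"record {record_id!r} contains letters outside ACGTN: "
                f"{sorted(invalid)} (use on_invalid='map_to_n' to mask them)"
            )
    return seq


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, on_invalid: str = "reject") -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Sequences are uppercased; ids are the first whitespace-delimited header
    token.  Letters outside ACGTN are rejected, or masked to N when
    ``on_invalid='map_to_n'``.
    """
    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(
                SequenceRecord(id=rec.id, sequence=_clean_sequence(str(rec.seq), rec.id, on_invalid))
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals; column 4 becomes the label, column 6 the strand.

    Track/browser headers, comments and blank lines are skipped.  Malformed
    coordinates raise with the offending line number.
    """
    intervals = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, label))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def shuffle_sequence(record: SequenceRecord, seed: int) -> SequenceRecord:
    """Uniformly permute the letters of a sequence.

    The letter multiset is conserved exactly; positional correlations — and
    with them any word clustering — are destroyed, which is the null baseline
    against which elevated q values are judged.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    shuffled = rng.permutation(arr)
    return SequenceRecord(id=f"{record.id}_shuffled", sequence=shuffled.tobytes().decode("ascii"))


def upstream_windows(
    intervals: Sequence[GenomicInterval],
    window: int = 2000,
    chrom_length: int | None = None,
    assume_plus: bool = False,
) -> list[GenomicInterval]:
    """Strand-aware upstream (promoter-side) windows of gene intervals.

    For a + strand gene ``[start, end)`` the window is ``[start-window, start)``
    clipped at 0; for a - strand gene it is ``[end, end+window)`` clipped at
    ``chrom_length``.  Genes whose window is clipped to zero length are
    dropped.  Default width 2000 bp.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = []
    for iv in intervals:
        strand = iv.strand
        if strand == ".":
            if not assume_plus:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} has no strand; "
                    "set assume_plus=True to treat strandless genes as +"
                )
            strand = "+"
        if strand == "+":
            start, end = max(0, iv.start - window), iv.start
        else:
            start = iv.end
            end = iv.end + window
            if chrom_length is not None:
                end = min(end, chrom_length)
        if start < end:
            out.append(GenomicInterval(iv.chrom, start, end, strand, iv.label))
    return out
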