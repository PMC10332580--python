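"""Reconstruction of small-RNA insert sequences from overlapping read pairs.

A small-RNA insert shorter than twice the read length is sequenced twice: read 1
covers it from the 5' end and read 2, taken from the opposite strand, from the
3' end. When the insert is shorter than one read, each read runs through the
insert into the ligation adapter. Sliding read 1 against the reverse complement
of read 2 over every relative placement identifies the insert as the stretch
from the start of read 1 to the end of the reverse-complemented read 2; bases
either read contributes outside that stretch are adapter read-through and are
discarded. A placement is accepted when the region covered by both reads is at
least ``min_overlap`` nucleotides (default 10) and agrees within
``max_mismatch_frac`` (default 0, i.e. exact agreement). With 151-nt reads and
a 10-nt minimum overlap the reconstructed insert is 10-292 nt long.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "MergedRNA",
    "MergeStats",
    "merge_pair",
    "merge_library",
    "reverse_complement",
]

_RC = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_VALID = frozenset("ACGTN")
_N = ord("N")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (U treated as T, N preserved)."""
    return seq.translate(_RC)[::-1]


def _canonical(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class MergedRNA:
    """One small-RNA sequence reconstructed from a read pair.

    ``sequence`` is reported in the orientation of read 1. ``overlap_len`` is
    the number of positions covered by both reads at the accepted placement.
    """

    sequence: str
    overlap_len: int
    pair_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence


@dataclass
class MergeStats:
    """Bookkeeping for a merged library; counts are conserved:
    ``pairs == merged + rejected`` and ``merged == kept + out_of_range``."""

    pairs: int = 0
    merged: int = 0
    rejected: int = 0
    kept: int = 0
    out_of_range: int = 0


def _exact_candidates(r1: str, r2rc: str, min_overlap: int) -> list[tuple[int, int]]:
    """All placements whose overlapping window matches exactly.

    Returns (matching_bases, offset) tuples where ``offset`` is the start of
    read 1 relative to the start of the reverse-complemented read 2. Exactness
    lets a short seed anchor each candidate: for offset >= 0 the window begins
    with the first bases of read 1, for offset < 0 with the first bases of the
    reverse-complemented read 2.
    """
    L = len(r1)
    seed_len = min(12, min_overlap)
    cands: list[tuple[int, int]] = []

    seed = r1[:seed_len]
    pos = 0
    while True:
        d = r2rc.find(seed, pos)
        if d == -1 or d > L - min_overlap:
            break
        if r1[: L - d] == r2rc[d:]:
            cands.append((L - d, d))
        pos = d + 1

    seed = r2rc[:seed_len]
    pos = 1
    while True:
        p = r1.find(seed, pos)
        if p == -1 or p > L - min_overlap:
            break
        if r1[p:] == r2rc[: L - p]:
            cands.append((L - p, -p))
        pos = p + 1
    return cands


def _scored_candidates(
    r1: str, r2rc: str, min_overlap: int, max_mismatch_frac: float
) -> list[tuple[int, int]]:
    """Every placement scored by matching bases; N counts neither as a match
    nor as a mismatch."""
    a1 = np.frombuffer(r1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(r2rc.encode("ascii"), dtype=np.uint8)
    L = len(r1)
    cands: list[tuple[int, int]] = []
    for d in range(-(L - min_overlap), L - min_overlap + 1):
        a, b = max(d, 0), min(d + L, L)
        window = b - a
        if window < min_overlap:
            continue
        s1 = a1[a - d : b - d]
        s2 = a2[a:b]
        called = (s1 != _N) & (s2 != _N)
        eq = (s1 == s2) & called
        mismatches = int((called & ~eq).sum())
        if mismatches <= max_mismatch_frac * window:
            cands.append((int(eq.sum()), d))
    return cands


def merge_pair(
    seq1: str,
    seq2: str,
    *,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.0,
    pair_id: str = "",
) -> MergedRNA | None:
    """Merge one read pair into the insert sequence, or return None.

    Read 2 is reverse-complemented and every relative placement against read 1
    is considered. The best valid placement (most matching bases) wins; an
    ambiguous best (tie) rejects the pair rather than risking a chimeric
    insert. Inside the overlap the read-1 base is reported.
    """
    if len(seq1) != len(seq2):
        raise ValueError(
            f"read pair {pair_id!r}: reads have unequal lengths "
            f"({len(seq1)} vs {len(seq2)})"
        )
    s1 = _canonical(seq1)
    r2rc = reverse_complement(_canonical(seq2))
    if not (_VALID.issuperset(s1) and _VALID.issuperset(r2rc)):
        raise ValueError(f"read pair {pair_id!r}: non-ACGTN characters")
    L = len(s1)
    if L < min_overlap:
        return None

    if max_mismatch_frac == 0.0 and "N" not in s1 and "N" not in r2rc:
        cands = _exact_candidates(s1, r2rc, min_overlap)
    else:
        cands = _scored_candidates(s1, r2rc, min_overlap, max_mismatch_frac)
    if not cands:
        return None
    best = max(m for m, _ in cands)
    best_offsets = [d for m, d in cands if m == best]
    if len(best_offsets) != 1:
        return None
    d = best_offsets[0]
    if d >= 0:
        insert = s1[: L - d]
    else:
        insert = s1 + r2rc[L + d :]
    return MergedRNA(sequence=insert, overlap_len=L - abs(d), pair_id=pair_id)


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _fastq_records(handle: IO[str]) -> Iterator[tuple[str, str, str]]:
    # local import keeps Bio off the hot path for callers that never touch files
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    return FastqGeneralIterator(handle)


def _pair_key(title: str) -> str:
    token = title.split()[0] if title else ""
    if token.endswith("/1") or token.endswith("/2"):
        token = token[:-2]
    return token


def read_pairs(fastq_r1, fastq_r2) -> Iterator[tuple[str, str, str, str]]:
    """Yield (pair_id, seq1, seq2, title1) from matched paired FASTQ files
    (plain or gzipped). Raises on truncated or mispaired input, naming the
    offending record."""
    with _open_text(fastq_r1) as h1, _open_text(fastq_r2) as h2:
        sentinel = object()
        for rec1, rec2 in itertools.zip_longest(
            _fastq_records(h1), _fastq_records(h2), fillvalue=sentinel
        ):
            if rec1 is sentinel or rec2 is sentinel:
                rec = rec2 if rec1 is sentinel else rec1
                short = fastq_r1 if rec1 is sentinel else fastq_r2
                raise ValueError(
                    f"unpaired FASTQ: {short} ended before record {rec[0]!r}"
                )
            t1, s1, _ = rec1
            t2, s2, _ = rec2
            k1, k2 = _pair_key(t1), _pair_key(t2)
            if k1 != k2:
                raise ValueError(f"mispaired FASTQ records: {t1!r} vs {t2!r}")
            yield k1, s1, s2, t1


def merge_library(
    fastq_r1,
    fastq_r2,
    *,
    min_overlap: int = 10,
    length_bounds: tuple[int, int] = (10, 292),
    max_mismatch_frac: float = 0.0,
    stats: MergeStats | None = None,
) -> Iterator[MergedRNA]:
    """Merge every pair of a paired FASTQ library, keeping inserts whose
    length lies within ``length_bounds`` (closed interval).

    Returns a lazy stream; pass a ``MergeStats`` to collect the bookkeeping
    (populated as the stream is consumed).
    """
    if stats is None:
        stats = MergeStats()
    lo, hi = length_bounds

    def _gen() -> Iterator[MergedRNA]:
        for pair_id, s1, s2, _ in read_pairs(fastq_r1, fastq_r2):
            stats.pairs += 1
            merged = merge_pair(
                s1,
                s2,
                min_overlap=min_overlap,
                max_mismatch_frac=max_mismatch_frac,
                pair_id=pair_id,
            )
            if merged is None:
                stats.rejected += 1
                continue
            stats.merged += 1
            if lo <= merged.length <= hi:
                stats.kept += 1
                yield merged
            else:
                stats.out_of_range += 1

    return _gen()


def merge_pairs(
    pairs: Iterable[tuple[str, str, str]],
    *,
    min_overlap: int = 10,
    length_bounds: tuple[int, int] = (10, 292),
    max_mismatch_frac: float = 0.0,
    stats: MergeStats | None = None,
) -> Iterator[MergedRNA]:
    """Like :func:`merge_library` but over in-memory (pair_id, seq1, seq2)
    triples, e.g. straight from the simulator."""
    if stats is None:
        stats = MergeStats()
    lo, hi = length_bounds
    for pair_id, s1, s2 in pairs:
        stats.pairs += 1
        merged = merge_pair(
            s1,
            s2,
            min_overlap=min_overlap,
            max_mismatch_frac=max_mismatch_frac,
            pair_id=pair_id,
        )
        if merged is None:
            stats.rejected += 1
            continue
        stats.merged += 1
        if lo <= merged.length <= hi:
            stats.kept += 1
            yield merged
        else:
            stats.out_of_range += 1
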