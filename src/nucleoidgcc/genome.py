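"""Circular-genome coordinate model and in-silico restriction digestion.

All coordinates in this package are 0-based, half-open and circular. A
:class:`GenomeMap` is the coordinate backbone of every downstream analysis:
the circular chromosome partitioned into restriction fragments by an
in-silico digest (HhaI by default, recognising ``GCGC`` and cutting after
the third base, ``GCG^C``). The enzyme's 2-nt overhang is ignored: a single
blunt cut coordinate defines fragment boundaries, because fragment identity
rather than end chemistry is what matters for interaction analysis.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Fragment",
    "GenomeMap",
    "digest_genome",
    "circular_distance",
    "read_fasta",
    "write_fragments_tsv",
]

_NON_ACGT = re.compile(r"[^ACGT]")

DEFAULT_MOTIF = "GCGC"
DEFAULT_CUT_OFFSET = 3


def _validate_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty genome sequence")
    seq = seq.upper()
    m = _NON_ACGT.search(seq)
    if m:
        raise ValueError(
            f"non-ACGT character {m.group()!r} at position {m.start()}"
        )
    return seq


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment on the circle.

    ``start`` lies in ``[0, L)``; the half-open interval ``[start,
    start+length)`` is taken modulo the genome length, so a fragment may
    wrap the origin of coordinates. ``end`` is ``(start+length) mod L``
    (equal to ``start`` for a fragment spanning the whole circle).
    """

    id: int
    start: int
    length: int
    genome_length: int

    @property
    def end(self) -> int:
        return (self.start + self.length) % self.genome_length

    @property
    def midpoint(self) -> int:
        return (self.start + self.length // 2) % self.genome_length

    def contains(self, pos: int) -> bool:
        return (pos - self.start) % self.genome_length < self.length

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fragment length must be >= 1")


@dataclass(frozen=True)
class GenomeMap:
    """A circular genome partitioned into restriction fragments.

    Fragments are non-overlapping, cover the circle exactly once and are
    numbered consecutively in coordinate order (fragment 0 starts at the
    smallest cut coordinate). With ``k >= 1`` cuts there are exactly ``k``
    fragments; an uncut genome is a single fragment ``[0, L)``.
    """

    length: int
    enzyme_motif: str
    cut_offset: int
    cut_positions: tuple[int, ...]
    fragments: tuple[Fragment, ...] = field(repr=False)

    def __post_init__(self) -> None:
        total = sum(f.length for f in self.fragments)
        if total != self.length:
            raise ValueError(
                f"fragments cover {total} bp, genome is {self.length} bp"
            )

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def locate_id(self, pos: int) -> int:
        """Fragment id of the unique fragment containing ``pos``."""
        if not 0 <= pos < self.length:
            raise ValueError(f"position {pos} outside genome [0, {self.length})")
        if not self.cut_positions:
            return 0
        i = bisect_right(self.cut_positions, pos) - 1
        return i if i >= 0 else len(self.cut_positions) - 1

    def locate_position(self, pos: int) -> Fragment:
        return self.fragments[self.locate_id(pos)]

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([f.midpoint for f in self.fragments], dtype=np.int64)

    def are_adjacent(self, i: int, j: int) -> bool:
        """Whether fragments ``i`` and ``j`` are circularly consecutive."""
        n = self.n_fragments
        if not (0 <= i < n and 0 <= j < n):
            raise KeyError(f"unknown fragment id in ({i}, {j})")
        if n < 2 or i == j:
            return False
        return (i - j) % n == 1 or (j - i) % n == 1


def _motif_occurrences(seq: str, motif: str) -> list[int]:
    """Start positions of (possibly overlapping) motif occurrences on the
    circle, including occurrences wrapping the coordinate origin."""
    L = len(seq)
    ext = seq + seq[: len(motif) - 1]
    occ: list[int] = []
    start = 0
    while True:
        i = ext.find(motif, start)
        if i == -1 or i >= L:
            break
        occ.append(i)
        start = i + 1
    return occ


def digest_genome(
    seq: str,
    motif: str = DEFAULT_MOTIF,
    cut_offset: int = DEFAULT_CUT_OFFSET,
) -> GenomeMap:
    """In-silico digest of a circular sequence.

    One cut is placed at ``(occurrence_start + cut_offset) mod L`` for every
    motif occurrence, including occurrences that wrap the coordinate origin
    and overlapping occurrences (``GCGCGC`` cuts twice). Fragments run
    between consecutive cuts in circular order.
    """
    seq = _validate_sequence(seq)
    motif = motif.upper()
    if not motif or _NON_ACGT.search(motif):
        raise ValueError("motif must be a non-empty, non-degenerate DNA word")
    if not 0 <= cut_offset <= len(motif):
        raise ValueError("cut_offset must lie within the motif")
    L = len(seq)
    cuts = sorted({(i + cut_offset) % L for i in _motif_occurrences(seq, motif)})
    if not cuts:
        fragments = (Fragment(0, 0, L, L),)
    else:
        fragments = tuple(
            Fragment(
                k,
                cuts[k],
                (cuts[(k + 1) % len(cuts)] - cuts[k]) % L or L,
                L,
            )
            for k in range(len(cuts))
        )
    return GenomeMap(L, motif, cut_offset, tuple(cuts), fragments)


def circular_distance(a, b, length: int):
    """Shortest arc length between two coordinates on a circle of the given
    length; always in ``[0, length/2]``. Accepts scalars or numpy arrays."""
    a = np.asarray(a)
    b = np.asarray(b)
    if np.any(a < 0) or np.any(a >= length) or np.any(b < 0) or np.any(b >= length):
        raise ValueError(f"coordinates out of range [0, {length})")
    d = np.abs(a - b)
    out = np.minimum(d, length - d)
    return out.item() if out.ndim == 0 else out


def read_fasta(path) -> str:
    """Read a single circular replicon from FASTA; multi-record input is
    rejected (multi-replicon genomes are out of scope)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} holds {len(records)} records; expected a single circular replicon"
        )
    return _validate_sequence(str(records[0].seq))


def write_fragments_tsv(gmap: GenomeMap, path) -> None:
    """Serialize a fragment map as BED-like TSV (id, start, end)."""
    with open(path, "w") as fh:
        fh.write("fragment_id\tstart\tend\n")
        for f in gmap.fragments:
            fh.write(f"{f.id}\t{f.start}\t{f.end}\n")
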