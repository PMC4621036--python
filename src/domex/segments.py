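"""Segments and candidate assemblies.

A boundary predictor splits a chain of length ``L`` into ``n+1`` contiguous
segments with ``n`` boundaries; a boundary at position ``B`` means "break
after residue B" (1-based).  A putative discontinuous domain is the
concatenation of two *non-adjacent* segments, optionally also assembled in
reversed (C-to-N segment) order to catch segment-swapping domains.
All coordinates in I/O are 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

DEFAULT_MIN_SEGMENT_LEN = 40


@dataclass(frozen=True)
class BoundarySet:
    """Predicted segment boundaries for one chain."""

    chain_id: str
    chain_length: int
    boundaries: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.chain_length <= 0:
            raise ValueError("chain_length must be positive")
        bs = self.boundaries
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError(f"{self.chain_id}: boundaries must be strictly increasing")
        if any(not (1 <= b < self.chain_length) for b in bs):
            raise ValueError(
                f"{self.chain_id}: boundaries must lie in [1, chain_length-1]"
            )

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) + 1


@dataclass(frozen=True)
class Segment:
    """A contiguous residue range of the query chain (1-based inclusive)."""

    index: int  # 1-based ordinal along the chain
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("segment sequence length mismatch")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AssembledCandidate:
    """An ordered pair of non-adjacent segments concatenated into a putative domain.

    ``junction`` is the position (within the concatenated sequence) of the
    last residue contributed by the first component; the alignment of the
    candidate to a template is split between ``junction`` and ``junction+1``.
    """

    first: Segment
    second: Segment
    reversed: bool = False

    def __post_init__(self) -> None:
        if abs(self.first.index - self.second.index) < 2:
            raise ValueError("candidate segments must be non-adjacent")
        if not self.reversed and self.first.index >= self.second.index:
            raise ValueError("forward candidate must be N-to-C ordered")
        if self.reversed and self.first.index <= self.second.index:
            raise ValueError("reversed candidate must be C-to-N ordered")

    @property
    def sequence(self) -> str:
        return self.first.sequence + self.second.sequence

    @property
    def junction(self) -> int:
        return len(self.first.sequence)

    @property
    def segment_indices(self) -> tuple[int, int]:
        return (self.first.index, self.second.index)

    @property
    def label(self) -> str:
        arrow = "rev" if self.reversed else "fwd"
        return f"S{self.first.index}+S{self.second.index}:{arrow}"


def segments_from_boundaries(sequence: str, b: BoundarySet) -> list[Segment]:
    """Cut a chain into the n+1 contiguous segments induced by n boundaries."""
    if b.chain_length != len(sequence):
        raise ValueError(
            f"{b.chain_id}: chain_length {b.chain_length} != sequence length {len(sequence)}"
        )
    edges = [0, *b.boundaries, len(sequence)]
    segments = []
    for idx, (lo, hi) in enumerate(zip(edges, edges[1:]), start=1):
        segments.append(
            Segment(index=idx, start=lo + 1, end=hi, sequence=sequence[lo:hi])
        )
    return segments


def enumerate_candidates(
    segments: Sequence[Segment],
    min_len: int = DEFAULT_MIN_SEGMENT_LEN,
    allow_reversed: bool = False,
) -> list[AssembledCandidate]:
    """All non-adjacent segment pairs long enough to be assembled.

    Pairs (i, j) with j >= i+2 and both segments at least ``min_len``
    residues; adjacent pairs are never assembled (they are continuous in
    sequence).  With ``allow_reversed`` each pair is additionally emitted in
    swapped segment order, residue order within each segment unchanged.
    """
    out: list[AssembledCandidate] = []
    for i, si in enumerate(segments):
        for sj in segments[i + 2 :]:
            if len(si) < min_len or len(sj) < min_len:
                continue
            out.append(AssembledCandidate(first=si, second=sj, reversed=False))
            if allow_reversed:
                out.append(AssembledCandidate(first=sj, second=si, reversed=True))
    return out


def read_boundary_tsv(path: str | Path) -> dict[str, list[int]]:
    """Read a boundary TSV (columns: chain_id, boundary_position).

    Positions use "break after residue B" semantics, 1-based.  A chain may
    appear on several rows; boundaries are collected and sorted.  A chain
    listed with an empty/zero position contributes no boundary (single
    segment chain).
    """
    path = Path(path)
    boundaries: dict[str, list[int]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "chain_id":
                continue
            chain_id = row[0].strip()
            boundaries.setdefault(chain_id, [])
            if len(row) > 1 and row[1].strip():
                pos = int(row[1])
                if pos > 0:
                    boundaries[chain_id].append(pos)
    return {cid: sorted(bs) for cid, bs in boundaries.items()}


def write_boundary_tsv(boundaries: dict[str, Sequence[int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tboundary_position\n")
        for cid, bs in boundaries.items():
            if not bs:
                fh.write(f"{cid}\t\n")
            for b in bs:
                fh.write(f"{cid}\t{b}\n")
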