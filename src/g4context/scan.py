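"""PG4 motif scanner: G_x-N_{1-7}-G_x-N_{1-7}-G_x-N_{1-7}-G_x with x >= 3.

Tracks are *maximal* runs of G, so an uninterrupted poly-G stretch is a single
track and cannot by itself satisfy the four-track pattern (each loop needs at
least ``loop_min`` non-track nucleotides).  When a region offers more than
four usable tracks, one match is reported per collapsed extent and the four
tetrad tracks are the in-order subset that minimizes total loop length (ties
broken to the leftmost subset), which makes loop accounting deterministic.
Skipped surplus tracks sit inside loops and their Gs count as loop
nucleotides; loops must still fit the ``[loop_min, loop_max]`` bounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .core_seq import SequenceRecord
from .errors import G4DataError

_RUN_RE = {base: re.compile(f"{base}+") for base in "GC"}


@dataclass(frozen=True)
class GTrack:
    """A maximal run of G (0-based start, run length)."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class PG4Match:
    """One detected PG4: its tracks, the chosen tetrad tracks, and loops."""

    record_id: str
    start: int
    end: int  # 0-based half-open span, first track start .. last track end
    tracks: tuple[GTrack, ...]
    tetrad_tracks: tuple[GTrack, ...]
    loops: tuple[int, int, int]

    @property
    def total_loop_length(self) -> int:
        return sum(self.loops)

    def motif(self, residues: str) -> str:
        return residues[self.start : self.end]


def find_g_tracks(residues: str, min_len: int = 3, base: str = "G") -> list[GTrack]:
    """All maximal runs of ``base`` with length >= ``min_len``, left to right."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if base not in _RUN_RE:
        raise ValueError("base must be 'G' or 'C'")
    return [
        GTrack(m.start(), m.end() - m.start())
        for m in _RUN_RE[base].finditer(residues)
        if m.end() - m.start() >= min_len
    ]


def _valid_chains(
    tracks: Sequence[GTrack], loop_min: int, loop_max: int
) -> list[tuple[int, int, int, int]]:
    """All in-order 4-subsets of tracks whose three inter-track gaps lie in
    [loop_min, loop_max].  Gaps are measured end-to-start, so Gs of skipped
    tracks count as loop nucleotides."""
    n = len(tracks)
    succ: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            gap = tracks[j].start - tracks[i].end
            if gap > loop_max:
                break  # tracks are ordered; later gaps only grow
            if gap >= loop_min:
                succ[i].append(j)
    chains: list[tuple[int, int, int, int]] = []
    for a in range(n):
        for b in succ[a]:
            for c in succ[b]:
                for d in succ[c]:
                    chains.append((a, b, c, d))
    return chains


def _best_tetrad(
    tracks: Sequence[GTrack], loop_min: int, loop_max: int
) -> tuple[tuple[int, int, int, int], tuple[int, int, int]] | None:
    """Minimum-total-loop valid 4-subset; ties go to the leftmost index tuple."""
    best: tuple[int, tuple[int, int, int, int]] | None = None
    for chain in _valid_chains(tracks, loop_min, loop_max):
        loops = tuple(
            tracks[chain[k + 1]].start - tracks[chain[k]].end for k in range(3)
        )
        key = (sum(loops), chain)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    total, chain = best
    loops = tuple(tracks[chain[k + 1]].start - tracks[chain[k]].end for k in range(3))
    return chain, loops  # type: ignore[return-value]


def scan_pg4(
    record: SequenceRecord | str,
    min_track: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    record_id: str | None = None,
) -> list[PG4Match]:
    """Detect PG4 motifs in a normalized sequence.

    Overlapping alternative extents are collapsed greedily to the
    leftmost-starting, then longest span; each reported span carries every
    maximal G-run of length >= ``min_track`` inside it, with the tetrad
    assignment minimizing total loop length.
    """
    if not (1 <= loop_min <= loop_max):
        raise ValueError("need 1 <= loop_min <= loop_max")
    if min_track < 2:
        raise ValueError("min_track must be >= 2")
    if isinstance(record, SequenceRecord):
        residues = record.residues
        rid = record.id
    else:
        residues = record
        rid = record_id or "seq"

    tracks = find_g_tracks(residues, min_track)
    chains = _valid_chains(tracks, loop_min, loop_max)
    if not chains:
        return []

    spans = sorted(
        {(tracks[c[0]].start, tracks[c[3]].end) for c in chains},
        key=lambda s: (s[0], -s[1]),
    )
    selected: list[tuple[int, int]] = []
    for span in spans:
        if all(span[0] >= e or span[1] <= s for s, e in selected):
            selected.append(span)

    matches: list[PG4Match] = []
    for start, end in sorted(selected):
        in_span = tuple(t for t in tracks if t.start >= start and t.end <= end)
        best = _best_tetrad(in_span, loop_min, loop_max)
        assert best is not None  # the span came from a valid chain
        chain, loops = best
        matches.append(
            PG4Match(
                record_id=rid,
                start=start,
                end=end,
                tracks=in_span,
                tetrad_tracks=tuple(in_span[i] for i in chain),
                loops=loops,
            )
        )
    return matches


def select_retained(matches: Sequence[PG4Match], min_gap: int = 10) -> list[PG4Match]:
    """Greedy left-to-right retention of matches separated by >= ``min_gap`` nt.

    The first match is kept; a later match is discarded when its start lies
    closer than ``min_gap`` nt to the end of the last retained match.
    """
    starts = [m.start for m in matches]
    if starts != sorted(starts):
        raise G4DataError("select_retained requires matches sorted by start")
    retained: list[PG4Match] = []
    for m in matches:
        if retained and m.start < retained[-1].end + min_gap:
            continue
        if retained and (m.start, m.end) == (retained[-1].start, retained[-1].end):
            continue  # duplicate of the last retained match
        retained.append(m)
    return retained


def loop_lengths(match: PG4Match) -> tuple[int, int, int, int]:
    """Loop lengths (l1, l2, l3) and their total for a match's tetrad tracks."""
    l1, l2, l3 = match.loops
    return l1, l2, l3, l1 + l2 + l3


def enumerate_tetrads(
    tracks: Sequence[GTrack], loop_min: int = 1, loop_max: int = 7
) -> Iterable[tuple[tuple[GTrack, GTrack, GTrack, GTrack], tuple[int, int, int]]]:
    """Exhaustively yield every valid in-order 4-subset with its loop gaps.

    Brute-force companion to the scanner used for verification: checks every
    4-combination rather than walking the successor graph.
    """
    for subset in combinations(range(len(tracks)), 4):
        loops = tuple(
            tracks[subset[k + 1]].start - tracks[subset[k]].end for k in range(3)
        )
        if all(loop_min <= g <= loop_max for g in loops):
            yield tuple(tracks[i] for i in subset), loops  # type: ignore[misc]
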