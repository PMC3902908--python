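"""Deterministic generator of test sequences with planted PG4s and
controllable C-track contexts.

The generator emulates the construct design used to probe context effects on
G4 folding: a canonical PG4 core (4-6 G-tracks of >= 3 Gs separated by
1-7 nt loops) flanked by background sequence into which C-runs of chosen
length and position can be planted, mirroring wild-type transcripts with
inhibitory C-tracks and their C/A-mutant versions.  Background flanks are
post-processed to break accidental G- or C-runs of length >= 3 so the planted
features are the only scanner-relevant ones and truth annotations stay exact.
Every record draws from a private random stream derived from
``(seed, record index)``, so regeneration is byte-identical and independent
of generation order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_seq import CandidateTableRow, SequenceRecord
from .errors import G4DataError

_BAD_RUN_RE = re.compile(r"G{3,}|C{3,}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one planted-PG4 record family.

    ``c_track_spec`` plants C-runs in the flanks as ``(offset, length)``
    pairs: a non-negative offset counts nucleotides from the PG4 3' boundary
    to the run start; a negative offset counts from the PG4 5' boundary back
    to the run end (so ``(-3, 4)`` ends 3 nt upstream of the PG4).
    """

    seed: int = 0
    n_records: int = 1
    track_count: int = 4
    track_length: int = 3
    loop_lengths: tuple[int, int, int] = (1, 1, 1)
    flank_length: int = 50
    c_track_spec: tuple[tuple[int, int], ...] = ()
    background_gc: float = 0.4

    def __post_init__(self) -> None:
        if not 4 <= self.track_count <= 6:
            raise G4DataError("track_count must be in 4..6")
        if self.track_length < 3:
            raise G4DataError("track_length must be >= 3")
        if len(self.loop_lengths) != 3 or any(not 1 <= l <= 7 for l in self.loop_lengths):
            raise G4DataError("loop_lengths must be three integers in [1, 7]")
        if not 0.0 <= self.background_gc <= 1.0:
            raise G4DataError("background_gc must be in [0, 1]")
        if self.flank_length < 0 or self.n_records < 1:
            raise G4DataError("flank_length must be >= 0 and n_records >= 1")
        for offset, length in self.c_track_spec:
            if length < 1:
                raise G4DataError("planted C-run length must be >= 1")
            extent = offset + length if offset >= 0 else -offset + length
            if extent > self.flank_length - 1:  # -1: room for a non-C separator
                raise G4DataError(
                    f"planted C-run (offset={offset}, length={length}) does not fit "
                    f"in a {self.flank_length}-nt flank"
                )


@dataclass(frozen=True)
class PlantedTruth:
    """Exact coordinates of the planted features (0-based half-open)."""

    pg4_start: int
    pg4_end: int
    tracks: tuple[tuple[int, int], ...]  # (start, length) per G-track
    loops: tuple[int, ...]
    c_runs: tuple[tuple[int, int], ...] = ()  # (start, length), absolute

    @property
    def total_c_run_length(self) -> int:
        return sum(length for _, length in self.c_runs)


def _loop_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(["A", "U"], size=length))


def _background(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    if length == 0:
        return []
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chars = list(rng.choice(["A", "C", "G", "U"], size=length, p=p))
    # break accidental G/C runs >= 3 by substituting the middle base with A
    text = "".join(chars)
    while (m := _BAD_RUN_RE.search(text)) is not None:
        mid = (m.start() + m.end()) // 2
        chars[mid] = "A"
        text = "".join(chars)
    return chars


def _span_recoverable(
    tracks: Sequence[tuple[int, int]], loop_min: int = 1, loop_max: int = 7
) -> bool:
    """Whether some in-order 4-subset of the planted tracks chains from the
    first to the last track with every end-to-start gap in [loop_min, loop_max].
    Pure arithmetic on planted coordinates (no scanner involved)."""
    n = len(tracks)
    for subset in combinations(range(1, n - 1), 2):
        chain = [0, *subset, n - 1]
        gaps = [
            tracks[chain[k + 1]][0] - (tracks[chain[k]][0] + tracks[chain[k]][1])
            for k in range(3)
        ]
        if all(loop_min <= g <= loop_max for g in gaps):
            return True
    return False


def make_pg4(
    spec: SyntheticSpec, index: int = 0, record_id: str | None = None
) -> tuple[SequenceRecord, PlantedTruth]:
    """Build one flanked planted-PG4 record with its truth annotation."""
    rng = np.random.default_rng([spec.seed, index])
    loops = [spec.loop_lengths[i % 3] for i in range(spec.track_count - 1)]

    core_parts: list[str] = []
    track_offsets: list[tuple[int, int]] = []
    pos = 0
    for i in range(spec.track_count):
        track_offsets.append((pos, spec.track_length))
        core_parts.append("G" * spec.track_length)
        pos += spec.track_length
        if i < spec.track_count - 1:
            core_parts.append(_loop_seq(rng, loops[i]))
            pos += loops[i]
    core = "".join(core_parts)

    if spec.track_count > 4 and not _span_recoverable(track_offsets):
        raise G4DataError(
            "infeasible spec: with >4 tracks no four-track chain spans the whole "
            "planted motif within the 1-7 nt loop bounds"
        )

    flank5 = _background(rng, spec.flank_length, spec.background_gc)
    flank3 = _background(rng, spec.flank_length, spec.background_gc)
    pg4_start = spec.flank_length
    pg4_end = pg4_start + len(core)

    c_runs: list[tuple[int, int]] = []
    for offset, length in sorted(spec.c_track_spec):
        if offset >= 0:  # downstream flank, offset from the PG4 3' boundary
            lo = offset
            flank, base = flank3, pg4_end
        else:  # upstream flank, |offset| from the PG4 5' boundary back
            lo = spec.flank_length + offset - length
            flank, base = flank5, 0
            if lo < 0:
                raise G4DataError("planted C-run extends past the 5' end")
        for k in range(length):
            flank[lo + k] = "C"
        # keep the planted run maximal: non-C separators on both sides
        if lo - 1 >= 0 and flank[lo - 1] == "C":
            flank[lo - 1] = "A"
        if lo + length < len(flank) and flank[lo + length] == "C":
            flank[lo + length] = "A"
        c_runs.append((base + lo, length))
    starts = sorted(c_runs)
    for (s1, l1), (s2, _) in zip(starts, starts[1:]):
        if s1 + l1 >= s2:
            raise G4DataError("planted C-runs overlap or touch; separate them")

    # a flank G adjacent to the core would extend a planted track
    if flank5 and flank5[-1] == "G":
        flank5[-1] = "A"
    if flank3 and flank3[0] == "G":
        flank3[0] = "A"

    residues = "".join(flank5) + core + "".join(flank3)
    rid = record_id or f"synth{spec.seed}_{index:03d}"
    truth = PlantedTruth(
        pg4_start=pg4_start,
        pg4_end=pg4_end,
        tracks=tuple((pg4_start + s, l) for s, l in track_offsets),
        loops=tuple(loops),
        c_runs=tuple(sorted(c_runs)),
    )
    return SequenceRecord(id=rid, residues=residues), truth


def mutate(
    record: SequenceRecord, truth: PlantedTruth, kind: str
) -> SequenceRecord:
    """Return a mutated copy of a planted record.

    ``G_to_A`` substitutes A at every third position of each planted G-track
    (one substitution for tracks up to 5 Gs), leaving no run of 3 Gs anywhere,
    which guarantees the scanner rejects the mutant.  ``C_to_A`` replaces
    every planted flank C-run with an A-run of equal length, removing the
    Watson-Crick competition and raising the cG/cC ratio.
    """
    chars = list(record.residues)
    if kind == "G_to_A":
        if not truth.tracks:
            raise G4DataError("G_to_A mutation requires a planted PG4")
        for start, length in truth.tracks:
            for off in range(2, length, 3):
                chars[start + off] = "A"
            if length <= 2:  # unreachable for valid specs, defensive
                chars[start] = "A"
    elif kind == "C_to_A":
        for start, length in truth.c_runs:
            for k in range(length):
                chars[start + k] = "A"
    else:
        raise ValueError(f"unknown mutation kind {kind!r}")
    return SequenceRecord(
        id=f"{record.id}|{kind}",
        residues="".join(chars),
        description=record.description,
        source_alphabet=record.source_alphabet,
    )


@dataclass(frozen=True)
class SyntheticCandidate:
    record: SequenceRecord
    truth: PlantedTruth
    fold_label: bool


def _default_label_rule(truth: PlantedTruth) -> bool:
    """Folding iff no planted C-run of length >= 3 sits in the flanks."""
    return all(length < 3 for _, length in truth.c_runs)


def make_dataset(
    specs: Sequence[SyntheticSpec],
    label_rule: Callable[[PlantedTruth], bool] | None = None,
) -> list[SyntheticCandidate]:
    """Generate one record per spec entry (honouring ``n_records``) and label
    it from the ground-truth construction, never from any score."""
    rule = label_rule or _default_label_rule
    out: list[SyntheticCandidate] = []
    ordinal = 0
    for spec in specs:
        for index in range(spec.n_records):
            record, truth = make_pg4(
                spec, index=ordinal, record_id=f"synth{spec.seed}_{ordinal:03d}"
            )
            out.append(SyntheticCandidate(record, truth, rule(truth)))
            ordinal += 1
    return out


def to_candidate_rows(candidates: Sequence[SyntheticCandidate]) -> list[CandidateTableRow]:
    return [
        CandidateTableRow(
            id=c.record.id,
            sequence=c.record.residues,
            fold_label=c.fold_label,
        )
        for c in candidates
    ]


def to_table(candidates: Sequence[SyntheticCandidate]) -> pd.DataFrame:
    """Candidate table (TSV-ready) with construction-truth labels."""
    return pd.DataFrame(
        {
            "id": [c.record.id for c in candidates],
            "sequence": [c.record.residues for c in candidates],
            "fold_label": [
                "folding" if c.fold_label else "non-folding" for c in candidates
            ],
        }
    )


def example_dataset(seed: int = 0, n: int = 20, flank: int = 50) -> list[SyntheticCandidate]:
    """A seeded benchmark set: half the candidates carry heavy planted
    C-tracks in their flanks (non-folding by construction, like wild-type
    transcripts with inhibitory contexts), half carry none (folding, like
    their C/A-mutant versions).  Loop lengths vary independently of the
    label so total loop length is uninformative by design.
    """
    rng = np.random.default_rng([seed, 986533])
    specs: list[SyntheticSpec] = []
    for i in range(n):
        heavy = i % 2 == 1
        loop_lengths = tuple(int(v) for v in rng.integers(1, 8, size=3))
        if heavy:
            # 2 runs per side, 3-6 C each, 5-20 nt away from the PG4
            c_spec = []
            for sign in (-1, 1):
                offs = sorted(int(v) for v in rng.integers(5, 21, size=2))
                lens = [int(v) for v in rng.integers(3, 7, size=2)]
                c_spec.append((sign * offs[0], lens[0]))
                c_spec.append((sign * (offs[1] + lens[0] + 8), lens[1]))
        else:
            c_spec = []
        specs.append(
            SyntheticSpec(
                seed=seed,
                track_count=4,
                track_length=int(rng.integers(3, 5)),
                loop_lengths=loop_lengths,  # type: ignore[arg-type]
                flank_length=flank,
                c_track_spec=tuple(c_spec),
                background_gc=0.4,
            )
        )
    out: list[SyntheticCandidate] = []
    for i, spec in enumerate(specs):
        record, truth = make_pg4(spec, index=i)
        out.append(SyntheticCandidate(record, truth, _default_label_rule(truth)))
    return out
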