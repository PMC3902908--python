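"""Consecutive-G / consecutive-C (cG, cC) scoring and the cG/cC ratio.

The cG score of a string counts every substring of consecutive Gs, weighting
a substring of length i by 10*i: each single G contributes 10, each GG
occurrence 20, each GGG occurrence 30, and so on.  A maximal run of length L
therefore contributes sum_{i=1..L} 10*i*(L-i+1) = 10*L*(L+1)*(L+2)/6, so the
score depends only on the multiset of maximal run lengths ("GGG" scores 100,
"GG" scores 40).  cC is the same with C.  The cG/cC ratio over a PG4 plus its
flanking context is the folding predictor: long G-tracks favour quadruplex
folding while long neighbouring C-tracks favour the competing Watson-Crick
hairpins, so high ratios predict folding.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .core_seq import SequenceRecord
from .errors import G4DataError
from .scan import PG4Match

#: Context-window presets (nt of flank on each side of the PG4).
SHORT_CONTEXT = 15
LONG_CONTEXT = 50

_BASE_RE = {"G": re.compile("G+"), "C": re.compile("C+")}


def run_substring_counts(residues: str, base: str) -> dict[int, int]:
    """Count substring occurrences of exactly i consecutive ``base`` characters.

    A maximal run of length L contains L - i + 1 occurrences for each
    i <= L (e.g. "GGGCGGG" has two GGG occurrences).  Lengths with zero count
    are omitted.
    """
    if base not in _BASE_RE:
        raise ValueError("base must be 'G' or 'C'")
    counts: dict[int, int] = {}
    for m in _BASE_RE[base].finditer(residues):
        run_len = m.end() - m.start()
        for i in range(1, run_len + 1):
            counts[i] = counts.get(i, 0) + (run_len - i + 1)
    return counts


def _run_score(residues: str, base: str) -> int:
    # closed form per maximal run: sum_{i=1..L} 10*i*(L-i+1) = 10*L(L+1)(L+2)/6
    total = 0
    for m in _BASE_RE[base].finditer(residues):
        run = m.end() - m.start()
        total += 10 * run * (run + 1) * (run + 2) // 6
    return total


def cg_score(residues: str) -> int:
    """Consecutive-G score: 10 per G, 20 per GG occurrence, 30 per GGG, ..."""
    return _run_score(residues, "G")


def cc_score(residues: str) -> int:
    """Consecutive-C score, computed exactly like :func:`cg_score` with C."""
    return _run_score(residues, "C")


def cgcc_ratio(residues: str) -> float:
    """cG/cC ratio.

    Degenerate cases are carried as sentinels rather than errors: ``inf``
    when cC = 0 (no Watson-Crick competition at all, classifies as folding)
    and ``nan`` when both scores are 0 (no G and no C — undefined, excluded
    from ROC analyses).
    """
    cg = cg_score(residues)
    cc = cc_score(residues)
    if cc == 0:
        return math.nan if cg == 0 else math.inf
    return cg / cc


@dataclass(frozen=True)
class ContextWindow:
    """A PG4-plus-context slice of a record, with clamping bookkeeping."""

    record_id: str
    match_start: int
    match_end: int
    flank5_requested: int
    flank3_requested: int
    flank5_actual: int
    flank3_actual: int
    window_start: int
    window_end: int
    window_residues: str

    @property
    def clamped(self) -> bool:
        """True when a sequence boundary truncated a requested flank."""
        return (
            self.flank5_actual < self.flank5_requested
            or self.flank3_actual < self.flank3_requested
        )


@dataclass(frozen=True)
class ScoreResult:
    """cG, cC and cG/cC for one context window."""

    cg: int
    cc: int
    ratio: float
    window: ContextWindow | None = None

    @property
    def cc_zero(self) -> bool:
        return self.cc == 0 and self.cg > 0

    @property
    def undefined(self) -> bool:
        """Both scores zero: the 0/0 case, excluded from ROC analyses."""
        return math.isnan(self.ratio)


def extract_context(
    record: SequenceRecord,
    match: PG4Match,
    flank5: int = LONG_CONTEXT,
    flank3: int = LONG_CONTEXT,
) -> ContextWindow:
    """Slice ``flank5``/``flank3`` nt of context around a match, clamping at
    the sequence ends (actual flank lengths are recorded)."""
    n = len(record.residues)
    if not (0 <= match.start < match.end <= n):
        raise G4DataError(
            f"match span {match.start}..{match.end} outside record {record.id!r} (length {n})"
        )
    if flank5 < 0 or flank3 < 0:
        raise ValueError("flank lengths must be >= 0")
    start = max(0, match.start - flank5)
    end = min(n, match.end + flank3)
    return ContextWindow(
        record_id=record.id,
        match_start=match.start,
        match_end=match.end,
        flank5_requested=flank5,
        flank3_requested=flank3,
        flank5_actual=match.start - start,
        flank3_actual=end - match.end,
        window_start=start,
        window_end=end,
        window_residues=record.residues[start:end],
    )


def score_candidate(
    record: SequenceRecord,
    match: PG4Match,
    flank5: int = LONG_CONTEXT,
    flank3: int = LONG_CONTEXT,
) -> ScoreResult:
    """Score the full context window (the PG4's own G-tracks included)."""
    window = extract_context(record, match, flank5, flank3)
    residues = window.window_residues
    return ScoreResult(
        cg=cg_score(residues),
        cc=cc_score(residues),
        ratio=cgcc_ratio(residues),
        window=window,
    )


def score_sequence(residues: str) -> ScoreResult:
    """Score a candidate sequence taken verbatim (already windowed)."""
    return ScoreResult(
        cg=cg_score(residues), cc=cc_score(residues), ratio=cgcc_ratio(residues)
    )
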