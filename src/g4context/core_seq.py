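"""Sequence data model, alphabet normalization, and FASTA/TSV/BED input-output.

All internal computation is on the RNA alphabet: T is rewritten to U on input
(the score treats DNA-derived UTR sequences as the transcript they encode).
IUPAC ambiguity codes are retained but never count as G or C.  Internal
coordinates are 0-based half-open; the TSV report uses 1-based inclusive
coordinates and BED output is standard BED6 (0-based half-open).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import G4DataError

#: IUPAC nucleotide one-letter codes after T->U normalization.
IUPAC_CODES = frozenset("ACGUNRYSWKMBDHV")

_FOLD_LABELS = {"folding": True, "non-folding": False}


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence normalized to the RNA alphabet."""

    id: str
    residues: str
    description: str = ""
    source_alphabet: str = "RNA"  # "DNA" if any T was seen on input

    def __post_init__(self) -> None:
        if not self.id:
            raise G4DataError("sequence record id must be non-empty")
        if not self.residues:
            raise G4DataError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, *, context: str = "sequence") -> tuple[str, str]:
    """Uppercase, map T->U, and validate against IUPAC codes.

    Returns ``(residues, source_alphabet)`` where the alphabet is ``"DNA"``
    when any T/t was present and ``"RNA"`` otherwise.
    """
    upper = raw.upper()
    alphabet = "DNA" if "T" in upper else "RNA"
    residues = upper.replace("T", "U")
    for pos, ch in enumerate(residues):
        if ch not in IUPAC_CODES:
            raise G4DataError(
                f"{context}: invalid character {ch!r} at position {pos + 1}"
            )
    return residues, alphabet


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized records, in file order.

    Raises :class:`G4DataError` for an empty file, duplicate ids, or
    characters outside the IUPAC nucleotide codes.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise G4DataError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        residues, alphabet = normalize_residues(
            str(entry.seq), context=f"record {entry.id!r}"
        )
        records.append(
            SequenceRecord(
                id=entry.id,
                residues=residues,
                description=entry.description,
                source_alphabet=alphabet,
            )
        )
    if not records:
        raise G4DataError(f"no FASTA records found in {path}")
    return records


@dataclass(frozen=True)
class CandidateTableRow:
    """One candidate: a sequence (or coordinates into a record) plus optional
    experimental fold label and precomputed Mfe / QGRS G-score columns."""

    id: str
    sequence: str | None = None
    record_id: str | None = None
    start: int | None = None  # 0-based half-open when coordinates are used
    end: int | None = None
    fold_label: bool | None = None  # True = folding
    mfe: float | None = None  # kcal/mol, externally precomputed
    gscore: float | None = None

    def __post_init__(self) -> None:
        has_seq = self.sequence is not None
        has_coords = self.record_id is not None or self.start is not None or self.end is not None
        if has_seq and has_coords:
            raise G4DataError(f"candidate {self.id!r}: both sequence and coordinates given")
        if not has_seq and not (
            self.record_id is not None and self.start is not None and self.end is not None
        ):
            raise G4DataError(
                f"candidate {self.id!r}: needs a sequence or complete (record, start, end)"
            )


def _parse_fold_label(value: object, row_id: str) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    text = str(value).strip().lower()
    if text not in _FOLD_LABELS:
        raise G4DataError(
            f"candidate {row_id!r}: fold_label must be 'folding' or 'non-folding', got {value!r}"
        )
    return _FOLD_LABELS[text]


def read_candidate_table(path: str | Path) -> list[CandidateTableRow]:
    """Read a TSV candidate table (header mandatory).

    Recognized columns: ``id`` plus either ``sequence`` or
    ``record``/``start``/``end``; optional ``fold_label`` (``folding`` /
    ``non-folding``, case-insensitive), ``mfe``, ``gscore``.  Missing optional
    columns yield ``None``, never defaults.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise G4DataError(f"{path}: candidate table needs an 'id' column")
    rows: list[CandidateTableRow] = []
    for _, raw in df.iterrows():
        row_id = str(raw["id"])

        def get(col: str) -> str | None:
            if col not in df.columns:
                return None
            val = raw[col]
            if pd.isna(val) or str(val) == "":
                return None
            return str(val)

        seq = get("sequence")
        if seq is not None:
            seq, _ = normalize_residues(seq, context=f"candidate {row_id!r}")
        record_id = get("record")
        start, end = get("start"), get("end")
        mfe, gscore = get("mfe"), get("gscore")
        rows.append(
            CandidateTableRow(
                id=row_id,
                sequence=seq,
                record_id=record_id,
                start=int(start) if start is not None else None,
                end=int(end) if end is not None else None,
                fold_label=_parse_fold_label(get("fold_label"), row_id),
                mfe=float(mfe) if mfe is not None else None,
                gscore=float(gscore) if gscore is not None else None,
            )
        )
    return rows


@dataclass(frozen=True)
class MatchRow:
    """One scored PG4 match, ready for report emission."""

    record_id: str
    start: int  # 0-based half-open internally
    end: int
    motif: str
    n_tracks: int
    loops: tuple[int, int, int]
    cg: int | None = None
    cc: int | None = None
    ratio: float | None = None
    classification: str | None = None

    @property
    def total_loop_length(self) -> int:
        return sum(self.loops)


TSV_COLUMNS = (
    "record_id\tstart\tend\tmotif\tn_tracks\tloop1\tloop2\tloop3\t"
    "total_loop_length\tcG\tcC\tcG_cC\tclassification"
)


def _format_ratio(ratio: float | None) -> str:
    if ratio is None:
        return ""
    if math.isinf(ratio):
        return "inf"
    if math.isnan(ratio):
        return "undefined"
    return f"{ratio:.2f}"


def _bed_score(ratio: float | None) -> int:
    if ratio is None or math.isnan(ratio):
        return 0
    if math.isinf(ratio):
        return 1000
    return min(1000, round(100 * ratio))


def write_matches(
    rows: Iterable[MatchRow], format: str = "tsv", out: IO[str] | None = None
) -> str:
    """Render match rows as TSV (1-based inclusive) or BED6 (0-based half-open).

    The BED score column is ``min(1000, round(100 * cG/cC))`` — capped at 1000
    as the BED format requires; an infinite ratio maps to 1000.
    """
    fmt = format.lower()
    if fmt not in {"tsv", "bed"}:
        raise G4DataError(f"unknown output format {format!r} (expected 'tsv' or 'bed')")
    lines: list[str] = []
    if fmt == "tsv":
        lines.append(TSV_COLUMNS)
        for row in rows:
            lines.append(
                "\t".join(
                    [
                        row.record_id,
                        str(row.start + 1),
                        str(row.end),
                        row.motif,
                        str(row.n_tracks),
                        str(row.loops[0]),
                        str(row.loops[1]),
                        str(row.loops[2]),
                        str(row.total_loop_length),
                        "" if row.cg is None else str(row.cg),
                        "" if row.cc is None else str(row.cc),
                        _format_ratio(row.ratio),
                        row.classification or "",
                    ]
                )
            )
    else:
        for ordinal, row in enumerate(rows, start=1):
            if not (0 <= row.start < row.end):
                raise G4DataError(
                    f"match {row.record_id} has invalid BED span {row.start}..{row.end}"
                )
            lines.append(
                "\t".join(
                    [
                        row.record_id,
                        str(row.start),
                        str(row.end),
                        f"{row.record_id}_{ordinal}",
                        str(_bed_score(row.ratio)),
                        "+",
                    ]
                )
            )
    text = "\n".join(lines) + "\n"
    if out is not None:
        out.write(text)
    return text


def write_fasta(records: Sequence[SequenceRecord], out: IO[str]) -> None:
    """Write records as unwrapped FASTA (RNA alphabet)."""
    for rec in records:
        header = rec.id if not rec.description or rec.description == rec.id else rec.description
        out.write(f">{header}\n{rec.residues}\n")
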