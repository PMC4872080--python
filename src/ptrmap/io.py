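"""Readers, writers and interval arithmetic for the pipeline's file formats.

All coordinates are 0-based half-open on the 3'UTR (position 0 = first UTR
base).  Sequences are stored as RNA (``T`` is normalised to ``U`` on read);
inputs are assumed pre-projected onto the sense strand of each transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def _normalize_rna(seq: str, *, context: str = "") -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise FormatError(
            f"non-ACGU characters {sorted(bad)} in sequence {context or '<anonymous>'}"
        )
    return seq


@dataclass
class Transcript:
    """A 3'UTR with optional upstream coding flank and per-base annotation.

    ``conservation``, when present, holds one score in [0, 1] per UTR base
    (PhastCons-style).  ``expression`` is the baseline abundance in the
    unperturbed condition, ``lfc`` the log fold change upon a knockdown and
    ``half_life`` the measured mRNA half-life.
    """

    id: str
    utr_seq: str
    chrom: str = "chr1"
    strand: str = "+"
    flank_seq: str = ""
    conservation: np.ndarray | None = None
    expression: float | None = None
    lfc: float | None = None
    half_life: float | None = None

    def __post_init__(self) -> None:
        if len(self.utr_seq) < 1:
            raise ValueError(f"transcript {self.id}: empty 3'UTR sequence")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"transcript {self.id}: strand must be '+' or '-'")
        if self.conservation is not None:
            self.conservation = np.asarray(self.conservation, dtype=float)
            if len(self.conservation) != len(self.utr_seq):
                raise ValueError(
                    f"transcript {self.id}: conservation length "
                    f"{len(self.conservation)} != UTR length {len(self.utr_seq)}"
                )
            if ((self.conservation < 0) | (self.conservation > 1)).any():
                raise ValueError(f"transcript {self.id}: conservation outside [0,1]")

    @property
    def folded_seq(self) -> str:
        """Flank + UTR, the sequence that is actually folded."""
        return self.flank_seq + self.utr_seq


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a transcript's 3'UTR.

    ``score_percentile`` carries the rank percentile of a CLIP peak
    (smaller = stronger peak) when one is known.
    """

    transcript_id: str
    start: int
    end: int
    name: str = "."
    score_percentile: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.transcript_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.transcript_id == other.transcript_id
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from FASTA; DNA is normalised to RNA (T -> U).

    The record id is the first whitespace-delimited token of the header.
    Raises :class:`FormatError` on a malformed header or an empty sequence,
    naming the offending line.
    """
    records: list[Transcript] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"empty sequence for record at line {header_line}")
        records.append(Transcript(id=header, utr_seq=_normalize_rna(seq, context=header)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FormatError(f"malformed FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"sequence before any header at line {lineno}")
                chunks.append(line)
        _flush()
    return records


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.utr_seq), width):
                fh.write(t.utr_seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED-like intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, kind: str = "peak") -> list[Interval]:
    """Read BED-like intervals: ``id  start  end  [name]  [score]``.

    The optional score column is interpreted as a CLIP peak rank percentile.
    ``kind`` is informational (peak / background / site).
    """
    out: list[Interval] = []
    with open(path) as fh:
        for recno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{kind} record {recno}: fewer than 3 columns")
            tid = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{kind} record {recno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{kind} record {recno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else "."
            pct = float(fields[4]) if len(fields) > 4 else None
            out.append(Interval(tid, start, end, name=name, score_percentile=pct))
    return out


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.transcript_id, str(iv.start), str(iv.end), iv.name]
            if iv.score_percentile is not None:
                cols.append(f"{iv.score_percentile:g}")
            fh.write("\t".join(cols) + "\n")


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Per-transcript set difference A \\ B; fragments inherit the parent peak's
    percentile.  Used to remove background-binding regions from CLIP peaks.
    """
    by_tid: dict[str, list[Interval]] = {}
    for iv in b:
        by_tid.setdefault(iv.transcript_id, []).append(iv)
    out: list[Interval] = []
    for peak in a:
        cuts = sorted(
            (iv for iv in by_tid.get(peak.transcript_id, []) if iv.overlaps(peak)),
            key=lambda iv: iv.start,
        )
        cursor = peak.start
        for cut in cuts:
            if cut.start > cursor:
                out.append(replace(peak, start=cursor, end=min(cut.start, peak.end)))
            cursor = max(cursor, cut.end)
            if cursor >= peak.end:
                break
        if cursor < peak.end:
            out.append(replace(peak, start=cursor, end=peak.end))
    return out


# ---------------------------------------------------------------------------
# bedGraph conservation
# ---------------------------------------------------------------------------

def read_conservation(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """bedGraph-style per-base conservation: ``id  start  end  value``."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for recno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"conservation record {recno}: need 4 columns")
            tid, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise FormatError(f"conservation record {recno}: start >= end")
            out.setdefault(tid, []).append((start, end, value))
    return out


def conservation_track(
    segments: list[tuple[int, int, float]], length: int
) -> np.ndarray:
    """Expand bedGraph segments into a dense per-base array of ``length``."""
    track = np.zeros(length, dtype=float)
    for start, end, value in segments:
        track[start : min(end, length)] = value
    return track


def write_conservation(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            if t.conservation is None:
                continue
            for pos, val in enumerate(t.conservation):
                fh.write(f"{t.id}\t{pos}\t{pos + 1}\t{val:.4f}\n")


# ---------------------------------------------------------------------------
# Expression / half-life tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRecord:
    lfc: float | None = None
    expression: float | None = None
    half_life: float | None = None
    utr_length: float | None = None


def read_expression_table(path: str | Path) -> dict[str, ExpressionRecord]:
    """TSV with header; recognised columns: ``transcript_id`` (mandatory),
    ``lfc``, ``expression``, ``half_life``, ``utr_length``.  Unparseable
    numeric cells become missing; duplicate ids keep the last row (warned).
    """
    import csv

    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "transcript_id" not in reader.fieldnames:
            raise FormatError("expression table: missing mandatory 'transcript_id' column")
        out: dict[str, ExpressionRecord] = {}
        n_dup = 0
        for row in reader:
            tid = (row.get("transcript_id") or "").strip()
            if not tid:
                continue
            if tid in out:
                n_dup += 1

            def _num(key: str) -> float | None:
                raw = (row.get(key) or "").strip()
                if not raw:
                    return None
                try:
                    return float(raw)
                except ValueError:
                    return None

            out[tid] = ExpressionRecord(
                lfc=_num("lfc"),
                expression=_num("expression"),
                half_life=_num("half_life"),
                utr_length=_num("utr_length"),
            )
        if n_dup:
            logger.warning("expression table %s: %d duplicate ids (last wins)", path, n_dup)
    return out


def write_expression_table(records: Mapping[str, ExpressionRecord], path: str | Path) -> None:
    def _fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write("transcript_id\tlfc\texpression\thalf_life\tutr_length\n")
        for tid, rec in records.items():
            fh.write(
                f"{tid}\t{_fmt(rec.lfc)}\t{_fmt(rec.expression)}\t"
                f"{_fmt(rec.half_life)}\t{_fmt(rec.utr_length)}\n"
            )


def attach_expression(
    transcripts: Sequence[Transcript], table: Mapping[str, ExpressionRecord]
) -> None:
    """Copy lfc / expression / half-life onto matching transcripts in place."""
    for t in transcripts:
        rec = table.get(t.id)
        if rec is None:
            continue
        t.lfc = rec.lfc
        t.expression = rec.expression
        t.half_life = rec.half_life
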