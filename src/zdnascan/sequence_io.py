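"""Readers and writers for the formats the scanner touches.

FASTA and headerless plain text in (gzip-transparent); CSV, BED and
BedGraph out; BED 3+ in for the interval-comparison utilities.  All
interval output uses 0-based half-open coordinates; the CSV export
additionally carries 1-based inclusive display coordinates for
spreadsheet users.
"""

from __future__ import annotations

import csv
import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .detector import ZfsHit

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "iter_fasta_chunks",
    "write_csv",
    "read_csv_hits",
    "write_bed",
    "write_bedgraph",
    "read_bed",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

CSV_COLUMNS = [
    "sequence_id", "start_0based", "end_0based", "start_1based", "end_1based",
    "length", "sequence", "gc_richness", "gt_richness", "raw_score",
    "score_percent",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence: id (first header token), description, residues."""

    sequence_id: str
    description: str
    residues: str


def _open_text(path) -> IO[str]:
    if hasattr(path, "read"):
        return path
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii",
                                errors="replace")
    return open(path, "r", encoding="ascii", errors="replace")


def iter_fasta_chunks(path, buffer_size: int = 1 << 20
                      ) -> Iterator[tuple[str, str, bool]]:
    """Yield ``(sequence_id, residue_chunk, is_last_chunk_of_record)``.

    Streaming core shared with :func:`read_fasta`: memory use is
    bounded by ``buffer_size`` regardless of record length.  A file
    with no ``>`` header is treated as one plain-text sequence with
    the synthesized id ``seq1``.
    """
    handle = _open_text(path)
    try:
        seen: set[str] = set()
        current_id: str | None = None
        plain_mode = False
        buf: list[str] = []
        buf_len = 0

        def flush(final: bool) -> Iterator[tuple[str, str, bool]]:
            nonlocal buf, buf_len
            chunk = "".join(buf)
            buf, buf_len = [], 0
            yield (current_id, chunk, final)

        first = True
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if first and stripped:
                first = False
                if not stripped.startswith(">"):
                    plain_mode = True
                    current_id = "seq1"
                    seen.add("seq1")
            if not stripped:
                continue
            if stripped.startswith(">"):
                if plain_mode:
                    raise ValueError(
                        f"line {lineno}: '>' header inside plain-text input")
                if current_id is not None:
                    yield from flush(final=True)
                header = stripped[1:].strip()
                current_id = header.split()[0] if header else ""
                if not current_id:
                    raise ValueError(f"line {lineno}: empty FASTA header")
                if current_id in seen:
                    raise ValueError(
                        f"line {lineno}: duplicate sequence id {current_id!r}")
                seen.add(current_id)
            else:
                if current_id is None:
                    raise ValueError(
                        f"line {lineno}: sequence data before any FASTA header")
                if plain_mode and not stripped.replace(" ", "").isalpha():
                    raise ValueError(
                        f"line {lineno}: non-sequence characters in plain-text "
                        "input (expected one nucleotide sequence)")
                piece = stripped.replace(" ", "")
                buf.append(piece)
                buf_len += len(piece)
                if buf_len >= buffer_size:
                    yield from flush(final=False)
        if current_id is not None:
            yield from flush(final=True)
    finally:
        if not hasattr(path, "read"):
            handle.close()


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Yield :class:`SequenceRecord` in file order.

    Residues are preserved verbatim (case kept; classification
    uppercases downstream).  Duplicate ids raise ``ValueError``.
    """
    # descriptions need header re-parse; chunk iterator keeps ids only
    handle = _open_text(path)
    try:
        descriptions: dict[str, str] = {}
        for line in handle:
            s = line.strip()
            if s.startswith(">"):
                header = s[1:].strip()
                sid = header.split()[0] if header else ""
                rest = header[len(sid):].strip()
                descriptions.setdefault(sid, rest)
    finally:
        if not hasattr(path, "read"):
            handle.close()
        elif hasattr(path, "seek"):
            path.seek(0)

    parts: list[str] = []
    for sid, chunk, is_last in iter_fasta_chunks(path):
        parts.append(chunk)
        if is_last:
            yield SequenceRecord(sid, descriptions.get(sid, ""), "".join(parts))
            parts = []


def _provenance_lines(model, params, extra: dict | None = None) -> list[str]:
    from . import __version__

    fields = {
        "tool": f"zdnascan {__version__}",
        "model": model.name,
        "score_gc": model.score_gc,
        "score_gt": model.score_gt,
        "score_at": model.score_at,
        "min_length": params.min_length,
        "min_score_percent": params.min_score_percent,
    }
    if extra:
        fields.update(extra)
    return ["# " + " ".join(f"{k}={v}" for k, v in fields.items())]


def write_csv(hits: Iterable[ZfsHit], path, model=None, params=None) -> None:
    """Write hits as RFC-4180 CSV (UTF-8, LF), reals to 2 decimals.

    A leading ``#`` comment line records the full parameter set when
    *model* and *params* are given.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if model is not None and params is not None:
            for line in _provenance_lines(model, params):
                fh.write(line + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for h in hits:
            writer.writerow([
                h.sequence_id, h.start, h.end, h.start + 1, h.end, h.length,
                h.sequence, f"{h.gc_richness:.2f}", f"{h.gt_richness:.2f}",
                f"{h.raw_score:.2f}", f"{h.score_percent:.2f}",
            ])


def read_csv_hits(path) -> list[ZfsHit]:
    """Parse a CSV written by :func:`write_csv` back into hits."""
    hits = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = csv.reader(line for line in fh if not line.startswith("#"))
        header = next(rows, None)
        if header != CSV_COLUMNS:
            raise ValueError(f"unrecognized CSV header: {header}")
        for row in rows:
            rec = dict(zip(CSV_COLUMNS, row))
            hits.append(ZfsHit(
                sequence_id=rec["sequence_id"],
                start=int(rec["start_0based"]),
                end=int(rec["end_0based"]),
                sequence=rec["sequence"],
                raw_score=float(rec["raw_score"]),
                score_percent=float(rec["score_percent"]),
                gc_richness=float(rec["gc_richness"]),
                gt_richness=float(rec["gt_richness"]),
            ))
    return hits


def write_bed(hits: Iterable[ZfsHit], path, model=None, params=None) -> None:
    """BED6: chrom, start, end, name, score (= score percent), strand."""
    hits = sorted(hits, key=lambda h: (h.sequence_id, h.start))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if model is not None and params is not None:
            for line in _provenance_lines(model, params):
                fh.write(line + "\n")
        for i, h in enumerate(hits, start=1):
            fh.write(f"{h.sequence_id}\t{h.start}\t{h.end}\tZFS{i}\t"
                     f"{h.score_percent:.2f}\t.\n")


def write_bedgraph(hits: Iterable[ZfsHit], path,
                   value_field: str = "score_percent",
                   track_header: bool = False) -> None:
    """4-column BedGraph sorted by (chrom, start).

    *value_field* selects the data value: ``score_percent`` (default)
    or ``raw_score``.  Overlapping intervals on one chrom are rejected
    (the format forbids them; single-model scans cannot produce them).
    """
    if value_field not in ("score_percent", "raw_score"):
        raise ValueError("value_field must be 'score_percent' or 'raw_score'")
    rows = sorted(hits, key=lambda h: (h.sequence_id, h.start))
    prev: ZfsHit | None = None
    for h in rows:
        if prev is not None and prev.sequence_id == h.sequence_id \
                and h.start < prev.end:
            raise ValueError(
                f"overlapping intervals on {h.sequence_id}: "
                f"[{prev.start},{prev.end}) and [{h.start},{h.end})")
        prev = h
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if track_header:
            fh.write("track type=bedGraph name=zdnascan\n")
        for h in rows:
            fh.write(f"{h.sequence_id}\t{h.start}\t{h.end}\t"
                     f"{getattr(h, value_field):.2f}\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED 3+ into ``{chrom: [(start, end), ...]}`` (file order).

    ``track``/``browser``/``#`` header lines are skipped; extra
    columns are ignored; empty or inverted intervals are rejected.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    handle = _open_text(path)
    try:
        for lineno, line in enumerate(handle, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split("\t")
            if len(parts) < 3:
                parts = s.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"line {lineno}: invalid interval [{start}, {end})")
            intervals.setdefault(chrom, []).append((start, end))
    finally:
        if not hasattr(path, "read"):
            handle.close()
    return intervals
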