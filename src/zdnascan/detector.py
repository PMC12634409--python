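"""Maximal-run scanning for Z-DNA forming sequences (ZFS).

The scanner walks a sequence left to right over its overlapping
dinucleotide steps.  A run extends while every step is scoreable under
the active :class:`~zdnascan.scoring.ScoringModel`; it terminates at a
*break*: a purine–purine / pyrimidine–pyrimidine step, a step touching
a non-ACGT symbol, a step whose class is scored 0 by the model, or the
end of the sequence.  At each break the maximal run just ended is
tested once against the length and score-percent thresholds and, if it
passes, emitted as a :class:`ZfsHit`.

The implementation is vectorized (numpy) and incremental: sequences are
consumed in chunks, so whole chromosomes scan in seconds with memory
bounded by the chunk size plus the current run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .scoring import ScoringModel

__all__ = ["ScanParams", "ZfsHit", "scan_sequence", "scan_fasta", "RunScanner"]

# Base codes: A=0 C=1 G=2 T=3, anything else 4.
_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
    _BASE_LUT[_b + 32] = _i  # lowercase (soft-masked) scored normally

# Step class ids: 0=GC, 1=GT/CA, 2=AT, 3=break.
_CLASS_LUT = np.full(25, 3, dtype=np.uint8)
for _pair, _cls in {
    (2, 1): 0, (1, 2): 0,                          # GC CG
    (2, 3): 1, (3, 2): 1, (1, 0): 1, (0, 1): 1,    # GT TG CA AC
    (0, 3): 2, (3, 0): 2,                          # AT TA
}.items():
    _CLASS_LUT[5 * _pair[0] + _pair[1]] = _cls


@dataclass(frozen=True)
class ScanParams:
    """Detection thresholds.

    min_length
        Minimum run length in bp (default 12: one full Z-DNA helical
        turn). Must be >= 2 so a run holds at least one step.
    min_score_percent
        Minimum score percent (0-100) a run must reach.
    """

    min_length: int = 12
    min_score_percent: float = 50.0

    def __post_init__(self) -> None:
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2 (at least one step)")
        if not 0.0 <= self.min_score_percent <= 100.0:
            raise ValueError("min_score_percent must lie in [0, 100]")


@dataclass(frozen=True)
class ZfsHit:
    """One detected Z-DNA forming sequence.

    Coordinates are 0-based half-open on the scanned sequence.
    ``gc_richness``/``gt_richness`` are the percentage of the hit's
    dinucleotide steps in the GC and GT/CA classes.
    """

    sequence_id: str
    start: int
    end: int
    sequence: str
    raw_score: float
    score_percent: float
    gc_richness: float
    gt_richness: float

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("hit interval must be non-empty with start >= 0")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("hit sequence length must equal end - start")


class RunScanner:
    """Incremental scanner: feed sequence chunks, collect hits.

    Keeps only one trailing character and the currently open run
    between ``feed`` calls, so peak memory is O(chunk + longest run).
    """

    def __init__(self, sequence_id: str, model: ScoringModel, params: ScanParams):
        self.sequence_id = sequence_id
        self.model = model
        self.params = params
        self._scores = np.array(
            [model.score_gc, model.score_gt, model.score_at, 0.0], dtype=np.float64
        )
        self._pos = 0               # absolute index of the next character
        self._carry: str = ""       # last character of the previous chunk
        # open-run accumulators (run continues past the chunk boundary)
        self._run_start = -1
        self._run_steps = 0
        self._run_raw = 0.0
        self._run_counts = [0, 0, 0]
        self._run_chars: list[str] = []
        self._hits: list[ZfsHit] = []

    # -- internal -----------------------------------------------------

    def _emit(self, start: int, steps: int, raw: float, counts: Sequence[int],
              seq: str) -> None:
        length = steps + 1
        if length < self.params.min_length:
            return
        percent = 100.0 * raw / (steps * self.model.max_step_score)
        if percent < self.params.min_score_percent:
            return
        self._hits.append(ZfsHit(
            sequence_id=self.sequence_id,
            start=start,
            end=start + length,
            sequence=seq,
            raw_score=raw,
            score_percent=percent,
            gc_richness=100.0 * counts[0] / steps,
            gt_richness=100.0 * counts[1] / steps,
        ))

    def _close_open_run(self) -> None:
        if self._run_steps:
            self._emit(self._run_start, self._run_steps, self._run_raw,
                       self._run_counts, "".join(self._run_chars))
        self._run_start = -1
        self._run_steps = 0
        self._run_raw = 0.0
        self._run_counts = [0, 0, 0]
        self._run_chars = []

    # -- public -------------------------------------------------------

    def feed(self, chunk: str) -> None:
        if not chunk:
            return
        joined = self._carry + chunk
        astart = self._pos - len(self._carry)  # absolute index of joined[0]
        codes = _BASE_LUT[np.frombuffer(
            joined.encode("latin-1", errors="replace"), dtype=np.uint8)]
        self._pos += len(chunk)
        self._carry = joined[-1]
        n = len(codes) - 1  # number of steps
        if n < 1:
            return
        cls = _CLASS_LUT[codes[:-1].astype(np.intp) * 5 + codes[1:]]
        sc = self._scores[cls]
        good = sc > 0.0  # zero-scored classes break the run, like BREAK

        # maximal segments of consecutive good steps
        edges = np.diff(good.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if good[0]:
            starts = np.concatenate(([0], starts))
        if good[-1]:
            ends = np.concatenate((ends, [n]))

        if self._run_steps and not (starts.size and starts[0] == 0):
            # the open run does not continue into this chunk
            self._close_open_run()

        if not starts.size:
            return

        # prefix sums let every segment close in O(1)
        csc = np.concatenate(([0.0], np.cumsum(sc)))
        ccnt = [np.concatenate(([0], np.cumsum(cls == k))) for k in range(3)]

        def seg_stats(s: int, e: int) -> tuple[float, list[int]]:
            return (float(csc[e] - csc[s]),
                    [int(c[e] - c[s]) for c in ccnt])

        # visit only segments that can matter: long enough to pass the
        # length threshold, continuing the open run, or open at the end
        candidate = (ends - starts + 1) >= self.params.min_length
        if starts.size:
            candidate[0] |= starts[0] == 0 and self._run_steps > 0
            candidate[-1] |= ends[-1] == n
        for i in np.flatnonzero(candidate):
            s, e = int(starts[i]), int(ends[i])
            open_at_end = e == n
            continues_open = i == 0 and s == 0 and self._run_steps > 0
            # segment steps [s, e) cover nucleotides joined[s : e+1]
            if continues_open:
                raw, counts = seg_stats(s, e)
                self._run_steps += e - s
                self._run_raw += raw
                for k in range(3):
                    self._run_counts[k] += counts[k]
                self._run_chars.append(joined[s + 1 : e + 1])
                if not open_at_end:
                    self._close_open_run()
                continue
            nt_len = e - s + 1
            if open_at_end:
                self._run_start = astart + s
                self._run_steps = e - s
                self._run_raw, counts = seg_stats(s, e)
                self._run_counts = list(counts)
                self._run_chars = [joined[s : e + 1]]
            elif nt_len >= self.params.min_length:
                raw, counts = seg_stats(s, e)
                self._emit(astart + s, e - s, raw, counts, joined[s : e + 1])

    def finish(self) -> list[ZfsHit]:
        """End of sequence acts as a break: evaluate the final run."""
        self._close_open_run()
        self._carry = ""
        return self._hits


def scan_sequence(record, model: ScoringModel,
                  params: ScanParams | None = None) -> list[ZfsHit]:
    """Scan one sequence and return all passing hits in start order.

    *record* is a :class:`~zdnascan.sequence_io.SequenceRecord` or any
    object with ``sequence_id`` and ``residues`` attributes; a bare
    string is accepted and given the id ``"seq1"``.
    """
    if params is None:
        params = ScanParams()
    if isinstance(record, str):
        seq_id, residues = "seq1", record
    else:
        seq_id, residues = record.sequence_id, record.residues
    scanner = RunScanner(seq_id, model, params)
    scanner.feed(residues)
    return scanner.finish()


def scan_fasta(path, model: ScoringModel, params: ScanParams | None = None,
               buffer_size: int = 1 << 20) -> Iterator[ZfsHit]:
    """Stream hits from a FASTA / plain-text file, grouped by record.

    Reads the file in ``buffer_size`` chunks; never materializes a
    whole chromosome.
    """
    from .sequence_io import iter_fasta_chunks

    if params is None:
        params = ScanParams()
    scanner: RunScanner | None = None
    for seq_id, chunk, is_last in iter_fasta_chunks(path, buffer_size):
        if scanner is None or scanner.sequence_id != seq_id:
            if scanner is not None:
                yield from scanner.finish()
            scanner = RunScanner(seq_id, model, params)
        scanner.feed(chunk)
        if is_last:
            yield from scanner.finish()
            scanner = None
    if scanner is not None:
        yield from scanner.finish()
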