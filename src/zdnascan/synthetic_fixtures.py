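"""Deterministic synthetic sequences with planted Z-forming motifs.

Test and benchmark data are generated, never downloaded: a uniform
ACGT background (verified hit-free under both preset models at
default thresholds) with alternating-dinucleotide motifs planted at
known coordinates.  Two copies of the motif's first (last) base are
written immediately before (after) each plant, which guarantees break
steps at both junctions — realized hit coordinates therefore equal
plant coordinates exactly, making truth tables deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .detector import ScanParams, ZfsHit, scan_sequence
from .scoring import MODEL_1, MODEL_2, ScoringModel

__all__ = ["MotifKind", "PlantSpec", "PlantedTruth", "motif_sequence",
           "expected_hit", "generate", "write_fixture", "default_plants"]

_GUARD = 2  # flanking guard bases on each side of a plant


class MotifKind(enum.Enum):
    GC_REPEAT = "GC"
    CA_REPEAT = "CA"
    AT_REPEAT = "AT"
    MIXED_ALTERNATING = "GCGT"  # GC/GT-class mixture


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant: kind, length (bp) and 0-based position."""

    motif_kind: MotifKind
    length: int
    position: int

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("plant length must be >= 2")
        if self.position < _GUARD:
            raise ValueError(f"plant position must be >= {_GUARD} (guard margin)")


@dataclass(frozen=True)
class PlantedTruth:
    """Realized plant with per-model detectability flags."""

    sequence_id: str
    motif_kind: MotifKind
    start: int
    end: int
    expected_model1_hit: bool
    expected_model2_hit: bool


def motif_sequence(kind: MotifKind, length: int) -> str:
    unit = kind.value
    return (unit * (length // len(unit) + 1))[:length]


def expected_hit(motif: str, model: ScoringModel, params: ScanParams) -> bool:
    """Whether an isolated motif passes the thresholds as one run."""
    hits = scan_sequence(motif, model, params)
    return len(hits) == 1 and hits[0].start == 0 and hits[0].end == len(motif)


def _hit_free_background(rng: np.random.Generator, length: int,
                         params: ScanParams, max_tries: int = 50) -> str:
    """Uniform ACGT string with no hit under either preset model."""
    for _ in range(max_tries):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        if not scan_sequence(seq, MODEL_1, params) and \
                not scan_sequence(seq, MODEL_2, params):
            return seq
    raise RuntimeError(
        f"no hit-free background of length {length} in {max_tries} draws")


def generate(seed: int, n_sequences: int, length: int,
             plants: Sequence[PlantSpec],
             params: ScanParams | None = None,
             ) -> tuple[str, list[PlantedTruth]]:
    """Build a FASTA text of *n_sequences* backgrounds, each carrying
    *plants*, plus the realized truth table.

    Reproducible for a fixed seed; the same plants are placed in every
    sequence.  Plants (with their 2-bp guards) must fit within
    *length* and must not touch each other.
    """
    if params is None:
        params = ScanParams()
    ordered = sorted(plants, key=lambda p: p.position)
    prev_end = 0
    for p in ordered:
        if p.position - _GUARD < prev_end:
            raise ValueError("plants (incl. guard margins) overlap or touch")
        prev_end = p.position + p.length + _GUARD
        if prev_end > length:
            raise ValueError("plant does not fit in the sequence length")

    expectations = {}
    for p in ordered:
        motif = motif_sequence(p.motif_kind, p.length)
        expectations[p] = (expected_hit(motif, MODEL_1, params),
                           expected_hit(motif, MODEL_2, params))

    rng = np.random.default_rng(seed)
    fasta_lines: list[str] = []
    truth: list[PlantedTruth] = []
    for i in range(1, n_sequences + 1):
        seq_id = f"synth{i}"
        for _ in range(50):
            chars = list(_hit_free_background(rng, length, params))
            for p in ordered:
                motif = motif_sequence(p.motif_kind, p.length)
                chars[p.position - _GUARD:p.position] = motif[0] * _GUARD
                chars[p.position:p.position + p.length] = motif
                chars[p.position + p.length:
                      p.position + p.length + _GUARD] = motif[-1] * _GUARD
            seq = "".join(chars)
            if _plants_exact(seq, ordered, expectations, params):
                break
        else:
            raise RuntimeError("could not realize an interference-free fixture")
        fasta_lines.append(f">{seq_id} synthetic planted fixture")
        fasta_lines.extend(seq[j:j + 70] for j in range(0, length, 70))
        for p in ordered:
            m1, m2 = expectations[p]
            truth.append(PlantedTruth(seq_id, p.motif_kind, p.position,
                                      p.position + p.length, m1, m2))
    return "\n".join(fasta_lines) + "\n", truth


def _plants_exact(seq: str, plants: Sequence[PlantSpec],
                  expectations: dict, params: ScanParams) -> bool:
    """True iff scanning yields exactly the expected planted intervals."""
    for model, flag_idx in ((MODEL_1, 0), (MODEL_2, 1)):
        found = {(h.start, h.end) for h in scan_sequence(seq, model, params)}
        wanted = {(p.position, p.position + p.length)
                  for p in plants if expectations[p][flag_idx]}
        if found != wanted:
            return False
    return True


def default_plants(length: int = 400) -> list[PlantSpec]:
    """A standard plant layout: one motif of each kind, well separated."""
    if length < 320:
        raise ValueError("default layout needs length >= 320")
    return [
        PlantSpec(MotifKind.GC_REPEAT, 16, 30),
        PlantSpec(MotifKind.CA_REPEAT, 20, 110),
        PlantSpec(MotifKind.MIXED_ALTERNATING, 16, 190),
        PlantSpec(MotifKind.AT_REPEAT, 20, 270),
    ]


def write_fixture(out_dir, seed: int, n_sequences: int = 3,
                  length: int = 400,
                  plants: Sequence[PlantSpec] | None = None,
                  params: ScanParams | None = None) -> tuple[Path, Path]:
    """Write a FASTA + truth-BED fixture pair; returns the two paths.

    The truth BED carries the motif kind and the two expected-hit
    flags (columns 4-6 style: name, model1, model2).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if plants is None:
        plants = default_plants(length)
    fasta_text, truth = generate(seed, n_sequences, length, plants, params)
    fasta_path = out_dir / f"planted_seed{seed}.fa"
    bed_path = out_dir / f"planted_seed{seed}.truth.bed"
    fasta_path.write_text(fasta_text)
    with open(bed_path, "w") as fh:
        for t in truth:
            fh.write(f"{t.sequence_id}\t{t.start}\t{t.end}\t"
                     f"{t.motif_kind.name}\t{int(t.expected_model1_hit)}\t"
                     f"{int(t.expected_model2_hit)}\n")
    return fasta_path, bed_path
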