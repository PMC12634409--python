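"""Dinucleotide scoring system for Z-DNA propensity.

Z-DNA formation requires a regular alternation of pyrimidine and purine
bases; the scanner therefore classifies every overlapping dinucleotide
step of a sequence into one of four classes:

* ``GC_CLASS`` — {GC, CG}: the strongest Z-forming steps.
* ``GT_CLASS`` — {GT, TG, CA, AC}: alternating steps of intermediate
  propensity (the GT/CA microsatellite class).
* ``AT_CLASS`` — {AT, TA}: alternating but weakly (if at all) Z-forming.
* ``BREAK`` — the eight purine–purine / pyrimidine–pyrimidine steps
  (AA, CC, GG, TT, AG, CT, GA, TC) that are incompatible with the
  zig-zag backbone, plus any step containing a non-ACGT symbol.

A :class:`ScoringModel` assigns one non-negative score to each of the
three alternating classes.  Scores are summed over the L−1 overlapping
steps of an L-bp window; the score percent normalizes by the best
achievable score for the same number of steps.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "DinucleotideClass",
    "ScoringModel",
    "MODEL_1",
    "MODEL_2",
    "classify_dinucleotide",
    "step_score",
    "window_score",
    "window_score_percent",
    "richness",
]


class DinucleotideClass(enum.Enum):
    """Scoring class of one dinucleotide step."""

    GC_CLASS = "GC"
    GT_CLASS = "GT"
    AT_CLASS = "AT"
    BREAK = "BREAK"


_CLASS_OF = {
    "GC": DinucleotideClass.GC_CLASS,
    "CG": DinucleotideClass.GC_CLASS,
    "GT": DinucleotideClass.GT_CLASS,
    "TG": DinucleotideClass.GT_CLASS,
    "CA": DinucleotideClass.GT_CLASS,
    "AC": DinucleotideClass.GT_CLASS,
    "AT": DinucleotideClass.AT_CLASS,
    "TA": DinucleotideClass.AT_CLASS,
}


@dataclass(frozen=True)
class ScoringModel:
    """Per-step scores for the three alternating dinucleotide classes.

    Parameters
    ----------
    name
        Label recorded in output provenance headers.
    score_gc, score_gt, score_at
        Non-negative score contributed by each step of the GC, GT/CA
        and AT class respectively.  A class scored 0 terminates runs
        during scanning (it is "rated 0", like a break).
    """

    name: str
    score_gc: float
    score_gt: float
    score_at: float

    def __post_init__(self) -> None:
        for field in ("score_gc", "score_gt", "score_at"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")
        if self.max_step_score <= 0:
            raise ValueError("at least one class score must be positive")

    @property
    def max_step_score(self) -> float:
        return max(self.score_gc, self.score_gt, self.score_at)

    def class_score(self, dinuc_class: DinucleotideClass) -> float:
        return step_score(dinuc_class, self)


#: Strict preset: essentially (GC)n with limited GT/CA admixture.
MODEL_1 = ScoringModel("model1", score_gc=25.0, score_gt=3.0, score_at=0.0)
#: Permissive preset: mixed alternating tracts, AT steps scored positively.
MODEL_2 = ScoringModel("model2", score_gc=2.0, score_gt=1.0, score_at=0.5)

PRESETS = {"model1": MODEL_1, "model2": MODEL_2}


def classify_dinucleotide(dinuc: str) -> DinucleotideClass:
    """Classify a 2-character dinucleotide step (case-insensitive).

    Any step containing a character outside {A, C, G, T} (e.g. N or an
    IUPAC ambiguity code) is a BREAK.
    """
    if len(dinuc) != 2:
        raise ValueError(f"dinucleotide must have length 2, got {dinuc!r}")
    return _CLASS_OF.get(dinuc.upper(), DinucleotideClass.BREAK)


def step_score(dinuc_class: DinucleotideClass, model: ScoringModel) -> float:
    """Score of one non-BREAK step under *model*."""
    if dinuc_class is DinucleotideClass.GC_CLASS:
        return model.score_gc
    if dinuc_class is DinucleotideClass.GT_CLASS:
        return model.score_gt
    if dinuc_class is DinucleotideClass.AT_CLASS:
        return model.score_at
    raise ValueError("BREAK steps are not scored; runs terminate at breaks")


def _steps(window: str) -> list[DinucleotideClass]:
    if len(window) < 2:
        raise ValueError("window must have length >= 2")
    classes = [classify_dinucleotide(window[i : i + 2]) for i in range(len(window) - 1)]
    if DinucleotideClass.BREAK in classes:
        i = classes.index(DinucleotideClass.BREAK)
        raise ValueError(
            f"window contains a BREAK step at offset {i} ({window[i:i + 2]!r})"
        )
    return classes


def window_score(window: str, model: ScoringModel) -> tuple[float, int]:
    """Raw score and step count of a break-free window.

    The score is the sum of step scores over the L−1 overlapping
    dinucleotide steps (stride 1) of an L-bp window.
    """
    classes = _steps(window)
    return sum(step_score(c, model) for c in classes), len(classes)


def window_score_percent(raw_score: float, n_steps: int, model: ScoringModel) -> float:
    """Raw score as a percentage of the best achievable score for n_steps."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return 100.0 * raw_score / (n_steps * model.max_step_score)


def richness(window: str, target_class: DinucleotideClass) -> float:
    """Percentage of a break-free window's steps in *target_class*."""
    if target_class is DinucleotideClass.BREAK:
        raise ValueError("richness is defined for scoring classes only")
    classes = _steps(window)
    return 100.0 * sum(c is target_class for c in classes) / len(classes)
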