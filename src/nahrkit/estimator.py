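"""Nonselective clone-assay outcome estimator.

The pipeline mirrors the assay's bookkeeping:

1. genetic-class frequencies among cut (HygS) clones, for uninduced and
   induced cultures;
2. background subtraction (uninduced percentages subtracted from induced,
   negatives clamped to zero) with a >50%-background culture QC gate;
3. normalization of class I + II + III to 100%;
4. plug-weighted outcome frequencies: class percent x (plugs of type /
   plugs analyzed in that class), with class III reported directly as
   chromosome loss;
5. a weighted binomial SEM, sqrt(p*q/n) scaled by the class percent,
   with assigned-count edge cases for saturated or empty cells.

Class percentages use the cut-clone (HygS) denominator — this is what
reproduces the worked numbers — with ``denominator="scored"`` available
for the literal total-scored reading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Condition",
    "GeneticClass",
    "OutcomeType",
    "CloneAssayCounts",
    "PlugSurvey",
    "ClassFrequencies",
    "FrequencyStage",
    "OutcomeEntry",
    "OutcomeTable",
    "SemEdgeCase",
    "SemInputs",
    "EstimatorError",
    "CultureRejected",
    "class_frequencies",
    "background_subtract",
    "normalize_classes",
    "repair_type_frequencies",
    "outcome_sem",
    "loss_sem",
    "bdr_total",
    "categorize_copy_number",
    "estimate_outcomes",
]


class EstimatorError(ValueError):
    pass


class CultureRejected(EstimatorError):
    """Uninduced culture failed the background QC gate."""

    def __init__(self, hygs_fraction: float) -> None:
        self.hygs_fraction = hygs_fraction
        super().__init__(
            f"uninduced culture rejected: HygS fraction {hygs_fraction:.3f} > 0.5"
        )


class Condition(str, Enum):
    UNINDUCED = "uninduced"
    INDUCED = "induced"


class GeneticClass(str, Enum):
    CLASS_I = "class_I"  # Leu+ HygS Ura+
    CLASS_II = "class_II"  # Leu+ HygS Ura-
    CLASS_III = "class_III"  # Leu- HygS Ura- (chromosome loss)
    CLASS_OTHER = "class_other"  # Leu- HygS Ura+ (rare; excluded)


class OutcomeType(str, Enum):
    ALLELIC = "allelic"
    INTERNAL_DELETION = "internal_deletion"  # inter-Ty deletion
    INTRA_TY_DELETION = "intra_ty_deletion"
    TY_GC = "ty_gc"
    ISOCHROMOSOME = "isochromosome"
    RING = "ring"
    TRANSLOCATION = "translocation"
    OTHER = "other"


class FrequencyStage(str, Enum):
    RAW = "raw"
    BACKGROUND_SUBTRACTED = "background_subtracted"
    NORMALIZED = "normalized"


# Outcome categories for the derived summaries.
BDR_TYPES = (
    OutcomeType.INTERNAL_DELETION,
    OutcomeType.ISOCHROMOSOME,
    OutcomeType.RING,
    OutcomeType.TRANSLOCATION,
)
COPY_NUMBER_CHANGE_TYPES = (
    OutcomeType.INTERNAL_DELETION,
    OutcomeType.TRANSLOCATION,
    OutcomeType.RING,
    OutcomeType.ISOCHROMOSOME,
    OutcomeType.OTHER,
)
COPY_NUMBER_NO_CHANGE_TYPES = (
    OutcomeType.INTRA_TY_DELETION,
    OutcomeType.TY_GC,
    OutcomeType.ALLELIC,
)


@dataclass(frozen=True)
class CloneAssayCounts:
    """Clone phenotyping counts for one culture."""

    condition: Condition
    n_scored: int
    n_hygs: int
    class_counts: Mapping[GeneticClass, int]

    def __post_init__(self) -> None:
        counts = dict(self.class_counts)
        for cls, count in counts.items():
            if count < 0:
                raise EstimatorError(f"negative count for {cls.value}: {count}")
        total = sum(counts.values())
        if total != self.n_hygs:
            raise EstimatorError(
                f"class counts sum to {total}, expected n_hygs={self.n_hygs}"
            )
        if self.n_hygs > self.n_scored:
            raise EstimatorError(
                f"n_hygs ({self.n_hygs}) exceeds n_scored ({self.n_scored})"
            )
        object.__setattr__(self, "class_counts", counts)

    def count(self, cls: GeneticClass) -> int:
        return self.class_counts.get(cls, 0)

    @property
    def hygs_fraction(self) -> float:
        return self.n_hygs / self.n_scored if self.n_scored else 0.0


@dataclass(frozen=True)
class PlugSurvey:
    """Per-class rearrangement-type counts from PFGE plug analysis.

    ``counts[cls][type]`` is the number of plugs of that type among the
    class's analyzed plugs; explicit zero-count entries declare that a
    type was looked for but not seen (they drive upper-bound SEMs).
    """

    counts: Mapping[GeneticClass, Mapping[OutcomeType, int]]

    def __post_init__(self) -> None:
        fixed: dict[GeneticClass, dict[OutcomeType, int]] = {}
        for cls, type_counts in self.counts.items():
            if cls not in (GeneticClass.CLASS_I, GeneticClass.CLASS_II):
                raise EstimatorError(f"plug survey classes must be I or II, got {cls.value}")
            for outcome, count in type_counts.items():
                if count < 0:
                    raise EstimatorError(
                        f"negative plug count for {cls.value}/{outcome.value}"
                    )
            fixed[cls] = dict(type_counts)
        object.__setattr__(self, "counts", fixed)

    def total(self, cls: GeneticClass) -> int:
        return sum(self.counts.get(cls, {}).values())

    def count(self, cls: GeneticClass, outcome: OutcomeType) -> int:
        return self.counts.get(cls, {}).get(outcome, 0)

    def types(self, cls: GeneticClass) -> list[OutcomeType]:
        return list(self.counts.get(cls, {}).keys())


@dataclass(frozen=True)
class ClassFrequencies:
    """Percent of cut clones in classes I/II/III at a pipeline stage."""

    class_i: float
    class_ii: float
    class_iii: float
    stage: FrequencyStage
    hygs_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("class_i", "class_ii", "class_iii"):
            if getattr(self, name) < 0:
                raise EstimatorError(f"{name} must be >= 0")
        if self.stage is FrequencyStage.NORMALIZED:
            if abs(self.total - 100.0) > 1e-6:
                raise EstimatorError(
                    f"normalized class frequencies must sum to 100, got {self.total}"
                )

    @property
    def total(self) -> float:
        return self.class_i + self.class_ii + self.class_iii

    def percent(self, cls: GeneticClass) -> float:
        return {
            GeneticClass.CLASS_I: self.class_i,
            GeneticClass.CLASS_II: self.class_ii,
            GeneticClass.CLASS_III: self.class_iii,
        }[cls]


@dataclass(frozen=True)
class OutcomeEntry:
    """One outcome cell: frequency percent, SEM percent, bound handling.

    Bound entries (printed as "<x" in assay tables) carry value 0 with
    the computed upper bound in ``bound``; summaries count them as 0.
    """

    frequency: float
    sem: float
    is_bound: bool = False
    bound: Optional[float] = None


@dataclass
class OutcomeTable:
    """Per-strain outcome frequencies with SEMs plus chromosome loss."""

    entries: dict[OutcomeType, OutcomeEntry]
    loss_percent: float
    loss_sem: Optional[float] = None
    strain: Optional[str] = None

    @classmethod
    def from_frequencies(
        cls,
        frequencies: Mapping[OutcomeType, float],
        loss_percent: float,
        bounds: Iterable[OutcomeType] = (),
        strain: Optional[str] = None,
    ) -> "OutcomeTable":
        """Build a table from explicit frequency cells (e.g. a published row).

        Types listed in ``bounds`` are "<x" cells: the given number is
        stored as the bound and the frequency is 0.
        """
        bound_set = set(bounds)
        entries = {}
        for outcome, value in frequencies.items():
            if outcome in bound_set:
                entries[outcome] = OutcomeEntry(0.0, 0.0, is_bound=True, bound=value)
            else:
                entries[outcome] = OutcomeEntry(value, 0.0)
        return cls(entries=entries, loss_percent=loss_percent, strain=strain)

    def frequency(self, outcome: OutcomeType) -> float:
        entry = self.entries.get(outcome)
        if entry is None or entry.is_bound:
            return 0.0
        return entry.frequency

    @property
    def total_percent(self) -> float:
        return sum(e.frequency for e in self.entries.values()) + self.loss_percent


class SemEdgeCase(str, Enum):
    NONE = "none"
    ALL_OF_CLASS = "all_of_class"  # every analyzed plug was this type
    ZERO_OF_TYPE = "zero_of_type"  # plugs analyzed, none of this type
    CLASS_ZERO = "class_zero"  # genetic class frequency is 0
    NO_PLUGS = "no_plugs"  # class present but no plugs analyzed


@dataclass(frozen=True)
class SemInputs:
    """Inputs to the weighted SEM: class percent, plug totals and counts."""

    class_freq: float  # percent (the paper's a or b)
    plugs_total: int  # c or d
    plugs_of_type: int  # e or f
    edge_case: SemEdgeCase = SemEdgeCase.NONE

    def __post_init__(self) -> None:
        if self.class_freq < 0:
            raise EstimatorError("class_freq must be >= 0")
        if self.plugs_total < 0 or self.plugs_of_type < 0:
            raise EstimatorError("plug counts must be >= 0")
        if self.edge_case is SemEdgeCase.NONE:
            if not 0 < self.plugs_of_type < self.plugs_total:
                raise EstimatorError(
                    "edge_case NONE requires 0 < plugs_of_type < plugs_total "
                    f"(got {self.plugs_of_type}/{self.plugs_total}); "
                    "classify the edge case explicitly"
                )
        elif self.edge_case is SemEdgeCase.ALL_OF_CLASS:
            if self.plugs_total == 0 or self.plugs_of_type != self.plugs_total:
                raise EstimatorError("ALL_OF_CLASS requires plugs_of_type == plugs_total > 0")
        elif self.edge_case is SemEdgeCase.ZERO_OF_TYPE:
            if self.plugs_total == 0 or self.plugs_of_type != 0:
                raise EstimatorError("ZERO_OF_TYPE requires plugs_of_type == 0 < plugs_total")
        elif self.edge_case is SemEdgeCase.NO_PLUGS:
            if self.plugs_total != 0:
                raise EstimatorError("NO_PLUGS requires plugs_total == 0")


def classify_sem_inputs(
    class_freq: float, plugs_total: int, plugs_of_type: int
) -> SemInputs:
    """Attach the right edge case to raw SEM inputs."""
    if class_freq == 0:
        case = SemEdgeCase.CLASS_ZERO
    elif plugs_total == 0:
        case = SemEdgeCase.NO_PLUGS
    elif plugs_of_type == 0:
        case = SemEdgeCase.ZERO_OF_TYPE
    elif plugs_of_type == plugs_total:
        case = SemEdgeCase.ALL_OF_CLASS
    else:
        case = SemEdgeCase.NONE
    return SemInputs(class_freq, plugs_total, plugs_of_type, case)


def _binomial_sem(count: float, total: float) -> float:
    p = count / total
    return math.sqrt(p * (1.0 - p) / total)


def outcome_sem(inputs: SemInputs) -> float:
    """Weighted binomial SEM (percent) for one outcome cell.

    The base formula is sqrt(p*q/n) with p = plugs_of_type/plugs_total
    and n = plugs_total, multiplied by the class percent. Edge cases use
    an assigned count of 1: a saturated cell (ALL_OF_CLASS) is recomputed
    with count n-1 (as if the next plug were a different outcome); empty
    cells (ZERO_OF_TYPE, CLASS_ZERO, NO_PLUGS) are recomputed with count
    1 (as if the next plug were this outcome), giving an upper bound.
    """
    weight = inputs.class_freq
    case = inputs.edge_case
    if case is SemEdgeCase.NONE:
        return _binomial_sem(inputs.plugs_of_type, inputs.plugs_total) * weight
    if case is SemEdgeCase.ALL_OF_CLASS:
        return _binomial_sem(inputs.plugs_total - 1, inputs.plugs_total) * weight
    if case is SemEdgeCase.ZERO_OF_TYPE:
        return _binomial_sem(1, inputs.plugs_total) * weight
    if case is SemEdgeCase.CLASS_ZERO:
        # class weight is zero; the assigned-count SEM collapses to 0
        return 0.0
    if case is SemEdgeCase.NO_PLUGS:
        # one assigned plug of one: p = 1, q = 0
        return 0.0
    raise EstimatorError(f"unhandled edge case: {case}")  # pragma: no cover


def class_frequencies(
    counts: CloneAssayCounts, denominator: str = "hygs"
) -> ClassFrequencies:
    """Raw per-class percentages for one culture.

    The denominator is the number of cut (HygS) clones by default; the
    rare fourth phenotype class (Leu- HygS Ura+) is excluded with a
    warning when present.
    """
    if denominator not in ("hygs", "scored"):
        raise EstimatorError(f"unknown denominator: {denominator!r}")
    if counts.n_hygs == 0:
        raise EstimatorError("no cut clones (n_hygs == 0)")
    other = counts.count(GeneticClass.CLASS_OTHER)
    if other:
        warnings.warn(
            f"excluding {other} Leu-HygS Ura+ clones from class frequencies",
            stacklevel=2,
        )
    denom = counts.n_hygs if denominator == "hygs" else counts.n_scored
    return ClassFrequencies(
        class_i=100.0 * counts.count(GeneticClass.CLASS_I) / denom,
        class_ii=100.0 * counts.count(GeneticClass.CLASS_II) / denom,
        class_iii=100.0 * counts.count(GeneticClass.CLASS_III) / denom,
        stage=FrequencyStage.RAW,
        hygs_fraction=counts.hygs_fraction,
    )


def background_subtract(
    induced: ClassFrequencies,
    uninduced: ClassFrequencies,
    max_background_hygs_fraction: float = 0.5,
) -> ClassFrequencies:
    """Subtract pre-induction background, clamping negatives to zero.

    Cultures whose uninduced HygS fraction exceeds the QC gate (default
    50%) are rejected outright.
    """
    if induced.stage is not FrequencyStage.RAW or uninduced.stage is not FrequencyStage.RAW:
        raise EstimatorError("background_subtract needs RAW-stage frequencies")
    if (
        uninduced.hygs_fraction is not None
        and uninduced.hygs_fraction > max_background_hygs_fraction
    ):
        raise CultureRejected(uninduced.hygs_fraction)

    def clamp(value: float, label: str) -> float:
        if value < 0:
            warnings.warn(
                f"{label} background exceeds induced frequency; clamping to 0",
                stacklevel=2,
            )
            return 0.0
        return value

    return ClassFrequencies(
        class_i=clamp(induced.class_i - uninduced.class_i, "class I"),
        class_ii=clamp(induced.class_ii - uninduced.class_ii, "class II"),
        class_iii=clamp(induced.class_iii - uninduced.class_iii, "class III"),
        stage=FrequencyStage.BACKGROUND_SUBTRACTED,
        hygs_fraction=induced.hygs_fraction,
    )


def normalize_classes(freqs: ClassFrequencies) -> ClassFrequencies:
    """Scale class I + II + III to total 100%."""
    if freqs.stage is not FrequencyStage.BACKGROUND_SUBTRACTED:
        raise EstimatorError("normalize_classes needs BACKGROUND_SUBTRACTED frequencies")
    total = freqs.total
    if total == 0:
        raise EstimatorError("cannot normalize: class frequencies sum to 0")
    scale = 100.0 / total
    return ClassFrequencies(
        class_i=freqs.class_i * scale,
        class_ii=freqs.class_ii * scale,
        class_iii=freqs.class_iii * scale,
        stage=FrequencyStage.NORMALIZED,
        hygs_fraction=freqs.hygs_fraction,
    )


def repair_type_frequencies(
    class_freqs: ClassFrequencies,
    plug_survey: PlugSurvey,
    n_hygs: Optional[int] = None,
    strain: Optional[str] = None,
) -> OutcomeTable:
    """Plug-weighted outcome frequencies with SEMs.

    frequency(type) = class percent x (plugs of type / plugs analyzed),
    summed over the classes the type appears in. The class III percent is
    reported directly as chromosome loss. Cells whose evidence is an
    assigned count (no plugs of the type, empty class, or no plugs
    analyzed) become bound entries.
    """
    if class_freqs.stage is not FrequencyStage.NORMALIZED:
        raise EstimatorError("repair_type_frequencies needs NORMALIZED frequencies")

    per_type: dict[OutcomeType, dict] = {}
    for cls in (GeneticClass.CLASS_I, GeneticClass.CLASS_II):
        class_percent = class_freqs.percent(cls)
        total = plug_survey.total(cls)
        surveyed_types = plug_survey.types(cls)
        if total == 0 and class_percent > 0 and surveyed_types:
            # class present but no informative plugs: every declared type
            # gets an upper bound of the whole class percent
            for outcome in surveyed_types:
                slot = per_type.setdefault(
                    outcome, {"freq": 0.0, "sem": 0.0, "bound": 0.0, "has_real": False}
                )
                slot["bound"] += class_percent
                slot["sem"] += outcome_sem(
                    SemInputs(class_percent, 0, 0, SemEdgeCase.NO_PLUGS)
                )
            continue
        for outcome in surveyed_types:
            count = plug_survey.count(cls, outcome)
            slot = per_type.setdefault(
                outcome, {"freq": 0.0, "sem": 0.0, "bound": 0.0, "has_real": False}
            )
            inputs = classify_sem_inputs(class_percent, total, count)
            sem = outcome_sem(inputs)
            slot["sem"] += sem
            if count > 0 and class_percent > 0:
                slot["freq"] += class_percent * count / total
                slot["has_real"] = True
            elif class_percent == 0:
                slot["bound"] += 100.0 / n_hygs if n_hygs else 0.0
            else:  # count == 0, plugs analyzed
                slot["bound"] += class_percent / total

    entries = {}
    for outcome, slot in per_type.items():
        if slot["has_real"]:
            entries[outcome] = OutcomeEntry(slot["freq"], slot["sem"])
        else:
            entries[outcome] = OutcomeEntry(0.0, slot["sem"], is_bound=True, bound=slot["bound"])
    return OutcomeTable(
        entries=entries,
        loss_percent=class_freqs.class_iii,
        strain=strain,
    )


def loss_sem(loss_percents_across_inductions: Sequence[float]) -> float:
    """Chromosome-loss SEM: sample SD across inductions / sqrt(n)."""
    values = np.asarray(loss_percents_across_inductions, dtype=float)
    if values.size < 2:
        raise EstimatorError("loss_sem needs >= 2 replicate inductions")
    return float(values.std(ddof=1) / math.sqrt(values.size))


def _round_half_up(value: float) -> int:
    return int(math.floor(value + 0.5))


def bdr_total(outcome_table: OutcomeTable) -> int:
    """Total break-distal-rearrangement percent (integer-rounded).

    Sum of internal deletion + isochromosome + ring + translocation
    frequencies; bound cells contribute 0.
    """
    total = sum(outcome_table.frequency(t) for t in BDR_TYPES)
    return _round_half_up(total)


def categorize_copy_number(
    outcome_table: OutcomeTable, dsb_in_repeat: bool = False
) -> tuple[int, int]:
    """(change, no_change) integer percents of gene-copy-number impact.

    Copy-number change: inter-Ty deletions, translocations, rings,
    isochromosomes, other rearrangements and chromosome loss. No change:
    intra-Ty deletions, Ty gene conversion and allelic repair (the latter
    two only arise when the DSB sits inside the repeat; ``dsb_in_repeat``
    is recorded for provenance and does not alter the arithmetic).
    Bound cells contribute 0.
    """
    del dsb_in_repeat
    change = sum(outcome_table.frequency(t) for t in COPY_NUMBER_CHANGE_TYPES)
    change += outcome_table.loss_percent
    no_change = sum(outcome_table.frequency(t) for t in COPY_NUMBER_NO_CHANGE_TYPES)
    return _round_half_up(change), _round_half_up(no_change)


def estimate_outcomes(
    induced: CloneAssayCounts,
    uninduced: Optional[CloneAssayCounts],
    plug_survey: PlugSurvey,
    loss_percents_across_inductions: Optional[Sequence[float]] = None,
    denominator: str = "hygs",
    strain: Optional[str] = None,
) -> OutcomeTable:
    """Full estimator chain: raw -> subtract -> normalize -> plug-weight.

    An uninduced culture with zero cut clones contributes zero
    background; passing ``uninduced=None`` means no background control.
    """
    induced_freqs = class_frequencies(induced, denominator=denominator)
    if uninduced is None or uninduced.n_hygs == 0:
        hygs_fraction = uninduced.hygs_fraction if uninduced is not None else None
        uninduced_freqs = ClassFrequencies(
            0.0, 0.0, 0.0, FrequencyStage.RAW, hygs_fraction=hygs_fraction
        )
    else:
        uninduced_freqs = class_frequencies(uninduced, denominator=denominator)
    subtracted = background_subtract(induced_freqs, uninduced_freqs)
    normalized = normalize_classes(subtracted)
    table = repair_type_frequencies(
        normalized, plug_survey, n_hygs=induced.n_hygs, strain=strain
    )
    if loss_percents_across_inductions is not None:
        table.loss_sem = loss_sem(loss_percents_across_inductions)
    return table
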