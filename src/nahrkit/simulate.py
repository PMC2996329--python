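"""Synthetic data generators: diverged repeat families and clone assays.

Everything is seeded through one ``numpy.random.Generator`` per call, so
outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np

from nahrkit.catalog import Family, RepeatCatalog, RepeatElement, Strand
from nahrkit.estimator import (
    CloneAssayCounts,
    Condition,
    GeneticClass,
    OutcomeTable,
    OutcomeType,
    PlugSurvey,
    estimate_outcomes,
)

__all__ = [
    "Clustering",
    "FamilyEvolutionConfig",
    "AssayDesign",
    "OutcomeTruth",
    "RecoveryReport",
    "DEFAULT_CLASS_MAP",
    "evolve_family",
    "simulate_clone_assay",
    "recovery_experiment",
    "expected_pairwise_identity",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class Clustering(str, Enum):
    UNIFORM = "uniform"
    CLUSTERED = "clustered"


@dataclass(frozen=True)
class FamilyEvolutionConfig:
    """A repeat family evolved from one common ancestor.

    Each copy is mutated independently of the ancestor: per-site
    substitutions with probability ``substitution_prob`` (to a uniformly
    chosen different base), either scattered uniformly or confined to
    ``n_clusters`` windows covering ``cluster_fraction`` of the length
    (with the per-site rate scaled up so the expected substitution count
    matches the uniform mode). Optional indels: per-site events with
    geometric lengths.
    """

    ancestor_length: int = 5900
    n_copies: int = 50
    substitution_prob: float = 0.04
    clustering: Clustering = Clustering.UNIFORM
    cluster_fraction: float = 0.2
    n_clusters: int = 3
    indel_prob: float = 0.0
    indel_mean_length: float = 3.0
    family: Family = Family.TY1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0 or self.n_copies <= 0:
            raise ValueError("ancestor_length and n_copies must be positive")
        if not 0 <= self.substitution_prob < 1:
            raise ValueError("substitution_prob must be in [0, 1)")
        if not 0 < self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in (0, 1]")
        if self.n_clusters <= 0:
            raise ValueError("n_clusters must be positive")
        if not 0 <= self.indel_prob < 1:
            raise ValueError("indel_prob must be in [0, 1)")
        if self.indel_mean_length < 1:
            raise ValueError("indel_mean_length must be >= 1")
        if self.clustering is Clustering.CLUSTERED:
            if self.substitution_prob / self.cluster_fraction > 1:
                raise ValueError(
                    "clustered per-site rate substitution_prob/cluster_fraction exceeds 1"
                )


def expected_pairwise_identity(substitution_prob: float) -> float:
    """Closed-form expected per-site identity between two mutated copies.

    Each copy keeps the ancestral base with probability 1-d or switches
    to one of the 3 alternatives uniformly. Two copies agree when both
    kept the base or both switched to the same alternative:
    (1-d)^2 + d^2/3, reported as a percent.
    """
    d = substitution_prob
    return 100.0 * ((1.0 - d) ** 2 + d * d / 3.0)


def _cluster_windows(length: int, n_clusters: int, cluster_fraction: float) -> np.ndarray:
    """Boolean mask of evenly spaced mutation windows."""
    mask = np.zeros(length, dtype=bool)
    window = max(1, int(round(length * cluster_fraction / n_clusters)))
    starts = np.linspace(0, length - window, n_clusters).astype(int)
    for start in starts:
        mask[start : start + window] = True
    return mask


def _mutate_copy(
    ancestor: np.ndarray,
    config: FamilyEvolutionConfig,
    rng: np.random.Generator,
    window_mask: Optional[np.ndarray],
) -> str:
    seq = ancestor.copy()
    length = len(seq)
    if config.clustering is Clustering.UNIFORM:
        sub_mask = rng.random(length) < config.substitution_prob
    else:
        rate = config.substitution_prob / config.cluster_fraction
        sub_mask = (rng.random(length) < rate) & window_mask
    # substitute to a uniformly chosen *different* base: shift by 1..3
    shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
    idx = np.flatnonzero(sub_mask)
    base_codes = np.searchsorted(_BASES, seq[idx])  # ACGT are sorted bytes
    seq[idx] = _BASES[(base_codes + shifts) % 4]

    if config.indel_prob > 0:
        event_sites = np.flatnonzero(rng.random(length) < config.indel_prob)
        if event_sites.size:
            pieces = []
            cursor = 0
            for site in event_sites:
                size = int(rng.geometric(1.0 / config.indel_mean_length))
                pieces.append(seq[cursor:site])
                if rng.random() < 0.5:  # insertion
                    pieces.append(seq[site : site + 1])
                    pieces.append(rng.choice(_BASES, size=size))
                    cursor = site + 1
                else:  # deletion
                    cursor = site + size
            pieces.append(seq[cursor:])
            seq = np.concatenate(pieces) if pieces else seq
            if len(seq) == 0:
                seq = rng.choice(_BASES, size=1)
    return seq.tobytes().decode("ascii")


def evolve_family(config: FamilyEvolutionConfig) -> RepeatCatalog:
    """Generate a catalog of diverged copies of one random ancestor.

    Elements are placed head-to-tail with a 100-bp spacer on a synthetic
    chromosome so coordinate invariants hold.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = rng.choice(_BASES, size=config.ancestor_length)
    window_mask = (
        _cluster_windows(config.ancestor_length, config.n_clusters, config.cluster_fraction)
        if config.clustering is Clustering.CLUSTERED
        else None
    )
    elements = []
    cursor = 0
    for i in range(config.n_copies):
        seq = _mutate_copy(ancestor, config, rng, window_mask)
        elements.append(
            RepeatElement(
                element_id=f"syn{i:04d}",
                family=config.family,
                sequence=seq,
                chromosome="chrSyn",
                start=cursor,
                end=cursor + len(seq),
                strand=Strand.PLUS,
            )
        )
        cursor += len(seq) + 100
    provenance = [
        f"evolve_family seed={config.seed} d={config.substitution_prob} "
        f"clustering={config.clustering.value} n={config.n_copies} "
        f"L={config.ancestor_length}"
    ]
    return RepeatCatalog(elements, provenance=provenance)


# ---------------------------------------------------------------------------
# Clone assays


# Which genetic class each outcome's clones land in (chromosome loss is
# class III and handled separately).
DEFAULT_CLASS_MAP: Mapping[OutcomeType, GeneticClass] = {
    OutcomeType.ALLELIC: GeneticClass.CLASS_I,
    OutcomeType.INTERNAL_DELETION: GeneticClass.CLASS_I,
    OutcomeType.INTRA_TY_DELETION: GeneticClass.CLASS_I,
    OutcomeType.TY_GC: GeneticClass.CLASS_I,
    OutcomeType.ISOCHROMOSOME: GeneticClass.CLASS_II,
    OutcomeType.RING: GeneticClass.CLASS_II,
    OutcomeType.TRANSLOCATION: GeneticClass.CLASS_II,
    OutcomeType.OTHER: GeneticClass.CLASS_II,
}


@dataclass(frozen=True)
class OutcomeTruth:
    """Generating truth: outcome probabilities plus loss, summing to 1."""

    probabilities: Mapping[OutcomeType, float]
    loss: float

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        if any(p < 0 for p in probs.values()) or self.loss < 0:
            raise ValueError("probabilities must be >= 0")
        total = sum(probs.values()) + self.loss
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"truth must sum to 1, got {total}")
        object.__setattr__(self, "probabilities", probs)

    @classmethod
    def from_percent_row(
        cls, percents: Mapping[OutcomeType, float], loss_percent: float
    ) -> "OutcomeTruth":
        """Build a truth vector from a published frequency row (percents)."""
        total = sum(percents.values()) + loss_percent
        return cls(
            probabilities={k: v / total for k, v in percents.items()},
            loss=loss_percent / total,
        )

    @property
    def outcomes(self) -> list[OutcomeType]:
        return list(self.probabilities.keys())


@dataclass(frozen=True)
class AssayDesign:
    n_induced_clones: int = 955
    n_uninduced_clones: int = 955
    plugs_class_i: int = 18
    plugs_class_ii: int = 52
    background_event_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_induced_clones", "n_uninduced_clones", "plugs_class_i", "plugs_class_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.background_event_prob <= 1:
            raise ValueError("background_event_prob must be in [0, 1]")


def _draw_outcome_counts(
    truth: OutcomeTruth, n: int, rng: np.random.Generator
) -> tuple[dict[OutcomeType, int], int]:
    outcomes = truth.outcomes
    pvals = [truth.probabilities[o] for o in outcomes] + [truth.loss]
    draws = rng.multinomial(n, pvals)
    return dict(zip(outcomes, (int(x) for x in draws[:-1]))), int(draws[-1])


def simulate_clone_assay(
    truth: OutcomeTruth,
    design: AssayDesign,
    class_map: Mapping[OutcomeType, GeneticClass] = DEFAULT_CLASS_MAP,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CloneAssayCounts, CloneAssayCounts, PlugSurvey]:
    """Draw one synthetic assay: induced + uninduced counts and a plug survey.

    Induced clones are multinomial from the truth; each clone's outcome
    maps to a genetic class. Uninduced clones suffer a background event
    with ``background_event_prob`` (outcome then drawn from the same
    truth). Plug surveys subsample class members without replacement; a
    request above the class size is truncated with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)

    outcome_counts, n_loss = _draw_outcome_counts(truth, design.n_induced_clones, rng)
    class_members: dict[GeneticClass, dict[OutcomeType, int]] = {
        GeneticClass.CLASS_I: {},
        GeneticClass.CLASS_II: {},
    }
    class_totals = {cls: 0 for cls in GeneticClass}
    for outcome, count in outcome_counts.items():
        cls = class_map[outcome]
        class_members[cls][outcome] = class_members[cls].get(outcome, 0) + count
        class_totals[cls] += count
    class_totals[GeneticClass.CLASS_III] = n_loss

    induced = CloneAssayCounts(
        condition=Condition.INDUCED,
        n_scored=design.n_induced_clones,
        n_hygs=design.n_induced_clones,
        class_counts={
            GeneticClass.CLASS_I: class_totals[GeneticClass.CLASS_I],
            GeneticClass.CLASS_II: class_totals[GeneticClass.CLASS_II],
            GeneticClass.CLASS_III: n_loss,
        },
    )

    n_background = int(rng.binomial(design.n_uninduced_clones, design.background_event_prob))
    bg_counts, bg_loss = _draw_outcome_counts(truth, n_background, rng)
    bg_classes = {
        GeneticClass.CLASS_I: 0,
        GeneticClass.CLASS_II: 0,
        GeneticClass.CLASS_III: bg_loss,
    }
    for outcome, count in bg_counts.items():
        bg_classes[class_map[outcome]] += count
    uninduced = CloneAssayCounts(
        condition=Condition.UNINDUCED,
        n_scored=design.n_uninduced_clones,
        n_hygs=n_background,
        class_counts=bg_classes,
    )

    survey_counts: dict[GeneticClass, dict[OutcomeType, int]] = {}
    for cls, n_plugs in (
        (GeneticClass.CLASS_I, design.plugs_class_i),
        (GeneticClass.CLASS_II, design.plugs_class_ii),
    ):
        members = class_members[cls]
        available = sum(members.values())
        if n_plugs > available:
            warnings.warn(
                f"{cls.value}: requested {n_plugs} plugs but only {available} "
                "clones simulated; truncating",
                stacklevel=2,
            )
            n_plugs = available
        types = sorted(members.keys(), key=lambda o: o.value)
        if n_plugs == 0 or not types:
            survey_counts[cls] = {t: 0 for t in types}
            continue
        colors = np.array([members[t] for t in types])
        draw = rng.multivariate_hypergeometric(colors, n_plugs)
        survey_counts[cls] = {t: int(c) for t, c in zip(types, draw)}
    survey = PlugSurvey(counts=survey_counts)
    return induced, uninduced, survey


@dataclass
class RecoveryReport:
    """Replicate-level calibration summary of the estimator."""

    truth: OutcomeTruth
    n_replicates: int
    mean_estimate: dict[OutcomeType, float]  # percent
    empirical_sd: dict[OutcomeType, float]
    mean_sem: dict[OutcomeType, float]
    bias: dict[OutcomeType, float]  # mean estimate - truth, percent
    mean_loss: float
    loss_bias: float


def recovery_experiment(
    truth: OutcomeTruth,
    design: AssayDesign,
    n_replicates: int,
    seed: int = 0,
    class_map: Mapping[OutcomeType, GeneticClass] = DEFAULT_CLASS_MAP,
) -> RecoveryReport:
    """Simulate -> estimate ``n_replicates`` times and summarize recovery."""
    if n_replicates < 2:
        raise ValueError("recovery_experiment needs >= 2 replicates")
    rng = np.random.default_rng(seed)
    outcomes = truth.outcomes
    estimates = {o: np.empty(n_replicates) for o in outcomes}
    sems = {o: np.empty(n_replicates) for o in outcomes}
    losses = np.empty(n_replicates)
    for r in range(n_replicates):
        induced, uninduced, survey = simulate_clone_assay(truth, design, class_map, rng=rng)
        table = estimate_outcomes(induced, uninduced, survey)
        for o in outcomes:
            estimates[o][r] = table.frequency(o)
            entry = table.entries.get(o)
            sems[o][r] = entry.sem if entry is not None else 0.0
        losses[r] = table.loss_percent
    return RecoveryReport(
        truth=truth,
        n_replicates=n_replicates,
        mean_estimate={o: float(estimates[o].mean()) for o in outcomes},
        empirical_sd={o: float(estimates[o].std(ddof=1)) for o in outcomes},
        mean_sem={o: float(sems[o].mean()) for o in outcomes},
        bias={
            o: float(estimates[o].mean() - 100.0 * truth.probabilities[o]) for o in outcomes
        },
        mean_loss=float(losses.mean()),
        loss_bias=float(losses.mean() - 100.0 * truth.loss),
    )
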