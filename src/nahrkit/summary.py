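"""Summaries over homology matrices: MEPS binning, family statistics,
heat-map tables and recipient->donor rankings.

The MEPS threshold comparison is inclusive (block >= threshold), and
bins are half-open intervals [k*w, (k+1)*w) so a block of exactly 250 nt
falls in bin 1 under the default width of 250.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from nahrkit.catalog import Family, RepeatCatalog
from nahrkit.homology import HomologyMatrix

__all__ = [
    "MepsBinning",
    "FractionResult",
    "FamilyIdentityStats",
    "DonorRanking",
    "bin_block_length",
    "meps_fraction",
    "family_identity_stats",
    "rank_donors",
    "heatmap_table",
]

# Full-length elements rank against full-length elements; solo LTRs
# against solo LTRs.
FULL_LENGTH_FAMILIES = frozenset({Family.TY1, Family.TY2})


@dataclass(frozen=True)
class MepsBinning:
    bin_width: int = 250
    meps_threshold: int = 250

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.meps_threshold <= 0:
            raise ValueError("meps_threshold must be positive")


@dataclass(frozen=True)
class FractionResult:
    count_at_or_above: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count_at_or_above / self.total if self.total else 0.0


@dataclass(frozen=True)
class FamilyIdentityStats:
    family_a: Family
    family_b: Family
    mean: float
    sd: float
    n_pairs: int


@dataclass(frozen=True)
class DonorRanking:
    """Ranked donors for one recipient under one metric; rank 1 is best.

    Ties are broken lexicographically by donor id, so ranks are unique
    and deterministic.
    """

    recipient_id: str
    metric: str
    ranked: tuple[tuple[str, float, int], ...]  # (donor_id, value, rank)


def bin_block_length(length: int, binning: MepsBinning = MepsBinning()) -> int:
    """Half-open bin index: floor(length / bin_width)."""
    if length < 0:
        raise ValueError(f"block length must be >= 0, got {length}")
    return int(length // binning.bin_width)


def meps_fraction(
    block_matrix: HomologyMatrix, binning: MepsBinning = MepsBinning()
) -> FractionResult:
    """Fraction of pairs whose longest block meets the MEPS threshold."""
    if block_matrix.metric != "longest_block":
        raise ValueError(
            f"meps_fraction needs a longest_block matrix, got {block_matrix.metric!r}"
        )
    values = [v for _, v in block_matrix.pair_values()]
    count = sum(1 for v in values if v >= binning.meps_threshold)
    return FractionResult(count_at_or_above=count, total=len(values))


def family_identity_stats(
    identity_matrix: HomologyMatrix,
    catalog: RepeatCatalog,
    family_a: Family,
    family_b: Family,
    sd_convention: str = "population",
) -> FamilyIdentityStats:
    """Mean +/- SD of overall identity within or between families.

    Within-family (family_a == family_b) uses all unordered pairs inside
    the family; between-family uses all cross pairs. The SD is the
    population SD by default (``sd_convention="sample"`` switches to the
    n-1 convention).
    """
    if identity_matrix.metric != "overall_identity":
        raise ValueError(
            f"family_identity_stats needs an overall_identity matrix, "
            f"got {identity_matrix.metric!r}"
        )
    if sd_convention not in ("population", "sample"):
        raise ValueError(f"unknown sd_convention: {sd_convention!r}")
    members_a = [e.element_id for e in catalog if e.family is family_a]
    members_b = [e.element_id for e in catalog if e.family is family_b]
    if family_a is family_b:
        if len(members_a) < 2:
            raise ValueError(
                f"within-family stats need >= 2 members of {family_a.value}"
            )
        values = [
            identity_matrix.value(members_a[i], members_a[j])
            for i in range(len(members_a))
            for j in range(i + 1, len(members_a))
        ]
    else:
        if not members_a or not members_b:
            raise ValueError("between-family stats need members in both families")
        values = [
            identity_matrix.value(a, b) for a in members_a for b in members_b
        ]
    arr = np.asarray(values, dtype=float)
    ddof = 0 if sd_convention == "population" else 1
    return FamilyIdentityStats(
        family_a=family_a,
        family_b=family_b,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=ddof)),
        n_pairs=len(values),
    )


def _candidate_donors(recipient_family: Family, catalog: RepeatCatalog) -> list[str]:
    if recipient_family in FULL_LENGTH_FAMILIES:
        pool = FULL_LENGTH_FAMILIES
    else:
        pool = frozenset({recipient_family})
    return [e.element_id for e in catalog if e.family in pool]


def rank_donors(
    recipient_id: str,
    catalog: RepeatCatalog,
    metric_matrices: Mapping[str, HomologyMatrix],
) -> dict[str, DonorRanking]:
    """One deterministic donor ranking per metric for a recipient.

    Candidate donors follow the family compatibility rule: full-length
    recipients (Ty1/Ty2) rank against the other full-length elements,
    LTR recipients against the other LTRs. The recipient is excluded
    from its own ranking.
    """
    recipient = catalog.get(recipient_id)
    donors = [d for d in _candidate_donors(recipient.family, catalog) if d != recipient_id]
    rankings = {}
    for metric, matrix in metric_matrices.items():
        scored = sorted(
            ((d, matrix.value(recipient_id, d)) for d in donors),
            key=lambda item: (-item[1], item[0]),
        )
        rankings[metric] = DonorRanking(
            recipient_id=recipient_id,
            metric=metric,
            ranked=tuple(
                (donor, value, rank) for rank, (donor, value) in enumerate(scored, start=1)
            ),
        )
    return rankings


def heatmap_table(
    block_matrix: HomologyMatrix, binning: MepsBinning = MepsBinning()
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Square table of bin indices plus a bin -> interval legend.

    Diagonal cells are NA (self-comparisons are undefined).
    """
    if block_matrix.metric != "longest_block":
        raise ValueError(
            f"heatmap_table needs a longest_block matrix, got {block_matrix.metric!r}"
        )
    ids = block_matrix.element_ids
    n = len(ids)
    table = pd.DataFrame(
        np.full((n, n), pd.NA), index=ids, columns=ids, dtype="object"
    )
    max_bin = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            value = block_matrix.values[i, j]
            if math.isnan(value):
                continue
            b = bin_block_length(int(value), binning)
            table.iat[i, j] = b
            max_bin = max(max_bin, b)
    legend = {
        k: f"[{k * binning.bin_width},{(k + 1) * binning.bin_width})"
        for k in range(max_bin + 1)
    }
    return table.astype("Int64"), legend


def write_heatmap(
    block_matrix: HomologyMatrix,
    csv_path: Union[str, Path],
    legend_path: Union[str, Path],
    binning: MepsBinning = MepsBinning(),
) -> None:
    table, legend = heatmap_table(block_matrix, binning)
    table.to_csv(csv_path)
    Path(legend_path).write_text(json.dumps({str(k): v for k, v in legend.items()}, indent=2))


def write_rankings_tsv(
    rankings: Mapping[str, DonorRanking], path: Union[str, Path]
) -> None:
    lines = ["recipient\tmetric\trank\tdonor\tvalue"]
    for metric in sorted(rankings):
        ranking = rankings[metric]
        for donor, value, rank in ranking.ranked:
            lines.append(f"{ranking.recipient_id}\t{metric}\t{rank}\t{donor}\t{value:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_family_stats_tsv(
    stats: Iterable[FamilyIdentityStats], path: Union[str, Path]
) -> None:
    lines = ["family_a\tfamily_b\tmean\tsd\tn_pairs"]
    for s in stats:
        lines.append(
            f"{s.family_a.value}\t{s.family_b.value}\t{s.mean:.1f}\t{s.sd:.1f}\t{s.n_pairs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
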