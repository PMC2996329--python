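"""Readers/writers for clone-assay tables, outcome tables and manifests.

Formats are plain text only:

* ``clone_counts.tsv`` — strain, condition, n_scored, n_hygS, class_I,
  class_II, class_III, class_other;
* ``plugs.tsv`` — strain, class, type, count;
* ``outcome_table.tsv`` — per-type frequency/SEM/bound columns plus the
  chromosome-loss row.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import pandas as pd

import nahrkit
from nahrkit.estimator import (
    CloneAssayCounts,
    Condition,
    EstimatorError,
    GeneticClass,
    OutcomeTable,
    OutcomeType,
    PlugSurvey,
)

__all__ = [
    "read_clone_counts",
    "read_plug_surveys",
    "write_outcome_table",
    "write_manifest",
]

CLONE_COLUMNS = [
    "strain",
    "condition",
    "n_scored",
    "n_hygS",
    "class_I",
    "class_II",
    "class_III",
    "class_other",
]
PLUG_COLUMNS = ["strain", "class", "type", "count"]

_CLASS_BY_LABEL = {
    "I": GeneticClass.CLASS_I,
    "II": GeneticClass.CLASS_II,
    "class_I": GeneticClass.CLASS_I,
    "class_II": GeneticClass.CLASS_II,
}


def read_clone_counts(path: Union[str, Path]) -> dict[tuple[str, Condition], CloneAssayCounts]:
    """Parse clone_counts.tsv into per-(strain, condition) counts."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in CLONE_COLUMNS if c not in frame.columns]
    if missing:
        raise EstimatorError(f"{path}: missing columns {missing}")
    out = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            condition = Condition(str(row.condition).lower())
            counts = CloneAssayCounts(
                condition=condition,
                n_scored=int(row.n_scored),
                n_hygs=int(row.n_hygS),
                class_counts={
                    GeneticClass.CLASS_I: int(row.class_I),
                    GeneticClass.CLASS_II: int(row.class_II),
                    GeneticClass.CLASS_III: int(row.class_III),
                    GeneticClass.CLASS_OTHER: int(row.class_other),
                },
            )
        except (ValueError, EstimatorError) as exc:
            raise EstimatorError(f"{path}: line {row_no}: {exc}") from exc
        key = (str(row.strain), condition)
        if key in out:
            raise EstimatorError(f"{path}: duplicate row for {key}")
        out[key] = counts
    return out


def read_plug_surveys(path: Union[str, Path]) -> dict[str, PlugSurvey]:
    """Parse plugs.tsv into one PlugSurvey per strain."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PLUG_COLUMNS if c not in frame.columns]
    if missing:
        raise EstimatorError(f"{path}: missing columns {missing}")
    frame = frame[PLUG_COLUMNS]  # fix order; itertuples shadows .count otherwise
    per_strain: dict[str, dict[GeneticClass, dict[OutcomeType, int]]] = {}
    for row_no, row in enumerate(frame.itertuples(index=False, name=None), start=2):
        strain_raw, cls_raw, type_raw, count_raw = row
        try:
            cls = _CLASS_BY_LABEL[str(cls_raw)]
            outcome = OutcomeType(str(type_raw))
            count = int(count_raw)
        except (KeyError, ValueError) as exc:
            raise EstimatorError(f"{path}: line {row_no}: {exc}") from exc
        strain = str(strain_raw)
        per_strain.setdefault(strain, {}).setdefault(cls, {})[outcome] = count
    return {strain: PlugSurvey(counts=counts) for strain, counts in per_strain.items()}


def write_outcome_table(table: OutcomeTable, path: Union[str, Path]) -> None:
    """Outcome table TSV: one row per outcome type plus chromosome loss.

    Frequencies and SEMs are printed at one decimal (matching assay-table
    precision); full precision lives in the run manifest.
    """
    lines = ["strain\toutcome\tfrequency\tsem\tis_bound\tbound"]
    strain = table.strain or "."
    for outcome in OutcomeType:
        entry = table.entries.get(outcome)
        if entry is None:
            continue
        bound = f"{entry.bound:.1f}" if entry.bound is not None else "."
        lines.append(
            f"{strain}\t{outcome.value}\t{entry.frequency:.1f}\t{entry.sem:.1f}"
            f"\t{int(entry.is_bound)}\t{bound}"
        )
    loss_sem = f"{table.loss_sem:.1f}" if table.loss_sem is not None else "."
    lines.append(f"{strain}\tchromosome_loss\t{table.loss_percent:.1f}\t{loss_sem}\t0\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(
    path: Union[str, Path],
    command: str,
    parameters: Mapping[str, Any],
    seed: Optional[int] = None,
) -> None:
    manifest = {
        "tool": "nahrkit",
        "version": nahrkit.__version__,
        "python": platform.python_version(),
        "command": command,
        "seed": seed,
        "parameters": dict(parameters),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
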