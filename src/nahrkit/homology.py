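"""Pairwise homology metrics for repeat elements.

Three metrics are computed per unordered pair:

* ``overall_identity`` — percent identity of the optimal affine-gap
  global alignment (gap columns included in the denominator);
* ``longest_block`` — exact longest common substring, i.e. the longest
  block of uninterrupted 100% identity (``block_from_hits`` provides the
  local-hit-scanning heuristic as a cross-check; it can never exceed the
  exact value);
* ``local_raw_score`` / ``local_bitscore`` — best local (Smith-Waterman)
  alignment score under +1/-3 with affine gaps, rescaled to bits with
  Karlin-Altschul constants.

Scoring conventions
-------------------
Global gaps follow the EMBOSS convention: a gap of length k costs
``gap_open + (k-1) * gap_extend``. Local gaps follow the BLAST
convention: a gap of length k scores ``gap_open + k * gap_extend``
(both terms negative). ``N`` never matches anything, including ``N``.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from enum import Enum
from math import log
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from nahrkit.catalog import (
    ElementPair,
    Family,
    RepeatCatalog,
    make_pair,
    reverse_complement,
)

__all__ = [
    "AlignmentParams",
    "StrandMode",
    "PairwiseHomology",
    "LocalHit",
    "HomologyMatrix",
    "METRICS",
    "global_identity",
    "longest_perfect_block",
    "local_hits",
    "bitscore",
    "block_from_hits",
    "compute_pair",
    "pairwise_matrix",
]

METRICS = ("overall_identity", "longest_block", "local_raw_score", "local_bitscore")


class StrandMode(str, Enum):
    FORWARD_ONLY = "forward_only"
    BEST_OF_BOTH = "best_of_both"


class StrandUsed(str, Enum):
    FORWARD = "forward"
    REVCOMP = "revcomp"


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment scoring parameters.

    Global penalties are positive magnitudes (EMBOSS style); local gap
    scores are negative (BLAST style). The substitution scores for the
    global alignment are not dictated by the cited tool's command line,
    so they default to the standard DNA full-matrix values (+5/-4).
    Bit-score constants default to the ungapped Karlin-Altschul values
    for +1/-3.
    """

    global_match: float = 5.0
    global_mismatch: float = -4.0
    global_gap_open: float = 10.0
    global_gap_extend: float = 0.5
    local_match: float = 1.0
    local_mismatch: float = -3.0
    local_gap_open: float = -1.0
    local_gap_extend: float = -1.0
    bitscore_lambda: float = 1.374
    bitscore_K: float = 0.711

    def __post_init__(self) -> None:
        for name in (
            "global_match",
            "global_mismatch",
            "global_gap_open",
            "global_gap_extend",
            "local_match",
            "local_mismatch",
            "local_gap_open",
            "local_gap_extend",
            "bitscore_lambda",
            "bitscore_K",
        ):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"AlignmentParams.{name} must be finite, got {value}")
        if self.bitscore_lambda <= 0 or self.bitscore_K <= 0:
            raise ValueError("bitscore lambda and K must be positive")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class PairwiseHomology:
    pair: ElementPair
    overall_identity: float
    longest_block: int
    local_raw_score: float
    local_bitscore: float
    strand_used: StrandUsed = StrandUsed.FORWARD


@dataclass(frozen=True)
class LocalHit:
    """One local alignment hit.

    ``columns`` encodes the aligned columns: ``M`` match, ``X`` mismatch,
    ``A`` gap in sequence a, ``B`` gap in sequence b. The raw score is
    recomputable from the columns under the local scoring scheme.
    """

    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    raw_score: float
    columns: str

    def recompute_score(self, params: AlignmentParams = DEFAULT_PARAMS) -> float:
        score = 0.0
        score += self.columns.count("M") * params.local_match
        score += self.columns.count("X") * params.local_mismatch
        for gap_char in "AB":
            run = 0
            for col in self.columns + ".":
                if col == gap_char:
                    run += 1
                elif run:
                    score += params.local_gap_open + run * params.local_gap_extend
                    run = 0
        return score


def _validate_sequences(*seqs: str) -> None:
    for seq in seqs:
        if not seq:
            raise ValueError("empty sequence")


def _dna_substitution_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    # N is scored as a mismatch against everything, including itself.
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            matrix[x, y] = match if (x == y and x != "N") else mismatch
    return matrix


def _global_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _dna_substitution_matrix(
        params.global_match, params.global_mismatch
    )
    # EMBOSS convention: gap of length k costs open + (k-1) * extend.
    aligner.open_gap_score = -params.global_gap_open
    aligner.extend_gap_score = -params.global_gap_extend
    return aligner


def _local_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _dna_substitution_matrix(
        params.local_match, params.local_mismatch
    )
    # BLAST convention: gap of length k scores open + k * extend, so the
    # first gapped residue carries open + extend.
    aligner.open_gap_score = params.local_gap_open + params.local_gap_extend
    aligner.extend_gap_score = params.local_gap_extend
    return aligner


def global_identity(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    denominator: str = "alignment",
) -> tuple[float, int]:
    """Percent identity of the optimal affine-gap global alignment.

    Identity is 100 x (identical non-N columns) / denominator, where the
    denominator is the full alignment length including gap columns
    (default) or the shorter sequence length (``denominator="shorter"``).
    Symmetry is enforced by canonical argument ordering.
    """
    _validate_sequences(seq_a, seq_b)
    if denominator not in ("alignment", "shorter"):
        raise ValueError(f"unknown identity denominator: {denominator!r}")
    first, second = sorted((seq_a.upper(), seq_b.upper()))
    aligner = _global_aligner(params)
    alignment = next(iter(aligner.align(first, second)))
    row_a, row_b = alignment[0], alignment[1]
    n_columns = len(row_a)
    identities = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x not in ("-", "N")
    )
    if denominator == "alignment":
        denom = n_columns
    else:
        denom = min(len(seq_a), len(seq_b))
    return 100.0 * identities / denom, n_columns


def _encode(seq: str, n_code: int) -> np.ndarray:
    table = np.full(256, -9, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    table[ord("N")] = n_code
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == -9).any():
        raise ValueError("sequence contains non-ACGTN characters")
    return codes


def _lcs_forward(seq_a: str, seq_b: str) -> int:
    """Exact longest common substring by row-wise DP (N never matches)."""
    # distinct sentinel codes for N so N never equals N across sequences
    a = _encode(seq_a, n_code=-1)
    b = _encode(seq_b, n_code=-2)
    if len(a) < len(b):
        a, b = b, a
    best = 0
    prev = np.zeros(len(a), dtype=np.int32)
    cur = np.zeros(len(a), dtype=np.int32)
    for code in b:
        eq = a == code
        cur[0] = 1 if eq[0] else 0
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        row_max = int(cur.max())
        if row_max > best:
            best = row_max
        prev, cur = cur, prev
    return best


def longest_perfect_block(
    seq_a: str,
    seq_b: str,
    strand_mode: StrandMode = StrandMode.BEST_OF_BOTH,
) -> int:
    """Exact longest block of uninterrupted identity (longest common substring).

    With ``BEST_OF_BOTH`` the reverse complement of ``seq_b`` is also
    scanned and the maximum returned.
    """
    _validate_sequences(seq_a, seq_b)
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    forward = _lcs_forward(seq_a, seq_b)
    if strand_mode is StrandMode.FORWARD_ONLY:
        return forward
    return max(forward, _lcs_forward(seq_a, reverse_complement(seq_b)))


def _hit_from_alignment(alignment, params: AlignmentParams) -> LocalHit:
    row_a, row_b = alignment[0], alignment[1]
    columns = []
    for x, y in zip(row_a, row_b):
        if x == "-":
            columns.append("A")
        elif y == "-":
            columns.append("B")
        elif x == y and x != "N":
            columns.append("M")
        else:
            columns.append("X")
    coords = alignment.coordinates
    return LocalHit(
        interval_a=(int(coords[0][0]), int(coords[0][-1])),
        interval_b=(int(coords[1][0]), int(coords[1][-1])),
        raw_score=float(alignment.score),
        columns="".join(columns),
    )


def local_hits(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    max_hits: int = 1,
    min_score: float = 1.0,
) -> list[LocalHit]:
    """Best local (Smith-Waterman) alignments under the local scheme.

    Returns at least the single best hit; with ``max_hits > 1``, further
    non-overlapping hits are found greedily by masking each hit's aligned
    intervals (with N, which matches nothing) and re-aligning. An empty
    list is returned when no alignment reaches ``min_score``.
    """
    _validate_sequences(seq_a, seq_b)
    work_a, work_b = seq_a.upper(), seq_b.upper()
    aligner = _local_aligner(params)
    hits: list[LocalHit] = []
    while len(hits) < max_hits:
        if aligner.score(work_a, work_b) < min_score:
            break
        alignment = next(iter(aligner.align(work_a, work_b)))
        if alignment.score < min_score:
            break
        hit = _hit_from_alignment(alignment, params)
        hits.append(hit)
        a0, a1 = hit.interval_a
        b0, b1 = hit.interval_b
        work_a = work_a[:a0] + "N" * (a1 - a0) + work_a[a1:]
        work_b = work_b[:b0] + "N" * (b1 - b0) + work_b[b1:]
    return hits


def bitscore(raw_score: float, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Karlin-Altschul bit score: (lambda * S - ln K) / ln 2."""
    if not np.isfinite(raw_score):
        raise ValueError("raw_score must be finite")
    return (params.bitscore_lambda * raw_score - log(params.bitscore_K)) / log(2.0)


def block_from_hits(hits: Iterable[LocalHit]) -> int:
    """Longest run of match columns across hits (heuristic block length).

    Guaranteed <= :func:`longest_perfect_block` on the same pair, since a
    run of match columns is a common substring.
    """
    best = 0
    for hit in hits:
        run = 0
        for col in hit.columns:
            if col == "M":
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
    return best


def compute_pair(
    element_a,
    element_b,
    params: AlignmentParams = DEFAULT_PARAMS,
    strand_mode: StrandMode = StrandMode.BEST_OF_BOTH,
) -> PairwiseHomology:
    """All three metrics for one element pair.

    Under ``BEST_OF_BOTH`` each metric independently takes the better of
    the forward and reverse-complement orientations of ``element_b``;
    ``strand_used`` records which orientation won the longest block
    (FORWARD on ties).
    """
    seq_a, seq_b = element_a.sequence, element_b.sequence
    pair = make_pair(element_a.element_id, element_b.element_id)

    def metrics(sb: str) -> tuple[float, int, float]:
        identity, _ = global_identity(seq_a, sb, params)
        block = _lcs_forward(seq_a, sb)
        hits = local_hits(seq_a, sb, params)
        raw = hits[0].raw_score if hits else 0.0
        return identity, block, raw

    fwd_identity, fwd_block, fwd_raw = metrics(seq_b)
    if strand_mode is StrandMode.FORWARD_ONLY:
        identity, block, raw = fwd_identity, fwd_block, fwd_raw
        strand = StrandUsed.FORWARD
    else:
        rc = reverse_complement(seq_b)
        rev_identity, rev_block, rev_raw = metrics(rc)
        identity = max(fwd_identity, rev_identity)
        block = max(fwd_block, rev_block)
        raw = max(fwd_raw, rev_raw)
        strand = StrandUsed.REVCOMP if rev_block > fwd_block else StrandUsed.FORWARD
    return PairwiseHomology(
        pair=pair,
        overall_identity=identity,
        longest_block=block,
        local_raw_score=raw,
        local_bitscore=bitscore(raw, params),
        strand_used=strand,
    )


class HomologyMatrix:
    """Symmetric all-vs-all metric table with an undefined diagonal."""

    def __init__(self, element_ids: Sequence[str], metric: str) -> None:
        if metric not in METRICS:
            raise ValueError(f"unknown metric: {metric!r} (choose from {METRICS})")
        self.element_ids = list(element_ids)
        self.metric = metric
        self._index = {eid: i for i, eid in enumerate(self.element_ids)}
        n = len(self.element_ids)
        self.values = np.full((n, n), np.nan)
        self.strands: dict[ElementPair, StrandUsed] = {}

    def set(self, id_a: str, id_b: str, value: float, strand: StrandUsed) -> None:
        i, j = self._index[id_a], self._index[id_b]
        if i == j:
            raise ValueError("diagonal (self-comparison) is undefined")
        self.values[i, j] = value
        self.values[j, i] = value
        self.strands[make_pair(id_a, id_b)] = strand

    def value(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def pair_values(self) -> list[tuple[ElementPair, float]]:
        out = []
        for i, id_a in enumerate(self.element_ids):
            for j in range(i + 1, len(self.element_ids)):
                out.append((make_pair(id_a, self.element_ids[j]), float(self.values[i, j])))
        return out

    def to_long_tsv(self, path: Union[str, Path]) -> None:
        lines = ["id_a\tid_b\tmetric\tvalue\tstrand_used"]
        for pair, value in self.pair_values():
            strand = self.strands.get(pair, StrandUsed.FORWARD)
            lines.append(
                f"{pair.id_a}\t{pair.id_b}\t{self.metric}\t{value:.6g}\t{strand.value}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_square_csv(self, path: Union[str, Path]) -> None:
        header = "," + ",".join(self.element_ids)
        lines = [header]
        for i, eid in enumerate(self.element_ids):
            cells = []
            for j in range(len(self.element_ids)):
                if i == j:
                    cells.append("")
                else:
                    cells.append(f"{self.values[i, j]:.6g}")
            lines.append(eid + "," + ",".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")


def pairwise_matrix(
    catalog: RepeatCatalog,
    metric: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    strand_mode: StrandMode = StrandMode.BEST_OF_BOTH,
    family_filter: Optional[Iterable[Family]] = None,
    progress: bool = False,
) -> HomologyMatrix:
    """Fill a symmetric metric matrix over all selected element pairs."""
    selection = catalog.subset(family_filter) if family_filter is not None else catalog
    if len(selection) < 2:
        raise ValueError("pairwise_matrix needs at least 2 selected elements")
    matrix = HomologyMatrix(selection.element_ids, metric)
    elements = {e.element_id: e for e in selection}
    pairs = [
        (a, b)
        for i, a in enumerate(selection.element_ids)
        for b in selection.element_ids[i + 1 :]
    ]
    for k, (id_a, id_b) in enumerate(pairs):
        try:
            result = compute_pair(elements[id_a], elements[id_b], params, strand_mode)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"pair ({id_a}, {id_b}): {exc}") from exc
        matrix.set(id_a, id_b, getattr(result, metric), result.strand_used)
        if progress and (k + 1) % 500 == 0:
            print(f"pairwise_matrix: {k + 1}/{len(pairs)} pairs", file=sys.stderr)
    return matrix
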