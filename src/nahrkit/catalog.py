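"""Repeat element catalogs: loading, corrections and pair enumeration.

Coordinates are 0-based half-open internally. GFF3 input (1-based
inclusive) is converted at the I/O boundary. Element sequences are
stored 5'->3' of the element itself, so a MINUS-strand element's
sequence is the reverse complement of the reference strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Family",
    "Strand",
    "RepeatElement",
    "RepeatCatalog",
    "CorrectionList",
    "ElementPair",
    "CatalogError",
    "load_catalog",
    "apply_corrections",
    "enumerate_pairs",
    "write_catalog_tsv",
    "write_fasta",
    "write_bed",
]

_VALID_BASES = frozenset("ACGTN")


class CatalogError(ValueError):
    """Raised on malformed catalog input or inconsistent corrections."""


class Family(str, Enum):
    TY1 = "TY1"
    TY2 = "TY2"
    LTR = "LTR"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, label: str) -> "Family":
        key = label.strip().upper()
        aliases = {
            "TY1": cls.TY1,
            "TY2": cls.TY2,
            "LTR": cls.LTR,
            "DELTA": cls.LTR,
            "SOLO_LTR": cls.LTR,
            "OTHER": cls.OTHER,
        }
        if key in aliases:
            return aliases[key]
        raise CatalogError(f"unknown family label: {label!r}")


def infer_family(name: str) -> Family:
    """Best-effort family from an element name (e.g. ``YCRWdelta8``)."""
    low = name.lower()
    if "ty1" in low:
        return Family.TY1
    if "ty2" in low:
        return Family.TY2
    if "delta" in low or "ltr" in low:
        return Family.LTR
    return Family.OTHER


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class RepeatElement:
    """One annotated repeat element.

    ``start``/``end`` are 0-based half-open on ``chromosome``; both may be
    None in FASTA-only mode. ``sequence`` is the element's own 5'->3'
    strand over {A, C, G, T, N}.
    """

    element_id: str
    family: Family
    sequence: str
    chromosome: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Strand = Strand.PLUS

    def __post_init__(self) -> None:
        if not self.element_id:
            raise CatalogError("element_id must be non-empty")
        if not self.sequence:
            raise CatalogError(f"element {self.element_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise CatalogError(
                f"element {self.element_id!r}: non-ACGTN characters {sorted(bad)!r}"
            )
        has_coords = self.start is not None and self.end is not None
        if (self.start is None) != (self.end is None):
            raise CatalogError(
                f"element {self.element_id!r}: start/end must both be set or both absent"
            )
        if has_coords:
            if self.end <= self.start:  # type: ignore[operator]
                raise CatalogError(
                    f"element {self.element_id!r}: end ({self.end}) must exceed start ({self.start})"
                )
            span = self.end - self.start  # type: ignore[operator]
            if span != len(self.sequence):
                raise CatalogError(
                    f"element {self.element_id!r}: coordinate span {span} != "
                    f"sequence length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sort_key(self) -> tuple:
        return (
            self.chromosome or "",
            self.start if self.start is not None else -1,
            self.element_id,
        )


class RepeatCatalog:
    """Ordered, deduplicated collection of :class:`RepeatElement`.

    Elements are kept sorted by (chromosome, start, element_id) so all
    downstream matrices and rankings are reproducible.
    """

    def __init__(
        self,
        elements: Iterable[RepeatElement],
        provenance: Optional[Sequence[str]] = None,
    ) -> None:
        elements = sorted(elements, key=RepeatElement.sort_key)
        seen: dict[str, RepeatElement] = {}
        for element in elements:
            if element.element_id in seen:
                raise CatalogError(f"duplicate element_id: {element.element_id!r}")
            seen[element.element_id] = element
        self._elements: list[RepeatElement] = elements
        self._by_id = seen
        self.provenance: list[str] = list(provenance or [])

    def __len__(self) -> int:
        return len(self._elements)

    def __iter__(self) -> Iterator[RepeatElement]:
        return iter(self._elements)

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    @property
    def elements(self) -> Sequence[RepeatElement]:
        return tuple(self._elements)

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for e in self._elements]

    def get(self, element_id: str) -> RepeatElement:
        try:
            return self._by_id[element_id]
        except KeyError:
            raise CatalogError(f"unknown element_id: {element_id!r}") from None

    def subset(self, families: Iterable[Family]) -> "RepeatCatalog":
        wanted = set(families)
        return RepeatCatalog(
            [e for e in self._elements if e.family in wanted],
            provenance=self.provenance + [f"subset families={sorted(f.value for f in wanted)}"],
        )


@dataclass
class CorrectionList:
    """Resequencing-driven catalog corrections: removals then additions."""

    additions: Sequence[RepeatElement] = field(default_factory=tuple)
    removals: Sequence[str] = field(default_factory=tuple)


@dataclass(frozen=True, order=True)
class ElementPair:
    """One unordered element pair, canonicalized so id_a < id_b."""

    id_a: str
    id_b: str

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise CatalogError(f"self-pair not allowed: {self.id_a!r}")
        if self.id_a > self.id_b:
            raise CatalogError("ElementPair ids must satisfy id_a < id_b; use make_pair")


def make_pair(id_x: str, id_y: str) -> ElementPair:
    a, b = sorted((id_x, id_y))
    return ElementPair(a, b)


# ---------------------------------------------------------------------------
# Annotation parsing


@dataclass(frozen=True)
class _AnnotationRecord:
    element_id: str
    family: Family
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: Strand


def _parse_bed(path: Path) -> list[_AnnotationRecord]:
    records = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise CatalogError(f"{path}:{line_no}: BED needs >= 6 columns, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        family = Family.parse(fields[6]) if len(fields) > 6 else infer_family(name)
        records.append(
            _AnnotationRecord(
                element_id=name,
                family=family,
                chromosome=chrom,
                start=int(start),
                end=int(end),
                strand=Strand(strand),
            )
        )
    return records


def _parse_gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def _parse_gff3(path: Path) -> list[_AnnotationRecord]:
    records = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise CatalogError(f"{path}:{line_no}: GFF3 needs 9 columns, got {len(fields)}")
        chrom, _source, _type, start, end, _score, strand, _phase, attrs = fields
        attributes = _parse_gff3_attributes(attrs)
        if "ID" not in attributes:
            raise CatalogError(f"{path}:{line_no}: GFF3 attributes missing ID")
        element_id = attributes["ID"]
        family = (
            Family.parse(attributes["family"])
            if "family" in attributes
            else infer_family(element_id)
        )
        records.append(
            _AnnotationRecord(
                element_id=element_id,
                family=family,
                chromosome=chrom,
                start=int(start) - 1,  # GFF3 is 1-based inclusive
                end=int(end),
                strand=Strand(strand),
            )
        )
    return records


def load_catalog(
    fasta_source: Union[str, Path],
    annotation_source: Optional[Union[str, Path]] = None,
    annotation_dialect: str = "bed",
    fasta_orientation: str = "element",
    default_family: Optional[Family] = None,
) -> RepeatCatalog:
    """Load a repeat catalog from FASTA plus an optional annotation table.

    Parameters
    ----------
    fasta_source
        FASTA file of element sequences, one record per element.
    annotation_source
        BED (0-based half-open) or GFF3 (1-based inclusive) table; every
        annotation record must have a matching FASTA record by id. When
        absent, a FASTA-only catalog is built (no coordinates; family from
        ``default_family`` or inferred from record ids).
    annotation_dialect
        ``"bed"`` or ``"gff3"``.
    fasta_orientation
        ``"element"`` (default): FASTA records are already the element's
        own 5'->3' sequence and are stored as-is. ``"reference"``: records
        are reference-strand slices, so MINUS-strand elements are
        reverse-complemented on load.
    """
    fasta_path = Path(fasta_source)
    if fasta_orientation not in ("element", "reference"):
        raise CatalogError(f"unknown fasta_orientation: {fasta_orientation!r}")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise CatalogError(f"duplicate FASTA record id: {record.id!r}")
        sequences[record.id] = str(record.seq).upper()

    provenance = [f"fasta={fasta_path}"]
    elements: list[RepeatElement] = []

    if annotation_source is None:
        for element_id, seq in sequences.items():
            elements.append(
                RepeatElement(
                    element_id=element_id,
                    family=default_family or infer_family(element_id),
                    sequence=seq,
                )
            )
        provenance.append("annotation=None (FASTA-only mode)")
        return RepeatCatalog(elements, provenance=provenance)

    annotation_path = Path(annotation_source)
    dialect = annotation_dialect.lower()
    if dialect == "bed":
        annotation = _parse_bed(annotation_path)
    elif dialect == "gff3":
        annotation = _parse_gff3(annotation_path)
    else:
        raise CatalogError(f"unknown annotation dialect: {annotation_dialect!r}")
    provenance.append(f"annotation={annotation_path} dialect={dialect}")

    annotated_ids = {rec.element_id for rec in annotation}
    missing_fasta = sorted(annotated_ids - sequences.keys())
    if missing_fasta:
        raise CatalogError(f"annotation ids missing from FASTA: {missing_fasta}")
    orphans = sorted(sequences.keys() - annotated_ids)
    if orphans:
        raise CatalogError(f"FASTA records missing from annotation: {orphans}")

    for rec in annotation:
        seq = sequences[rec.element_id]
        if fasta_orientation == "reference" and rec.strand is Strand.MINUS:
            seq = reverse_complement(seq)
        elements.append(
            RepeatElement(
                element_id=rec.element_id,
                family=rec.family,
                sequence=seq,
                chromosome=rec.chromosome,
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
            )
        )
    return RepeatCatalog(elements, provenance=provenance)


def apply_corrections(catalog: RepeatCatalog, corrections: CorrectionList) -> RepeatCatalog:
    """Apply removals, then additions, recording both in provenance."""
    by_id = {e.element_id: e for e in catalog}
    for element_id in corrections.removals:
        if element_id not in by_id:
            raise CatalogError(f"correction removes unknown element_id: {element_id!r}")
        del by_id[element_id]
    for element in corrections.additions:
        if element.element_id in by_id:
            raise CatalogError(
                f"correction adds colliding element_id: {element.element_id!r}"
            )
        by_id[element.element_id] = element
    provenance = catalog.provenance + [
        f"removed={list(corrections.removals)}",
        f"added={[e.element_id for e in corrections.additions]}",
    ]
    return RepeatCatalog(by_id.values(), provenance=provenance)


def enumerate_pairs(
    catalog: RepeatCatalog,
    family_filter: Optional[Iterable[Family]] = None,
) -> list[ElementPair]:
    """All n(n-1)/2 unordered pairs among the selected elements.

    Order is deterministic: combinations in catalog sort order, each pair
    canonicalized to id_a < id_b. An empty selection yields no pairs.
    """
    if family_filter is not None:
        selected = [e for e in catalog if e.family in set(family_filter)]
    else:
        selected = list(catalog)
    return [
        make_pair(a.element_id, b.element_id)
        for a, b in itertools.combinations(selected, 2)
    ]


# ---------------------------------------------------------------------------
# Writers (round-trip partners of load_catalog)


def write_catalog_tsv(catalog: RepeatCatalog, path: Union[str, Path]) -> None:
    lines = ["element_id\tfamily\tchromosome\tstart\tend\tstrand\tlength"]
    for e in catalog:
        lines.append(
            "\t".join(
                [
                    e.element_id,
                    e.family.value,
                    e.chromosome or ".",
                    str(e.start) if e.start is not None else ".",
                    str(e.end) if e.end is not None else ".",
                    e.strand.value,
                    str(e.length),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(catalog: RepeatCatalog, path: Union[str, Path], width: int = 60) -> None:
    chunks = []
    for e in catalog:
        chunks.append(f">{e.element_id}")
        for i in range(0, len(e.sequence), width):
            chunks.append(e.sequence[i : i + width])
    Path(path).write_text("\n".join(chunks) + "\n")


def write_bed(catalog: RepeatCatalog, path: Union[str, Path]) -> None:
    lines = []
    for e in catalog:
        if e.start is None:
            raise CatalogError(
                f"element {e.element_id!r} has no coordinates; cannot write BED"
            )
        lines.append(
            "\t".join(
                [
                    e.chromosome or ".",
                    str(e.start),
                    str(e.end),
                    e.element_id,
                    "0",
                    e.strand.value,
                    e.family.value,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
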