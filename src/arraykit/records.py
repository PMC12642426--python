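"""Shared domain records: source references and fragment annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from arraykit._seq import validate_dna

#: Recognised source classes for references in an injection mix / host.
SOURCE_CLASSES = ("transgene", "selection", "stuffer", "host")


@dataclass(frozen=True)
class ReferenceRecord:
    """A named source sequence with a class label.

    Parameters
    ----------
    id : str
        Unique reference name (FASTA id).
    seq : str
        Upper-case DNA.
    source_class : str
        One of ``transgene``, ``selection``, ``stuffer``, ``host``.
    atts : tuple
        Optional att-site annotations as ``(kind, start, end, strand)``
        tuples in reference coordinates.
    """

    id: str
    seq: str
    source_class: str
    atts: tuple = field(default=())

    def __post_init__(self):
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"unknown source class {self.source_class!r}; "
                f"expected one of {SOURCE_CLASSES}"
            )
        validate_dna(self.seq, name=f"reference {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


def check_unique_ids(references: Iterable[ReferenceRecord]) -> dict:
    """Return an id -> record map, raising on duplicate reference ids."""
    by_id: dict[str, ReferenceRecord] = {}
    for rec in references:
        if rec.id in by_id:
            raise ValueError(f"duplicate reference id {rec.id!r}")
        by_id[rec.id] = rec
    return by_id


@dataclass
class FragmentAnnotation:
    """One source-derived interval placed on an array contig.

    Contig and source intervals are 0-based half-open and have equal length
    (substitution-only alignment model). ``strand`` is '+' when the contig
    carries the source sequence forward, '-' when reverse-complemented.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    source_id: str
    source_start: int
    source_end: int
    identity: float = 1.0
    full_length: bool | None = None

    def __post_init__(self):
        if self.end - self.start != self.source_end - self.source_start:
            raise ValueError(
                "contig and source interval lengths differ for "
                f"{self.source_id} at {self.contig_id}:{self.start}-{self.end}"
            )
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must be in (0, 1]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        """Comparison key used when matching annotations against truth."""
        return (
            self.contig_id,
            self.start,
            self.end,
            self.strand,
            self.source_id,
            self.source_start,
            self.source_end,
        )
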