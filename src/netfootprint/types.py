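"""Core record types shared across the pipeline.

A protein is the unit of classification: it belongs to one species, may carry
a sequence, and is annotated with protein domains.  A protein counts as a
transcription factor (TF) when at least one of its domains is in a curated
catalog of sequence-specific DNA-binding domains (DBDs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: residues accepted in protein sequences: 20 amino acids, X (unknown), * (stop)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

PFAM_ACCESSION_RE = re.compile(r"^PF\d+(\.\d+)?$")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with a species tag and optional sequence.

    ``protein_id`` must be unique within its species; uniqueness across a
    collection is enforced by the readers, not by this record.
    """

    protein_id: str
    species_id: str
    sequence: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.sequence is not None:
            bad = set(self.sequence) - VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"illegal residue(s) {sorted(bad)} in protein {self.protein_id}"
                )


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain hit on a protein, with 1-based inclusive coordinates."""

    protein_id: str
    domain_accession: str
    start: int
    end: int
    domain_name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} on {self.protein_id}: "
                "require 1 <= start <= end"
            )

    @property
    def is_pfam(self) -> bool:
        """True when the accession follows the Pfam ``PF#####`` pattern."""
        return PFAM_ACCESSION_RE.match(self.domain_accession) is not None


@dataclass(frozen=True)
class DBDCatalog:
    """Curated set of Pfam accessions that bind DNA sequence-specifically.

    Membership of a protein's domain set in this catalog is the TF criterion.
    """

    accessions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("DBD catalog is empty: a TF census against an "
                             "empty catalog is meaningless")

    def __contains__(self, accession: str) -> bool:
        return accession in self.accessions

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass(frozen=True)
class SourceEdge:
    """An experimentally observed TF-TF interaction in an assayed species.

    Endpoints are stored in canonical (lexicographic) order; ``a == b`` is a
    homodimer.  ``edge_id`` is the provenance key carried by every interlog
    inferred from this edge.
    """

    edge_id: str
    a: str
    b: str
    species_id: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.a or not self.b:
            raise ValueError("source edge endpoints must be non-empty ids")
        if self.a > self.b:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @property
    def is_homodimer(self) -> bool:
        return self.a == self.b

    @property
    def endpoints(self) -> tuple[str, str]:
        return (self.a, self.b)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered protein pair lexicographically (loops allowed)."""
    return (a, b) if a <= b else (b, a)
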