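"""Transcription-factor census: ORF finding, CDS selection, classification, PPV.

A transcriptome contig is translated in all six reading frames; one coding
sequence per contig is selected (the ORF with the best database hit when one
exists, otherwise the longest).  A protein is classified as a transcription
factor iff it carries at least one domain from the curated catalog of
sequence-specific DNA-binding domains.  Predictions are validated against a
known TF set by positive predictive value, PPV = 100 * TP / (TP + FP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .types import DBDCatalog, DomainAnnotation, ProteinRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate coding region of a contig.

    Coordinates are 1-based inclusive on the forward strand and cover the
    peptide's codons only (no stop codon), so end - start + 1 == 3 * len(peptide).
    Frame +f reads the forward strand from offset f-1; frame -f reads the
    reverse complement from offset f-1.
    """

    contig_id: str
    frame: int
    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"invalid frame {self.frame}")
        if (self.end - self.start + 1) != 3 * len(self.peptide):
            raise ValueError("coordinates do not match peptide length")
        if "*" in self.peptide:
            raise ValueError("peptide contains an internal stop")

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}|{self.frame:+d}|{self.start}-{self.end}"


@dataclass(frozen=True)
class BestHit:
    contig_id: str
    orf_id: str
    hit_found: bool
    bitscore: float = 0.0
    evalue: float = float("inf")


class BestHitTable:
    """At most one database best-hit row per (contig, ORF)."""

    def __init__(self, hits: Iterable[BestHit] = ()) -> None:
        self._hits: dict[tuple[str, str], BestHit] = {}
        for h in hits:
            self.add(h)

    def add(self, hit: BestHit) -> None:
        key = (hit.contig_id, hit.orf_id)
        if key in self._hits:
            raise ValueError(f"duplicate best-hit row for {key}")
        self._hits[key] = hit

    def get(self, contig_id: str, orf_id: str) -> BestHit | None:
        return self._hits.get((contig_id, orf_id))

    def __len__(self) -> int:
        return len(self._hits)


def _translate(codon: str) -> str:
    if set(codon) <= {"A", "C", "G", "T"}:
        if codon in STOP_CODONS:
            return "*"
        return str(Seq(codon).translate())
    return "X"  # any N makes the residue unknown


def _frame_peptide(nt: str, offset: int) -> str:
    return "".join(_translate(nt[i:i + 3])
                   for i in range(offset, len(nt) - 2, 3))


def find_orfs(contig_id: str, sequence: str, min_aa_length: int = 30,
              orf_mode: str = "atg_to_stop") -> list[OrfCandidate]:
    """Find maximal ORFs in all six frames of a nucleotide sequence.

    atg_to_stop: from the first ATG after the previous stop to the next stop
    (or sequence end); stop_to_stop: the whole stretch between stops.  The
    stop codon is excluded from coordinates and peptide.  N-containing codons
    translate to X.  Returns ORFs with peptide length >= ``min_aa_length``.
    """
    if orf_mode not in ("atg_to_stop", "stop_to_stop"):
        raise ValueError(f"unknown orf_mode {orf_mode!r}")
    if min_aa_length < 1:
        raise ValueError("min_aa_length must be >= 1")
    sequence = sequence.upper()
    bad = set(sequence) - NUCLEOTIDES
    if bad:
        raise ValueError(f"illegal nucleotide(s) {sorted(bad)} in {contig_id}")
    L = len(sequence)
    if L < 3:
        return []
    rc = str(Seq(sequence).reverse_complement())

    orfs: list[OrfCandidate] = []
    for strand, nt in ((1, sequence), (-1, rc)):
        for off in range(3):
            pep = _frame_peptide(nt, off)
            frame = strand * (off + 1)
            for seg_start, seg in _split_on_stops(pep):
                if orf_mode == "atg_to_stop":
                    m = seg.find("M")
                    if m < 0:
                        continue
                    seg_start, seg = seg_start + m, seg[m:]
                if len(seg) < min_aa_length:
                    continue
                # codon positions on the reading strand, 1-based
                s_nt = off + 3 * seg_start + 1
                e_nt = s_nt + 3 * len(seg) - 1
                if strand == 1:
                    start, end = s_nt, e_nt
                else:
                    start, end = L - e_nt + 1, L - s_nt + 1
                orfs.append(OrfCandidate(contig_id, frame, start, end, seg))
    orfs.sort(key=lambda o: (-len(o.peptide), o.start, o.frame))
    return orfs


def _split_on_stops(pep: str) -> list[tuple[int, str]]:
    """Segments of a frame translation between stops, with codon offsets."""
    segments = []
    pos = 0
    for seg in pep.split("*"):
        if seg:
            segments.append((pos, seg))
        pos += len(seg) + 1
    return segments


def select_cds(
    orfs_by_contig: Mapping[str, Sequence[OrfCandidate]],
    best_hits: BestHitTable,
) -> dict[str, tuple[OrfCandidate, str]]:
    """Choose one CDS per contig and tag its provenance.

    If any ORF of the contig has a database hit, the hit ORF wins (highest
    bitscore; ties: lowest e-value, then longest peptide, then smallest
    start) and is tagged ``best_hit``; otherwise the longest peptide wins
    (ties: smallest start, then lowest frame number), tagged ``longest``.
    Contigs with zero ORFs are excluded with a warning.
    """
    chosen: dict[str, tuple[OrfCandidate, str]] = {}
    for contig_id in sorted(orfs_by_contig):
        orfs = list(orfs_by_contig[contig_id])
        if not orfs:
            logger.warning("contig %s has no ORFs; excluded", contig_id)
            continue
        hit_orfs = []
        for o in orfs:
            h = best_hits.get(contig_id, o.orf_id)
            if h is not None and h.hit_found:
                hit_orfs.append((o, h))
        if hit_orfs:
            best = min(hit_orfs, key=lambda oh: (
                -oh[1].bitscore, oh[1].evalue, -len(oh[0].peptide), oh[0].start))
            chosen[contig_id] = (best[0], "best_hit")
        else:
            best_o = min(orfs, key=lambda o: (-len(o.peptide), o.start, o.frame))
            chosen[contig_id] = (best_o, "longest")
    return chosen


@dataclass(frozen=True)
class TFSet:
    """The TF repertoire of one species: members and their DBD accessions."""

    species_id: str
    members: frozenset[str]
    dbd_accessions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in self.members if not self.dbd_accessions.get(m)]
        if missing:
            raise ValueError(
                f"TF member(s) without any DBD accession: {sorted(missing)[:5]}"
            )

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.members

    def __len__(self) -> int:
        return len(self.members)


def classify_tfs(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[DomainAnnotation],
    catalog: DBDCatalog,
    strict: bool = True,
) -> TFSet:
    """Classify proteins as TFs: membership iff >= 1 domain is in the catalog.

    In strict mode an annotation referencing an unknown protein raises; in
    lenient mode it is skipped with a warning.  All proteins must share one
    species tag.
    """
    species = {p.species_id for p in proteins}
    if len(species) > 1:
        raise ValueError(f"proteins span multiple species: {sorted(species)}")
    species_id = species.pop() if species else ""
    known_ids = {p.protein_id for p in proteins}
    dbds: dict[str, list[str]] = {}
    for ann in annotations:
        if ann.protein_id not in known_ids:
            msg = (f"annotation references unknown protein "
                   f"{ann.protein_id!r} (species {species_id})")
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
            continue
        if ann.domain_accession in catalog:
            dbds.setdefault(ann.protein_id, [])
            if ann.domain_accession not in dbds[ann.protein_id]:
                dbds[ann.protein_id].append(ann.domain_accession)
    return TFSet(
        species_id=species_id,
        members=frozenset(dbds),
        dbd_accessions={pid: tuple(sorted(accs)) for pid, accs in dbds.items()},
    )


@dataclass(frozen=True)
class ValidationReport:
    """Counts and PPV of a predicted TF set against a curated known set."""

    n_known: int
    n_predicted: int
    tp: int
    fp: int
    fn: int
    ppv: float | None  # percentage, 2 decimals half-up; None when undefined

    def __post_init__(self) -> None:
        assert self.tp + self.fp == self.n_predicted
        assert self.tp + self.fn == self.n_known


def validate_against_known(predicted: Iterable[str],
                           known: Iterable[str]) -> ValidationReport:
    """Compare a predicted TF id set with a known set.

    tp = |predicted ∩ known|, fp = |predicted \\ known|, fn = |known \\ predicted|;
    PPV = 100 * tp / (tp + fp) as a percentage rounded half-up to 2 decimals.
    An empty predicted set leaves PPV undefined (None) with a warning.
    """
    pred = set(predicted)
    kn = set(known)
    tp = len(pred & kn)
    fp = len(pred - kn)
    fn = len(kn - pred)
    if pred:
        ppv = float((Decimal(100 * tp) / Decimal(tp + fp))
                    .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    else:
        logger.warning("empty predicted set: PPV undefined")
        ppv = None
    return ValidationReport(n_known=len(kn), n_predicted=len(pred),
                            tp=tp, fp=fp, fn=fn, ppv=ppv)
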