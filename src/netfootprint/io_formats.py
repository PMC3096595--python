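"""Readers and writers for the external formats the pipeline touches.

Dialects: FASTA (Biopython), InterProScan 5 TSV (column layout configurable —
the tool's TSV changed across versions), a one-accession-per-line DBD catalog,
the Inparanoid "sqltable" ortholog dialect, and TSV/SIF edge lists with
provenance columns.  All text I/O is UTF-8; edge-list output is sorted for
reproducible diffs, and write/read of an edge list round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .orthology import Interaction, InteractionNetwork, OrthologGroup, OrthologMap
from .types import DBDCatalog, DomainAnnotation, ProteinRecord, SourceEdge, VALID_RESIDUES

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species_id: str) -> list[ProteinRecord]:
    """Read a protein FASTA; every record is tagged with ``species_id``.

    Raises ParseError naming the offending line for illegal residues or
    duplicate ids.  An empty file yields an empty list.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ParseError(
                f"{path}: line {_find_bad_residue_line(path, bad)}: "
                f"illegal residue(s) {sorted(bad)} in record {rec.id!r}"
            )
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(
            protein_id=rec.id, species_id=species_id,
            sequence=seq, description=rec.description,
        ))
    return records


def _find_bad_residue_line(path: Path, bad: set[str]) -> int:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return 0


def write_fasta(records: Sequence[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if rec.sequence is None:
                raise ValueError(f"protein {rec.protein_id} has no sequence")
            header = rec.protein_id
            if rec.description and rec.description != rec.protein_id:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# InterProScan TSV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterProScanDialect:
    """0-based column positions; defaults map to the InterProScan 5 TSV."""

    protein_col: int = 0
    analysis_col: int = 3
    accession_col: int = 4
    name_col: int = 5
    start_col: int = 6
    end_col: int = 7
    score_col: int = 8
    analysis_filter: str | None = "Pfam"


def read_interproscan_tsv(
    path: str | Path,
    dialect: InterProScanDialect = InterProScanDialect(),
) -> list[DomainAnnotation]:
    """Parse domain annotations; only rows matching the analysis filter are kept.

    Rows with end < start raise ParseError citing the row number.  Returns an
    empty list (with a warning) when no row survives the filter.
    """
    path = Path(path)
    annotations: list[DomainAnnotation] = []
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_rows += 1
            cols = line.split("\t")
            needed = max(dialect.protein_col, dialect.analysis_col,
                         dialect.accession_col, dialect.start_col,
                         dialect.end_col)
            if len(cols) <= needed:
                raise ParseError(
                    f"{path}: row {lineno}: expected >= {needed + 1} columns, "
                    f"got {len(cols)}"
                )
            if (dialect.analysis_filter is not None
                    and cols[dialect.analysis_col] != dialect.analysis_filter):
                continue
            try:
                start = int(cols[dialect.start_col])
                end = int(cols[dialect.end_col])
            except ValueError as exc:
                raise ParseError(f"{path}: row {lineno}: bad coordinate: {exc}")
            if end < start or start < 1:
                raise ParseError(
                    f"{path}: row {lineno}: invalid coordinates {start}..{end}"
                )
            score: float | None = None
            if dialect.score_col < len(cols):
                raw = cols[dialect.score_col].strip()
                if raw and raw != "-":
                    try:
                        score = float(raw)
                    except ValueError:
                        score = None
            name = (cols[dialect.name_col]
                    if dialect.name_col < len(cols) else "")
            annotations.append(DomainAnnotation(
                protein_id=cols[dialect.protein_col],
                domain_accession=cols[dialect.accession_col],
                start=start, end=end, domain_name=name, score=score,
            ))
    if n_rows and not annotations:
        logger.warning("%s: no rows retained under analysis filter %r",
                       path, dialect.analysis_filter)
    return annotations


def write_interproscan_tsv(annotations: Sequence[DomainAnnotation],
                           path: str | Path, analysis: str = "Pfam") -> None:
    """Emit annotations in the InterProScan 5 column layout (md5/length blank)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            score = f"{ann.score:.6g}" if ann.score is not None else "-"
            fh.write("\t".join([
                ann.protein_id, "-", "-", analysis, ann.domain_accession,
                ann.domain_name, str(ann.start), str(ann.end), score,
            ]) + "\n")


# ---------------------------------------------------------------------------
# DBD catalog
# ---------------------------------------------------------------------------

def read_dbd_catalog(path: str | Path) -> DBDCatalog:
    """One accession per line; '#' comments and blank lines ignored."""
    accessions: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                accessions.add(line)
    if not accessions:
        raise ParseError(f"{path}: DBD catalog is empty")
    logger.info("%s: read %d DBD accessions", path, len(accessions))
    return DBDCatalog(frozenset(accessions))


def write_dbd_catalog(catalog: DBDCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(catalog.accessions):
            fh.write(acc + "\n")


# ---------------------------------------------------------------------------
# Inparanoid sqltable
# ---------------------------------------------------------------------------

def read_inparanoid_sqltable(path: str | Path) -> OrthologMap:
    """Parse the Inparanoid sqltable dialect into an OrthologMap.

    Rows are (group_id, bitscore, species_id, confidence, protein_id); each
    group must span exactly two species and confidences lie in [0, 1].
    """
    path = Path(path)
    rows_by_group: dict[str, list[tuple[str, float, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"{path}: row {lineno}: expected 5 columns")
            group_id, _bitscore, species_id, conf_s, protein_id = cols[:5]
            try:
                conf = float(conf_s)
            except ValueError:
                raise ParseError(f"{path}: row {lineno}: bad confidence {conf_s!r}")
            if not (0.0 <= conf <= 1.0):
                raise ParseError(
                    f"{path}: row {lineno}: confidence {conf} outside [0, 1]"
                )
            rows_by_group.setdefault(group_id, []).append(
                (species_id, conf, protein_id))
    omap: OrthologMap | None = None
    for group_id in sorted(rows_by_group):
        rows = rows_by_group[group_id]
        species = sorted({sp for sp, _, _ in rows})
        if len(species) != 2:
            raise ParseError(
                f"{path}: group {group_id} spans {len(species)} species "
                f"({', '.join(species)}); expected exactly 2"
            )
        sx, sy = species
        if omap is None:
            omap = OrthologMap(sx, sy)
        group = OrthologGroup(
            group_id=group_id, species_x=sx, species_y=sy,
            members_x=tuple((pid, conf) for sp, conf, pid in rows if sp == sx),
            members_y=tuple((pid, conf) for sp, conf, pid in rows if sp == sy),
        )
        omap.add_group(group)
    if omap is None:
        raise ParseError(f"{path}: empty ortholog table")
    return omap


def write_inparanoid_sqltable(omap: OrthologMap, path: str | Path,
                              bitscore: float = 100.0) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(omap.groups, key=lambda g: _group_sort_key(g.group_id)):
            for pid, conf in g.members_x:
                fh.write(f"{g.group_id}\t{bitscore:.6g}\t{g.species_x}\t{conf:.6g}\t{pid}\n")
            for pid, conf in g.members_y:
                fh.write(f"{g.group_id}\t{bitscore:.6g}\t{g.species_y}\t{conf:.6g}\t{pid}\n")


def _group_sort_key(group_id: str) -> tuple:
    return (0, int(group_id)) if group_id.isdigit() else (1, group_id)


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

EDGE_TSV_HEADER = ["protein_a", "protein_b", "species",
                   "provenance", "source_edge_ids", "evidence"]


def read_source_edges(path: str | Path, species_id: str | None = None,
                      evidence: str = "") -> list[SourceEdge]:
    """Read a raw TSV edge list of experimentally observed interactions.

    Columns: protein_a, protein_b[, species_id[, evidence]].  Duplicate
    unordered rows collapse with a logged count; edge ids are assigned
    deterministically as ``species:a--b``.
    """
    path = Path(path)
    edges: dict[tuple[str, str, str], SourceEdge] = {}
    n_dups = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_a\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}: row {lineno}: expected >= 2 columns")
            a, b = cols[0].strip(), cols[1].strip()
            if not a or not b:
                raise ParseError(f"{path}: row {lineno}: blank endpoint id")
            sp = cols[2].strip() if len(cols) > 2 and cols[2].strip() else species_id
            if sp is None:
                raise ParseError(
                    f"{path}: row {lineno}: no species column and no "
                    "species_id supplied"
                )
            ev = cols[3].strip() if len(cols) > 3 else evidence
            a, b = (a, b) if a <= b else (b, a)
            key = (a, b, sp)
            if key in edges:
                n_dups += 1
                continue
            edges[key] = SourceEdge(edge_id=f"{sp}:{a}--{b}", a=a, b=b,
                                    species_id=sp, evidence=ev)
    if n_dups:
        logger.info("%s: collapsed %d duplicate unordered edge rows", path, n_dups)
    return [edges[k] for k in sorted(edges)]


def write_edge_list(network: InteractionNetwork, path: str | Path,
                    format: str = "tsv", relation: str = "tf_tf") -> None:
    """Write a network as TSV (with provenance columns) or SIF.

    Output is deterministically ordered by the sorted endpoint pair;
    self-loops are written with identical endpoints.
    """
    path = Path(path)
    edges = network.edges  # already sorted by canonical pair
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(EDGE_TSV_HEADER) + "\n")
            for e in edges:
                fh.write("\t".join([
                    e.a, e.b, e.species_id, e.provenance,
                    ",".join(e.source_edge_ids), e.evidence,
                ]) + "\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in edges:
                fh.write(f"{e.a} {relation} {e.b}\n")
    else:
        raise ValueError(f"unknown edge-list format {format!r}")


def read_edge_list(path: str | Path,
                   species_id: str | None = None) -> InteractionNetwork:
    """Read back a TSV edge list written by :func:`write_edge_list`.

    ``species_id`` is only needed for a header-only (empty) file, where the
    species cannot be recovered from the rows.
    """
    path = Path(path)
    net: InteractionNetwork | None = None
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EDGE_TSV_HEADER:
            raise ParseError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(EDGE_TSV_HEADER):
                raise ParseError(f"{path}: row {lineno}: bad column count")
            a, b, sp, prov, ids, ev = cols
            if net is None:
                net = InteractionNetwork(sp)
            net.add(Interaction(
                a, b, sp, provenance=prov,
                source_edge_ids=tuple(i for i in ids.split(",") if i),
                evidence=ev,
            ))
    if net is None:
        if species_id is None:
            raise ParseError(f"{path}: edge list has no rows and no "
                             "species_id was supplied")
        net = InteractionNetwork(species_id)
    return net
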