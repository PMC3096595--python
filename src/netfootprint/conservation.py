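"""Cross-species alignment of interaction networks.

Because every inferred interlog carries the id of the source interaction it
derives from, network alignment is exact: an *interaction class* is one
source edge together with its interlog sets in every analyzed species.  A
class present in all species is a conserved interaction; a class whose
presence pattern is a proper non-empty subset is a Taxonomically Restricted
Interaction (TRI) — the interaction-level analogue of taxonomically
restricted genes.  Several interlogs for one class in one species indicate a
lineage-specific network expansion via gene duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .orthology import InteractionNetwork, OrthologMap
from .tf_repertoire import TFSet
from .types import SourceEdge

logger = logging.getLogger(__name__)

CAUSE_ORTHOLOG_LOSS = "ortholog_loss"
CAUSE_DBD_LOSS = "dbd_loss"
CAUSE_UNKNOWN = "unknown"


@dataclass
class InteractionClass:
    """One source interaction plus its interlogs in every species."""

    class_id: str                       # = source edge id
    source_edge: SourceEdge
    interlogs: dict[str, frozenset[tuple[str, str]]]  # species -> unordered pairs

    @property
    def presence_pattern(self) -> frozenset[str]:
        present = {sp for sp, pairs in self.interlogs.items() if pairs}
        present.add(self.source_edge.species_id)
        return frozenset(present)

    @property
    def multiplicity(self) -> dict[str, int]:
        mult = {sp: len(pairs) for sp, pairs in self.interlogs.items()}
        src = self.source_edge.species_id
        if mult.get(src, 0) == 0:
            mult[src] = 1  # the source edge itself
        return mult


def build_interaction_classes(
    source_edges: Sequence[SourceEdge],
    inferred_networks: Mapping[str, InteractionNetwork],
) -> list[InteractionClass]:
    """Group inferred edges by originating source edge.

    Every inferred edge must name known source edges in its provenance;
    an unknown ``source_edge_id`` raises.  The source species' own edge is
    recorded in its class, so the source species is always present.
    """
    by_id = {e.edge_id: e for e in source_edges}
    classes: dict[str, dict[str, set[tuple[str, str]]]] = {
        eid: {} for eid in by_id
    }
    for sp, net in inferred_networks.items():
        for e in net.edges:
            if not e.source_edge_ids:
                raise ValueError(
                    f"inferred edge {e.endpoints} in {sp} lacks provenance")
            for eid in e.source_edge_ids:
                if eid not in by_id:
                    raise ValueError(
                        f"inferred edge {e.endpoints} in {sp} cites unknown "
                        f"source edge {eid!r}")
                classes[eid].setdefault(sp, set()).add(e.endpoints)
    out = []
    for eid in sorted(by_id):
        src = by_id[eid]
        interlogs = {sp: frozenset(pairs)
                     for sp, pairs in classes[eid].items()}
        interlogs.setdefault(src.species_id, frozenset())
        interlogs[src.species_id] = interlogs[src.species_id] | {src.endpoints}
        out.append(InteractionClass(class_id=eid, source_edge=src,
                                    interlogs=interlogs))
    return out


def conserved_classes(
    classes: Sequence[InteractionClass],
    required_species: Sequence[str],
) -> list[InteractionClass]:
    """Classes whose presence pattern covers ``required_species``."""
    req = frozenset(required_species)
    return [c for c in classes if req <= c.presence_pattern]


@dataclass(frozen=True)
class TRIRecord:
    """A taxonomically restricted interaction and, when resolvable, its cause.

    ``causes`` maps each missing species to ortholog_loss (no ortholog of an
    endpoint exists there), dbd_loss (orthologs exist but none kept a
    catalog DBD) or unknown.  ``cause`` summarizes: the shared value when all
    missing species agree, else ``unknown``.
    """

    class_id: str
    presence_pattern: frozenset[str]
    restricted_to: frozenset[str]
    causes: tuple[tuple[str, str], ...] = ()  # (missing species, cause)

    def __post_init__(self) -> None:
        if not self.restricted_to:
            raise ValueError("TRI pattern must be non-empty")

    @property
    def cause(self) -> str:
        vals = {c for _, c in self.causes}
        return vals.pop() if len(vals) == 1 else CAUSE_UNKNOWN


def _diagnose_missing(
    cls: InteractionClass,
    missing_sp: str,
    ortholog_maps: Mapping[tuple[str, str], OrthologMap] | None,
    tf_sets: Mapping[str, TFSet] | None,
) -> str:
    if ortholog_maps is None:
        return CAUSE_UNKNOWN
    src_sp = cls.source_edge.species_id
    omap = ortholog_maps.get((src_sp, missing_sp))
    if omap is None:
        omap = ortholog_maps.get((missing_sp, src_sp))
    if omap is None:
        return CAUSE_UNKNOWN
    orth_sets = [omap.lookup(p) for p in {cls.source_edge.a, cls.source_edge.b}]
    if any(not o for o in orth_sets):
        return CAUSE_ORTHOLOG_LOSS
    if tf_sets is not None and missing_sp in tf_sets:
        tf = tf_sets[missing_sp]
        if any(all(p not in tf for p in o) for o in orth_sets):
            return CAUSE_DBD_LOSS
    return CAUSE_UNKNOWN


def detect_tris(
    classes: Sequence[InteractionClass],
    species: Sequence[str],
    ortholog_maps: Mapping[tuple[str, str], OrthologMap] | None = None,
    tf_sets: Mapping[str, TFSet] | None = None,
) -> list[TRIRecord]:
    """Find classes restricted to a proper non-empty subset of ``species``.

    A class present only in its source species is a TRI with |pattern| = 1.
    When ortholog maps and TF sets are supplied, each missing species is
    diagnosed as ortholog_loss or dbd_loss where the data allow.
    """
    allsp = frozenset(species)
    if len(allsp) < 2:
        raise ValueError("TRI detection needs >= 2 analyzed species")
    records = []
    for cls in classes:
        pattern = cls.presence_pattern & allsp
        if pattern == allsp or not pattern:
            continue
        causes = tuple(
            (sp, _diagnose_missing(cls, sp, ortholog_maps, tf_sets))
            for sp in sorted(allsp - pattern)
        )
        records.append(TRIRecord(class_id=cls.class_id,
                                 presence_pattern=pattern,
                                 restricted_to=pattern, causes=causes))
    return records


@dataclass(frozen=True)
class ConservedSubnetwork:
    """A connected conserved module, projected into every species."""

    component_id: int
    reference_species: str
    class_ids: frozenset[str]
    edges_by_species: Mapping[str, frozenset[tuple[str, str]]]
    ortholog_links: tuple[tuple[str, str, str, str], ...] = ()
    # (species_a, protein_a, species_b, protein_b) for adjacent species pairs


def conserved_subnetworks(
    conserved: Sequence[InteractionClass],
    reference_species: str,
    species_order: Sequence[str] | None = None,
    ortholog_maps: Mapping[tuple[str, str], OrthologMap] | None = None,
) -> list[ConservedSubnetwork]:
    """Connected components of the reference-species graph of conserved classes.

    Each component is reported with every species' corresponding interlog
    edges and, when ortholog maps and a display order are given, the
    orthology links between adjacent species restricted to component nodes.
    """
    g = nx.Graph()
    cls_by_edge: dict[tuple[str, str], list[InteractionClass]] = {}
    for cls in conserved:
        for pair in cls.interlogs.get(reference_species, ()):  # ref edges
            g.add_edge(*pair)
            cls_by_edge.setdefault(pair, []).append(cls)
    out: list[ConservedSubnetwork] = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for comp_id, comp in enumerate(components, start=1):
        comp_classes: list[InteractionClass] = []
        for pair, clss in cls_by_edge.items():
            if pair[0] in comp:
                comp_classes.extend(clss)
        seen: set[str] = set()
        uniq = [c for c in comp_classes
                if not (c.class_id in seen or seen.add(c.class_id))]
        edges_by_sp: dict[str, frozenset[tuple[str, str]]] = {}
        for cls in uniq:
            for sp, pairs in cls.interlogs.items():
                edges_by_sp[sp] = edges_by_sp.get(sp, frozenset()) | pairs
        links: list[tuple[str, str, str, str]] = []
        if species_order and ortholog_maps:
            nodes_by_sp = {
                sp: {p for pair in pairs for p in pair}
                for sp, pairs in edges_by_sp.items()
            }
            for sa, sb in zip(species_order, species_order[1:]):
                omap = ortholog_maps.get((sa, sb))
                if omap is None:
                    omap = ortholog_maps.get((sb, sa))
                if omap is None:
                    continue
                for pa in sorted(nodes_by_sp.get(sa, ())):
                    for pb in sorted(omap.lookup(pa)):
                        if pb in nodes_by_sp.get(sb, set()):
                            links.append((sa, pa, sb, pb))
        out.append(ConservedSubnetwork(
            component_id=comp_id,
            reference_species=reference_species,
            class_ids=frozenset(c.class_id for c in uniq),
            edges_by_species={sp: frozenset(p) for sp, p in edges_by_sp.items()},
            ortholog_links=tuple(links),
        ))
    return out


def detect_expansions(classes: Sequence[InteractionClass],
                      threshold: int = 2) -> pd.DataFrame:
    """Lineage-specific network expansions: multiplicity >= threshold.

    Returns a table (class_id, species, multiplicity) sorted by multiplicity
    descending (ties: class_id, species).
    """
    if threshold < 2:
        raise ValueError("expansion threshold must be >= 2")
    rows = []
    for cls in classes:
        for sp, mult in sorted(cls.multiplicity.items()):
            if mult >= threshold:
                rows.append({"class_id": cls.class_id, "species": sp,
                             "multiplicity": mult})
    df = pd.DataFrame(rows, columns=["class_id", "species", "multiplicity"])
    if len(df):
        df = df.sort_values(["multiplicity", "class_id", "species"],
                            ascending=[False, True, True],
                            ignore_index=True)
    return df
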