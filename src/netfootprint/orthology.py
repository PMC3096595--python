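"""Ortholog groups and interolog (interlog) inference.

The central computation: an experimentally observed TF-TF interaction (A, B)
in an assayed species is transferred to species *i* by taking all orthologs
A_i1..A_iP of A and B_i1..B_iQ of B and regarding every pair (A_ip, B_iq) as
an inferred interaction — an *interlog*.  One-to-many and many-to-many
ortholog relations (inparalogs from post-speciation duplication) therefore
expand a single source edge into several interlogs ("network expansion").
Candidates in which an endpoint is not a catalog-positive TF are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import SourceEdge, canonical_pair

logger = logging.getLogger(__name__)

PROVENANCE_SOURCE = "source"
PROVENANCE_INFERRED = "inferred"


@dataclass(frozen=True)
class OrthologGroup:
    """One Inparanoid-style group: seed orthologs plus same-species inparalogs.

    Members are (protein_id, confidence) pairs for exactly the two species of
    ``species_pair``; in the Inparanoid dialect the seed of each side carries
    confidence 1.0.
    """

    group_id: str
    species_x: str
    species_y: str
    members_x: tuple[tuple[str, float], ...]
    members_y: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.members_x or not self.members_y:
            raise ValueError(f"group {self.group_id}: both sides must be non-empty")
        for pid, conf in (*self.members_x, *self.members_y):
            if not (0.0 <= conf <= 1.0):
                raise ValueError(
                    f"group {self.group_id}: confidence {conf} for {pid} "
                    "outside [0, 1]"
                )

    @property
    def seed_x(self) -> str:
        return max(self.members_x, key=lambda m: (m[1], m[0]))[0]

    @property
    def seed_y(self) -> str:
        return max(self.members_y, key=lambda m: (m[1], m[0]))[0]

    @property
    def ids_x(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.members_x)

    @property
    def ids_y(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.members_y)


class OrthologMap:
    """All ortholog groups for one species pair, with protein-level lookup.

    ``lookup(protein)`` returns the set of partner-species co-orthologs, i.e.
    the union over groups containing the protein.  The relation is symmetric:
    a in lookup(b) iff b in lookup(a).
    """

    def __init__(self, species_x: str, species_y: str,
                 groups: Iterable[OrthologGroup] = ()) -> None:
        self.species_x = species_x
        self.species_y = species_y
        self.groups: list[OrthologGroup] = []
        self._partners: dict[str, set[str]] = defaultdict(set)
        self._species_of: dict[str, str] = {}
        for g in groups:
            self.add_group(g)

    def add_group(self, group: OrthologGroup) -> None:
        if {group.species_x, group.species_y} != {self.species_x, self.species_y}:
            raise ValueError(
                f"group {group.group_id} spans ({group.species_x}, {group.species_y}), "
                f"map covers ({self.species_x}, {self.species_y})"
            )
        self.groups.append(group)
        for pid, _ in group.members_x:
            self._species_of[pid] = group.species_x
            for qid, _ in group.members_y:
                self._partners[pid].add(qid)
                self._partners[qid].add(pid)
        for qid, _ in group.members_y:
            self._species_of[qid] = group.species_y

    def lookup(self, protein_id: str) -> frozenset[str]:
        """Co-orthologs of ``protein_id`` in the partner species (may be empty)."""
        return frozenset(self._partners.get(protein_id, ()))

    def species_of(self, protein_id: str) -> str | None:
        return self._species_of.get(protein_id)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def species_pair(self) -> tuple[str, str]:
        return (self.species_x, self.species_y)


@dataclass(frozen=True)
class Interaction:
    """An unordered TF-TF edge in one species, with provenance.

    ``a == b`` encodes a homodimer loop.  ``source_edge_ids`` lists every
    source interaction this edge derives from (merged on collision).
    """

    a: str
    b: str
    species_id: str
    provenance: str = PROVENANCE_SOURCE
    source_edge_ids: tuple[str, ...] = ()
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.a or not self.b:
            raise ValueError("interaction endpoints must be non-empty")
        if self.a > self.b:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)
        if self.provenance not in (PROVENANCE_SOURCE, PROVENANCE_INFERRED):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def endpoints(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def is_self_loop(self) -> bool:
        return self.a == self.b


class InteractionNetwork:
    """Per-species set of unordered interactions; duplicates merge on add.

    When the same unordered pair arrives both as a source edge and as an
    inferred interlog, the stored edge keeps provenance=source with the
    inferred origins appended to its ``source_edge_ids``.
    """

    def __init__(self, species_id: str,
                 edges: Iterable[Interaction] = ()) -> None:
        self.species_id = species_id
        self._edges: dict[tuple[str, str], Interaction] = {}
        self.isolated_nodes: set[str] = set()
        for e in edges:
            self.add(e)

    def add(self, interaction: Interaction) -> None:
        if interaction.species_id != self.species_id:
            raise ValueError(
                f"edge species {interaction.species_id!r} != network species "
                f"{self.species_id!r}"
            )
        key = interaction.endpoints
        old = self._edges.get(key)
        if old is None:
            self._edges[key] = interaction
            return
        ids = tuple(dict.fromkeys(old.source_edge_ids + interaction.source_edge_ids))
        prov = PROVENANCE_SOURCE if PROVENANCE_SOURCE in (
            old.provenance, interaction.provenance) else PROVENANCE_INFERRED
        evidence = old.evidence or interaction.evidence
        self._edges[key] = Interaction(
            key[0], key[1], self.species_id,
            provenance=prov, source_edge_ids=ids, evidence=evidence,
        )

    @property
    def edges(self) -> tuple[Interaction, ...]:
        return tuple(self._edges[k] for k in sorted(self._edges))

    @property
    def nodes(self) -> frozenset[str]:
        nodes = set(self.isolated_nodes)
        for a, b in self._edges:
            nodes.add(a)
            nodes.add(b)
        return frozenset(nodes)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._edges

    def get(self, a: str, b: str) -> Interaction | None:
        return self._edges.get(canonical_pair(a, b))

    def edge_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (self.species_id == other.species_id
                and set(self.edges) == set(other.edges))


# ---------------------------------------------------------------------------
# Bidirectional-best-hit ortholog calling (Inparanoid-style, simplified)
# ---------------------------------------------------------------------------

def infer_orthologs_bbh(
    scores: Mapping[tuple[str, str], float],
    proteins_x: Sequence[str],
    proteins_y: Sequence[str],
    species_x: str,
    species_y: str,
) -> OrthologMap:
    """Call ortholog groups from a similarity-score matrix.

    Seeds are mutual best hits between the two species; ties break
    lexicographically.  A same-species protein p joins a seed's group as an
    inparalog iff score(p, seed) >= the seed-seed score — the Inparanoid
    inparalog rule, which captures post-speciation duplications.  Confidence
    follows Inparanoid's interpolation when self-scores are in the matrix,
    otherwise inparalogs get confidence 1.0.

    ``scores`` is symmetric in intent: (a, b) and (b, a) are treated alike;
    missing pairs score 0.
    """

    def s(a: str, b: str) -> float:
        v = scores.get((a, b))
        if v is None:
            v = scores.get((b, a), 0.0)
        return v

    def best_hit(p: str, candidates: Sequence[str]) -> str | None:
        scored = [(s(p, c), c) for c in candidates]
        scored = [(v, c) for v, c in scored if v > 0]
        if not scored:
            return None
        top = max(v for v, _ in scored)
        return min(c for v, c in scored if v == top)

    if not proteins_x or not proteins_y:
        return OrthologMap(species_x, species_y)

    proteins_x = sorted(set(proteins_x))
    proteins_y = sorted(set(proteins_y))

    seeds: list[tuple[str, str]] = []
    for x in proteins_x:
        y = best_hit(x, proteins_y)
        if y is not None and best_hit(y, proteins_x) == x:
            seeds.append((x, y))

    def inparalogs(seed: str, pool: Sequence[str], seed_score: float,
                   taken: set[str]) -> list[tuple[str, float]]:
        members = [(seed, 1.0)]
        self_score = s(seed, seed)
        for p in pool:
            if p == seed or p in taken:
                continue
            sp = s(p, seed)
            if sp >= seed_score:
                if self_score > seed_score:
                    conf = (sp - seed_score) / (self_score - seed_score)
                    conf = max(0.0, min(1.0, conf))
                else:
                    conf = 1.0
                members.append((p, conf))
        return members

    groups: list[OrthologGroup] = []
    taken_x: set[str] = {x for x, _ in seeds}
    taken_y: set[str] = {y for _, y in seeds}
    for i, (x, y) in enumerate(sorted(seeds), start=1):
        ss = s(x, y)
        mx = inparalogs(x, proteins_x, ss, taken_x - {x})
        my = inparalogs(y, proteins_y, ss, taken_y - {y})
        taken_x.update(p for p, _ in mx)
        taken_y.update(p for p, _ in my)
        groups.append(OrthologGroup(
            group_id=str(i), species_x=species_x, species_y=species_y,
            members_x=tuple(mx), members_y=tuple(my),
        ))
    return OrthologMap(species_x, species_y, groups)


# ---------------------------------------------------------------------------
# Interlog inference
# ---------------------------------------------------------------------------

def _homodimer_pairs(orthologs: frozenset[str], mode: str) -> set[tuple[str, str]]:
    """Expand a homodimeric source (A, A) into target-species pairs.

    full: every unordered pair of co-orthologs, diagonal included — the
    literal "all possible pairs" reading.  diagonal: each co-ortholog pairs
    only with itself (a set of homodimers).
    """
    ids = sorted(orthologs)
    if mode == "full":
        return {(ids[i], ids[j]) for i in range(len(ids)) for j in range(i, len(ids))}
    if mode == "diagonal":
        return {(p, p) for p in ids}
    raise ValueError(f"unknown homodimer_mode {mode!r}")


def infer_interlogs(
    source_edges: Sequence[SourceEdge],
    ortholog_maps: Mapping[tuple[str, str], OrthologMap],
    tf_sets: Mapping[str, "TFSet"],
    target_species: Sequence[str],
    homodimer_mode: str = "full",
    dbd_filter: str = "both",
) -> dict[str, InteractionNetwork]:
    """Transfer source edges into every target species via ortholog cross-products.

    For source edge (A, B) of species s and target species i != s the
    candidate set is {(a, b) : a in orth_i(A), b in orth_i(B)}, canonicalized
    and de-duplicated; a candidate is kept iff its endpoints pass the DBD
    filter (``both``: both endpoints are TFs of species i; ``either``: at
    least one).  Homodimer sources expand per ``homodimer_mode``.  Transfer is
    direct only — no chaining through intermediate species.

    ``ortholog_maps`` is keyed by (source_species, target_species) in either
    order.  A missing map for a needed pair raises KeyError naming the pair.
    """
    if dbd_filter not in ("both", "either"):
        raise ValueError(f"unknown dbd_filter {dbd_filter!r}")

    def get_map(s: str, i: str) -> OrthologMap:
        m = ortholog_maps.get((s, i))
        if m is None:  # an empty map is a valid (falsy) object: test for None
            m = ortholog_maps.get((i, s))
        if m is None:
            raise KeyError(f"no ortholog map for species pair ({s}, {i})")
        return m

    networks = {sp: InteractionNetwork(sp) for sp in target_species}
    for edge in source_edges:
        for sp in target_species:
            if sp == edge.species_id:
                continue
            omap = get_map(edge.species_id, sp)
            if edge.is_homodimer:
                orth = omap.lookup(edge.a)
                candidates = _homodimer_pairs(orth, homodimer_mode)
            else:
                orth_a = omap.lookup(edge.a)
                orth_b = omap.lookup(edge.b)
                candidates = {canonical_pair(a, b)
                              for a in orth_a for b in orth_b}
            tf = tf_sets[sp].members if sp in tf_sets else frozenset()
            for a, b in sorted(candidates):
                if dbd_filter == "both":
                    ok = a in tf and b in tf
                else:
                    ok = a in tf or b in tf
                if not ok:
                    continue
                networks[sp].add(Interaction(
                    a, b, sp, provenance=PROVENANCE_INFERRED,
                    source_edge_ids=(edge.edge_id,),
                ))
    return networks


def source_networks(source_edges: Sequence[SourceEdge]) -> dict[str, InteractionNetwork]:
    """Group source edges into per-species networks with source provenance."""
    nets: dict[str, InteractionNetwork] = {}
    for e in source_edges:
        net = nets.setdefault(e.species_id, InteractionNetwork(e.species_id))
        net.add(Interaction(e.a, e.b, e.species_id,
                            provenance=PROVENANCE_SOURCE,
                            source_edge_ids=(e.edge_id,),
                            evidence=e.evidence))
    return nets


def merge_networks(
    source_nets: Mapping[str, InteractionNetwork],
    inferred_nets: Mapping[str, InteractionNetwork],
) -> tuple[dict[str, InteractionNetwork], pd.DataFrame]:
    """Union source and inferred edges per species and tabulate counts.

    Returns the merged per-species networks and a count table with rows =
    species and columns = (source, inferred, total); the total is the size of
    the union of unordered edges, so an edge that is both sourced and
    inferred counts once (and keeps provenance=source).
    """
    all_species = sorted(set(source_nets) | set(inferred_nets))
    merged: dict[str, InteractionNetwork] = {}
    rows = []
    for sp in all_species:
        net = InteractionNetwork(sp)
        n_source = 0
        n_inferred = 0
        if sp in source_nets:
            for e in source_nets[sp].edges:
                net.add(e)
            n_source = len(source_nets[sp])
        if sp in inferred_nets:
            for e in inferred_nets[sp].edges:
                net.add(e)
            n_inferred = len(inferred_nets[sp])
        merged[sp] = net
        rows.append({"species": sp, "source": n_source,
                     "inferred": n_inferred, "total": len(net)})
    counts = pd.DataFrame(rows).set_index("species")
    return merged, counts
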