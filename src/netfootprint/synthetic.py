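"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the data regime the analysis assumes: five species
related by a known tree; ancestral gene families expanded by post-speciation
duplication (pure inparalogs, the relation Inparanoid captures) and thinned
by lineage-specific loss; domain architectures in which a configurable
fraction of families carry a sequence-specific DNA-binding domain; a
scale-free source interaction network among the TFs of one or two "assayed"
species; and planted interaction losses (ortholog deletion or DBD stripping)
as ground truth for taxonomically restricted interactions.

Every expectation downstream code should reproduce — ortholog groups,
per-species interlog sets, presence patterns, TRIs with causes, expansion
multiplicities — is computed here by an independent brute-force application
of the cross-product rule and stored in :class:`GroundTruth`.

Protein sequences are random placeholders (length 100-1500): no stage after
TF classification reads sequence, only the domain annotations matter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io_formats
from .orthology import OrthologGroup, OrthologMap
from .types import DBDCatalog, DomainAnnotation, ProteinRecord, SourceEdge, canonical_pair

logger = logging.getLogger(__name__)

DEFAULT_SPECIES = ("HS", "MM", "SP", "DM", "AM")
#: ultrametric default topology: mammals, then sea urchin, fly, coral
DEFAULT_TREE = "((((HS:1,MM:1):1,SP:2):1,DM:3):1,AM:4);"
#: same topology with depth-doubling heights (1, 2, 4, 8): successive splits
#: are separated by a factor of two in path distance, the regime in which a
#: Brownian trait model cleanly identifies every level of the tree
PROFILE_TREE = "((((HS:1,MM:1):1,SP:2):2,DM:4):4,AM:8);"

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator; one seed drives all randomness."""

    species: tuple[str, ...] = DEFAULT_SPECIES
    species_tree: str = DEFAULT_TREE
    n_families: int = 1000
    duplication_rate: float = 0.2      # Poisson mean of extra copies per lineage
    loss_rate: float = 0.05            # per-lineage family loss probability
    dbd_fraction: float = 0.1          # probability a family carries a DBD
    n_source_edges: int = 500
    source_species: tuple[str, ...] = ("HS", "MM")
    attachment_exponent: float = 1.0
    homodimer_fraction: float = 0.03
    tri_loss_rate: float = 0.0         # probability a TF family gets a planted loss
    dbd_loss_fraction: float = 0.5     # planted losses that strip the DBD only
    homodimer_mode: str = "full"
    n_dbd_accessions: int = 147        # size of the synthetic DBD catalog
    n_aux_accessions: int = 60
    min_seq_len: int = 100
    max_seq_len: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "dbd_fraction", "homodimer_fraction",
                     "tri_loss_rate", "dbd_loss_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.duplication_rate < 0:
            raise ValueError("duplication_rate must be >= 0")
        if self.n_families < 0 or self.n_source_edges < 0:
            raise ValueError("counts must be >= 0")
        if not set(self.source_species) <= set(self.species):
            raise ValueError("source_species must be a subset of species")
        if self.homodimer_mode not in ("full", "diagonal"):
            raise ValueError(f"unknown homodimer_mode {self.homodimer_mode!r}")

    @property
    def dbd_pool(self) -> tuple[str, ...]:
        return tuple(f"PF9{i:04d}" for i in range(1, self.n_dbd_accessions + 1))

    @property
    def aux_pool(self) -> tuple[str, ...]:
        return tuple(f"PF8{i:04d}" for i in range(1, self.n_aux_accessions + 1))


@dataclass
class Family:
    """One ancestral gene family and its per-lineage descendants."""

    fam_id: int
    is_tf: bool
    dbd_accession: str | None
    aux_accessions: tuple[str, ...]
    members: dict[str, list[str]]       # species -> protein ids (may be empty)
    dbd_lost_in: set[str] = field(default_factory=set)  # planted DBD stripping

    def tf_members(self, species_id: str) -> list[str]:
        """Members that still qualify as TFs in this species."""
        if not self.is_tf or species_id in self.dbd_lost_in:
            return []
        return self.members.get(species_id, [])


@dataclass(frozen=True)
class PlantedLoss:
    fam_id: int
    species_id: str
    cause: str  # ortholog_loss | dbd_loss


@dataclass
class GroundTruth:
    """Brute-force expectations for every downstream stage."""

    true_ortholog_groups: dict[int, dict[str, list[str]]]
    true_interlogs: dict[str, dict[str, list[tuple[str, str]]]]
    presence_patterns: dict[str, frozenset[str]]
    planted_tris: set[tuple[str, str, str]]      # (edge_id, missing species, cause)
    tri_patterns: dict[str, frozenset[str]]      # edge_id -> pattern, TRIs only
    planted_expansions: set[tuple[str, str, int]]  # (edge_id, species, multiplicity)
    planted_losses: tuple[PlantedLoss, ...]

    def to_json(self) -> str:
        obj = {
            "true_ortholog_groups": {
                str(f): sp_map for f, sp_map in
                sorted(self.true_ortholog_groups.items())
            },
            "true_interlogs": {
                eid: {sp: [list(p) for p in pairs]
                      for sp, pairs in sorted(spmap.items())}
                for eid, spmap in sorted(self.true_interlogs.items())
            },
            "presence_patterns": {eid: sorted(p) for eid, p in
                                  sorted(self.presence_patterns.items())},
            "planted_tris": sorted(list(t) for t in self.planted_tris),
            "tri_patterns": {eid: sorted(p) for eid, p in
                             sorted(self.tri_patterns.items())},
            "planted_expansions": sorted(list(e) for e in self.planted_expansions),
            "planted_losses": [dataclasses.asdict(p) for p in self.planted_losses],
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            true_ortholog_groups={int(f): sp for f, sp in
                                  obj["true_ortholog_groups"].items()},
            true_interlogs={
                eid: {sp: [tuple(p) for p in pairs]
                      for sp, pairs in spmap.items()}
                for eid, spmap in obj["true_interlogs"].items()
            },
            presence_patterns={eid: frozenset(p) for eid, p in
                               obj["presence_patterns"].items()},
            planted_tris={tuple(t) for t in obj["planted_tris"]},
            tri_patterns={eid: frozenset(p) for eid, p in
                          obj["tri_patterns"].items()},
            planted_expansions={(e[0], e[1], int(e[2]))
                                for e in obj["planted_expansions"]},
            planted_losses=tuple(PlantedLoss(**p)
                                 for p in obj["planted_losses"]),
        )


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------

def simulate_gene_families(config: SimulationConfig,
                           rng: np.random.Generator) -> list[Family]:
    """Draw families: per-lineage survival, 1 + Poisson(duplication_rate) copies.

    Each family carries a DBD with probability dbd_fraction (accession drawn
    from a rank-weighted catalog pool so a few DBD types dominate, as in real
    repertoires) plus 0-2 auxiliary non-DBD domains.
    """
    dbd_pool = config.dbd_pool
    ranks = np.arange(1, len(dbd_pool) + 1, dtype=float)
    dbd_weights = (1.0 / ranks) / (1.0 / ranks).sum()
    families: list[Family] = []
    for fam_id in range(config.n_families):
        is_tf = bool(rng.random() < config.dbd_fraction)
        dbd = str(rng.choice(np.array(dbd_pool), p=dbd_weights)) if is_tf else None
        n_aux = int(rng.integers(0, 3))
        aux = tuple(sorted(
            str(a) for a in rng.choice(np.array(config.aux_pool),
                                       size=n_aux, replace=False)
        )) if n_aux else ()
        members: dict[str, list[str]] = {}
        for sp in config.species:
            if rng.random() < config.loss_rate:
                members[sp] = []
                continue
            n_copies = 1 + int(rng.poisson(config.duplication_rate))
            members[sp] = [f"{sp}_F{fam_id:05d}_{k}" for k in range(n_copies)]
        families.append(Family(fam_id=fam_id, is_tf=is_tf, dbd_accession=dbd,
                               aux_accessions=aux, members=members))
    return families


def plant_losses(families: Sequence[Family], config: SimulationConfig,
                 rng: np.random.Generator) -> list[PlantedLoss]:
    """Knock out a TF family's ortholog (or only its DBD) in one lineage.

    Losses are planted only in non-assayed lineages, keeping the source
    species present in every affected interaction class by construction.
    Families are mutated in place; the planted events are returned.
    """
    non_source = [sp for sp in config.species
                  if sp not in config.source_species]
    planted: list[PlantedLoss] = []
    if config.tri_loss_rate == 0 or not non_source:
        return planted
    for fam in families:
        if not fam.is_tf:
            continue
        if rng.random() >= config.tri_loss_rate:
            continue
        sp = non_source[int(rng.integers(len(non_source)))]
        if not fam.members.get(sp):
            continue  # already absent through background loss
        if rng.random() < config.dbd_loss_fraction:
            fam.dbd_lost_in.add(sp)
            planted.append(PlantedLoss(fam.fam_id, sp, "dbd_loss"))
        else:
            fam.members[sp] = []
            planted.append(PlantedLoss(fam.fam_id, sp, "ortholog_loss"))
    return planted


def simulate_source_network(families: Sequence[Family],
                            config: SimulationConfig,
                            rng: np.random.Generator) -> list[SourceEdge]:
    """Scale-free TF-TF edges within each assayed species.

    Nodes (DBD-bearing proteins) enter the network one at a time and attach
    to existing nodes with probability proportional to
    degree ** attachment_exponent (growth-based preferential attachment; at
    exponent 1 this is the Barabasi-Albert regime with a power-law degree
    tail).  Once all nodes have entered, any remaining edge budget is spent
    on internal edges whose endpoints are both degree-weighted.  A
    configurable fraction of edges are homodimer self-loops.  Duplicate
    unordered edges are resampled.
    """
    if config.n_source_edges == 0:
        return []
    eligible: dict[str, list[str]] = {}
    for sp in config.source_species:
        pool: list[str] = []
        for fam in families:
            pool.extend(fam.tf_members(sp))
        if len(pool) < 10:
            raise ValueError(
                f"source species {sp} has only {len(pool)} DBD-bearing "
                "proteins; need >= 10"
            )
        eligible[sp] = sorted(pool)

    # split edges across assayed species proportional to TF counts
    sizes = np.array([len(eligible[sp]) for sp in config.source_species], float)
    quota = np.floor(config.n_source_edges * sizes / sizes.sum()).astype(int)
    for i in range(config.n_source_edges - quota.sum()):
        quota[i % len(quota)] += 1

    edges: list[SourceEdge] = []
    for sp, n_edges in zip(config.source_species, quota):
        pool = list(rng.permutation(eligible[sp]))
        degree = np.zeros(len(pool), dtype=float)
        seen: set[tuple[int, int]] = set()
        made = 0

        def weights(active: int) -> np.ndarray:
            w = (degree[:active] + 1e-12) ** config.attachment_exponent
            if w.sum() <= 0:
                w = np.ones(active)
            return w / w.sum()

        def add_edge(i: int, j: int) -> bool:
            nonlocal made
            key = (i, j) if i <= j else (j, i)
            if key in seen:
                return False
            seen.add(key)
            degree[i] += 1
            degree[j] += 1 if j != i else 1  # loop counts once for weighting
            pair = canonical_pair(pool[i], pool[j])
            edges.append(SourceEdge(
                edge_id=f"{sp}:{pair[0]}--{pair[1]}",
                a=pair[0], b=pair[1], species_id=sp,
                evidence="synthetic_assay"))
            made += 1
            return True

        # seed: connect the first two nodes
        if n_edges > 0 and len(pool) >= 2:
            add_edge(0, 1)
        active = 2
        m = max(1, int(round(n_edges / max(1, len(pool)))))
        while made < n_edges and active < len(pool):
            i = active
            targets = min(m, n_edges - made)
            for _ in range(targets):
                if rng.random() < config.homodimer_fraction:
                    add_edge(i, i)
                    continue
                for _attempt in range(20):
                    j = int(rng.choice(active, p=weights(active)))
                    if add_edge(i, j):
                        break
            active += 1
        attempts = 0
        while made < n_edges and attempts < 200 * n_edges:
            attempts += 1
            w = weights(active)
            i = int(rng.choice(active, p=w))
            if rng.random() < config.homodimer_fraction:
                add_edge(i, i)
                continue
            j = int(rng.choice(active, p=w))
            if j != i:
                add_edge(i, j)
        if made < n_edges:
            logger.warning("%s: only %d/%d unique edges generated",
                           sp, made, n_edges)
    return sorted(edges, key=lambda e: e.edge_id)


def _brute_force_interlogs(edge: SourceEdge, fam_a: Family, fam_b: Family,
                           species_id: str,
                           homodimer_mode: str) -> list[tuple[str, str]]:
    """The cross-product rule applied directly to family ground truth."""
    mem_a = fam_a.tf_members(species_id)
    mem_b = fam_b.tf_members(species_id)
    if edge.is_homodimer:
        if homodimer_mode == "diagonal":
            pairs = {(p, p) for p in mem_a}
        else:
            pairs = {canonical_pair(p, q) for p in mem_a for q in mem_a}
    else:
        pairs = {canonical_pair(p, q) for p in mem_a for q in mem_b}
    return sorted(pairs)


def build_ground_truth(families: Sequence[Family],
                       source_edges: Sequence[SourceEdge],
                       planted: Sequence[PlantedLoss],
                       config: SimulationConfig) -> GroundTruth:
    """Recompute every downstream expectation by brute force."""
    fam_by_id = {f.fam_id: f for f in families}
    fam_of: dict[str, int] = {}
    for f in families:
        for sp, pids in f.members.items():
            for pid in pids:
                fam_of[pid] = f.fam_id

    true_groups = {
        f.fam_id: {sp: list(f.members.get(sp, [])) for sp in config.species}
        for f in families
    }

    true_interlogs: dict[str, dict[str, list[tuple[str, str]]]] = {}
    patterns: dict[str, frozenset[str]] = {}
    tris: set[tuple[str, str, str]] = set()
    tri_patterns: dict[str, frozenset[str]] = {}
    expansions: set[tuple[str, str, int]] = set()
    for edge in source_edges:
        fam_a = fam_by_id[fam_of[edge.a]]
        fam_b = fam_by_id[fam_of[edge.b]]
        per_sp: dict[str, list[tuple[str, str]]] = {}
        present = {edge.species_id}
        for sp in config.species:
            if sp == edge.species_id:
                continue
            pairs = _brute_force_interlogs(edge, fam_a, fam_b, sp,
                                           config.homodimer_mode)
            per_sp[sp] = pairs
            if pairs:
                present.add(sp)
                if len(pairs) >= 2:
                    expansions.add((edge.edge_id, sp, len(pairs)))
        true_interlogs[edge.edge_id] = per_sp
        pattern = frozenset(present)
        patterns[edge.edge_id] = pattern
        if pattern != frozenset(config.species):
            tri_patterns[edge.edge_id] = pattern
            for sp in sorted(set(config.species) - pattern):
                if not fam_a.members.get(sp) or not fam_b.members.get(sp):
                    cause = "ortholog_loss"
                elif not fam_a.tf_members(sp) or not fam_b.tf_members(sp):
                    cause = "dbd_loss"
                else:  # pragma: no cover - cannot happen by construction
                    cause = "unknown"
                tris.add((edge.edge_id, sp, cause))
    return GroundTruth(
        true_ortholog_groups=true_groups,
        true_interlogs=true_interlogs,
        presence_patterns=patterns,
        planted_tris=tris,
        tri_patterns=tri_patterns,
        planted_expansions=expansions,
        planted_losses=tuple(planted),
    )


# ---------------------------------------------------------------------------
# Dataset assembly and emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimulationConfig
    families: list[Family]
    source_edges: list[SourceEdge]
    ground_truth: GroundTruth
    sequences: dict[str, str]  # protein id -> placeholder sequence

    def proteins_by_species(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {sp: [] for sp in self.config.species}
        for fam in self.families:
            for sp in self.config.species:
                for pid in fam.members.get(sp, []):
                    out[sp].append(ProteinRecord(
                        protein_id=pid, species_id=sp,
                        sequence=self.sequences[pid]))
        for sp in out:
            out[sp].sort(key=lambda r: r.protein_id)
        return out

    def annotations_by_species(self) -> dict[str, list[DomainAnnotation]]:
        out: dict[str, list[DomainAnnotation]] = {sp: [] for sp in self.config.species}
        for fam in self.families:
            for sp in self.config.species:
                for pid in fam.members.get(sp, []):
                    pos = 10
                    if fam.is_tf and sp not in fam.dbd_lost_in:
                        out[sp].append(DomainAnnotation(
                            protein_id=pid, domain_accession=fam.dbd_accession,
                            start=pos, end=pos + 59,
                            domain_name="synthetic_dbd", score=1e-20))
                        pos += 70
                    for acc in fam.aux_accessions:
                        out[sp].append(DomainAnnotation(
                            protein_id=pid, domain_accession=acc,
                            start=pos, end=pos + 49,
                            domain_name="synthetic_aux", score=1e-10))
                        pos += 60
        for sp in out:
            out[sp].sort(key=lambda a: (a.protein_id, a.start))
        return out

    def catalog(self) -> DBDCatalog:
        return DBDCatalog(frozenset(self.config.dbd_pool))

    def ortholog_maps(self) -> dict[tuple[str, str], OrthologMap]:
        """Pairwise Inparanoid-style maps listing each family as one group."""
        maps: dict[tuple[str, str], OrthologMap] = {}
        species = self.config.species
        for i, sa in enumerate(species):
            for sb in species[i + 1:]:
                omap = OrthologMap(sa, sb)
                gid = 0
                for fam in self.families:
                    ma = fam.members.get(sa, [])
                    mb = fam.members.get(sb, [])
                    if not ma or not mb:
                        continue
                    gid += 1
                    conf = lambda k: 1.0 if k == 0 else 0.8
                    omap.add_group(OrthologGroup(
                        group_id=str(gid), species_x=sa, species_y=sb,
                        members_x=tuple((p, conf(k)) for k, p in enumerate(ma)),
                        members_y=tuple((p, conf(k)) for k, p in enumerate(mb)),
                    ))
                maps[(sa, sb)] = omap
        return maps


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages under one seeded stream."""
    rng = np.random.default_rng(config.seed)
    families = simulate_gene_families(config, rng)
    planted = plant_losses(families, config, rng)
    edges = simulate_source_network(families, config, rng)
    truth = build_ground_truth(families, edges, planted, config)
    sequences: dict[str, str] = {}
    for fam in families:
        for sp in config.species:
            for pid in fam.members.get(sp, []):
                length = int(rng.integers(config.min_seq_len,
                                          config.max_seq_len + 1))
                seq = "M" + "".join(
                    rng.choice(AMINO_ACIDS, size=length - 1))
                sequences[pid] = seq
    return SyntheticDataset(config=config, families=families,
                            source_edges=edges, ground_truth=truth,
                            sequences=sequences)


def emit_dataset(directory: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Write the full dataset to disk; same seed => byte-identical files.

    Emits per-species FASTA and InterProScan-style TSV, the DBD catalog,
    pairwise Inparanoid sqltables, the source-edge TSV, the ground-truth JSON
    and the generating config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config)
    paths: dict[str, Path] = {}

    proteins = ds.proteins_by_species()
    annotations = ds.annotations_by_species()
    for sp in config.species:
        p = directory / f"{sp}.fasta"
        io_formats.write_fasta(proteins[sp], p)
        paths[f"fasta:{sp}"] = p
        p = directory / f"{sp}.domains.tsv"
        io_formats.write_interproscan_tsv(annotations[sp], p)
        paths[f"domains:{sp}"] = p

    p = directory / "dbd_catalog.txt"
    io_formats.write_dbd_catalog(ds.catalog(), p)
    paths["dbd_catalog"] = p

    for (sa, sb), omap in sorted(ds.ortholog_maps().items()):
        p = directory / f"inparanoid.{sa}-{sb}.sqltable"
        io_formats.write_inparanoid_sqltable(omap, p)
        paths[f"orthologs:{sa}-{sb}"] = p

    p = directory / "source_edges.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tspecies\tevidence\n")
        for e in ds.source_edges:
            fh.write(f"{e.a}\t{e.b}\t{e.species_id}\t{e.evidence}\n")
    paths["source_edges"] = p

    p = directory / "ground_truth.json"
    p.write_text(ds.ground_truth.to_json(), encoding="utf-8")
    paths["ground_truth"] = p

    p = directory / "config.json"
    p.write_text(json.dumps(dataclasses.asdict(config), indent=1,
                            sort_keys=True), encoding="utf-8")
    paths["config"] = p
    return paths


# ---------------------------------------------------------------------------
# Profiles evolved on a known tree (for domain-tree recovery tests)
# ---------------------------------------------------------------------------

def simulate_profiles_from_tree(
    newick: str = PROFILE_TREE,
    n_domains: int = 150,
    n_tfs: int = 1000,
    sigma: float = 0.03,
    seed: int = 0,
):
    """Evolve domain-composition profiles along a known tree.

    Arcsine-transformed domain proportions evolve by Brownian motion with
    per-unit-branch standard deviation ``sigma``; leaves are converted back
    to integer TF counts out of ``n_tfs``.  Returns (profiles, newick) where
    the profiles' transformed Euclidean distances approximate the tree's
    path distances — the regime in which UPGMA/NJ should recover the
    generating topology.
    """
    from io import StringIO
    from skbio import TreeNode

    from .domain_phylogeny import DomainCompositionProfile

    tree = TreeNode.read(StringIO(newick))
    rng = np.random.default_rng(seed)
    root_theta = rng.uniform(0.3, 1.2, size=n_domains)
    leaf_theta: dict[str, np.ndarray] = {}

    def walk(node, theta):
        for child in node.children:
            bl = child.length if child.length is not None else 1.0
            child_theta = theta + rng.normal(0.0, sigma * np.sqrt(bl),
                                             size=n_domains)
            child_theta = np.clip(child_theta, 0.05, np.pi / 2 - 0.05)
            if child.is_tip():
                leaf_theta[child.name] = child_theta
            else:
                walk(child, child_theta)

    walk(tree, root_theta)
    profiles = []
    for sp in sorted(leaf_theta):
        p = np.sin(leaf_theta[sp]) ** 2
        counts = np.maximum(1, np.rint(p * n_tfs)).astype(int)
        counts = np.minimum(counts, n_tfs)
        profiles.append(DomainCompositionProfile(
            species_id=sp,
            counts={f"PF7{d:04d}": int(c) for d, c in enumerate(counts, 1)},
            n_tfs=n_tfs,
        ))
    return profiles, newick
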