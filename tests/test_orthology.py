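"""Ortholog calling and interlog inference: oracle equivalence and laws."""

import numpy as np
import pytest

from netfootprint.orthology import (Interaction, InteractionNetwork,
                                    OrthologGroup, OrthologMap,
                                    infer_interlogs, infer_orthologs_bbh,
                                    merge_networks, source_networks)
from netfootprint.tf_repertoire import TFSet
from netfootprint.types import SourceEdge, canonical_pair


def make_map(sx, sy, groups):
    """groups: list of (members_x ids, members_y ids)."""
    omap = OrthologMap(sx, sy)
    for i, (mx, my) in enumerate(groups, 1):
        omap.add_group(OrthologGroup(
            group_id=str(i), species_x=sx, species_y=sy,
            members_x=tuple((p, 1.0) for p in mx),
            members_y=tuple((p, 1.0) for p in my)))
    return omap


def make_tfset(sp, ids):
    return TFSet(species_id=sp, members=frozenset(ids),
                 dbd_accessions={i: ("PF00046",) for i in ids})


# ---------------------------------------------------------------------------
# BBH ortholog caller
# ---------------------------------------------------------------------------

def test_bbh_unique_mutual_best_pair():
    scores = {("x1", "y1"): 100.0, ("x1", "y2"): 50.0, ("x2", "y1"): 40.0}
    omap = infer_orthologs_bbh(scores, ["x1", "x2"], ["y1", "y2"], "X", "Y")
    assert omap.lookup("x1") == {"y1"}
    assert omap.lookup("x2") == frozenset()


def test_bbh_inparalog_joins_when_closer_than_seed():
    scores = {("x1", "y1"): 100.0, ("x2", "x1"): 120.0, ("x2", "y1"): 30.0}
    omap = infer_orthologs_bbh(scores, ["x1", "x2"], ["y1"], "X", "Y")
    assert omap.lookup("y1") == {"x1", "x2"}


def test_bbh_below_seed_score_stays_out():
    scores = {("x1", "y1"): 100.0, ("x2", "x1"): 80.0}
    omap = infer_orthologs_bbh(scores, ["x1", "x2"], ["y1"], "X", "Y")
    assert omap.lookup("y1") == {"x1"}


def test_bbh_empty_matrix():
    assert len(infer_orthologs_bbh({}, [], [], "X", "Y")) == 0


def test_bbh_recovers_generator_families(zero_loss_dataset):
    """Scores dominated by within-family similarity recover the true groups."""
    ds = zero_loss_dataset
    rng = np.random.default_rng(0)
    sa, sb = "HS", "AM"
    fams = [f for f in ds.families if f.members.get(sa) and f.members.get(sb)][:40]
    px = [p for f in fams for p in f.members[sa]]
    py = [p for f in fams for p in f.members[sb]]
    scores = {}
    for f in fams:
        # within-species family members score above the cross-species seed
        # pair, the regime in which the inparalog rule gathers them all
        for side in (f.members[sa], f.members[sb]):
            for i, p in enumerate(side):
                for q in side[i:]:
                    scores[(p, q)] = 300.0 + rng.random()
        for p in f.members[sa]:
            for q in f.members[sb]:
                scores[(p, q)] = 200.0 + rng.random()
    omap = infer_orthologs_bbh(scores, px, py, sa, sb)
    for f in fams:
        expect = set(f.members[sb])
        for p in f.members[sa]:
            assert omap.lookup(p) == expect


# ---------------------------------------------------------------------------
# interlog inference: worked examples
# ---------------------------------------------------------------------------

TF_ALL = {
    "HS": make_tfset("HS", ["A", "B"]),
    "AM": make_tfset("AM", ["a1", "a2", "b1"]),
}
EDGE_AB = SourceEdge("e1", "A", "B", "HS")


def test_cross_product_expansion_2x1():
    maps = {("HS", "AM"): make_map("HS", "AM", [(["A"], ["a1", "a2"]),
                                                (["B"], ["b1"])])}
    nets = infer_interlogs([EDGE_AB], maps, TF_ALL, ["HS", "AM"])
    assert nets["AM"].edge_pairs() == {("a1", "b1"), ("a2", "b1")}


def test_no_ortholog_means_no_interlog():
    maps = {("HS", "AM"): make_map("HS", "AM", [(["A"], ["a1", "a2"])])}
    nets = infer_interlogs([EDGE_AB], maps, TF_ALL, ["HS", "AM"])
    assert len(nets["AM"]) == 0


def test_dbd_filter_drops_non_tf_endpoint():
    maps = {("HS", "AM"): make_map("HS", "AM", [(["A"], ["a1", "a2"]),
                                                (["B"], ["b1"])])}
    tf = {"HS": TF_ALL["HS"], "AM": make_tfset("AM", ["a1", "b1"])}  # a2 lost DBD
    nets = infer_interlogs([EDGE_AB], maps, tf, ["HS", "AM"])
    assert nets["AM"].edge_pairs() == {("a1", "b1")}
    either = infer_interlogs([EDGE_AB], maps, tf, ["HS", "AM"],
                             dbd_filter="either")
    assert either["AM"].edge_pairs() == {("a1", "b1"), ("a2", "b1")}


@pytest.mark.parametrize("mode,expected", [
    ("full", {("a1", "a1"), ("a1", "a2"), ("a2", "a2")}),
    ("diagonal", {("a1", "a1"), ("a2", "a2")}),
])
def test_homodimer_modes(mode, expected):
    """Both readings of homodimer expansion, checked against enumeration."""
    edge = SourceEdge("e1", "A", "A", "HS")
    maps = {("HS", "AM"): make_map("HS", "AM", [(["A"], ["a1", "a2"])])}
    nets = infer_interlogs([edge], maps, TF_ALL, ["HS", "AM"],
                           homodimer_mode=mode)
    assert nets["AM"].edge_pairs() == expected
    # oracle: enumerate unordered pairs directly
    orth = ["a1", "a2"]
    if mode == "full":
        oracle = {canonical_pair(x, y) for x in orth for y in orth}
    else:
        oracle = {(x, x) for x in orth}
    assert nets["AM"].edge_pairs() == oracle


def test_missing_map_names_the_pair():
    with pytest.raises(KeyError, match=r"\(HS, AM\)"):
        infer_interlogs([EDGE_AB], {}, TF_ALL, ["HS", "AM"])


# ---------------------------------------------------------------------------
# randomized equivalence with a from-scratch oracle
# ---------------------------------------------------------------------------

def random_instance(rng):
    """A small random source species + two targets with random family structure."""
    species = ["S", "T", "U"]
    n_fam = int(rng.integers(2, 7))
    members = {}  # (fam, sp) -> ids
    for f in range(n_fam):
        for sp in species:
            k = int(rng.integers(0, 5))  # 0..4 members
            members[(f, sp)] = [f"{sp}{f}_{i}" for i in range(k)]
    maps = {}
    for tgt in ("T", "U"):
        groups = [(members[(f, "S")], members[(f, tgt)]) for f in range(n_fam)
                  if members[(f, "S")] and members[(f, tgt)]]
        maps[("S", tgt)] = make_map("S", tgt, groups)
    tf_sets = {}
    for sp in species:
        ids = [p for f in range(n_fam) for p in members[(f, sp)]]
        keep = [p for p in ids if rng.random() < 0.8]
        tf_sets[sp] = make_tfset(sp, keep) if keep else make_tfset(sp, [])
    s_prots = [p for f in range(n_fam) for p in members[(f, "S")]]
    edges = []
    n_edges = int(rng.integers(1, 21))
    for i in range(n_edges):
        if not s_prots:
            break
        a = s_prots[int(rng.integers(len(s_prots)))]
        b = a if rng.random() < 0.15 else s_prots[int(rng.integers(len(s_prots)))]
        edges.append(SourceEdge(f"e{i}", a, b, "S"))
    return members, maps, tf_sets, edges, n_fam


def oracle_interlogs(members, tf_sets, edges, n_fam, tgt, mode, dbd_filter):
    """Exhaustive enumeration straight from the family table."""
    def fam_of(p):
        for f in range(n_fam):
            for sp in ("S", "T", "U"):
                if p in members[(f, sp)]:
                    return f
        raise AssertionError(p)

    result = {}
    tf = tf_sets[tgt].members
    for e in edges:
        pairs = set()
        orth_a = members[(fam_of(e.a), tgt)]
        orth_b = members[(fam_of(e.b), tgt)]
        if e.a == e.b:
            if mode == "diagonal":
                cands = [(x, x) for x in orth_a]
            else:
                cands = [(x, y) for x in orth_a for y in orth_a]
        else:
            cands = [(x, y) for x in orth_a for y in orth_b]
        for x, y in cands:
            if dbd_filter == "both" and not (x in tf and y in tf):
                continue
            if dbd_filter == "either" and not (x in tf or y in tf):
                continue
            pairs.add(canonical_pair(x, y))
        for p in pairs:
            result.setdefault(p, set()).add(e.edge_id)
    return result


@pytest.mark.parametrize("dbd_filter", ["both", "either"])
@pytest.mark.parametrize("mode", ["full", "diagonal"])
def test_interlogs_equal_brute_force_on_random_instances(mode, dbd_filter):
    rng = np.random.default_rng(12345)
    for trial in range(60):
        members, maps, tf_sets, edges, n_fam = random_instance(rng)
        nets = infer_interlogs(edges, maps, tf_sets, ["S", "T", "U"],
                               homodimer_mode=mode, dbd_filter=dbd_filter)
        for tgt in ("T", "U"):
            oracle = oracle_interlogs(members, tf_sets, edges, n_fam, tgt,
                                      mode, dbd_filter)
            got = {e.endpoints: set(e.source_edge_ids)
                   for e in nets[tgt].edges}
            assert got == oracle, f"trial {trial} target {tgt}"


def test_interlog_symmetry_under_endpoint_swap():
    """Results are invariant to the stored order of source-edge endpoints."""
    maps = {("HS", "AM"): make_map("HS", "AM", [(["A"], ["a1", "a2"]),
                                                (["B"], ["b1", "b2"])])}
    tf = {"HS": TF_ALL["HS"],
          "AM": make_tfset("AM", ["a1", "a2", "b1", "b2"])}
    e1 = SourceEdge("e", "A", "B", "HS")
    e2 = SourceEdge("e", "B", "A", "HS")  # canonicalized on construction
    n1 = infer_interlogs([e1], maps, tf, ["AM"])
    n2 = infer_interlogs([e2], maps, tf, ["AM"])
    assert n1["AM"] == n2["AM"]


def test_interlog_monotonicity_in_tf_set():
    """Removing a protein from a TFSet never increases any interlog count."""
    rng = np.random.default_rng(777)
    for _ in range(30):
        members, maps, tf_sets, edges, n_fam = random_instance(rng)
        nets = infer_interlogs(edges, maps, tf_sets, ["T", "U"])
        for sp in ("T", "U"):
            tf_members = sorted(tf_sets[sp].members)
            if not tf_members:
                continue
            drop = tf_members[int(rng.integers(len(tf_members)))]
            smaller = dict(tf_sets)
            remaining = [p for p in tf_members if p != drop]
            smaller[sp] = make_tfset(sp, remaining)
            nets2 = infer_interlogs(edges, maps, smaller, ["T", "U"])
            assert len(nets2[sp]) <= len(nets[sp])


def test_cardinality_law_on_zero_loss_synthetic(zero_loss_dataset,
                                                zero_loss_tf_sets):
    """|interlogs| = P x Q for distinct-family endpoints with no losses."""
    ds = zero_loss_dataset
    fam_of = {p: f.fam_id for f in ds.families
              for sp in ds.config.species for p in f.members.get(sp, [])}
    fams = {f.fam_id: f for f in ds.families}
    maps = ds.ortholog_maps()
    nets = infer_interlogs(ds.source_edges, maps, zero_loss_tf_sets,
                           ds.config.species)
    by_edge = {}
    for sp, net in nets.items():
        for e in net.edges:
            for eid in e.source_edge_ids:
                by_edge.setdefault((eid, sp), set()).add(e.endpoints)
    checked = 0
    for edge in ds.source_edges:
        fa, fb = fam_of[edge.a], fam_of[edge.b]
        if fa == fb:
            continue  # cross products within one family collapse pairs
        for sp in ds.config.species:
            if sp == edge.species_id:
                continue
            P = len(fams[fa].tf_members(sp))
            Q = len(fams[fb].tf_members(sp))
            got = len(by_edge.get((edge.edge_id, sp), ()))
            assert got == P * Q
            checked += 1
    assert checked > 100


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_union_keeps_source_provenance():
    src = InteractionNetwork("HS")
    src.add(Interaction("a", "b", "HS", provenance="source",
                        source_edge_ids=("e1",)))
    inf = InteractionNetwork("HS")
    inf.add(Interaction("a", "b", "HS", provenance="inferred",
                        source_edge_ids=("e9",)))
    inf.add(Interaction("a", "c", "HS", provenance="inferred",
                        source_edge_ids=("e9",)))
    merged, counts = merge_networks({"HS": src}, {"HS": inf})
    assert len(merged["HS"]) == 2
    ab = merged["HS"].get("a", "b")
    assert ab.provenance == "source"
    assert set(ab.source_edge_ids) == {"e1", "e9"}
    assert counts.loc["HS"].to_dict() == {"source": 1, "inferred": 2, "total": 2}


def test_merge_species_without_source_data():
    inf = InteractionNetwork("AM")
    inf.add(Interaction("x", "y", "AM", provenance="inferred",
                        source_edge_ids=("e1",)))
    merged, counts = merge_networks({}, {"AM": inf})
    assert counts.loc["AM", "total"] == counts.loc["AM", "inferred"] == 1


def test_merge_totals_match_ground_truth_on_zero_loss(zero_loss_dataset,
                                                      zero_loss_tf_sets):
    ds = zero_loss_dataset
    nets = infer_interlogs(ds.source_edges, ds.ortholog_maps(),
                           zero_loss_tf_sets, ds.config.species)
    merged, counts = merge_networks(source_networks(ds.source_edges), nets)
    for sp in ds.config.species:
        expected = {p for spmap in ds.ground_truth.true_interlogs.values()
                    for p in spmap.get(sp, [])}
        expected |= {e.endpoints for e in ds.source_edges
                     if e.species_id == sp}
        assert merged[sp].edge_pairs() == {tuple(p) for p in expected}
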