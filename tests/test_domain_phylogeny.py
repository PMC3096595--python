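"""Domain composition, arcsine transform, Fisher tests, distance trees."""

import math
from io import StringIO
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from skbio import TreeNode

from netfootprint.domain_phylogeny import (arcsine_transform,
                                           build_domain_tree,
                                           composition_profile,
                                           contingency_table,
                                           fisher_species_test,
                                           species_distance_matrix,
                                           top_k_domains, upgma_tree)
from netfootprint.synthetic import simulate_profiles_from_tree
from netfootprint.tf_repertoire import TFSet
from netfootprint.types import DomainAnnotation


def _tf_set(sp, ids):
    return TFSet(sp, frozenset(ids), {i: ("PF00046",) for i in ids})


def _ann(pid, acc):
    return DomainAnnotation(pid, acc, 1, 50)


# ---------------------------------------------------------------------------
# composition profiles
# ---------------------------------------------------------------------------

def test_profile_presence_semantics():
    tf = _tf_set("AM", ["t1", "t2"])
    anns = [_ann("t1", "PF00046"), _ann("t2", "PF00046"),
            _ann("t2", "PF00170"), _ann("t2", "PF00046")]  # duplicate hit
    prof = composition_profile(tf, anns)
    assert prof.counts == {"PF00046": 2, "PF00170": 1}
    assert prof.proportions == {"PF00046": 1.0, "PF00170": 0.5}


def test_profile_copy_count_mode():
    tf = _tf_set("AM", ["t1"])
    anns = [_ann("t1", "PF00046"), _ann("t1", "PF00046")]
    assert composition_profile(tf, anns).counts["PF00046"] == 1
    assert composition_profile(tf, anns,
                               copy_counts=True).counts["PF00046"] == 2


def test_profile_unannotated_tf_counts_toward_n_only():
    tf = _tf_set("AM", ["t1", "t2"])
    prof = composition_profile(tf, [_ann("t1", "PF00046")])
    assert prof.n_tfs == 2
    assert prof.counts == {"PF00046": 1}


def test_top_k_ordering_and_union():
    profs = [
        composition_profile(_tf_set("X", ["a", "b", "c"]),
                            [_ann("a", "P1"), _ann("b", "P1"),
                             _ann("c", "P2")]),
        composition_profile(_tf_set("Y", ["d"]),
                            [_ann("d", "P3"), _ann("d", "P4")]),
    ]
    per, union = top_k_domains(profs, 2)
    assert per["X"] == ["P1", "P2"]
    assert per["Y"] == ["P3", "P4"]  # tie at 1 broken lexicographically
    assert union == ["P1", "P2", "P3", "P4"]


def test_top_k_tie_break():
    prof = composition_profile(_tf_set("X", ["a", "b", "c"]),
                               [_ann("a", "B"), _ann("b", "B"),
                                _ann("a", "A"), _ann("c", "A")])
    per, _ = top_k_domains([prof], 1)
    assert per["X"] == ["A"]  # counts tie at 2; A < B


# ---------------------------------------------------------------------------
# arcsine transform
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,expected", [
    (0.0, 0.0),
    (1.0, math.pi / 2),
    (0.25, math.pi / 6),
])
def test_arcsine_closed_forms(p, expected):
    assert arcsine_transform(p) == pytest.approx(expected, abs=1e-12)


def test_arcsine_domain_error_and_monotone():
    with pytest.raises(ValueError):
        arcsine_transform(-0.1)
    with pytest.raises(ValueError):
        arcsine_transform(1.1)
    grid = np.linspace(0, 1, 101)
    vals = [arcsine_transform(p) for p in grid]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_arcsine_variance_stabilization():
    """Transformed binomial proportions have near-constant variance across p."""
    rng = np.random.default_rng(5)
    n = 100
    raw_vars, trans_vars = [], []
    for p in np.arange(0.1, 0.95, 0.1):
        draws = rng.binomial(n, p, size=4000) / n
        raw_vars.append(draws.var())
        trans_vars.append(np.arcsin(np.sqrt(draws)).var())
    assert max(raw_vars) / min(raw_vars) >= 2.0
    assert max(trans_vars) / min(trans_vars) < 1.6


# ---------------------------------------------------------------------------
# Fisher tests
# ---------------------------------------------------------------------------

def _exact_2x2_two_sided(m):
    """Enumeration oracle: sum hypergeometric probabilities <= observed."""
    (a, b), (c, d) = m
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize("table", [
    [[3, 1], [1, 3]],
    [[5, 0], [0, 5]],
    [[8, 2], [1, 5]],
    [[2, 7], [8, 2]],
])
def test_fisher_2x2_matches_enumeration(table):
    res = fisher_species_test(pd.DataFrame(table))
    assert res.p_value == pytest.approx(_exact_2x2_two_sided(table), rel=1e-9)


def test_fisher_2x2_worked_examples():
    assert fisher_species_test(pd.DataFrame([[3, 1], [1, 3]])).p_value == \
        pytest.approx(0.4857, abs=2e-4)
    assert fisher_species_test(pd.DataFrame([[5, 0], [0, 5]])).p_value == \
        pytest.approx(2 / 252, rel=1e-9)


def test_fisher_monte_carlo_identical_rows():
    m = pd.DataFrame([[5, 3, 2], [5, 3, 2], [5, 3, 2]])
    res = fisher_species_test(m, seed=1, n_draws=20000)
    assert res.method == "freeman_halton_mc"
    assert res.p_value > 0.99
    assert res.standard_error is not None


def test_fisher_monte_carlo_detects_structure():
    m = pd.DataFrame([[40, 0, 0], [0, 40, 0], [0, 0, 40]])
    res = fisher_species_test(m, seed=1, n_draws=20000)
    assert res.p_value < 0.001


def test_fisher_drops_zero_margins(caplog):
    m = pd.DataFrame([[3, 1, 0], [1, 3, 0]])
    with caplog.at_level("WARNING"):
        res = fisher_species_test(m)
    assert res.method == "fisher_exact_2x2"


def test_fisher_chi2_fallback():
    m = pd.DataFrame([[10, 5, 3], [2, 9, 8]])
    res = fisher_species_test(m, method="chi2")
    assert res.method == "chi2"
    assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_identical_profiles_zero():
    prof = composition_profile(_tf_set("X", ["a"]), [_ann("a", "P1")])
    prof2 = composition_profile(_tf_set("Y", ["b"]), [_ann("b", "P1")])
    d = species_distance_matrix([prof, prof2], ["P1"])
    assert d.loc["X", "Y"] == 0.0


def test_distance_single_coordinate_delta():
    p1 = composition_profile(_tf_set("X", ["a", "b"]),
                             [_ann("a", "P1"), _ann("b", "P1")])
    p2 = composition_profile(_tf_set("Y", ["c", "d"]),
                             [_ann("c", "P1")])
    d = species_distance_matrix([p1, p2], ["P1"])
    delta = arcsine_transform(1.0) - arcsine_transform(0.5)
    assert d.loc["X", "Y"] == pytest.approx(delta)


def test_distance_metric_properties():
    rng = np.random.default_rng(3)
    profs = []
    for i in range(4):
        counts = {f"P{j}": int(rng.integers(0, 21)) for j in range(6)}
        ids = [f"s{i}t{k}" for k in range(20)]
        anns = []
        k = 0
        for acc, c in counts.items():
            for _ in range(c):
                anns.append(_ann(ids[k % 20], acc))
                k += 1
        profs.append(composition_profile(_tf_set(f"S{i}", ids), anns))
    d = species_distance_matrix(profs, [f"P{j}" for j in range(6)])
    m = d.to_numpy()
    assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
    for i, j, k in combinations(range(4), 3):
        assert m[i, j] <= m[i, k] + m[k, j] + 1e-12


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _heights_and_clades(newick):
    tree = TreeNode.read(StringIO(newick))
    out = {}
    for node in tree.non_tips(include_self=True):
        leaves = frozenset(t.name for t in node.tips())
        # ultrametric height = distance to any descendant leaf
        h = 0.0
        n = node
        while n.children:
            n = n.children[0]
            h += n.length
        out[leaves] = h
    return out


def test_upgma_forced_topology():
    d = pd.DataFrame([[0, 2, 10], [2, 0, 10], [10, 10, 0]],
                     index=list("ABC"), columns=list("ABC"))
    nwk = build_domain_tree(d, "upgma")
    clades = _heights_and_clades(nwk)
    assert frozenset("AB") in clades
    assert clades[frozenset("AB")] == pytest.approx(1.0)
    assert clades[frozenset("ABC")] == pytest.approx(5.0)


def test_upgma_deterministic():
    rng = np.random.default_rng(8)
    m = rng.random((5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    d = pd.DataFrame(m, index=list("ABCDE"), columns=list("ABCDE"))
    assert build_domain_tree(d, "upgma") == build_domain_tree(d, "upgma")


def brute_force_upgma_heights(dist):
    """Oracle: agglomerate using plain average over original leaf pairs."""
    labels = list(dist.index)
    clusters = [frozenset([l]) for l in labels]
    heights = {}
    while len(clusters) > 1:
        best = None
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                avg = np.mean([dist.loc[x, y] for x in a for y in b])
                key = tuple(sorted([min(a), min(b)]))
                if best is None or (avg, key) < (best[0], best[3]):
                    best = (avg, a, b, key)
        avg, a, b, _ = best
        merged = a | b
        heights[merged] = avg / 2
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
    return heights


def test_upgma_heights_match_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(3, 7))
        m = rng.random((n, n)) * 10
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"T{i}" for i in range(n)]
        d = pd.DataFrame(m, index=labels, columns=labels)
        got = _heights_and_clades(upgma_tree(d))
        expected = brute_force_upgma_heights(d)
        assert set(got) == set(expected)
        for clade, h in expected.items():
            # newick branch lengths are written with 6 significant digits
            assert got[clade] == pytest.approx(h, rel=1e-4)


def test_nj_recovers_additive_tree():
    """NJ is consistent on additive distances from a known 4-taxon tree."""
    # tree ((A:1,B:2):1,(C:3,D:1):1) -> additive path distances
    d = pd.DataFrame(
        [[0, 3, 6, 4], [3, 0, 7, 5], [6, 7, 0, 4], [4, 5, 4, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float)
    nwk = build_domain_tree(d, "nj")
    tree = TreeNode.read(StringIO(nwk))
    true = TreeNode.read(StringIO("((A:1,B:2):1,(C:3,D:1):1);"))
    assert tree.compare_rfd(true) == 0


def test_degenerate_small_trees(caplog):
    d = pd.DataFrame([[0, 4], [4, 0]], index=["A", "B"], columns=["A", "B"])
    with caplog.at_level("WARNING"):
        nwk = build_domain_tree(d)
    assert nwk == "(A:2,B:2);"


def test_topology_recovery_from_perturbed_profiles():
    """Profiles evolved on a known tree yield that topology back (UPGMA & NJ)."""
    profiles, true_nwk = simulate_profiles_from_tree(seed=1)
    domains = sorted(profiles[0].counts)
    dist = species_distance_matrix(profiles, domains)
    true = TreeNode.read(StringIO(true_nwk))
    for method in ("upgma", "nj"):
        got = TreeNode.read(StringIO(build_domain_tree(dist, method)))
        assert got.compare_rfd(true) == 0
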