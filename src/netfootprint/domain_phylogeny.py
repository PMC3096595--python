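"""Domain-composition comparison of TF repertoires across species.

Each species' TF set is summarized by the fraction of TFs carrying each
protein-family domain (presence per TF, not copy number).  Proportions are
variance-stabilized with the arcsine-square-root transform asin(sqrt(p)), a
standard transform for binomial proportions; species are compared by a
Fisher contingency test over the top domains and clustered into a tree from
Euclidean distances between transformed profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .tf_repertoire import TFSet
from .types import DomainAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainCompositionProfile:
    """Per-species domain counts over TFs, with proportions and transforms."""

    species_id: str
    counts: Mapping[str, int]  # domain accession -> number of TFs carrying it
    n_tfs: int
    count_semantics: str = "presence"  # or "copies" (raw hit counts)

    def __post_init__(self) -> None:
        if self.n_tfs < 0:
            raise ValueError("n_tfs must be >= 0")
        for acc, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count {c} for {acc}")
            if self.count_semantics == "presence" and c > self.n_tfs:
                raise ValueError(f"count {c} for {acc} exceeds n_tfs")

    @property
    def proportions(self) -> dict[str, float]:
        # presence counts are per-TF fractions; copy counts are normalized by
        # total hits so the values stay valid binomial proportions
        denom = (self.n_tfs if self.count_semantics == "presence"
                 else max(1, sum(self.counts.values())))
        return {acc: c / denom for acc, c in self.counts.items()}

    @property
    def transformed(self) -> dict[str, float]:
        return {acc: arcsine_transform(p)
                for acc, p in self.proportions.items()}

    @property
    def n_domain_types(self) -> int:
        return len(self.counts)


def composition_profile(
    tf_set: TFSet,
    annotations: Sequence[DomainAnnotation],
    copy_counts: bool = False,
) -> DomainCompositionProfile:
    """Count domain types across a species' TFs.

    Default is presence semantics: a TF with k copies of a domain contributes
    1 to that domain's count.  ``copy_counts=True`` counts every hit instead.
    All domain types on TF members are counted (not only catalog DBDs); a TF
    without annotations contributes to n_tfs only.
    """
    if len(tf_set) == 0:
        raise ValueError("composition profile of an empty TF set")
    counts: dict[str, int] = {}
    if copy_counts:
        for ann in annotations:
            if ann.protein_id in tf_set:
                counts[ann.domain_accession] = counts.get(ann.domain_accession, 0) + 1
    else:
        per_tf: dict[str, set[str]] = {}
        for ann in annotations:
            if ann.protein_id in tf_set:
                per_tf.setdefault(ann.protein_id, set()).add(ann.domain_accession)
        for accs in per_tf.values():
            for acc in accs:
                counts[acc] = counts.get(acc, 0) + 1
    return DomainCompositionProfile(
        species_id=tf_set.species_id, counts=dict(sorted(counts.items())),
        n_tfs=len(tf_set),
        count_semantics="copies" if copy_counts else "presence",
    )


def top_k_domains(
    profiles: Sequence[DomainCompositionProfile], k: int,
) -> tuple[dict[str, list[str]], list[str]]:
    """Top-k domains per species (count desc, accession asc) and their union."""
    if k < 1:
        raise ValueError("k must be >= 1")
    per_species: dict[str, list[str]] = {}
    union: set[str] = set()
    for prof in profiles:
        ranked = sorted(prof.counts, key=lambda a: (-prof.counts[a], a))
        if len(ranked) < k:
            logger.info("%s has only %d domain types (< k=%d)",
                        prof.species_id, len(ranked), k)
        top = ranked[:k]
        per_species[prof.species_id] = top
        union.update(top)
    return per_species, sorted(union)


def arcsine_transform(p: float) -> float:
    """Variance-stabilizing transform for a binomial proportion: asin(sqrt(p))."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"proportion {p} outside [0, 1]")
    return math.asin(math.sqrt(p))


def contingency_table(
    profiles: Sequence[DomainCompositionProfile],
    domains: Sequence[str],
) -> pd.DataFrame:
    """TF-count table: rows = species, columns = domains (absent => 0)."""
    rows = {p.species_id: [int(p.counts.get(d, 0)) for d in domains]
            for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(domains))


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    statistic: float | None
    method: str
    standard_error: float | None = None


def fisher_species_test(
    table: pd.DataFrame,
    method: str = "monte_carlo",
    n_draws: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Test association between species and domain composition.

    2x2 tables use the exact two-sided Fisher test.  Larger tables use the
    Freeman-Halton generalization estimated by Monte Carlo: tables with the
    observed margins are sampled (Patefield algorithm) and the p-value is the
    fraction at most as probable as the observed table under the multivariate
    hypergeometric law (add-one correction; standard error reported).
    ``method='chi2'`` falls back to the chi-square test of independence.
    Zero-margin rows/columns are dropped with a warning.
    """
    m = table.to_numpy(dtype=np.int64)
    keep_r = m.sum(axis=1) > 0
    keep_c = m.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping %d zero-margin rows and %d columns",
                       int((~keep_r).sum()), int((~keep_c).sum()))
        m = m[keep_r][:, keep_c]
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a table of at least 2x2 after margin pruning")

    if m.shape == (2, 2):
        stat, p = stats.fisher_exact(m, alternative="two-sided")
        return FisherResult(p_value=float(p), statistic=float(stat),
                            method="fisher_exact_2x2")
    if method == "chi2":
        res = stats.chi2_contingency(m)
        return FisherResult(p_value=float(res.pvalue),
                            statistic=float(res.statistic), method="chi2")
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")

    logp_obs = _log_table_probability(m)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(m.sum(axis=1), m.sum(axis=0))
    draws = sampler.rvs(n_draws, random_state=rng)
    logps = np.array([_log_table_probability(t.astype(np.int64)) for t in draws])
    hits = int(np.sum(logps <= logp_obs + 1e-9))
    p = (hits + 1) / (n_draws + 1)
    se = math.sqrt(p * (1 - p) / n_draws)
    return FisherResult(p_value=p, statistic=None,
                        method="freeman_halton_mc", standard_error=se)


def _log_table_probability(m: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given its margins."""
    r = m.sum(axis=1)
    c = m.sum(axis=0)
    n = m.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(m + 1).sum())


def species_distance_matrix(
    profiles: Sequence[DomainCompositionProfile],
    domains: Sequence[str],
) -> pd.DataFrame:
    """Euclidean distances between arcsine-transformed proportion vectors.

    Vectors are built over the shared ``domains`` list; a domain absent from
    a species contributes asin(sqrt(0)) = 0.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    species = [p.species_id for p in profiles]
    vecs = np.array([
        [arcsine_transform(p.counts.get(d, 0) / p.n_tfs) for d in domains]
        for p in profiles
    ])
    diff = vecs[:, None, :] - vecs[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(dist, index=species, columns=species)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class _Cluster:
    name: str            # lexicographically smallest leaf, for tie-breaks
    leaves: frozenset[str]
    height: float
    newick: str


def upgma_tree(dist: pd.DataFrame) -> str:
    """UPGMA (average-linkage) tree as a Newick string with branch lengths.

    Deterministic: the merged pair with minimal average distance is chosen,
    ties broken by the lexicographic pair of cluster names; children are
    ordered lexicographically in the output.  Heights are cluster-average
    distances / 2, so the result is ultrametric.
    """
    labels = list(dist.index)
    clusters: dict[str, _Cluster] = {
        l: _Cluster(name=l, leaves=frozenset([l]), height=0.0, newick=l)
        for l in labels
    }
    # average distances between current clusters
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            key = (a, b) if a < b else (b, a)
            d[key] = float(dist.loc[a, b])

    while len(clusters) > 1:
        (a, b), dmin = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ca, cb = clusters.pop(a), clusters.pop(b)
        height = dmin / 2.0
        first, second = sorted((ca, cb), key=lambda c: c.name)
        newick = (f"({first.newick}:{height - first.height:.6g},"
                  f"{second.newick}:{height - second.height:.6g})")
        merged = _Cluster(name=min(ca.name, cb.name),
                          leaves=ca.leaves | cb.leaves,
                          height=height, newick=newick)
        # average linkage update, size-weighted
        na, nb = len(ca.leaves), len(cb.leaves)
        new_d: dict[tuple[str, str], float] = {}
        for (x, y), v in d.items():
            if a in (x, y) or b in (x, y):
                continue
            new_d[(x, y)] = v
        for other in clusters:
            key_a = (a, other) if a < other else (other, a)
            key_b = (b, other) if b < other else (other, b)
            v = (na * d[key_a] + nb * d[key_b]) / (na + nb)
            key = (merged.name, other) if merged.name < other else (other, merged.name)
            new_d[key] = v
        d = new_d
        clusters[merged.name] = merged
    root = next(iter(clusters.values()))
    return root.newick + ";"


def nj_tree(dist: pd.DataFrame) -> str:
    """Neighbor-joining tree (scikit-bio) as a Newick string."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    labels = sorted(dist.index)
    dm = DistanceMatrix(dist.loc[labels, labels].to_numpy(dtype=float), labels)
    tree = nj(dm)
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def build_domain_tree(dist: pd.DataFrame, method: str = "upgma") -> str:
    """Cluster species from a domain-composition distance matrix.

    ``method`` is ``upgma`` (ultrametric average linkage, the default) or
    ``nj`` (neighbor joining).  Fewer than 3 taxa yield a degenerate tree
    with a warning.
    """
    if not np.allclose(dist.to_numpy(), dist.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist.to_numpy()) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if len(dist) < 3:
        logger.warning("fewer than 3 taxa: degenerate tree")
        if len(dist) == 1:
            return f"{dist.index[0]};"
        a, b = sorted(dist.index)
        h = float(dist.loc[a, b]) / 2
        return f"({a}:{h:.6g},{b}:{h:.6g});"
    if method == "upgma":
        return upgma_tree(dist)
    if method == "nj":
        return nj_tree(dist)
    raise ValueError(f"unknown tree method {method!r}")
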