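"""Degree distributions and power-law fits for TF interaction networks.

Scale-free structure is assessed with the discrete maximum-likelihood
estimator: P(k) = k^-alpha / zeta(alpha, xmin) for k >= xmin, alpha fitted by
maximizing the Hurwitz-zeta likelihood and xmin chosen by minimizing the
Kolmogorov-Smirnov distance between the tail of the empirical distribution
and the fitted model.  A log-log least-squares fit is available for
comparison; it is the historical method but statistically biased.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .orthology import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegreeDistribution:
    species_id: str
    degrees: Mapping[str, int]        # node -> degree
    self_loop_policy: str

    @property
    def histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(self.degrees.values()).items()))

    @property
    def values(self) -> np.ndarray:
        return np.array(sorted(self.degrees.values()), dtype=np.int64)


def degree_distribution(network: InteractionNetwork,
                        self_loop_policy: str = "partner_count") -> DegreeDistribution:
    """Node degrees of a TF network.

    partner_count (default): the degree is the number of distinct interaction
    partners; a self-loop contributes 1 (the TF is its own partner).
    graph_degree: the usual graph-theoretic degree where a self-loop
    contributes 2.
    """
    if self_loop_policy not in ("partner_count", "graph_degree"):
        raise ValueError(f"unknown self_loop_policy {self_loop_policy!r}")
    if len(network) == 0 and not network.isolated_nodes:
        raise ValueError("empty network")
    partners: dict[str, set[str]] = {n: set() for n in network.nodes}
    loops: set[str] = set()
    for e in network.edges:
        partners[e.a].add(e.b)
        partners[e.b].add(e.a)
        if e.is_self_loop:
            loops.add(e.a)
    degrees: dict[str, int] = {}
    for node, ps in partners.items():
        deg = len(ps)
        if self_loop_policy == "graph_degree" and node in loops:
            deg += 1  # the loop counts twice in graph degree
        degrees[node] = deg
    return DegreeDistribution(network.species_id, degrees, self_loop_policy)


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    xmin: int
    ks_statistic: float
    method: str
    n_tail: int

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("power-law exponent must exceed 1")
        if self.xmin < 1:
            raise ValueError("xmin must be >= 1")


def _mle_alpha(ks: np.ndarray, xmin: int) -> float:
    """Discrete MLE: maximize -n*log zeta(a, xmin) - a*sum(log k)."""
    slog = np.log(ks).sum()
    n = len(ks)

    def nll(a: float) -> float:
        return n * np.log(zeta(a, xmin)) + a * slog

    res = minimize_scalar(nll, bounds=(1.000001, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def _ks_distance(ks: np.ndarray, alpha: float, xmin: int) -> float:
    tail = np.sort(ks[ks >= xmin])
    kmax = int(tail[-1])
    support = np.arange(xmin, kmax + 1)
    z = zeta(alpha, xmin)
    pmf = support.astype(float) ** (-alpha) / z
    cdf_model = np.cumsum(pmf)
    counts = np.bincount(tail, minlength=kmax + 1)[xmin:]
    cdf_emp = np.cumsum(counts) / len(tail)
    return float(np.max(np.abs(cdf_emp - cdf_model)))


def fit_power_law(degrees: Sequence[int], method: str = "mle",
                  xmin_mode: str | int = "auto",
                  min_tail: int = 10) -> PowerLawFit:
    """Fit a discrete power law to a degree sequence.

    Degree-0 observations are excluded.  ``xmin_mode='auto'`` scans candidate
    cutoffs and keeps the one minimizing the KS distance subject to
    n_tail >= min_tail; an integer fixes the cutoff.  ``method='ols'``
    regresses log frequency on log degree over k >= xmin (biased; reported
    for comparison only).  Deterministic given its input.
    """
    ks = np.asarray([k for k in degrees if k > 0], dtype=np.int64)
    if len(ks) < min_tail:
        raise ValueError(f"need at least {min_tail} positive degrees")
    if len(np.unique(ks)) == 1:
        raise ValueError("degenerate input: all degrees equal")

    if xmin_mode == "auto":
        candidates = sorted(np.unique(ks))[:-1]  # need >= 2 distinct tail values
        candidates = [int(x) for x in candidates
                      if int(np.sum(ks >= x)) >= min_tail]
        if not candidates:
            candidates = [int(ks.min())]
    else:
        candidates = [int(xmin_mode)]

    best: tuple[float, int, float] | None = None  # (ks_stat, xmin, alpha)
    for xmin in candidates:
        tail = ks[ks >= xmin]
        alpha = _mle_alpha(tail, xmin)
        d = _ks_distance(ks, alpha, xmin)
        if best is None or (d, xmin) < (best[0], best[1]):
            best = (d, xmin, alpha)
    ks_stat, xmin, alpha = best
    n_tail = int(np.sum(ks >= xmin))

    if method == "mle":
        return PowerLawFit(alpha=alpha, xmin=xmin, ks_statistic=ks_stat,
                           method="mle", n_tail=n_tail)
    if method == "ols":
        tail = ks[ks >= xmin]
        vals, counts = np.unique(tail, return_counts=True)
        slope, _ = np.polyfit(np.log(vals), np.log(counts / len(tail)), 1)
        alpha_ols = float(-slope)
        d = _ks_distance(ks, alpha_ols, xmin) if alpha_ols > 1 else float("nan")
        return PowerLawFit(alpha=max(alpha_ols, 1.000001), xmin=xmin,
                           ks_statistic=d, method="ols", n_tail=n_tail)
    raise ValueError(f"unknown fit method {method!r}")


def sample_discrete_power_law(alpha: float, n: int,
                              rng: np.random.Generator,
                              xmin: int = 1, kmax: int = 1_000_000) -> np.ndarray:
    """Draw n values from P(k) ∝ k^-alpha, k in [xmin, kmax], by inverse CDF.

    The truncation at kmax loses only the extreme tail (mass < 1e-9 for
    alpha 2.5, kmax 1e6).
    """
    support = np.arange(xmin, kmax + 1, dtype=np.float64)
    pmf = support ** (-alpha)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    return (idx + xmin).astype(np.int64)


def network_summary(network: InteractionNetwork) -> dict[str, float | int | str]:
    """One deterministic summary row: sizes, loops, degrees, components."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((e.a, e.b) for e in network.edges)
    n_loops = sum(1 for e in network.edges if e.is_self_loop)
    if len(network.nodes) > 0:
        dd = degree_distribution(network, "partner_count") if len(network) else None
        degs = list(dd.degrees.values()) if dd else [0] * len(network.nodes)
        mean_deg = float(np.mean(degs))
        max_deg = int(max(degs))
    else:
        mean_deg, max_deg = 0.0, 0
    return {
        "species": network.species_id,
        "nodes": len(network.nodes),
        "edges": len(network),
        "self_loops": n_loops,
        "mean_degree": mean_deg,
        "max_degree": max_deg,
        "components": nx.number_connected_components(g) if len(g) else 0,
    }
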