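"""Coalteration statistics: the experiments x nodes matrix, Patel's kappa,
and Dirichlet Monte-Carlo edge significance.

For a node pair (a, b), the rows of the binary coalteration matrix give the
four joint alteration states with probabilities

    theta1 = P(a=1, b=1),  theta2 = P(a=1, b=0),
    theta3 = P(a=0, b=1),  theta4 = P(a=0, b=0),

estimated as multinomial frequencies.  Patel's kappa measures the excess of
theta1 over the independence expectation E = (theta1+theta2)(theta1+theta3),
normalized by the distance to the Frechet bound the excess points at:

    max(theta1) = min(theta1+theta2, theta1+theta3)
    min(theta1) = max(0, 2*theta1 + theta2 + theta3 - 1)
    D = 1 if theta1 >= E else 0
    kappa = (theta1 - E) / (D*(max(theta1) - E) + (1-D)*(E - min(theta1)))

so kappa ranges over [-1, 1], hitting 1 under perfect co-occurrence and -1
under perfectly complementary alteration.  Edge significance is assessed by
sampling theta from the Dirichlet posterior of the 4-cell multinomial (flat
prior) and requiring the posterior probability of kappa exceeding a
threshold e (default 0) to reach 1 - p (default p = 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

from .io import Experiment
from .nodes import NetworkNode

logger = logging.getLogger(__name__)


class ThetaEstimate(NamedTuple):
    """Joint alteration probabilities of a node pair (sum to 1)."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float


@dataclass
class CoalterationMatrix:
    """Binary experiments x nodes alteration incidence."""

    experiment_ids: list[str]
    node_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.experiment_ids), len(self.node_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix cells must be 0/1")
        self.values = self.values.astype(np.uint8)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def column(self, node_id: str) -> np.ndarray:
        return self.values[:, self.node_ids.index(node_id)]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 joint alteration counts of a node pair over experiments."""

    node_a: str
    node_b: str
    n1: int  # both altered
    n2: int  # a only
    n3: int  # b only
    n4: int  # neither

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3, self.n4) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4])

    def thetas(self) -> ThetaEstimate:
        if self.N == 0:
            raise ValueError("empty contingency table")
        return ThetaEstimate(*(self.counts / self.N))


@dataclass(frozen=True)
class KappaResult:
    """Patel's kappa point estimate and Monte-Carlo significance for a pair."""

    node_a: str
    node_b: str
    kappa: float
    E: float
    theta1_max: float
    theta1_min: float
    posterior_prob: float
    significant: bool
    n_mc_samples: int
    seed: int | None
    n_rejected: int = 0


def build_matrix(experiments: list[Experiment], nodes: list[NetworkNode],
                 assign_radius_mm: float = 10.0, assign_rule: str = "radius",
                 atlas=None) -> CoalterationMatrix:
    """Mark which experiments altered which nodes.

    With ``assign_rule="radius"`` (default) cell (e, j) is 1 iff experiment
    e reports at least one focus within ``assign_radius_mm`` of node j's
    peak coordinate (one focus may mark several nearby nodes).  With
    ``assign_rule="region"`` a focus marks a node when it falls inside the
    node's atlas region (requires ``atlas``).  All-zero rows are retained;
    they contribute to the "neither altered" cell.
    """
    if not nodes:
        raise ValueError("node list is empty")
    if assign_rule not in ("radius", "region"):
        raise ValueError(f"unknown assign_rule {assign_rule!r}")
    if assign_rule == "radius" and assign_radius_mm <= 0:
        raise ValueError("assign_radius_mm must be positive")
    if assign_rule == "region" and atlas is None:
        raise ValueError("assign_rule='region' requires an atlas")

    values = np.zeros((len(experiments), len(nodes)), dtype=np.uint8)
    if assign_rule == "radius":
        node_xyz = np.array([n.xyz for n in nodes])
        for i, exp in enumerate(experiments):
            d = np.linalg.norm(
                exp.foci_array[:, None, :] - node_xyz[None, :, :], axis=2)
            values[i] = (d <= assign_radius_mm).any(axis=0)
    else:
        node_labels = np.array([n.atlas_label for n in nodes])
        for i, exp in enumerate(experiments):
            vox = atlas.grid.world_to_voxel(exp.foci_array)
            inside = atlas.grid.contains_voxel(vox)
            labs = {int(atlas.labels[tuple(v)]) for v in vox[inside]}
            values[i] = np.isin(node_labels, list(labs - {0}))
    return CoalterationMatrix(
        experiment_ids=[e.id for e in experiments],
        node_ids=[n.id for n in nodes], values=values)


def contingency(matrix: CoalterationMatrix, a: str, b: str) -> ContingencyCounts:
    """Tally the four joint alteration states of columns ``a`` and ``b``."""
    if a == b:
        raise ValueError("a and b must differ")
    if matrix.n_experiments == 0:
        raise ValueError("matrix has no experiments")
    ca, cb = matrix.column(a).astype(bool), matrix.column(b).astype(bool)
    return ContingencyCounts(
        node_a=a, node_b=b,
        n1=int(np.sum(ca & cb)), n2=int(np.sum(ca & ~cb)),
        n3=int(np.sum(~ca & cb)), n4=int(np.sum(~ca & ~cb)))


def _kappa_terms(theta: np.ndarray):
    """E, max(theta1), min(theta1) and marginals for (..., 4) theta arrays."""
    t1, t2, t3 = theta[..., 0], theta[..., 1], theta[..., 2]
    pa = t1 + t2
    pb = t1 + t3
    E = pa * pb
    t1_max = np.minimum(pa, pb)
    t1_min = np.maximum(0.0, pa + pb - 1.0)
    return pa, pb, E, t1_max, t1_min


def kappa_array(theta: np.ndarray) -> np.ndarray:
    """Vectorized Patel's kappa over (..., 4) theta arrays.

    Returns NaN where a marginal is degenerate (0 or 1), where the formula
    is undefined.
    """
    theta = np.asarray(theta, dtype=float)
    t1 = theta[..., 0]
    pa, pb, E, t1_max, t1_min = _kappa_terms(theta)
    D = t1 >= E
    denom = np.where(D, t1_max - E, E - t1_min)
    degenerate = (np.minimum(pa, pb) <= 0.0) | (np.maximum(pa, pb) >= 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (t1 - E) / denom, 0.0)
    return np.where(degenerate, np.nan, kappa)


class DegenerateMarginalError(ValueError):
    """A node is altered in all or none of the experiments: kappa undefined."""


def patel_kappa(theta) -> float:
    """Patel's kappa of one theta vector (theta1..theta4, summing to 1).

    Raises :class:`DegenerateMarginalError` when either marginal alteration
    probability is 0 or 1.
    """
    arr = np.asarray(tuple(theta), dtype=float)
    if arr.shape != (4,):
        raise ValueError("theta must have four components")
    if np.any(arr < -1e-12) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("theta must lie on the probability simplex")
    k = kappa_array(arr)
    if np.isnan(k):
        raise DegenerateMarginalError(
            "marginal alteration probability is 0 or 1; kappa undefined")
    return float(k)


def edge_significance(counts: ContingencyCounts, e_threshold: float = 0.0,
                      p_threshold: float = 0.01, n_samples: int = 10_000,
                      seed: int | None = None,
                      prior_alpha: float = 1.0) -> KappaResult:
    """Dirichlet Monte-Carlo significance of a node pair's coalteration.

    Samples theta from Dirichlet(prior_alpha + n1, ..., prior_alpha + n4)
    (flat prior by default), computes kappa per draw, and reports the
    posterior probability that kappa exceeds ``e_threshold``.  The edge is
    significant when that probability reaches ``1 - p_threshold``.  Draws
    with a degenerate marginal are rejected and redrawn (counted in
    ``n_rejected``); they have probability zero under a continuous
    posterior and only arise from floating-point underflow.

    The reported ``kappa`` is the maximum-likelihood point estimate from
    the observed frequencies (NaN if the observed marginals are degenerate).
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a stable tail estimate")
    if counts.N < 2:
        raise ValueError("need at least two experiments")
    rng = np.random.default_rng(seed)
    alpha = prior_alpha + counts.counts
    draws = rng.dirichlet(alpha, size=n_samples)
    kappas = kappa_array(draws)
    n_rejected = 0
    bad = np.isnan(kappas)
    while np.any(bad):
        n_bad = int(bad.sum())
        n_rejected += n_bad
        redraw = rng.dirichlet(alpha, size=n_bad)
        kappas[bad] = kappa_array(redraw)
        draws[bad] = redraw
        bad = np.isnan(kappas)
    posterior_prob = float(np.mean(kappas > e_threshold))
    significant = posterior_prob >= 1.0 - p_threshold

    theta = counts.thetas()
    arr = np.asarray(theta, dtype=float)
    _, _, E, t1_max, t1_min = _kappa_terms(arr)
    point = kappa_array(arr)
    return KappaResult(
        node_a=counts.node_a, node_b=counts.node_b,
        kappa=float(point), E=float(E), theta1_max=float(t1_max),
        theta1_min=float(t1_min), posterior_prob=posterior_prob,
        significant=bool(significant), n_mc_samples=n_samples, seed=seed,
        n_rejected=n_rejected)


@dataclass
class CoalterationNetwork:
    """Undirected coalteration graph plus all per-pair kappa results.

    ``graph`` holds every node (isolated nodes retained) and one edge per
    significant pair, weighted by the kappa point estimate.  ``results``
    lists the :class:`KappaResult` of every evaluated pair, significant or
    not; ``excluded`` names columns skipped for degenerate marginals.
    """

    graph: nx.Graph
    results: list[KappaResult]
    excluded: list[str]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)


def build_network(matrix: CoalterationMatrix, nodes: list[NetworkNode],
                  e_threshold: float = 0.0, p_threshold: float = 0.01,
                  n_samples: int = 10_000, seed: int | None = None,
                  prior_alpha: float = 1.0,
                  bonferroni: bool = False) -> CoalterationNetwork:
    """Evaluate all unordered node pairs and assemble the network.

    Columns altered in all or none of the experiments are excluded from
    pair evaluation (logged) — their kappa is undefined.  Per-pair Monte-
    Carlo seeds are spawned deterministically from ``seed``.  With
    ``bonferroni=True`` the per-pair p threshold is divided by the number
    of evaluated pairs (reported decisions change; the raw posterior
    probabilities are always stored).
    """
    if list(matrix.node_ids) != [n.id for n in nodes]:
        raise ValueError("matrix columns do not match the node list")
    col_sums = matrix.values.sum(axis=0)
    excluded = [nid for nid, s in zip(matrix.node_ids, col_sums)
                if s == 0 or s == matrix.n_experiments]
    for nid in excluded:
        logger.info("node %s altered in all or no experiments; "
                    "excluded from pair evaluation", nid)
    usable = [n for n in nodes if n.id not in set(excluded)]

    n_pairs = len(usable) * (len(usable) - 1) // 2
    p_eff = p_threshold / n_pairs if (bonferroni and n_pairs) else p_threshold
    seeds = np.random.SeedSequence(seed).spawn(max(n_pairs, 1))

    graph = nx.Graph()
    for n in nodes:
        graph.add_node(n.id, region=n.region_name, hemisphere=n.hemisphere,
                       x=n.x, y=n.y, z=n.z, ale_value=n.ale_value)
    results: list[KappaResult] = []
    idx = 0
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            pair_seed = int(seeds[idx].generate_state(1)[0] % (2 ** 31))
            idx += 1
            cc = contingency(matrix, usable[i].id, usable[j].id)
            res = edge_significance(cc, e_threshold=e_threshold,
                                    p_threshold=p_eff, n_samples=n_samples,
                                    seed=pair_seed, prior_alpha=prior_alpha)
            results.append(res)
            if res.significant:
                graph.add_edge(res.node_a, res.node_b, kappa=res.kappa,
                               posterior_prob=res.posterior_prob)
    return CoalterationNetwork(graph=graph, results=results, excluded=excluded)
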