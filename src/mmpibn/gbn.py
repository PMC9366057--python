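"""Linear-Gaussian Bayesian networks over continuous scale profiles.

A network is a directed acyclic graph in which every node carries a linear
conditional Gaussian: ``child = intercept + beta . parents + Normal(0, sigma)``.
The joint distribution of such a network is multivariate normal, which the
module exploits for exact density evaluation, closed-form joints and network
scoring.

Scoring convention: BIC is a penalized log-likelihood, *higher is better*,
with penalty ``(k/2) * ln(n)`` where ``k`` counts the free parameters of a
node's family (one slope per parent, one intercept, one variance).  Maximum-
likelihood variance estimates divide by ``n`` (not ``n - p``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDensityError, FittingError, StructuralError

__all__ = [
    "Dag",
    "LinearGaussianCpd",
    "GaussianNetwork",
    "MvnJoint",
    "topological_order",
    "fit_parameters",
    "log_density",
    "to_joint_mvn",
    "bic_score",
    "arc_strength",
    "GaussianSuffStats",
    "network_to_json",
    "network_from_json",
    "save_network",
    "load_network",
    "dag_to_graphml",
    "dag_to_dot",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph with a fixed, ordered node list.

    ``nodes`` fixes the canonical order used for data columns and reporting;
    ``arcs`` is a frozenset of ``(parent, child)`` pairs.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in self.arcs))
        declared = set(self.nodes)
        if len(declared) != len(self.nodes):
            raise StructuralError("duplicate node names")
        for parent, child in self.arcs:
            if parent == child:
                raise StructuralError(f"self-loop on node {parent!r}")
            if parent not in declared or child not in declared:
                raise StructuralError(f"arc ({parent!r}, {child!r}) uses undeclared node")
        topological_order(self)  # raises on cycles

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in canonical node order."""
        ps = {p for p, c in self.arcs if c == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {c for p, c in self.arcs if p == node}
        return tuple(n for n in self.nodes if n in cs)

    def with_arc(self, parent: str, child: str) -> "Dag":
        return Dag(self.nodes, self.arcs | {(parent, child)})

    def without_arc(self, parent: str, child: str) -> "Dag":
        return Dag(self.nodes, self.arcs - {(parent, child)})

    def has_path(self, source: str, target: str) -> bool:
        """True if a directed path source -> ... -> target exists."""
        stack, seen = [source], set()
        while stack:
            u = stack.pop()
            if u == target:
                return True
            if u in seen:
                continue
            seen.add(u)
            stack.extend(c for p, c in self.arcs if p == u)
        return False


def _find_cycle(nodes: Sequence[str], arcs: Iterable[tuple[str, str]]) -> list[str]:
    """Return one directed cycle as a node list (used for error messages)."""
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for p, c in arcs:
        adj[p].append(c)
    color: dict[str, int] = {n: 0 for n in nodes}
    stack: list[str] = []

    def dfs(u: str) -> list[str] | None:
        color[u] = 1
        stack.append(u)
        for v in adj[u]:
            if color[v] == 1:
                return stack[stack.index(v):] + [v]
            if color[v] == 0:
                found = dfs(v)
                if found is not None:
                    return found
        stack.pop()
        color[u] = 2
        return None

    for n in nodes:
        if color[n] == 0:
            found = dfs(n)
            if found is not None:
                return found
    return []


def topological_order(dag_or_nodes, arcs=None) -> list[str]:
    """Topological ordering with ties broken by canonical node order.

    Accepts either a :class:`Dag` or ``(nodes, arcs)``.  Raises
    :class:`StructuralError` naming one cycle when no ordering exists.
    """
    if arcs is None:
        nodes, arcs = dag_or_nodes.nodes, dag_or_nodes.arcs
    else:
        nodes = tuple(dag_or_nodes)
    rank = {n: i for i, n in enumerate(nodes)}
    indeg = {n: 0 for n in nodes}
    children: dict[str, list[str]] = {n: [] for n in nodes}
    for p, c in arcs:
        indeg[c] += 1
        children[p].append(c)
    # Kahn's algorithm; the ready set is always drained in canonical order.
    ready = sorted((n for n in nodes if indeg[n] == 0), key=rank.get)
    order: list[str] = []
    while ready:
        u = min(ready, key=rank.get)
        ready.remove(u)
        order.append(u)
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                ready.append(v)
    if len(order) != len(nodes):
        cycle = _find_cycle(nodes, arcs)
        raise StructuralError("cycle detected: " + " -> ".join(cycle))
    return order


@dataclass(frozen=True)
class LinearGaussianCpd:
    """``child = intercept + beta . parents + Normal(0, sigma)``."""

    child: str
    parents: tuple[str, ...]
    beta: tuple[float, ...]
    intercept: float
    sigma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if len(self.beta) != len(self.parents):
            raise ValueError("one coefficient required per parent")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class GaussianNetwork:
    """A Dag plus one linear-Gaussian CPD per node."""

    dag: Dag
    cpds: Mapping[str, LinearGaussianCpd] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpds", dict(self.cpds))
        if set(self.cpds) != set(self.dag.nodes):
            raise ValueError("exactly one CPD per node required")
        for node, cpd in self.cpds.items():
            if cpd.child != node:
                raise ValueError(f"CPD child {cpd.child!r} stored under {node!r}")
            if cpd.parents != self.dag.parents(node):
                raise ValueError(f"CPD parents of {node!r} disagree with the DAG")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes


@dataclass(frozen=True)
class MvnJoint:
    """Closed-form multivariate-normal joint of a network, in node order."""

    nodes: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (mean.size, mean.size) or mean.size != len(self.nodes):
            raise ValueError("dimension mismatch")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance not symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", 0.5 * (cov + cov.T))

    def marginal(self, names: Sequence[str]) -> "MvnJoint":
        idx = [self.nodes.index(n) for n in names]
        return MvnJoint(tuple(names), self.mean[idx],
                        self.covariance[np.ix_(idx, idx)])


def _as_matrix(data, nodes: Sequence[str]) -> np.ndarray:
    """Coerce a DataFrame / array to an (n, p) float matrix in node order."""
    if isinstance(data, pd.DataFrame):
        missing = [n for n in nodes if n not in data.columns]
        if missing:
            raise FittingError(f"missing columns: {missing}")
        mat = data.loc[:, list(nodes)].to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if mat.shape[1] != len(nodes):
            raise FittingError(
                f"data has {mat.shape[1]} columns, graph has {len(nodes)} nodes")
    if not np.isfinite(mat).all():
        raise FittingError("non-finite values in data")
    return mat


class GaussianSuffStats:
    """Sufficient statistics (mean, ML covariance) with cached family scores.

    Local family scores are computed from the Schur complement of the
    covariance: the ML residual variance of ``child | parents`` is
    ``S_cc - S_cp S_pp^{-1} S_pc``, so no per-family regression is needed.
    The cache makes greedy structure search cheap: each candidate move
    re-scores at most two families.
    """

    def __init__(self, data, nodes: Sequence[str]):
        self.nodes = tuple(nodes)
        x = _as_matrix(data, self.nodes)
        self.n = x.shape[0]
        if self.n < 1:
            raise FittingError("empty data")
        self.mean = x.mean(axis=0)
        xc = x - self.mean
        self.cov = (xc.T @ xc) / self.n  # ML covariance (divide by n)
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self._ll_cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def residual(self, child: str, parents: Sequence[str]) -> tuple[float, np.ndarray]:
        """ML residual variance and OLS slopes of child on parents."""
        c = self._index[child]
        if not parents:
            return float(self.cov[c, c]), np.empty(0)
        p = [self._index[q] for q in parents]
        spp = self.cov[np.ix_(p, p)]
        spc = self.cov[p, c]
        try:
            beta = np.linalg.solve(spp, spc)
        except np.linalg.LinAlgError:
            raise FittingError(f"singular design for node {child!r} "
                               f"(collinear parents {tuple(parents)})")
        var = float(self.cov[c, c] - spc @ beta)
        if var < -1e-8 * max(self.cov[c, c], 1.0):
            raise FittingError(f"singular design for node {child!r}")
        return max(var, 0.0), beta

    def family_loglik(self, child: str, parents: Sequence[str]) -> float:
        """Maximized Gaussian log-likelihood of one family (cached)."""
        key = (self._index[child],
               tuple(sorted(self._index[q] for q in parents)))
        hit = self._ll_cache.get(key)
        if hit is not None:
            return hit
        var, _ = self.residual(child, parents)
        if var <= 0.0:
            raise FittingError(
                f"zero residual variance for node {child!r}: deterministic family")
        ll = -0.5 * self.n * (LOG_2PI + math.log(var) + 1.0)
        self._ll_cache[key] = ll
        return ll

    def family_bic(self, child: str, parents: Sequence[str]) -> float:
        k = len(parents) + 2  # slopes + intercept + variance
        return self.family_loglik(child, parents) - 0.5 * k * math.log(self.n)


def fit_parameters(dag: Dag, data) -> GaussianNetwork:
    """Maximum-likelihood CPDs for a fixed structure.

    Each node is regressed on its parents by ordinary least squares; the
    residual variance is the ML estimate (denominator ``n``).  Orphan nodes
    get their sample mean and ML standard deviation.
    """
    x = _as_matrix(data, dag.nodes)
    n = x.shape[0]
    if n == 0:
        raise FittingError("no rows to fit")
    max_indeg = max((len(dag.parents(v)) for v in dag.nodes), default=0)
    if n <= max_indeg + 1:
        raise FittingError(
            f"need n > max in-degree + 1 ({max_indeg + 1}), got n={n}")
    idx = {v: i for i, v in enumerate(dag.nodes)}
    cpds: dict[str, LinearGaussianCpd] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        y = x[:, idx[node]]
        if not parents:
            mu = float(y.mean())
            sigma = float(np.sqrt(np.mean((y - mu) ** 2)))
            cpds[node] = LinearGaussianCpd(node, (), (), mu, sigma)
            continue
        xp = x[:, [idx[p] for p in parents]]
        design = np.column_stack([np.ones(n), xp])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise FittingError(f"singular design for node {node!r} "
                               f"(collinear parents {parents})")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sigma = float(np.sqrt(np.mean(resid ** 2)))
        cpds[node] = LinearGaussianCpd(node, parents, tuple(coef[1:]),
                                       float(coef[0]), sigma)
    return GaussianNetwork(dag, cpds)


def _profile_vector(network: GaussianNetwork, profile) -> np.ndarray:
    if isinstance(profile, Mapping):
        return np.array([float(profile[n]) for n in network.nodes])
    vec = np.asarray(profile, dtype=float).ravel()
    if vec.size != len(network.nodes):
        raise ValueError("profile length does not match node count")
    return vec


def log_density(network: GaussianNetwork, profile) -> float:
    """Joint log density: sum of per-node Gaussian log densities.

    Zero-sigma nodes: off the deterministic value the density is 0, so the
    function returns ``-inf``; exactly on it the density is singular and a
    :class:`DegenerateDensityError` is raised for the caller to handle.
    """
    vec = _profile_vector(network, profile)
    idx = {n: i for i, n in enumerate(network.nodes)}
    total = 0.0
    for node in network.nodes:
        cpd = network.cpds[node]
        mean = cpd.intercept
        if cpd.parents:
            mean += float(np.dot(cpd.beta,
                                 vec[[idx[p] for p in cpd.parents]]))
        resid = vec[idx[node]] - mean
        if cpd.sigma == 0.0:
            if resid != 0.0:
                return float("-inf")
            raise DegenerateDensityError(
                f"node {node!r} is deterministic and the profile lies on it")
        total += -0.5 * (LOG_2PI + 2.0 * math.log(cpd.sigma)
                         + (resid / cpd.sigma) ** 2)
    return total


def to_joint_mvn(network: GaussianNetwork) -> MvnJoint:
    """Closed-form joint MVN of the network, reported in node order.

    In topological order the structural system is ``x = B x + c + e`` with B
    strictly lower triangular, so mean = (I-B)^-1 c and covariance =
    (I-B)^-1 D (I-B)^-T with D = diag(sigma^2).
    """
    topo = topological_order(network.dag)
    p = len(topo)
    pos = {n: i for i, n in enumerate(topo)}
    b = np.zeros((p, p))
    c = np.zeros(p)
    d = np.zeros(p)
    for node in topo:
        cpd = network.cpds[node]
        i = pos[node]
        c[i] = cpd.intercept
        d[i] = cpd.sigma ** 2
        for parent, beta in zip(cpd.parents, cpd.beta):
            b[i, pos[parent]] = beta
    a = np.linalg.solve(np.eye(p) - b, np.eye(p))  # (I - B)^-1
    mean_topo = a @ c
    cov_topo = a @ np.diag(d) @ a.T
    # permute back to the network's canonical node order
    perm = [pos[n] for n in network.nodes]
    return MvnJoint(network.nodes, mean_topo[perm],
                    cov_topo[np.ix_(perm, perm)])


def bic_score(dag: Dag, data, stats: GaussianSuffStats | None = None) -> float:
    """Network BIC (higher is better); decomposes over node families."""
    if stats is None:
        stats = GaussianSuffStats(data, dag.nodes)
    return sum(stats.family_bic(v, dag.parents(v)) for v in dag.nodes)


def arc_strength(dag: Dag, data) -> dict[tuple[str, str], float]:
    """Score gain of each arc: BIC(dag) - BIC(dag without the arc).

    Positive strength means the arc improves the penalized fit; the values
    are used to scale edge thickness in renderings.
    """
    stats = GaussianSuffStats(data, dag.nodes)
    strengths: dict[tuple[str, str], float] = {}
    for parent, child in sorted(dag.arcs):
        full = stats.family_bic(child, dag.parents(child))
        reduced_parents = tuple(q for q in dag.parents(child) if q != parent)
        strengths[(parent, child)] = full - stats.family_bic(child, reduced_parents)
    return strengths


# ---------------------------------------------------------------------------
# Persistence and graph export


def network_to_json(network: GaussianNetwork) -> dict:
    return {
        "nodes": list(network.nodes),
        "arcs": sorted([list(a) for a in network.dag.arcs]),
        "cpds": [
            {
                "child": cpd.child,
                "parents": list(cpd.parents),
                "beta": list(cpd.beta),
                "intercept": cpd.intercept,
                "sigma": cpd.sigma,
            }
            for cpd in (network.cpds[n] for n in network.nodes)
        ],
    }


def network_from_json(doc: Mapping) -> GaussianNetwork:
    dag = Dag(tuple(doc["nodes"]),
              frozenset((a[0], a[1]) for a in doc["arcs"]))
    cpds = {
        c["child"]: LinearGaussianCpd(c["child"], tuple(c["parents"]),
                                      tuple(c["beta"]), float(c["intercept"]),
                                      float(c["sigma"]))
        for c in doc["cpds"]
    }
    return GaussianNetwork(dag, cpds)


def save_network(network: GaussianNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_json(network), fh, indent=1)


def load_network(path) -> GaussianNetwork:
    with open(path) as fh:
        return network_from_json(json.load(fh))


def dag_to_graphml(dag: Dag, path, strengths: Mapping[tuple[str, str], float] | None = None) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    for parent, child in sorted(dag.arcs):
        attrs = {}
        if strengths is not None and (parent, child) in strengths:
            attrs["strength"] = float(strengths[(parent, child)])
        g.add_edge(parent, child, **attrs)
    nx.write_graphml(g, path)


def dag_to_dot(dag: Dag, path, strengths: Mapping[tuple[str, str], float] | None = None) -> None:
    lines = ["digraph G {"]
    for node in dag.nodes:
        lines.append(f'  "{node}";')
    for parent, child in sorted(dag.arcs):
        attr = ""
        if strengths is not None and (parent, child) in strengths:
            attr = f' [strength={strengths[(parent, child)]:.6g}]'
        lines.append(f'  "{parent}" -> "{child}"{attr};')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
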