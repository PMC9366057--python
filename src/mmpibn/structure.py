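"""Hybrid structure learning: CI-tested skeleton, then BIC hill-climbing.

The learner follows the hybrid (constraint-then-score) architecture: a
grow-shrink neighbourhood search with Fisher-z partial-correlation tests
builds an undirected skeleton, and a greedy BIC hill-climb restricted to
that skeleton orients and prunes it.  Everything is deterministic for a
given input: candidate nodes are visited in canonical order and score ties
break lexicographically by (operation, parent, child).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError
from .gbn import Dag, GaussianSuffStats

__all__ = [
    "CiTestResult",
    "Skeleton",
    "fisher_z_test",
    "discover_neighbors",
    "build_skeleton",
    "hill_climb",
    "learn_structure",
]

_SATURATION_EPS = 1e-12


@dataclass(frozen=True)
class CiTestResult:
    """Outcome of one Fisher-z conditional-independence test."""

    partial_r: float
    z_stat: float
    p_value: float
    conditioning_size: int
    saturated: bool = False


@dataclass(frozen=True)
class Skeleton:
    """Undirected graph over the node set (unordered edge pairs)."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "edges", frozenset(frozenset(e) for e in self.edges))
        declared = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"bad edge {set(e)}")
            if not e <= declared:
                raise ValueError(f"edge {set(e)} uses undeclared node")

    def allows(self, x: str, y: str) -> bool:
        return frozenset((x, y)) in self.edges

    def neighbors(self, node: str) -> tuple[str, ...]:
        ns = {next(iter(e - {node})) for e in self.edges if node in e}
        return tuple(n for n in self.nodes if n in ns)


def _ensure_stats(data, nodes) -> GaussianSuffStats:
    if isinstance(data, GaussianSuffStats):
        return data
    if nodes is None:
        if isinstance(data, pd.DataFrame):
            nodes = tuple(data.columns)
        else:
            arr = np.asarray(data)
            nodes = tuple(f"X{i}" for i in range(arr.shape[1]))
    return GaussianSuffStats(data, nodes)


def _partial_corr(stats: GaussianSuffStats, x: str, y: str,
                  cond: Sequence[str]) -> float:
    """Partial correlation via the precision matrix of the (x, y, cond) block."""
    names = [x, y, *cond]
    idx = [stats.nodes.index(n) for n in names]
    sub = stats.cov[np.ix_(idx, idx)]
    d = np.sqrt(np.diag(sub))
    if np.any(d <= 0):
        raise InsufficientDataError(
            f"zero-variance column among {names}")
    corr = sub / np.outer(d, d)
    prec = np.linalg.pinv(corr)
    denom = math.sqrt(abs(prec[0, 0] * prec[1, 1]))
    if denom == 0:
        return 0.0
    return float(np.clip(-prec[0, 1] / denom, -1.0, 1.0))


def fisher_z_test(data, x: str, y: str, cond: Sequence[str] = (),
                  nodes: Sequence[str] | None = None) -> CiTestResult:
    """Fisher-z test of ``x _||_ y | cond`` under joint Gaussianity.

    z = atanh(r) * sqrt(n - |cond| - 3), two-sided p from the standard
    normal.  ``data`` may be a DataFrame, an array, or a pre-built
    :class:`GaussianSuffStats` (reused across many tests).
    """
    cond = tuple(cond)
    if x == y or x in cond or y in cond:
        raise ValueError("x, y and the conditioning set must be distinct")
    stats = _ensure_stats(data, nodes)
    dof = stats.n - len(cond) - 3
    if dof <= 0:
        raise InsufficientDataError(
            f"need n - |cond| - 3 > 0, got n={stats.n}, |cond|={len(cond)}")
    r = _partial_corr(stats, x, y, cond)
    if abs(r) >= 1.0 - _SATURATION_EPS:
        return CiTestResult(partial_r=float(np.sign(r)),
                            z_stat=math.copysign(math.inf, r),
                            p_value=0.0, conditioning_size=len(cond),
                            saturated=True)
    z = 0.5 * math.log((1.0 + r) / (1.0 - r)) * math.sqrt(dof)
    p = 2.0 * sps.norm.sf(abs(z))
    return CiTestResult(partial_r=r, z_stat=z, p_value=min(p, 1.0),
                        conditioning_size=len(cond))


def discover_neighbors(data, target: str, alpha: float = 0.05,
                       max_sepset: int = 3,
                       nodes: Sequence[str] | None = None) -> set[str]:
    """Grow-shrink candidate parents-children set of ``target``.

    Grow: repeatedly admit the candidate with the smallest p-value below
    ``alpha`` given the current set (conditioning capped at ``max_sepset``
    most recent admissions).  Shrink: drop any member rendered independent
    of the target by some subset of the others of size <= ``max_sepset``.
    Deterministic given canonical node order.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    stats = _ensure_stats(data, nodes)
    others = [n for n in stats.nodes if n != target]
    admitted: list[str] = []
    # grow phase
    while True:
        cond = tuple(admitted[-max_sepset:])
        best: tuple[float, str] | None = None
        for cand in others:
            if cand in admitted:
                continue
            res = fisher_z_test(stats, target, cand, cond)
            if res.p_value < alpha and (best is None or res.p_value < best[0]):
                best = (res.p_value, cand)
        if best is None:
            break
        admitted.append(best[1])
    # shrink phase
    members = [n for n in stats.nodes if n in admitted]
    changed = True
    while changed:
        changed = False
        for y in list(members):
            rest = [m for m in members if m != y]
            removed = False
            for size in range(0, min(max_sepset, len(rest)) + 1):
                for z in itertools.combinations(rest, size):
                    if stats.n - size - 3 <= 0:
                        continue
                    if fisher_z_test(stats, target, y, z).p_value >= alpha:
                        members.remove(y)
                        removed = changed = True
                        break
                if removed:
                    break
    return set(members)


def build_skeleton(data, alpha: float = 0.05, max_sepset: int = 3,
                   nodes: Sequence[str] | None = None) -> Skeleton:
    """Symmetrised (AND-rule) union of per-node neighbour sets."""
    stats = _ensure_stats(data, nodes)
    nbrs = {t: discover_neighbors(stats, t, alpha=alpha, max_sepset=max_sepset)
            for t in stats.nodes}
    edges = {
        frozenset((x, y))
        for i, x in enumerate(stats.nodes)
        for y in stats.nodes[i + 1:]
        if y in nbrs[x] and x in nbrs[y]
    }
    return Skeleton(stats.nodes, frozenset(edges))


def _candidate_moves(dag: Dag, constraint: Skeleton | None):
    """All legal moves in deterministic lexicographic order."""
    nodes = dag.nodes
    moves: list[tuple[str, str, str]] = []
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if (u, v) in dag.arcs:
                moves.append(("delete", u, v))
                # reversal legal iff no other directed path u ~> v remains
                if not dag.without_arc(u, v).has_path(u, v):
                    moves.append(("reverse", u, v))
            elif (v, u) not in dag.arcs:
                if constraint is not None and not constraint.allows(u, v):
                    continue
                if dag.has_path(v, u):  # adding u->v would close a cycle
                    continue
                moves.append(("add", u, v))
    moves.sort()
    return moves


def hill_climb(data, constraint: Skeleton | None = None, max_iter: int = 500,
               nodes: Sequence[str] | None = None) -> Dag:
    """Greedy BIC search over add/delete/reverse moves from the empty graph.

    Arc additions are restricted to pairs adjacent in ``constraint`` (either
    orientation); deletions and reversals are always allowed.  Each
    iteration applies the single best strictly-improving move; ties break
    lexicographically by (operation, parent, child).
    """
    stats = _ensure_stats(data, nodes)
    dag = Dag(stats.nodes)
    local = {v: stats.family_bic(v, ()) for v in stats.nodes}
    for _ in range(max_iter):
        best_delta = 1e-9  # strictly-improving threshold
        best_move = None
        for op, u, v in _candidate_moves(dag, constraint):
            pa_v = dag.parents(v)
            if op == "add":
                delta = stats.family_bic(v, (*pa_v, u)) - local[v]
            elif op == "delete":
                delta = stats.family_bic(
                    v, tuple(q for q in pa_v if q != u)) - local[v]
            else:  # reverse u->v  =>  v->u
                pa_u = dag.parents(u)
                delta = (stats.family_bic(v, tuple(q for q in pa_v if q != u))
                         - local[v]
                         + stats.family_bic(u, (*pa_u, v)) - local[u])
            if delta > best_delta:
                best_delta, best_move = delta, (op, u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            dag = dag.with_arc(u, v)
        elif op == "delete":
            dag = dag.without_arc(u, v)
        else:
            dag = dag.without_arc(u, v).with_arc(v, u)
            local[u] = stats.family_bic(u, dag.parents(u))
        local[v] = stats.family_bic(v, dag.parents(v))
    return dag


def learn_structure(data, alpha: float = 0.05, max_sepset: int = 3,
                    max_iter: int = 500,
                    nodes: Sequence[str] | None = None) -> Dag:
    """Hybrid learner: skeleton discovery, then constrained hill-climb.

    Every arc of the returned DAG joins a pair that is adjacent in the
    learned skeleton.
    """
    stats = _ensure_stats(data, nodes)
    skeleton = build_skeleton(stats, alpha=alpha, max_sepset=max_sepset)
    return hill_climb(stats, constraint=skeleton, max_iter=max_iter)
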