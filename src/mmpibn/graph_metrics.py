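"""Structure-recovery metrics: CPDAG conversion, SHD, skeleton F1.

Two DAGs are Markov equivalent iff they share skeleton and v-structures; the
CPDAG (completed partially directed graph) keeps compelled arcs directed and
leaves reversible ones undirected.  Recovery is scored on CPDAGs so that
statistically indistinguishable orientations are not penalized.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

from .gbn import Dag

__all__ = ["cpdag_edges", "shd_cpdag", "skeleton_f1", "enumerate_dags"]

Edge = tuple[str, str]


def cpdag_edges(dag: Dag) -> dict[frozenset[str], str | Edge]:
    """CPDAG of a DAG as a map {unordered pair: 'undirected' | (parent, child)}.

    V-structure arcs are compelled; remaining orientations are propagated by
    the Meek rules (R1-R3 suffice when starting from a DAG's own pattern).
    """
    adj: dict[str, set[str]] = {n: set() for n in dag.nodes}
    for p, c in dag.arcs:
        adj[p].add(c)
        adj[c].add(p)
    state: dict[frozenset[str], str | Edge] = {
        frozenset((p, c)): "undirected" for p, c in dag.arcs
    }

    def orient(p: str, c: str) -> bool:
        key = frozenset((p, c))
        if state[key] == (p, c):
            return False
        state[key] = (p, c)
        return True

    # v-structures: a -> c <- b with a, b non-adjacent
    for c in dag.nodes:
        parents = dag.parents(c)
        for a, b in itertools.combinations(parents, 2):
            if b not in adj[a]:
                orient(a, c)
                orient(b, c)

    def directed(p: str, c: str) -> bool:
        return state.get(frozenset((p, c))) == (p, c)

    def undirected(a: str, b: str) -> bool:
        return state.get(frozenset((a, b))) == "undirected"

    changed = True
    while changed:
        changed = False
        for a, b in itertools.permutations(dag.nodes, 2):
            if not undirected(a, b):
                continue
            # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
            for c in dag.nodes:
                if directed(c, a) and b not in adj[c] and c != b:
                    changed |= orient(a, b)
                    break
            if not undirected(a, b):
                continue
            # R2: a -> c -> b and a - b  =>  a -> b
            for c in dag.nodes:
                if directed(a, c) and directed(c, b):
                    changed |= orient(a, b)
                    break
            if not undirected(a, b):
                continue
            # R3: a - c -> b, a - d -> b, c and d non-adjacent  =>  a -> b
            cands = [c for c in adj[a]
                     if undirected(a, c) and directed(c, b)]
            if any(d not in adj[c] for c, d in itertools.combinations(cands, 2)):
                changed |= orient(a, b)
    return state


def shd_cpdag(dag_a: Dag, dag_b: Dag) -> int:
    """Structural Hamming distance between the CPDAGs of two DAGs.

    Each node pair whose edge mark differs (absent / undirected /
    directed-one-way) contributes 1.
    """
    ea, eb = cpdag_edges(dag_a), cpdag_edges(dag_b)
    return sum(1 for key in set(ea) | set(eb) if ea.get(key) != eb.get(key))


def skeleton_f1(true_edges: Iterable, estimated_edges: Iterable) -> float:
    """F1 of undirected edge recovery; 1.0 when both edge sets are empty."""
    truth = {frozenset(e) for e in true_edges}
    est = {frozenset(e) for e in estimated_edges}
    if not truth and not est:
        return 1.0
    tp = len(truth & est)
    if tp == 0:
        return 0.0
    precision = tp / len(est)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


def enumerate_dags(nodes: Sequence[str]) -> list[Dag]:
    """All DAGs over ``nodes`` by brute force (practical for <= 4 nodes)."""
    nodes = tuple(nodes)
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    out: list[Dag] = []
    for mask in range(1 << len(pairs)):
        arcs = {pairs[i] for i in range(len(pairs)) if mask >> i & 1}
        if any((v, u) in arcs for u, v in arcs):
            continue
        try:
            out.append(Dag(nodes, frozenset(arcs)))
        except Exception:
            continue
    return out
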