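"""Score-based greedy equivalence search (FGES) over the penalized BIC.

The search state is a CPDAG.  The forward phase repeatedly applies the
highest-scoring valid Insert(x, y, T) operator; the backward phase the best
valid Delete(x, y, H); after every move the pattern is re-closed by
extending it to a consistent DAG and rebuilding the CPDAG from that DAG's
v-structures plus the Meek rules.  Ties between equal-score candidates are
broken lexicographically by node order so the search is deterministic.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Callable, Iterable, Optional, Sequence

from .graph import Mark, MixedGraph, semi_directed_path_exists
from .stats import CovarianceModel, SearchParams, local_bic

log = logging.getLogger(__name__)

_EPS = 1e-10


# ---------------------------------------------------------------------------
# PDAG machinery
# ---------------------------------------------------------------------------

def meek_orient(pdag: MixedGraph) -> MixedGraph:
    """Close a PDAG's orientations under the four Meek rules.

    Never adds or removes adjacencies; idempotent; raises if the closure
    produces a directed cycle (inconsistent input orientations).
    """
    g = pdag.copy()
    for e in g.edges():
        if Mark.CIRCLE in (e.mark_a, e.mark_b):
            raise ValueError("Meek rules apply to directed/undirected edges only")

    def orient(u: str, v: str) -> None:
        g.set_endpoint(u, v, Mark.ARROW)
        g.set_endpoint(v, u, Mark.TAIL)

    changed = True
    while changed:
        changed = False
        for a, b in [(e.a, e.b) for e in g.edges()] + \
                    [(e.b, e.a) for e in g.edges()]:
            if not (g.endpoint(a, b) is Mark.TAIL
                    and g.endpoint(b, a) is Mark.TAIL):
                continue  # need an undirected edge a–b
            # R1: c→a, c not adjacent b  =>  a→b
            if any(g.has_directed_edge(c, a) and not g.adjacent(c, b)
                   for c in g.adjacencies(a)):
                orient(a, b); changed = True; continue
            # R2: a→c→b  =>  a→b
            if any(g.has_directed_edge(a, c) and g.has_directed_edge(c, b)
                   for c in g.adjacencies(a)):
                orient(a, b); changed = True; continue
            # R3: a—c, a—d, c→b, d→b, c,d non-adjacent  =>  a→b
            und = [c for c in g.undirected_neighbors(a)
                   if g.has_directed_edge(c, b)]
            if any(not g.adjacent(c, d)
                   for c, d in itertools.combinations(und, 2)):
                orient(a, b); changed = True; continue
            # R4: a—d, d→c, c→b, a,c adjacent, d,b non-adjacent  =>  a→b
            fired = False
            for d in g.undirected_neighbors(a):
                if g.adjacent(d, b):
                    continue
                for c in g.adjacencies(a):
                    if g.has_directed_edge(d, c) and g.has_directed_edge(c, b):
                        fired = True
                        break
                if fired:
                    break
            if fired:
                orient(a, b); changed = True
    if g.has_directed_cycle():
        raise ValueError("Meek closure produced a directed cycle")
    return g


def pdag_to_dag(pdag: MixedGraph) -> MixedGraph:
    """Dor–Tarsi consistent extension of a PDAG to a DAG.

    Raises ``ValueError`` if no consistent extension exists.
    """
    g = pdag.copy()
    # working copies of adjacency structure
    live = set(g.nodes)
    order = list(g.nodes)

    def removable(x: str) -> bool:
        nbrs = [v for v in g.adjacencies(x) if v in live]
        if any(g.has_directed_edge(x, v) for v in nbrs):
            return False
        und = [v for v in nbrs
               if g.endpoint(x, v) is Mark.TAIL and g.endpoint(v, x) is Mark.TAIL]
        for u in und:
            if any(w != u and not g.adjacent(u, w) for w in nbrs):
                return False
        return True

    result = pdag.copy(kind="CPDAG")
    while live:
        for x in order:
            if x in live and removable(x):
                for v in g.adjacencies(x):
                    if v in live and g.endpoint(x, v) is Mark.TAIL \
                            and g.endpoint(v, x) is Mark.TAIL:
                        result.set_endpoint(v, x, Mark.ARROW)
                        result.set_endpoint(x, v, Mark.TAIL)
                live.discard(x)
                break
        else:
            raise ValueError("PDAG admits no consistent DAG extension")
    out = result.copy(kind="DAG")
    out.validate()
    return out


def dag_to_cpdag(dag: MixedGraph) -> MixedGraph:
    """CPDAG of a DAG: skeleton + v-structures, closed under Meek rules."""
    g = MixedGraph(dag.nodes, kind="CPDAG")
    for e in dag.edges():
        g.add_edge(e.a, e.b, Mark.TAIL, Mark.TAIL)
    for z in dag.nodes:
        for x, y in itertools.combinations(dag.parents(z), 2):
            if not dag.adjacent(x, y):
                for p in (x, y):
                    g.set_endpoint(p, z, Mark.ARROW)
                    g.set_endpoint(z, p, Mark.TAIL)
    return meek_orient(g)


def consistent_extensions(pdag: MixedGraph) -> list[MixedGraph]:
    """All DAGs extending a CPDAG-like PDAG (exhaustive; small graphs only).

    An extension keeps every directed edge, orients every undirected edge,
    is acyclic, and has exactly the v-structures the PDAG's directed part
    already shows — for a CPDAG these are precisely the members of its
    Markov equivalence class.
    """
    und = [(e.a, e.b) for e in pdag.edges()
           if e.mark_a is Mark.TAIL and e.mark_b is Mark.TAIL]
    required = vstructures(pdag)
    out = []
    for dirs in itertools.product((0, 1), repeat=len(und)):
        g = pdag.copy()
        for (a, b), d in zip(und, dirs):
            u, v = (a, b) if d == 0 else (b, a)
            g.set_endpoint(u, v, Mark.ARROW)
            g.set_endpoint(v, u, Mark.TAIL)
        if g.has_directed_cycle():
            continue
        dag = g.copy(kind="DAG")
        if vstructures(dag) == required:
            out.append(dag)
    return out


def vstructures(g: MixedGraph) -> set:
    """Unshielded colliders among the directed edges of a graph."""
    out = set()
    for z in g.nodes:
        for x, y in itertools.combinations(g.parents(z), 2):
            if not g.adjacent(x, y):
                out.add((frozenset((x, y)), z))
    return out


# ---------------------------------------------------------------------------
# FGES proper
# ---------------------------------------------------------------------------

class _ScoreCache:
    def __init__(self, cov: CovarianceModel, c: float) -> None:
        self.cov = cov
        self.c = c
        self._cache: dict[tuple[str, frozenset], float] = {}

    def local(self, y: str, parents: Iterable[str]) -> float:
        key = (y, frozenset(parents))
        if key not in self._cache:
            self._cache[key] = local_bic(self.cov, y, sorted(key[1]), self.c)
        return self._cache[key]


def _is_clique(g: MixedGraph, S: Iterable[str]) -> bool:
    S = list(S)
    return all(g.adjacent(u, v) for u, v in itertools.combinations(S, 2))


def fges_search(cov: CovarianceModel,
                params: Optional[SearchParams] = None) -> MixedGraph:
    """Greedy equivalence search; returns the estimated CPDAG.

    Forward phase: apply the valid Insert with the largest positive score
    gain until none remains.  Backward phase: apply the best valid Delete
    with positive gain until none remains.  The total score is
    non-decreasing across moves (asserted).
    """
    params = params or SearchParams()
    if len(cov.variables) < 2:
        raise ValueError("need at least 2 variables")
    cache = _ScoreCache(cov, params.penalty_discount)
    g = MixedGraph(cov.variables, kind="CPDAG")
    idx = {v: i for i, v in enumerate(cov.variables)}

    allowed_pairs = None
    if params.faithfulness_assumed:
        # heuristic shortcut: only marginally score-improving pairs may
        # ever be joined
        allowed_pairs = {
            frozenset((x, y))
            for x, y in itertools.combinations(cov.variables, 2)
            if cache.local(y, [x]) > cache.local(y, [])
            or cache.local(x, [y]) > cache.local(x, [])
        }

    def total_score(graph: MixedGraph) -> float:
        dag = pdag_to_dag(graph)
        return sum(cache.local(v, dag.parents(v)) for v in dag.nodes)

    score = total_score(g)

    # ---- forward phase -------------------------------------------------
    while True:
        best = None  # (delta, x_idx, y_idx, T)
        for y in g.nodes:
            if params.max_degree is not None \
                    and len(g.adjacencies(y)) >= params.max_degree:
                continue
            pa_y = frozenset(g.parents(y))
            for x in g.nodes:
                if x == y or g.adjacent(x, y):
                    continue
                if params.max_degree is not None \
                        and len(g.adjacencies(x)) >= params.max_degree:
                    continue
                if allowed_pairs is not None \
                        and frozenset((x, y)) not in allowed_pairs:
                    continue
                na_yx = [v for v in g.undirected_neighbors(y)
                         if g.adjacent(v, x)]
                u = [v for v in g.undirected_neighbors(y)
                     if not g.adjacent(v, x)]
                for r in range(len(u) + 1):
                    for T in itertools.combinations(u, r):
                        cond = set(na_yx) | set(T)
                        new_pa = pa_y | cond | {x}
                        old_pa = pa_y | cond
                        delta = cache.local(y, new_pa) - cache.local(y, old_pa)
                        key = (idx[x], idx[y], tuple(sorted(idx[t] for t in T)))
                        if delta <= _EPS:
                            continue
                        if best is not None and (-delta, key) >= best[0]:
                            continue
                        if not _is_clique(g, cond):
                            continue
                        if semi_directed_path_exists(g, y, x, avoid=cond):
                            continue
                        best = ((-delta, key), x, y, T)
        if best is None:
            break
        _, x, y, T = best
        g.add_edge(x, y, Mark.TAIL, Mark.ARROW)
        for t in T:
            g.set_endpoint(t, y, Mark.ARROW)
            g.set_endpoint(y, t, Mark.TAIL)
        g = dag_to_cpdag(pdag_to_dag(g))
        new_score = total_score(g)
        assert new_score >= score - 1e-6, "forward move decreased the score"
        score = new_score

    # ---- backward phase ------------------------------------------------
    while True:
        best = None
        for y in g.nodes:
            pa_y = frozenset(g.parents(y))
            for x in g.adjacencies(y):
                if not (g.has_directed_edge(x, y)
                        or (g.endpoint(x, y) is Mark.TAIL
                            and g.endpoint(y, x) is Mark.TAIL)):
                    continue
                na_yx = [v for v in g.undirected_neighbors(y)
                         if g.adjacent(v, x)]
                for r in range(len(na_yx) + 1):
                    for H in itertools.combinations(na_yx, r):
                        keep = set(na_yx) - set(H)
                        old_pa = (pa_y | keep | {x}) - set(H)
                        new_pa = old_pa - {x}
                        delta = cache.local(y, new_pa) - cache.local(y, old_pa)
                        key = (idx[x], idx[y], tuple(sorted(idx[h] for h in H)))
                        if delta <= _EPS:
                            continue
                        if best is not None and (-delta, key) >= best[0]:
                            continue
                        if not _is_clique(g, keep):
                            continue
                        best = ((-delta, key), x, y, H)
        if best is None:
            break
        _, x, y, H = best
        g.remove_edge(x, y)
        for h in H:
            g.set_endpoint(y, h, Mark.ARROW)
            g.set_endpoint(h, y, Mark.TAIL)
            if g.adjacent(x, h) and g.endpoint(x, h) is Mark.TAIL \
                    and g.endpoint(h, x) is Mark.TAIL:
                g.set_endpoint(x, h, Mark.ARROW)
                g.set_endpoint(h, x, Mark.TAIL)
        g = dag_to_cpdag(pdag_to_dag(g))
        new_score = total_score(g)
        assert new_score >= score - 1e-6, "backward move decreased the score"
        score = new_score

    return g
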