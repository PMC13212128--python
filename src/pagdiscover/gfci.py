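"""GFCI: FCI-style refinement of the FGES supergraph into a PAG.

Phase one (``fges_search``) proposes adjacencies by score; phase two prunes
them with conditional-independence tests over adjacency subsets, reorients
every endpoint to a circle, restores unshielded colliders (from the phase-one
CPDAG or from separating sets), removes any adjacencies separable over
possible-d-sep sets, and finally closes the orientation under the standard
final rules R1–R4 and R8–R10.  R5–R7 are omitted: the pipeline assumes no
selection bias, so tail–tail edges never arise.

``oracle_gfci`` runs the same refinement with graphical separation in a
ground-truth DAG substituted for the test and a complete graph as the
phase-one supergraph; on faithful input its output is the population PAG of
the latent projection of the truth.
"""

from __future__ import annotations

import itertools
import logging
from typing import Callable, Iterable, Optional, Sequence

from .graph import Mark, MixedGraph, separated
from .fges import fges_search
from .stats import CovarianceModel, SearchParams, fisher_z_test, oracle_independence

log = logging.getLogger(__name__)

IndepFn = Callable[[str, str, tuple[str, ...]], bool]


class SepsetMap:
    """Separating sets recorded for removed adjacencies."""

    def __init__(self) -> None:
        self._map: dict[frozenset, tuple[str, ...]] = {}

    def set(self, x: str, y: str, S: Iterable[str]) -> None:
        self._map[frozenset((x, y))] = tuple(sorted(S))

    def get(self, x: str, y: str) -> Optional[tuple[str, ...]]:
        return self._map.get(frozenset((x, y)))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._map

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def gfci_search(cov: CovarianceModel,
                params: Optional[SearchParams] = None) -> MixedGraph:
    """Run the full sample-based GFCI pipeline on a covariance model."""
    params = params or SearchParams()

    def indep(x: str, y: str, S: tuple[str, ...]) -> bool:
        return fisher_z_test(cov, x, y, list(S), params.alpha).independent

    cpdag = fges_search(cov, params)
    return _refine(cpdag, indep, params)


def oracle_gfci(truth: MixedGraph,
                params: Optional[SearchParams] = None) -> MixedGraph:
    """Population-level GFCI against a ground-truth DAG with latents.

    Uses graphical separation as the independence oracle and the complete
    graph over the observed variables as the phase-one supergraph, so the
    refinement alone determines the output.
    """
    params = params or SearchParams()
    if truth.kind != "DAG":
        raise ValueError("oracle_gfci expects a ground-truth DAG")
    obs = truth.observed

    def indep(x: str, y: str, S: tuple[str, ...]) -> bool:
        return oracle_independence(truth, x, y, S)

    complete = MixedGraph(obs, kind="CPDAG")
    for a, b in itertools.combinations(obs, 2):
        complete.add_edge(a, b, Mark.TAIL, Mark.TAIL)
    return _refine(complete, indep, params)


# ---------------------------------------------------------------------------
# refinement core
# ---------------------------------------------------------------------------

def _refine(cpdag: MixedGraph, indep: IndepFn,
            params: SearchParams) -> MixedGraph:
    sepsets = SepsetMap()
    skeleton = cpdag.copy()
    _prune_by_adjacency_subsets(skeleton, indep, sepsets, params.max_cond_size)

    pag = MixedGraph(skeleton.nodes, kind="PAG")
    for e in skeleton.edges():
        pag.add_edge(e.a, e.b, Mark.CIRCLE, Mark.CIRCLE)
    _orient_colliders(pag, cpdag, sepsets, indep, params.max_cond_size)

    removed = _possible_dsep_prune(pag, indep, sepsets, params.max_cond_size)
    if removed:
        for e in pag.edges():
            pag.set_endpoint(e.a, e.b, Mark.CIRCLE)
            pag.set_endpoint(e.b, e.a, Mark.CIRCLE)
        _orient_colliders(pag, cpdag, sepsets, indep, params.max_cond_size)

    get_sepset = _sepset_getter(pag, sepsets, indep, params.max_cond_size)
    fci_final_rules(pag, sepsets, _get_sepset=get_sepset)
    return pag


def _subset_sizes(limit: int, max_cond: Optional[int]) -> range:
    top = limit if max_cond is None else min(limit, max_cond)
    return range(top + 1)


def _search_sepset(g: MixedGraph, x: str, y: str, indep: IndepFn,
                   max_cond: Optional[int]) -> Optional[tuple[str, ...]]:
    """First separating subset of adj(x)\\{y} or adj(y)\\{x}, ascending size."""
    adj_x = [v for v in g.adjacencies(x) if v != y]
    adj_y = [v for v in g.adjacencies(y) if v != x]
    top = max(len(adj_x), len(adj_y))
    for size in _subset_sizes(top, max_cond):
        for base in (adj_x, adj_y):
            if len(base) < size:
                continue
            for S in itertools.combinations(base, size):
                if indep(x, y, S):
                    return S
    return None


def _prune_by_adjacency_subsets(g: MixedGraph, indep: IndepFn,
                                sepsets: SepsetMap,
                                max_cond: Optional[int]) -> int:
    """PC-style edge removal over subsets of current adjacencies."""
    removed = 0
    size = 0
    while True:
        if max_cond is not None and size > max_cond:
            break
        any_candidate = False
        for x, y in [(e.a, e.b) for e in g.edges()]:
            found = None
            for u, v in ((x, y), (y, x)):
                base = [w for w in g.adjacencies(u) if w != v]
                if len(base) < size:
                    continue
                any_candidate = True
                for S in itertools.combinations(base, size):
                    if indep(x, y, S):
                        found = S
                        break
                if found is not None:
                    break
            if found is not None:
                g.remove_edge(x, y)
                sepsets.set(x, y, found)
                removed += 1
        if not any_candidate and size > 0:
            break
        size += 1
    if removed:
        log.info("phase 2 removed %d adjacencies by subset search", removed)
    return removed


def _orient_colliders(pag: MixedGraph, cpdag: MixedGraph, sepsets: SepsetMap,
                      indep: IndepFn, max_cond: Optional[int]) -> None:
    """Orient unshielded colliders x *→ z ←* y.

    A triple is oriented if the phase-one CPDAG already had both arrows
    into z, or if z lies outside the separating set recorded when the
    (x, y) adjacency was removed.  Pairs that were never adjacent carry no
    sepset and contribute no orientation — testing them after the fact
    would let borderline acceptances plant spurious colliders.
    """
    del indep, max_cond  # orientation uses recorded evidence only
    for z in pag.nodes:
        adj = pag.adjacencies(z)
        for x, y in itertools.combinations(adj, 2):
            if pag.adjacent(x, y):
                continue
            collider = False
            if (cpdag.adjacent(x, z) and cpdag.adjacent(y, z)
                    and cpdag.endpoint(x, z) is Mark.ARROW
                    and cpdag.endpoint(y, z) is Mark.ARROW):
                collider = True
            else:
                S = sepsets.get(x, y)
                if S is not None and z not in S:
                    collider = True
            if collider:
                pag.set_endpoint(x, z, Mark.ARROW)
                pag.set_endpoint(y, z, Mark.ARROW)


def possible_dsep(pag: MixedGraph, x: str,
                  y: Optional[str] = None) -> list[str]:
    """Possible-d-sep set of x: nodes reachable along paths every interior
    triple of which is a collider or a triangle.  ``y`` (if given) is
    excluded from the result along with ``x`` itself."""
    pag._check_node(x)
    reached: set[str] = set()

    # DFS over simple paths: the criterion is path-based, and a walk that
    # revisits nodes can qualify where no simple path does, so a plain
    # (prev, cur) state search would overshoot.
    def rec(path: list[str]) -> None:
        cur = path[-1]
        for nxt in pag.adjacencies(cur):
            if nxt in path:
                continue
            if len(path) >= 2:
                prev = path[-2]
                collider = (pag.endpoint(prev, cur) is Mark.ARROW
                            and pag.endpoint(nxt, cur) is Mark.ARROW)
                if not collider and not pag.adjacent(prev, nxt):
                    continue
            reached.add(nxt)
            rec(path + [nxt])

    rec([x])
    reached.discard(x)
    if y is not None:
        reached.discard(y)
    return [v for v in pag.nodes if v in reached]


def _possible_dsep_prune(pag: MixedGraph, indep: IndepFn, sepsets: SepsetMap,
                         max_cond: Optional[int]) -> int:
    removed = 0
    for x, y in [(e.a, e.b) for e in pag.edges()]:
        found = None
        for u, v in ((x, y), (y, x)):
            base = possible_dsep(pag, u, v)
            for size in _subset_sizes(len(base), max_cond):
                for S in itertools.combinations(base, size):
                    if indep(x, y, S):
                        found = S
                        break
                if found is not None:
                    break
            if found is not None:
                break
        if found is not None:
            pag.remove_edge(x, y)
            sepsets.set(x, y, found)
            removed += 1
    if removed:
        log.info("possible-d-sep pass removed %d adjacencies", removed)
    return removed


def _sepset_getter(pag: MixedGraph, sepsets: SepsetMap, indep: IndepFn,
                   max_cond: Optional[int]):
    def get(x: str, y: str) -> Optional[tuple[str, ...]]:
        S = sepsets.get(x, y)
        if S is None:
            S = _search_sepset(pag, x, y, indep, max_cond)
            if S is not None:
                sepsets.set(x, y, S)
        return S

    return get


# ---------------------------------------------------------------------------
# final orientation rules
# ---------------------------------------------------------------------------

def _set_mark(pag: MixedGraph, u: str, v: str, mark: Mark) -> bool:
    """Set the mark at v on edge u–v; first-writer-wins on conflicts."""
    cur = pag.endpoint(u, v)
    if cur is mark:
        return False
    if cur is not Mark.CIRCLE:
        log.warning(
            "orientation conflict on %s–%s: keeping %s at %s, refusing %s",
            u, v, cur.name, v, mark.name,
        )
        return False
    pag.set_endpoint(u, v, mark)
    return True


def fci_final_rules(pag: MixedGraph, sepsets: SepsetMap,
                    _get_sepset=None) -> MixedGraph:
    """Close a collider-oriented PAG under rules R1–R4 and R8–R10 in place.

    Adjacencies are never changed; the closure is idempotent.  Orientation
    conflicts (an attempt to overwrite a tail or arrow) indicate test
    inconsistency and are logged, first writer wins.
    """
    get_sepset = _get_sepset or (lambda x, y: sepsets.get(x, y))
    changed = True
    while changed:
        changed = False
        changed |= _rule_r1(pag)
        changed |= _rule_r2(pag)
        changed |= _rule_r3(pag)
        changed |= _rule_r4(pag, get_sepset)
        changed |= _rule_r8(pag)
        changed |= _rule_r9(pag)
        changed |= _rule_r10(pag)
    return pag


def _rule_r1(pag: MixedGraph) -> bool:
    """a *→ b o–* c with a, c non-adjacent  ⇒  b → c."""
    changed = False
    for b in pag.nodes:
        for a in pag.adjacencies(b):
            if pag.endpoint(a, b) is not Mark.ARROW:
                continue
            for c in pag.adjacencies(b):
                if c == a or pag.adjacent(a, c):
                    continue
                if pag.endpoint(c, b) is Mark.CIRCLE:
                    changed |= _set_mark(pag, c, b, Mark.TAIL)
                    changed |= _set_mark(pag, b, c, Mark.ARROW)
    return changed


def _rule_r2(pag: MixedGraph) -> bool:
    """a → b *→ c or a *→ b → c, with a *–o c  ⇒  a *→ c."""
    changed = False
    for a in pag.nodes:
        for c in pag.adjacencies(a):
            if pag.endpoint(a, c) is not Mark.CIRCLE:
                continue
            for b in pag.adjacencies(a):
                if b == c or not pag.adjacent(b, c):
                    continue
                chain1 = (pag.has_directed_edge(a, b)
                          and pag.endpoint(b, c) is Mark.ARROW)
                chain2 = (pag.endpoint(a, b) is Mark.ARROW
                          and pag.has_directed_edge(b, c))
                if chain1 or chain2:
                    changed |= _set_mark(pag, a, c, Mark.ARROW)
                    break
    return changed


def _rule_r3(pag: MixedGraph) -> bool:
    """a *→ b ←* c, a *–o d o–* c, a,c non-adjacent, d *–o b  ⇒  d *→ b."""
    changed = False
    for d in pag.nodes:
        for b in pag.adjacencies(d):
            if pag.endpoint(d, b) is not Mark.CIRCLE:
                continue
            cands = [v for v in pag.adjacencies(d)
                     if v != b and pag.adjacent(v, b)
                     and pag.endpoint(v, d) is Mark.CIRCLE
                     and pag.endpoint(v, b) is Mark.ARROW]
            for a, c in itertools.combinations(cands, 2):
                if not pag.adjacent(a, c):
                    changed |= _set_mark(pag, d, b, Mark.ARROW)
                    break
    return changed


def _discriminating_paths(pag: MixedGraph, b: str, c: str):
    """Yield origins d of discriminating paths ⟨d, …, a, b, c⟩ for b.

    Interior vertices between d and b are colliders on the path and parents
    of c; d is not adjacent to c; the path has at least three edges.
    """
    if not pag.adjacent(b, c):
        return

    def rec(u: str, seen: frozenset):
        # u: innermost interior vertex so far (collider pending its far-side
        # arrow, parent of c).  Extending with t completes u's collider.
        for t in pag.adjacencies(u):
            if t in seen:
                continue
            if pag.endpoint(t, u) is not Mark.ARROW:
                continue  # far-side arrow at u: u must be a collider
            if not pag.adjacent(t, c):
                yield t  # origin of a discriminating path
            elif pag.has_directed_edge(t, c) \
                    and pag.endpoint(u, t) is Mark.ARROW:
                # t is a further interior vertex: into t, parent of c
                yield from rec(t, seen | {t})

    for a in pag.adjacencies(b):
        if a == c or not pag.adjacent(a, c):
            continue
        # a sits next to b: collider on the path (into a) and parent of c
        if pag.endpoint(b, a) is not Mark.ARROW:
            continue
        if not pag.has_directed_edge(a, c):
            continue
        yield from rec(a, frozenset((c, b, a)))


def _rule_r4(pag: MixedGraph, get_sepset) -> bool:
    """Discriminating-path rule.

    For a discriminating path ⟨d, …, a, b, c⟩ with a circle at b on b–c:
    if b lies in the separating set of (d, c), orient b → c; otherwise
    orient a ↔ b ↔ c.
    """
    changed = False
    for b in pag.nodes:
        for c in pag.adjacencies(b):
            if pag.endpoint(c, b) is not Mark.CIRCLE:
                continue
            fired = False
            for d in _discriminating_paths(pag, b, c):
                S = get_sepset(d, c)
                if S is not None and b in S:
                    changed |= _set_mark(pag, c, b, Mark.TAIL)
                    changed |= _set_mark(pag, b, c, Mark.ARROW)
                else:
                    # collider: a ↔ b ↔ c for every a next to b on the path;
                    # setting the b–c edge bidirected suffices for closure,
                    # the a-side arrows are already present.
                    changed |= _set_mark(pag, c, b, Mark.ARROW)
                    changed |= _set_mark(pag, b, c, Mark.ARROW)
                fired = True
                break
            if fired:
                continue
    return changed


def _rule_r8(pag: MixedGraph) -> bool:
    """a → b → c (or a –o b → c) with a o→ c  ⇒  a → c."""
    changed = False
    for a in pag.nodes:
        for c in pag.adjacencies(a):
            if not (pag.endpoint(c, a) is Mark.CIRCLE
                    and pag.endpoint(a, c) is Mark.ARROW):
                continue
            for b in pag.adjacencies(a):
                if b == c or not pag.adjacent(b, c):
                    continue
                if not pag.has_directed_edge(b, c):
                    continue
                first = (pag.has_directed_edge(a, b)
                         or (pag.endpoint(b, a) is Mark.TAIL
                             and pag.endpoint(a, b) is Mark.CIRCLE))
                if first:
                    changed |= _set_mark(pag, c, a, Mark.TAIL)
                    break
    return changed


def _uncovered_pd_path(pag: MixedGraph, a: str, target: str,
                       first: Optional[str] = None) -> bool:
    """Uncovered potentially-directed path from a to target (≥ 2 edges when
    ``first`` is given, else ≥ 1 edge via any first step ≠ target)."""

    def pd(u: str, v: str) -> bool:
        return (pag.endpoint(v, u) is not Mark.ARROW
                and pag.endpoint(u, v) is not Mark.TAIL)

    starts = [first] if first is not None else \
        [w for w in pag.adjacencies(a) if w != target]
    stack = [[a, w] for w in starts if pag.adjacent(a, w) and pd(a, w)]
    while stack:
        path = stack.pop()
        u = path[-1]
        if u == target:
            return True
        for w in pag.adjacencies(u):
            if w in path:
                continue
            if not pd(u, w):
                continue
            if len(path) >= 2 and pag.adjacent(path[-2], w):
                continue  # covered triple
            stack.append(path + [w])
    return False


def _rule_r9(pag: MixedGraph) -> bool:
    """a o→ c with an uncovered p.d. path ⟨a, b, …, c⟩, b ∉ adj(c)  ⇒ a → c."""
    changed = False
    for a in pag.nodes:
        for c in pag.adjacencies(a):
            if not (pag.endpoint(c, a) is Mark.CIRCLE
                    and pag.endpoint(a, c) is Mark.ARROW):
                continue
            for b in pag.adjacencies(a):
                if b == c or pag.adjacent(b, c):
                    continue
                if _uncovered_pd_path(pag, a, c, first=b):
                    changed |= _set_mark(pag, c, a, Mark.TAIL)
                    break
    return changed


def _rule_r10(pag: MixedGraph) -> bool:
    """a o→ c, b → c ← d, uncovered p.d. paths a…b and a…d whose first
    steps μ ≠ ω are non-adjacent  ⇒  a → c."""
    changed = False
    for a in pag.nodes:
        for c in pag.adjacencies(a):
            if not (pag.endpoint(c, a) is Mark.CIRCLE
                    and pag.endpoint(a, c) is Mark.ARROW):
                continue
            parents_c = [p for p in pag.parents(c) if p != a]
            done = False
            for b, d in itertools.permutations(parents_c, 2):
                if done:
                    break
                for mu in pag.adjacencies(a):
                    if done or mu == c:
                        continue
                    if not _uncovered_pd_path(pag, a, b, first=mu):
                        continue
                    for om in pag.adjacencies(a):
                        if om in (c, mu) or pag.adjacent(mu, om):
                            continue
                        if _uncovered_pd_path(pag, a, d, first=om):
                            changed |= _set_mark(pag, c, a, Mark.TAIL)
                            done = True
                            break
    return changed
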