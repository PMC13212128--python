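"""Mixed causal graphs and their separation / classification machinery.

A single :class:`MixedGraph` container serves as DAG, CPDAG, MAG or PAG
depending on which endpoint marks its edges carry:

* DAG    — every edge is tail→arrow and the directed part is acyclic;
* CPDAG  — directed (tail→arrow) and undirected (tail–tail) edges;
* MAG    — tail→arrow and arrow–arrow edges, ancestral and maximal;
* PAG    — tail, arrow and circle marks; tail–tail edges are rejected
           because the selection-bias-free setting never produces them.

On top of the container this module implements the graphical criteria the
discovery pipeline needs: d-/m-separation, ancestor closure, latent
projection of a DAG onto its observed margin, Zhang's visibility criterion,
the "definitely direct" test (no alternative semi-directed channel), and the
seven-type classification of PAG edges used in the consensus reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence


class Mark(Enum):
    """Endpoint mark of a mixed-graph edge."""

    TAIL = "-"
    ARROW = ">"
    CIRCLE = "o"


class EdgeType(Enum):
    """Seven-way taxonomy of PAG edges.

    Directed edges split on two axes: *visible* (provably no latent
    confounder, "NLC") versus invisible ("PLC" — a latent confounder is
    possible), and *definitely direct* ("DD" — no alternative semi-directed
    channel) versus possibly direct ("PD" — an observed mediator may carry
    part of the effect).  Circle–arrow, circle–circle and bidirected edges
    are classified by their mark pattern alone.
    """

    T1_DD_NLC = 1
    T2_PD_NLC = 2
    T3_DD_PLC = 3
    T4_PD_PLC = 4
    T5_CIRCLE_ARROW = 5
    T6_CIRCLE_CIRCLE = 6
    T7_BIDIRECTED = 7

    @property
    def number(self) -> int:
        return self.value

    @property
    def is_directed(self) -> bool:
        return self.value <= 4

    @property
    def glyph(self) -> str:
        return {1: "-->", 2: "-->", 3: "-->", 4: "-->",
                5: "o->", 6: "o-o", 7: "<->"}[self.value]

    @property
    def code(self) -> str:
        """Short label used in reports, e.g. ``"DD PLC"`` for type 3."""
        return {1: "DD NLC", 2: "PD NLC", 3: "DD PLC", 4: "PD PLC",
                5: "", 6: "", 7: ""}[self.value]

    @property
    def label(self) -> str:
        base = f"N.{self.value} {self.glyph}"
        return f"{base} {self.code}" if self.code else base


@dataclass(frozen=True)
class NodeRef:
    """A named graph node; ``is_latent`` marks unobserved variables."""

    name: str
    is_latent: bool = False


@dataclass(frozen=True)
class Edge:
    """Endpoint-marked edge; identity is symmetric under endpoint swap."""

    a: str
    b: str
    mark_a: Mark
    mark_b: Mark

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop at {self.a!r}")

    def _key(self) -> frozenset:
        return frozenset([(self.a, self.mark_a), (self.b, self.mark_b)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Edge):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def reversed(self) -> "Edge":
        return Edge(self.b, self.a, self.mark_b, self.mark_a)


GRAPH_KINDS = ("DAG", "CPDAG", "MAG", "PAG")

# marks a kind may carry on a single edge, as unordered mark pairs
_LEGAL_MARK_PAIRS = {
    "DAG": {frozenset([Mark.TAIL, Mark.ARROW])},
    "CPDAG": {frozenset([Mark.TAIL, Mark.ARROW]), frozenset([Mark.TAIL])},
    "MAG": {frozenset([Mark.TAIL, Mark.ARROW]), frozenset([Mark.ARROW])},
    "PAG": {frozenset([Mark.TAIL, Mark.ARROW]), frozenset([Mark.ARROW]),
            frozenset([Mark.CIRCLE]), frozenset([Mark.CIRCLE, Mark.ARROW]),
            frozenset([Mark.CIRCLE, Mark.TAIL])},
}


class MixedGraph:
    """Node-ordered mixed graph with at most one marked edge per pair.

    Node order is the order of first insertion (matching the column order
    of the data table the graph was estimated from) and is used for all
    deterministic iteration and rendering.
    """

    def __init__(self, nodes: Iterable = (), kind: str = "PAG") -> None:
        if kind not in GRAPH_KINDS:
            raise ValueError(f"unknown graph kind {kind!r}")
        self.kind = kind
        self._order: list[str] = []
        self._latent: set[str] = set()
        # _marks[(u, v)] = mark at v on the edge u–v
        self._marks: dict[tuple[str, str], Mark] = {}
        self._nbrs: dict[str, set[str]] = {}
        for node in nodes:
            if isinstance(node, NodeRef):
                self.add_node(node.name, latent=node.is_latent)
            else:
                self.add_node(node)

    # -- nodes ----------------------------------------------------------
    def add_node(self, name: str, latent: bool = False) -> None:
        if name in self._nbrs:
            raise ValueError(f"duplicate node name {name!r}")
        self._order.append(name)
        self._nbrs[name] = set()
        if latent:
            self._latent.add(name)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._order)

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(n for n in self._order if n not in self._latent)

    def is_latent(self, name: str) -> bool:
        self._check_node(name)
        return name in self._latent

    def node_index(self, name: str) -> int:
        self._check_node(name)
        return self._order.index(name)

    def _check_node(self, name: str) -> None:
        if name not in self._nbrs:
            raise KeyError(f"unknown node {name!r}")

    # -- edges ----------------------------------------------------------
    def add_edge(self, a: str, b: str, mark_a: Mark, mark_b: Mark) -> None:
        self._check_node(a)
        self._check_node(b)
        if a == b:
            raise ValueError(f"self-loop at {a!r}")
        if b in self._nbrs[a]:
            raise ValueError(f"duplicate edge {a!r}–{b!r}")
        pair = frozenset([mark_a, mark_b])
        if pair not in _LEGAL_MARK_PAIRS[self.kind]:
            raise ValueError(
                f"mark pair {mark_a.name}–{mark_b.name} illegal in a "
                f"{self.kind} (selection-bias configurations unsupported)"
            )
        self._nbrs[a].add(b)
        self._nbrs[b].add(a)
        self._marks[(a, b)] = mark_b
        self._marks[(b, a)] = mark_a

    def remove_edge(self, a: str, b: str) -> None:
        if b not in self._nbrs.get(a, ()):
            raise KeyError(f"no edge {a!r}–{b!r}")
        self._nbrs[a].discard(b)
        self._nbrs[b].discard(a)
        del self._marks[(a, b)]
        del self._marks[(b, a)]

    def adjacent(self, a: str, b: str) -> bool:
        self._check_node(a)
        self._check_node(b)
        return b in self._nbrs[a]

    def adjacencies(self, a: str) -> list[str]:
        """Neighbours of ``a`` in node order."""
        self._check_node(a)
        nbrs = self._nbrs[a]
        return [n for n in self._order if n in nbrs]

    def endpoint(self, a: str, b: str) -> Mark:
        """Mark at ``b`` on the edge ``a``–``b``."""
        if (a, b) not in self._marks:
            self._check_node(a)
            self._check_node(b)
            raise KeyError(f"no edge {a!r}–{b!r}")
        return self._marks[(a, b)]

    def set_endpoint(self, a: str, b: str, mark: Mark) -> None:
        if (a, b) not in self._marks:
            raise KeyError(f"no edge {a!r}–{b!r}")
        other = self._marks[(b, a)]
        pair = frozenset([other, mark])
        if pair not in _LEGAL_MARK_PAIRS[self.kind]:
            raise ValueError(
                f"mark pair {other.name}–{mark.name} illegal in a {self.kind}"
            )
        self._marks[(a, b)] = mark

    def edge(self, a: str, b: str) -> Edge:
        return Edge(a, b, self.endpoint(b, a), self.endpoint(a, b))

    def edges(self) -> list[Edge]:
        """All edges, endpoints ordered by node order, edges sorted likewise."""
        idx = {n: i for i, n in enumerate(self._order)}
        out = []
        for (a, b) in self._marks:
            if idx[a] < idx[b]:
                out.append(Edge(a, b, self._marks[(b, a)], self._marks[(a, b)]))
        out.sort(key=lambda e: (idx[e.a], idx[e.b]))
        return out

    def n_edges(self) -> int:
        return len(self._marks) // 2

    def has_directed_edge(self, a: str, b: str) -> bool:
        """True iff a→b (tail at a, arrow at b)."""
        return (self.adjacent(a, b)
                and self.endpoint(a, b) is Mark.ARROW
                and self.endpoint(b, a) is Mark.TAIL)

    def parents(self, b: str) -> list[str]:
        return [a for a in self.adjacencies(b) if self.has_directed_edge(a, b)]

    def children(self, a: str) -> list[str]:
        return [b for b in self.adjacencies(a) if self.has_directed_edge(a, b)]

    def undirected_neighbors(self, a: str) -> list[str]:
        return [b for b in self.adjacencies(a)
                if self.endpoint(a, b) is Mark.TAIL
                and self.endpoint(b, a) is Mark.TAIL]

    def copy(self, kind: Optional[str] = None) -> "MixedGraph":
        g = MixedGraph(kind=kind or self.kind)
        g._order = list(self._order)
        g._latent = set(self._latent)
        g._nbrs = {n: set(s) for n, s in self._nbrs.items()}
        g._marks = dict(self._marks)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixedGraph):
            return NotImplemented
        return (set(self._order) == set(other._order)
                and self._latent == other._latent
                and self._marks == other._marks)

    def __repr__(self) -> str:
        es = ", ".join(
            f"{e.a} {e.mark_a.value}-{e.mark_b.value} {e.b}" for e in self.edges()
        )
        return f"MixedGraph({self.kind}; {len(self._order)} nodes; [{es}])"

    # -- structural validation ------------------------------------------
    def has_directed_cycle(self) -> bool:
        color: dict[str, int] = {}

        def visit(u: str) -> bool:
            color[u] = 1
            for v in self._nbrs[u]:
                if self.has_directed_edge(u, v):
                    c = color.get(v, 0)
                    if c == 1 or (c == 0 and visit(v)):
                        return True
            color[u] = 2
            return False

        return any(color.get(n, 0) == 0 and visit(n) for n in self._order)

    def validate(self) -> None:
        """Raise ``ValueError`` on a kind-specific structural violation."""
        if self.kind in ("DAG", "CPDAG", "MAG") and self.has_directed_cycle():
            raise ValueError(f"{self.kind} contains a directed cycle")
        if self.kind == "MAG" and not is_ancestral(self):
            raise ValueError("MAG is not ancestral")


# ---------------------------------------------------------------------------
# ancestry and separation
# ---------------------------------------------------------------------------

def ancestors(graph: MixedGraph, x: str) -> set[str]:
    """Reflexive-transitive closure of the parent relation above ``x``."""
    graph._check_node(x)
    seen = {x}
    stack = [x]
    while stack:
        v = stack.pop()
        for u in graph._nbrs[v]:
            if u not in seen and graph.has_directed_edge(u, v):
                seen.add(u)
                stack.append(u)
    return seen


def descendants(graph: MixedGraph, x: str) -> set[str]:
    graph._check_node(x)
    seen = {x}
    stack = [x]
    while stack:
        v = stack.pop()
        for u in graph._nbrs[v]:
            if u not in seen and graph.has_directed_edge(v, u):
                seen.add(u)
                stack.append(u)
    return seen


def separated(graph: MixedGraph, x: str, y: str,
              Z: Iterable[str] = ()) -> bool:
    """d-separation (DAG) / m-separation (MAG) of ``x`` and ``y`` given ``Z``.

    A path connects given Z iff every non-collider on it lies outside Z and
    every collider on it is an ancestor of Z.  The criterion is symmetric in
    ``x`` and ``y``.
    """
    Z = set(Z)
    graph._check_node(x)
    graph._check_node(y)
    for z in Z:
        graph._check_node(z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in Z or y in Z:
        raise ValueError("conditioning set must not contain x or y")

    an_z: set[str] = set()
    for z in Z:
        an_z |= ancestors(graph, z)

    if graph.adjacent(x, y):
        return False
    # BFS over (prev, cur) edge-walk states; a connecting walk implies a
    # connecting path, so walks suffice.
    queue: list[tuple[str, str]] = [(x, w) for w in graph.adjacencies(x)]
    visited: set[tuple[str, str]] = set()
    while queue:
        state = queue.pop()
        if state in visited:
            continue
        visited.add(state)
        prev, cur = state
        arrow_in = graph.endpoint(prev, cur) is Mark.ARROW
        for nxt in graph._nbrs[cur]:
            if nxt == prev:
                continue
            collider = arrow_in and graph.endpoint(nxt, cur) is Mark.ARROW
            passable = (cur in an_z) if collider else (cur not in Z)
            if not passable:
                continue
            if nxt == y:
                return False
            queue.append((cur, nxt))
    return True


# ---------------------------------------------------------------------------
# latent projection DAG -> MAG
# ---------------------------------------------------------------------------

def latent_project(dag: MixedGraph, method: str = "ancestral") -> MixedGraph:
    """Project a DAG with latent variables onto its observed margin.

    Two observed variables are adjacent in the MAG iff no subset of the
    remaining observed variables d-separates them in the DAG; the mark at X
    on an edge X–Y is a tail iff X is an ancestor of Y in the DAG.

    ``method="ancestral"`` (default) decides adjacency with the single
    candidate separator (An(x) ∪ An(y)) ∩ O \\ {x, y}: if any observed
    subset separates the pair, that ancestral set does.  ``"exhaustive"``
    enumerates all observed subsets in ascending size, which is exponential
    and only sensible on small graphs; the two agree (asserted by test).
    """
    if dag.kind != "DAG":
        raise ValueError("latent_project expects a DAG")
    obs = dag.observed
    if len(obs) < 2:
        raise ValueError("need at least 2 observed nodes")
    an = {v: ancestors(dag, v) for v in dag.nodes}
    mag = MixedGraph(obs, kind="MAG")
    for x, y in itertools.combinations(obs, 2):
        rest = [o for o in obs if o not in (x, y)]
        if method == "ancestral":
            cand = [o for o in rest if o in an[x] or o in an[y]]
            adjacent = not separated(dag, x, y, cand)
        elif method == "exhaustive":
            adjacent = True
            for size in range(len(rest) + 1):
                if any(separated(dag, x, y, S)
                       for S in itertools.combinations(rest, size)):
                    adjacent = False
                    break
        else:
            raise ValueError(f"unknown method {method!r}")
        if adjacent:
            mark_x = Mark.TAIL if x in an[y] else Mark.ARROW
            mark_y = Mark.TAIL if y in an[x] else Mark.ARROW
            mag.add_edge(x, y, mark_x, mark_y)
    return mag


def is_ancestral(mag: MixedGraph) -> bool:
    """No directed cycle and no node ancestral to a bidirected neighbour."""
    if mag.has_directed_cycle():
        return False
    for e in mag.edges():
        if e.mark_a is Mark.ARROW and e.mark_b is Mark.ARROW:
            if e.a in ancestors(mag, e.b) or e.b in ancestors(mag, e.a):
                return False
    return True


def is_maximal(mag: MixedGraph) -> bool:
    """Every non-adjacent observed pair is m-separated by some subset.

    Exhaustive over subsets — intended for small test fixtures.
    """
    nodes = mag.nodes
    for x, y in itertools.combinations(nodes, 2):
        if mag.adjacent(x, y):
            continue
        rest = [o for o in nodes if o not in (x, y)]
        if not any(separated(mag, x, y, S)
                   for size in range(len(rest) + 1)
                   for S in itertools.combinations(rest, size)):
            return False
    return True


# ---------------------------------------------------------------------------
# path predicates and edge classification
# ---------------------------------------------------------------------------

def semi_directed_path_exists(
    graph: MixedGraph, x: str, y: str,
    avoid: Iterable[str] = (),
    without_edge: Optional[tuple[str, str]] = None,
) -> bool:
    """Reachability x→y along paths never leaving a node through an arrow.

    An edge u–v may be traversed from u only if its mark at u is not an
    arrow.  ``avoid`` nodes may not appear as interior or terminal steps
    other than ``y``; ``without_edge`` ignores one adjacency (both
    orientations), which lets callers test deletion without mutating.
    """
    graph._check_node(x)
    graph._check_node(y)
    if x == y:
        raise ValueError("x and y must differ")
    banned = set(avoid) - {x}
    skip = frozenset(without_edge) if without_edge else frozenset()

    stack = [x]
    seen = {x}
    while stack:
        u = stack.pop()
        for v in graph._nbrs[u]:
            if v in seen or v in banned:
                continue
            if {u, v} == skip:
                continue
            if graph.endpoint(v, u) is Mark.ARROW:  # mark at u
                continue
            if v == y:
                return True
            seen.add(v)
            stack.append(v)
    return False


def _require_directed(graph: MixedGraph, a: str, b: str) -> None:
    if not graph.has_directed_edge(a, b):
        raise ValueError(f"edge {a!r}→{b!r} is not directed tail→arrow")


def is_visible(graph: MixedGraph, a: str, b: str) -> bool:
    """Zhang's visibility criterion for the directed edge a→b.

    Visible ⇔ some node C not adjacent to b has an edge into a, or a
    collider path into a from such a C on which every interior node is a
    parent of b.  A visible edge cannot be produced by latent confounding
    alone ("no latent confounder", solid line in the reports).
    """
    if graph.kind not in ("MAG", "PAG"):
        raise ValueError("visibility is defined on MAGs and PAGs")
    _require_directed(graph, a, b)
    for c in graph.nodes:
        if c in (a, b) or graph.adjacent(c, b):
            continue
        if graph.adjacent(c, a) and graph.endpoint(c, a) is Mark.ARROW:
            return True
        if _collider_path_into(graph, c, a, b):
            return True
    return False


def _collider_path_into(graph: MixedGraph, c: str, a: str, b: str) -> bool:
    """Collider path c ... a, into a, all interior nodes parents of b."""

    def extend(path: list[str]) -> bool:
        u = path[-1]
        prev = path[-2]
        for w in graph._nbrs[u]:
            if w in path:
                continue
            # u must be a collider on the path and a parent of b
            if graph.endpoint(prev, u) is not Mark.ARROW:
                continue
            if graph.endpoint(w, u) is not Mark.ARROW:
                continue
            if not graph.has_directed_edge(u, b):
                continue
            if w == a:
                if graph.endpoint(u, a) is Mark.ARROW:
                    return True
                continue
            if extend(path + [w]):
                return True
        return False

    return any(extend([c, v]) for v in graph._nbrs[c] if v not in (a, b))


def is_definitely_direct(graph: MixedGraph, a: str, b: str) -> bool:
    """True iff removing a→b leaves no semi-directed path from a to b.

    A surviving semi-directed path means an observed channel could mediate
    part of the effect ("possibly direct"); absence makes the edge
    definitely direct.
    """
    _require_directed(graph, a, b)
    return not semi_directed_path_exists(graph, a, b, without_edge=(a, b))


def classify_edge(graph: MixedGraph, a: str, b: str) -> EdgeType:
    """Map a PAG edge to its seven-type classification.

    Directed edges combine visibility (NLC/PLC) with directness (DD/PD);
    circle–arrow, circle–circle and bidirected edges classify by mark
    pattern alone.  Tail–tail edges (selection bias) are rejected.
    """
    if graph.kind != "PAG":
        raise ValueError("classification is defined on PAGs")
    ma, mb = graph.endpoint(b, a), graph.endpoint(a, b)
    pat = frozenset([ma, mb])
    if pat == frozenset([Mark.TAIL, Mark.ARROW]):
        t, h = (a, b) if mb is Mark.ARROW else (b, a)
        vis = is_visible(graph, t, h)
        dd = is_definitely_direct(graph, t, h)
        if vis:
            return EdgeType.T1_DD_NLC if dd else EdgeType.T2_PD_NLC
        return EdgeType.T3_DD_PLC if dd else EdgeType.T4_PD_PLC
    if pat == frozenset([Mark.CIRCLE, Mark.ARROW]):
        return EdgeType.T5_CIRCLE_ARROW
    if pat == frozenset([Mark.CIRCLE]):
        return EdgeType.T6_CIRCLE_CIRCLE
    if pat == frozenset([Mark.ARROW]):
        return EdgeType.T7_BIDIRECTED
    raise ValueError(
        f"edge {a!r}–{b!r} with marks {ma.name}–{mb.name} has no "
        "classification (selection-bias configurations unsupported)"
    )
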