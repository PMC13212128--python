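"""Graph-core: separation, ancestry, projection, visibility, classification."""

import itertools

import numpy as np
import pytest

from pagdiscover.graph import (Edge, EdgeType, Mark, MixedGraph, ancestors,
                               classify_edge, is_ancestral,
                               is_definitely_direct, is_maximal, is_visible,
                               latent_project, semi_directed_path_exists,
                               separated)

from conftest import make_dag, random_dag


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def all_paths(g, x, y):
    """All simple paths between x and y as node lists."""
    out = []

    def rec(path):
        u = path[-1]
        for v in g.adjacencies(u):
            if v in path:
                continue
            if v == y:
                out.append(path + [v])
            else:
                rec(path + [v])

    rec([x])
    return out


def separated_bruteforce(g, x, y, Z):
    """Path-by-path application of the blocking rules."""
    Z = set(Z)
    an_z = set()
    for z in Z:
        an_z |= ancestors(g, z)
    for path in all_paths(g, x, y):
        open_path = True
        for i in range(1, len(path) - 1):
            prev, cur, nxt = path[i - 1], path[i], path[i + 1]
            collider = (g.endpoint(prev, cur) is Mark.ARROW
                        and g.endpoint(nxt, cur) is Mark.ARROW)
            if collider:
                if cur not in an_z:
                    open_path = False
                    break
            elif cur in Z:
                open_path = False
                break
        if open_path:
            return False
    return True


def ancestors_matrix(g, x):
    """Reachability via boolean matrix closure over directed edges."""
    nodes = list(g.nodes)
    k = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((k, k), dtype=bool)
    for e in g.edges():
        if e.mark_a is Mark.TAIL and e.mark_b is Mark.ARROW:
            A[idx[e.a], idx[e.b]] = True
        elif e.mark_a is Mark.ARROW and e.mark_b is Mark.TAIL:
            A[idx[e.b], idx[e.a]] = True
    reach = np.eye(k, dtype=bool)
    for _ in range(k):
        reach = reach | (reach @ A)
    return {nodes[i] for i in range(k) if reach[i, idx[x]]}


# ---------------------------------------------------------------------------
# separation and ancestry
# ---------------------------------------------------------------------------

def test_chain_blocked_by_mediator():
    g = make_dag("ABC", [("A", "B"), ("B", "C")])
    assert separated(g, "A", "C", {"B"})
    assert not separated(g, "A", "C")


def test_collider_opens_when_conditioned():
    g = make_dag("ABC", [("A", "C"), ("B", "C")])
    assert separated(g, "A", "B")
    assert not separated(g, "A", "B", {"C"})


def test_separation_errors():
    g = make_dag("AB", [("A", "B")])
    with pytest.raises(KeyError):
        separated(g, "A", "Q")
    with pytest.raises(ValueError):
        separated(g, "A", "B", {"A"})


@pytest.mark.parametrize("seed", range(20))
def test_separation_matches_path_enumeration(seed):
    """On random 7-node DAGs the BFS criterion equals exhaustive paths."""
    rng = np.random.default_rng(seed)
    g = random_dag(rng, 7, p_edge=0.35)
    nodes = list(g.nodes)
    for _ in range(15):
        x, y = (nodes[i] for i in rng.choice(7, size=2, replace=False))
        rest = [n for n in nodes if n not in (x, y)]
        Z = {rest[i] for i in rng.choice(5, size=rng.integers(0, 4),
                                         replace=False)}
        assert separated(g, x, y, Z) == separated_bruteforce(g, x, y, Z)
        assert separated(g, x, y, Z) == separated(g, y, x, Z)


def test_ancestors_chain_and_identity():
    g = make_dag("ABC", [("A", "B"), ("B", "C")])
    assert ancestors(g, "C") == {"A", "B", "C"}
    empty = MixedGraph(["X"], kind="DAG")
    assert ancestors(empty, "X") == {"X"}


@pytest.mark.parametrize("seed", range(10))
def test_ancestors_match_matrix_closure(seed):
    rng = np.random.default_rng(seed)
    g = random_dag(rng, 6, p_edge=0.4)
    for x in g.nodes:
        assert ancestors(g, x) == ancestors_matrix(g, x)


def test_mag_separation_equals_dag_separation_without_latents():
    rng = np.random.default_rng(3)
    for _ in range(10):
        g = random_dag(rng, 5, p_edge=0.4)
        mag = latent_project(g)
        nodes = list(g.nodes)
        for x, y in itertools.combinations(nodes, 2):
            rest = [n for n in nodes if n not in (x, y)]
            for size in range(len(rest) + 1):
                for Z in itertools.combinations(rest, size):
                    assert separated(g, x, y, Z) == separated(mag, x, y, Z)


# ---------------------------------------------------------------------------
# latent projection
# ---------------------------------------------------------------------------

def test_projection_without_latents_is_identity():
    g = make_dag("ABC", [("A", "B"), ("B", "C")])
    mag = latent_project(g)
    assert mag.has_directed_edge("A", "B")
    assert mag.has_directed_edge("B", "C")
    assert not mag.adjacent("A", "C")


def test_pure_confounder_projects_to_bidirected():
    g = make_dag("ABL", [("L", "A"), ("L", "B")], latent={"L"})
    mag = latent_project(g)
    e = mag.edge("A", "B")
    assert e.mark_a is Mark.ARROW and e.mark_b is Mark.ARROW


def test_confounder_plus_direct_edge_keeps_tail():
    g = MixedGraph(kind="DAG")
    for n in ("A", "B"):
        g.add_node(n)
    g.add_node("L", latent=True)
    for p, c in [("L", "A"), ("L", "B"), ("A", "B")]:
        g.add_edge(p, c, Mark.TAIL, Mark.ARROW)
    mag = latent_project(g)
    assert mag.has_directed_edge("A", "B")


def test_projection_rejects_degenerate_input():
    g = MixedGraph(kind="DAG")
    g.add_node("L1", latent=True)
    g.add_node("A")
    with pytest.raises(ValueError):
        latent_project(g)


@pytest.mark.parametrize("seed", range(25))
def test_projection_is_ancestral_maximal_and_method_consistent(seed):
    """Random DAGs (≤6 observed, ≤3 latent): ancestral, maximal, and the
    ancestral-set shortcut agrees with exhaustive subset search."""
    rng = np.random.default_rng(seed)
    g = random_dag(rng, int(rng.integers(3, 7)), int(rng.integers(0, 4)),
                   p_edge=0.4)
    mag = latent_project(g, method="ancestral")
    assert mag == latent_project(g, method="exhaustive")
    assert is_ancestral(mag)
    assert is_maximal(mag)


# ---------------------------------------------------------------------------
# semi-directed paths, visibility, directness, classification
# ---------------------------------------------------------------------------

def sdp_bruteforce(g, x, y):
    for path in all_paths(g, x, y):
        if all(g.endpoint(path[i + 1], path[i]) is not Mark.ARROW
               for i in range(len(path) - 1)):
            return True
    return False


def test_semi_directed_path_directed_chain():
    g = make_dag("ABC", [("A", "B"), ("B", "C")])
    assert semi_directed_path_exists(g, "A", "C")
    assert not semi_directed_path_exists(g, "C", "A")


def test_semi_directed_path_bidirected_blocks():
    g = MixedGraph(["A", "B"], kind="PAG")
    g.add_edge("A", "B", Mark.ARROW, Mark.ARROW)
    assert not semi_directed_path_exists(g, "A", "B")
    assert not semi_directed_path_exists(g, "B", "A")


@pytest.mark.parametrize("seed", range(15))
def test_semi_directed_path_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    marks = [Mark.TAIL, Mark.ARROW, Mark.CIRCLE]
    g = MixedGraph([f"V{i}" for i in range(6)], kind="PAG")
    for a, b in itertools.combinations(g.nodes, 2):
        if rng.random() < 0.4:
            while True:
                ma, mb = (marks[i] for i in rng.integers(0, 3, size=2))
                if {ma, mb} != {Mark.TAIL} and not (
                        Mark.TAIL in (ma, mb) and Mark.CIRCLE in (ma, mb)):
                    break
            g.add_edge(a, b, ma, mb)
    for x, y in itertools.combinations(g.nodes, 2):
        assert semi_directed_path_exists(g, x, y) == sdp_bruteforce(g, x, y)
        assert semi_directed_path_exists(g, y, x) == sdp_bruteforce(g, y, x)


def test_visibility_two_node_mag_is_false():
    g = MixedGraph(["A", "B"], kind="MAG")
    g.add_edge("A", "B", Mark.TAIL, Mark.ARROW)
    assert not is_visible(g, "A", "B")


def test_visibility_direct_clause():
    g = MixedGraph(["C", "A", "B"], kind="MAG")
    g.add_edge("C", "A", Mark.TAIL, Mark.ARROW)
    g.add_edge("A", "B", Mark.TAIL, Mark.ARROW)
    assert is_visible(g, "A", "B")


def test_visibility_collider_path_clause():
    # c *→ m ↔ a → b with m → b: c is not adjacent to b, the path
    # c → m ↔ a is a collider path into a, and the interior node m is a
    # parent of b — only the collider-path clause fires (m itself is
    # adjacent to b, so it cannot serve as the witness directly).
    g = MixedGraph(["c", "m", "a", "b"], kind="PAG")
    g.add_edge("c", "m", Mark.TAIL, Mark.ARROW)
    g.add_edge("m", "a", Mark.ARROW, Mark.ARROW)
    g.add_edge("m", "b", Mark.TAIL, Mark.ARROW)
    g.add_edge("a", "b", Mark.TAIL, Mark.ARROW)
    assert is_visible(g, "a", "b")
    # break the collider: with m → a the path is no longer into-m on both
    # sides, and no witness remains
    h = MixedGraph(["c", "m", "a", "b"], kind="PAG")
    h.add_edge("c", "m", Mark.TAIL, Mark.ARROW)
    h.add_edge("m", "a", Mark.TAIL, Mark.ARROW)
    h.add_edge("m", "b", Mark.TAIL, Mark.ARROW)
    h.add_edge("a", "b", Mark.TAIL, Mark.ARROW)
    assert not is_visible(h, "a", "b")


def test_definitely_direct_single_edge_and_mediated():
    g = MixedGraph(["A", "B"], kind="PAG")
    g.add_edge("A", "B", Mark.TAIL, Mark.ARROW)
    assert is_definitely_direct(g, "A", "B")

    h = MixedGraph(["A", "M", "B"], kind="PAG")
    h.add_edge("A", "B", Mark.TAIL, Mark.ARROW)
    h.add_edge("A", "M", Mark.TAIL, Mark.ARROW)
    h.add_edge("M", "B", Mark.CIRCLE, Mark.ARROW)
    assert not is_definitely_direct(h, "A", "B")
    # the probe must not mutate the graph
    assert h.adjacent("A", "B")


def test_classification_by_mark_pattern():
    g = MixedGraph(["A", "B", "C"], kind="PAG")
    g.add_edge("A", "B", Mark.CIRCLE, Mark.CIRCLE)
    g.add_edge("B", "C", Mark.ARROW, Mark.ARROW)
    assert classify_edge(g, "A", "B") is EdgeType.T6_CIRCLE_CIRCLE
    assert classify_edge(g, "B", "C") is EdgeType.T7_BIDIRECTED


def test_tail_tail_rejected_in_pag():
    g = MixedGraph(["A", "B"], kind="PAG")
    with pytest.raises(ValueError):
        g.add_edge("A", "B", Mark.TAIL, Mark.TAIL)


def test_classification_partition_and_visibility_consistency():
    """Every legal PAG edge gets exactly one type; T1/T2 ⇔ visible."""
    rng = np.random.default_rng(11)
    marks = [(Mark.TAIL, Mark.ARROW), (Mark.ARROW, Mark.TAIL),
             (Mark.CIRCLE, Mark.ARROW), (Mark.ARROW, Mark.CIRCLE),
             (Mark.CIRCLE, Mark.CIRCLE), (Mark.ARROW, Mark.ARROW)]
    for _ in range(30):
        g = MixedGraph([f"V{i}" for i in range(5)], kind="PAG")
        for a, b in itertools.combinations(g.nodes, 2):
            if rng.random() < 0.45:
                ma, mb = marks[rng.integers(0, len(marks))]
                g.add_edge(a, b, ma, mb)
        for e in g.edges():
            et = classify_edge(g, e.a, e.b)
            assert et in EdgeType
            if frozenset((e.mark_a, e.mark_b)) == frozenset(
                    (Mark.TAIL, Mark.ARROW)):
                t, h = (e.a, e.b) if e.mark_b is Mark.ARROW else (e.b, e.a)
                vis = is_visible(g, t, h)
                assert (et in (EdgeType.T1_DD_NLC, EdgeType.T2_PD_NLC)) == vis


def test_edge_identity_is_unordered():
    e1 = Edge("A", "B", Mark.TAIL, Mark.ARROW)
    e2 = Edge("B", "A", Mark.ARROW, Mark.TAIL)
    assert e1 == e2 and hash(e1) == hash(e2)
    assert e1 != Edge("A", "B", Mark.ARROW, Mark.TAIL)
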