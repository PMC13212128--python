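"""Edge-stability bootstrap: ensemble GFCI runs, tallies and consensus.

The protocol re-estimates the PAG on B subsamples (by default 1,000
subsamples of 90% of the rows, drawn without replacement), classifies every
edge of every replicate into the seven-type taxonomy, and tallies, per
variable pair, how often the pair is connected at all and how often each
classified edge signature occurs.  Pairs present in strictly more than the
retention threshold of replicates enter the consensus graph with their most
frequent signature; the full tally is rendered as a tab-separated report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .graph import EdgeType, Mark, MixedGraph, classify_edge, is_ancestral
from .gfci import gfci_search
from .stats import CovarianceModel, SearchParams, covariance_from_table

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeSignature:
    """Canonical classified edge: oriented pair for asymmetric patterns,
    lexicographically ordered pair for symmetric ones (o–o, ↔)."""

    a: str
    b: str
    edge_type: EdgeType

    @classmethod
    def from_pag_edge(cls, pag: MixedGraph, x: str, y: str) -> "EdgeSignature":
        et = classify_edge(pag, x, y)
        if et in (EdgeType.T6_CIRCLE_CIRCLE, EdgeType.T7_BIDIRECTED):
            a, b = sorted((x, y))
        elif et is EdgeType.T5_CIRCLE_ARROW:
            # circle-role node first, arrow-role node second
            if pag.endpoint(x, y) is Mark.ARROW:
                a, b = x, y
            else:
                a, b = y, x
        else:  # directed: tail first, head second
            if pag.has_directed_edge(x, y):
                a, b = x, y
            else:
                a, b = y, x
        return cls(a, b, et)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))

    @property
    def glyph(self) -> str:
        return self.edge_type.glyph

    @property
    def label(self) -> str:
        return self.edge_type.label


def _marks_for_type(et: EdgeType) -> tuple[Mark, Mark]:
    """Marks (at signature.a, at signature.b) implied by an edge type."""
    if et.is_directed:
        return Mark.TAIL, Mark.ARROW
    if et is EdgeType.T5_CIRCLE_ARROW:
        return Mark.CIRCLE, Mark.ARROW
    if et is EdgeType.T6_CIRCLE_CIRCLE:
        return Mark.CIRCLE, Mark.CIRCLE
    return Mark.ARROW, Mark.ARROW


@dataclass
class EdgeTally:
    """Per-pair signature counts over B replicates."""

    B: int
    counts: dict[frozenset, dict[EdgeSignature, int]] = field(
        default_factory=dict)
    nodes: tuple[str, ...] = ()

    def presence_count(self, pair: frozenset) -> int:
        return sum(self.counts.get(pair, {}).values())

    def presence_probability(self, pair: frozenset) -> float:
        return self.presence_count(pair) / self.B

    def pairs(self) -> list[frozenset]:
        """Pairs with nonzero presence, in node order."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        return sorted(self.counts,
                      key=lambda p: tuple(sorted(idx[n] for n in p)))


@dataclass
class ReportRow:
    """One tallied pair; counts are integers so the bookkeeping identity
    presence_count = Σ type_counts holds exactly."""

    var_a: str
    var_b: str
    signature: EdgeSignature
    presence_count: int
    type_counts: dict[EdgeType, int]
    B: int
    retained: bool

    @property
    def presence(self) -> float:
        return self.presence_count / self.B

    @property
    def type_probs(self) -> dict[EdgeType, float]:
        return {t: c / self.B for t, c in self.type_counts.items()}


@dataclass
class ConsensusReport:
    B: int
    rows: list[ReportRow]

    def observed_types(self) -> list[EdgeType]:
        seen = {t for row in self.rows for t in row.type_probs
                if row.type_probs[t] > 0}
        return sorted(seen, key=lambda t: t.value)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def subsample(table: pd.DataFrame, fraction: float,
              rng: np.random.Generator,
              with_replacement: bool = False) -> pd.DataFrame:
    """Random row subsample of ``floor(fraction·n)`` rows, order randomized.

    Without replacement by default (the subsampling protocol); pass
    ``with_replacement=True`` for a classic bootstrap draw.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(table)
    m = math.floor(fraction * n)
    if m < 5:
        raise ValueError(f"subsample of {m} rows is too small")
    idx = rng.choice(n, size=m, replace=with_replacement)
    return table.iloc[idx].reset_index(drop=True)


def _replicate_rng(seed: int, replicate: int, attempt: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(replicate, attempt)))


def run_ensemble(table: pd.DataFrame,
                 params: SearchParams) -> list[MixedGraph]:
    """B independent subsample → GFCI runs; returns the replicate PAGs.

    Replicate r draws its generator from (seed, r), so changing B never
    reshuffles earlier replicates.  Replicates that fail numerically
    (singular matrices) are redrawn and counted; more than 5% failures
    aborts with diagnostics.
    """
    B = params.bootstrap_count
    pags: list[MixedGraph] = []
    failures = 0
    for r in range(B):
        attempt = 0
        while True:
            rng = _replicate_rng(params.seed, r, attempt)
            sub = subsample(table, params.subsample_fraction, rng,
                            params.with_replacement)
            try:
                cov = covariance_from_table(sub)
                pag = gfci_search(cov, params)
                break
            except np.linalg.LinAlgError as exc:
                failures += 1
                attempt += 1
                log.warning("replicate %d attempt %d failed (%s); redrawing",
                            r, attempt, exc)
                if failures > 0.05 * B:
                    raise RuntimeError(
                        f"{failures} replicate failures exceed 5% of "
                        f"B={B}; data too unstable for the ensemble"
                    ) from exc
        pags.append(pag)
    if failures:
        log.info("ensemble complete with %d redrawn replicates", failures)
    return pags


def tally(pags: Sequence[MixedGraph]) -> EdgeTally:
    """Count canonical edge signatures per pair across replicate PAGs."""
    if not pags:
        raise ValueError("no replicates to tally")
    nodes = pags[0].nodes
    if any(set(p.nodes) != set(nodes) for p in pags):
        raise ValueError("replicate PAGs disagree on the node set")
    out = EdgeTally(B=len(pags), nodes=nodes)
    for pag in pags:
        for e in pag.edges():
            sig = EdgeSignature.from_pag_edge(pag, e.a, e.b)
            bucket = out.counts.setdefault(sig.pair, {})
            bucket[sig] = bucket.get(sig, 0) + 1
    return out


# preference order used to break count ties: less informative first
_TIE_ORDER = {EdgeType.T6_CIRCLE_CIRCLE: 0, EdgeType.T5_CIRCLE_ARROW: 1,
              EdgeType.T7_BIDIRECTED: 2, EdgeType.T4_PD_PLC: 3,
              EdgeType.T3_DD_PLC: 4, EdgeType.T2_PD_NLC: 5,
              EdgeType.T1_DD_NLC: 6}


def consensus(tally_: EdgeTally,
              params: SearchParams) -> tuple[MixedGraph, ConsensusReport]:
    """Retain pairs above the threshold with their most frequent signature.

    Presence must be *strictly* greater than ``retention_threshold``.  Count
    ties are broken toward the less informative signature (circle–circle
    over circle–arrow over bidirected over directed; within directed the
    higher type number, i.e. the weaker claim, wins) with a logged warning.
    The assembled graph is checked edge-wise only; most-frequent-per-pair
    assembly can violate global PAG axioms, in which case a warning is
    logged.
    """
    idx = {n: i for i, n in enumerate(tally_.nodes)}
    rows: list[ReportRow] = []
    graph = MixedGraph(tally_.nodes, kind="PAG")
    for pair in tally_.pairs():
        bucket = tally_.counts[pair]
        presence = tally_.presence_count(pair) / tally_.B
        best_count = max(bucket.values())
        winners = sorted(
            (s for s, c in bucket.items() if c == best_count),
            key=lambda s: (_TIE_ORDER[s.edge_type], s.a, s.b),
        )
        if len(winners) > 1:
            log.warning(
                "signature tie for pair %s at count %d; keeping %s",
                "–".join(sorted(pair)), best_count, winners[0].label,
            )
        sig = winners[0]
        type_counts: dict[EdgeType, int] = {}
        for s, c in bucket.items():
            type_counts[s.edge_type] = type_counts.get(s.edge_type, 0) + c
        retained = presence > params.retention_threshold
        rows.append(ReportRow(var_a=sig.a, var_b=sig.b, signature=sig,
                              presence_count=tally_.presence_count(pair),
                              type_counts=type_counts, B=tally_.B,
                              retained=retained))
        if retained:
            ma, mb = _marks_for_type(sig.edge_type)
            graph.add_edge(sig.a, sig.b, ma, mb)
    rows.sort(key=lambda r: (-r.presence, idx[r.var_a], idx[r.var_b]))
    if graph.has_directed_cycle() or not is_ancestral(graph):
        log.warning("consensus graph violates PAG/ancestrality axioms "
                    "(edge-wise assembly; reported as-is)")
    return graph, ConsensusReport(B=tally_.B, rows=rows)


def render_report(report: ConsensusReport) -> str:
    """Tab-separated rendering of the consensus tally.

    One column per edge type observed anywhere in the tally; probabilities
    to 3 decimals; values below 0.0005 shown as "-".
    """
    types = report.observed_types()
    header = ["Variable A", "Most frequent edge", "Variable B",
              "Presence probability"] + [t.label for t in types]
    lines = ["\t".join(header)]

    def fmt(p: float) -> str:
        return "-" if p < 0.0005 else f"{p:.3f}"

    for row in report.rows:
        cells = [row.var_a, row.signature.label, row.var_b,
                 f"{row.presence:.3f}"]
        cells += [fmt(row.type_probs.get(t, 0.0)) for t in types]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
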