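"""Linear Gaussian SEM simulation with latent confounders.

The generator stands in for cohort data that cannot be shipped: it draws
multivariate continuous observations from a linear structural equation
model over observed and latent variables, rescales the observed columns to
instrument-like means and standard deviations, and exposes the model's
ground truth (DAG, projected MAG, oracle PAG) so every stage of the
discovery pipeline can be scored against a known answer.

``clinical_preset`` emulates a 16-variable schizophrenia cohort
(symptoms, cognition, metacognition, insight, functioning; n = 215): a
sparse directed skeleton among cognitive and symptom variables, pure latent
confounders over the pairs whose associations should look confounded, and
three isolated variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .graph import Mark, MixedGraph, latent_project, separated
from .gfci import oracle_gfci
from .graph import classify_edge, EdgeType
from .stats import CovarianceModel, SearchParams


@dataclass
class SemModel:
    """Linear Gaussian SEM: X_j = Σ_k b_jk X_k + ε_j, ε_j ~ N(0, sd_j²)."""

    graph: MixedGraph  # DAG; latent nodes flagged
    coefficients: dict[tuple[str, str], float]  # (parent, child) -> weight
    noise_sd: dict[str, float]
    output_scale: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.graph.kind != "DAG":
            raise ValueError("SemModel needs a DAG")
        self.graph.validate()
        for (p, ch) in self.coefficients:
            if not self.graph.has_directed_edge(p, ch):
                raise ValueError(f"coefficient on non-edge {p!r}->{ch!r}")
        for v in self.graph.nodes:
            if self.noise_sd.get(v, 0.0) <= 0:
                raise ValueError(f"noise_sd must be positive for {v!r}")

    def topological_order(self) -> list[str]:
        g = self.graph
        indeg = {v: len(g.parents(v)) for v in g.nodes}
        order, ready = [], [v for v in g.nodes if indeg[v] == 0]
        while ready:
            v = ready.pop(0)
            order.append(v)
            for ch in g.children(v):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    ready.append(ch)
        assert len(order) == len(g.nodes)
        return order


@dataclass
class GroundTruth:
    """A SEM plus its projected MAG, oracle PAG and classified edge list."""

    model: SemModel
    mag: MixedGraph
    pag: MixedGraph
    classified_edges: list[tuple[str, str, EdgeType]]


def ground_truth(model: SemModel,
                 params: Optional[SearchParams] = None) -> GroundTruth:
    mag = latent_project(model.graph)
    pag = oracle_gfci(model.graph, params)
    classified = []
    for e in pag.edges():
        classified.append((e.a, e.b, classify_edge(pag, e.a, e.b)))
    return GroundTruth(model=model, mag=mag, pag=pag,
                       classified_edges=classified)


# ---------------------------------------------------------------------------
# population quantities
# ---------------------------------------------------------------------------

def population_covariance(model: SemModel) -> tuple[list[str], np.ndarray]:
    """Implied covariance Σ = (I−B)⁻¹ D (I−B)⁻ᵀ over all nodes (latents too)."""
    nodes = list(model.graph.nodes)
    k = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    B = np.zeros((k, k))
    for (p, ch), b in model.coefficients.items():
        B[idx[ch], idx[p]] = b
    D = np.diag([model.noise_sd[v] ** 2 for v in nodes])
    inv = np.linalg.inv(np.eye(k) - B)
    return nodes, inv @ D @ inv.T


def population_correlation_model(model: SemModel,
                                 n: int = 10**9) -> CovarianceModel:
    """Observed-margin population correlations packaged as a CovarianceModel.

    ``n`` only enters test statistics downstream; a huge default makes the
    model behave like an oracle for consistency checks.
    """
    nodes, sigma = population_covariance(model)
    obs = [v for v in nodes if not model.graph.is_latent(v)]
    oi = [nodes.index(v) for v in obs]
    sub = sigma[np.ix_(oi, oi)]
    d = np.sqrt(np.diag(sub))
    corr = sub / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return CovarianceModel(n=n, variables=tuple(obs), corr=corr)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_sem(model: SemModel, n: int,
               rng: np.random.Generator) -> pd.DataFrame:
    """Draw n observations; latent columns dropped, observed columns rescaled.

    Rescaling is affine using the *population* SD of each column, so it is
    deterministic given the model and leaves every correlation untouched.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    order = model.topological_order()
    cols = {v: rng.normal(0.0, model.noise_sd[v], size=n) for v in order}
    for v in order:
        for p in model.graph.parents(v):
            cols[v] = cols[v] + model.coefficients[(p, v)] * cols[p]
    nodes, sigma = population_covariance(model)
    pop_sd = {v: float(np.sqrt(sigma[i, i])) for i, v in enumerate(nodes)}
    data = {}
    for v in model.graph.nodes:
        if model.graph.is_latent(v):
            continue
        x = cols[v]
        if v in model.output_scale:
            mean, sd = model.output_scale[v]
            x = mean + sd * x / pop_sd[v]
        data[v] = x
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# random model generator
# ---------------------------------------------------------------------------

def random_sem(n_observed: int, n_latent: int, expected_degree: float,
               rng: np.random.Generator,
               coeff_range: tuple[float, float] = (0.3, 0.9),
               max_rejects: int = 200) -> SemModel:
    """Random sparse linear SEM with pure latent confounders.

    Observed nodes get a random topological order and pairwise edges sampled
    to hit the expected degree; each latent is a root with exactly two
    observed children.  Coefficient magnitudes are drawn from
    ``coeff_range`` with random sign, bounded away from zero.  Models whose
    population partial correlations come too close to zero on small
    conditioning sets (near-unfaithful cancellation) are rejected and
    redrawn.
    """
    if n_observed < 3:
        raise ValueError("need at least 3 observed nodes")
    lo, hi = coeff_range
    if lo <= 0:
        raise ValueError("coefficient magnitudes must be bounded away from 0")
    p_edge = min(1.0, expected_degree / max(n_observed - 1, 1))

    for _ in range(max_rejects):
        obs = [f"X{i + 1}" for i in range(n_observed)]
        order = [obs[i] for i in rng.permutation(n_observed)]
        g = MixedGraph(obs, kind="DAG")
        coeffs: dict[tuple[str, str], float] = {}
        for i, j in itertools.combinations(range(n_observed), 2):
            if rng.random() < p_edge:
                p, ch = order[i], order[j]
                g.add_edge(p, ch, Mark.TAIL, Mark.ARROW)
                coeffs[(p, ch)] = float(rng.uniform(lo, hi)
                                        * rng.choice([-1.0, 1.0]))
        for li in range(n_latent):
            name = f"L{li + 1}"
            g.add_node(name, latent=True)
            ch1, ch2 = (obs[i] for i in rng.choice(n_observed, size=2,
                                                   replace=False))
            for ch in (ch1, ch2):
                g.add_edge(name, ch, Mark.TAIL, Mark.ARROW)
                coeffs[(name, ch)] = float(rng.uniform(lo, hi)
                                           * rng.choice([-1.0, 1.0]))
        model = SemModel(graph=g, coefficients=coeffs,
                         noise_sd={v: 1.0 for v in g.nodes})
        if _faithful_enough(model):
            return model
    raise RuntimeError("rejection limit exceeded; parameters pathological")


def _faithful_enough(model: SemModel, floor: float = 1e-3) -> bool:
    """Guard against near-cancelling parameterizations.

    For every observed pair and conditioning set of size ≤ 2 that the graph
    declares dependent, the population partial correlation must stay above
    ``floor`` in magnitude.
    """
    cov = population_correlation_model(model)
    obs = list(cov.variables)
    corr = cov.corr
    idx = {v: i for i, v in enumerate(obs)}
    for x, y in itertools.combinations(obs, 2):
        rest = [v for v in obs if v not in (x, y)]
        for size in (0, 1, 2):
            for S in itertools.combinations(rest, size):
                if separated(model.graph, x, y, S):
                    continue
                sel = [idx[x], idx[y]] + [idx[s] for s in S]
                sub = corr[np.ix_(sel, sel)]
                try:
                    om = np.linalg.inv(sub)
                except np.linalg.LinAlgError:
                    return False
                r = -om[0, 1] / np.sqrt(om[0, 0] * om[1, 1])
                if abs(r) < floor:
                    return False
    return True


# ---------------------------------------------------------------------------
# clinical emulation preset
# ---------------------------------------------------------------------------

#: Observed variables, in reporting order, with emulated instrument scales
#: (mean, SD): symptom factors, cognitive percentiles, metacognition,
#: insight and functioning totals.
CLINICAL_SCALES: dict[str, tuple[float, float]] = {
    "Pos": (9.43, 4.15),       # positive symptoms factor
    "Dis": (2.60, 1.48),       # conceptual disorganization item
    "Avl": (19.46, 9.32),      # avolition (experiential negatives)
    "ExD": (13.54, 7.68),      # expressive deficits
    "Dep": (3.95, 4.60),       # depression total
    "SoP": (25.81, 8.30),      # speed of processing percentile
    "Att": (30.01, 11.02),     # attention/vigilance percentile
    "WM": (32.82, 11.36),      # working memory percentile
    "VerL": (34.70, 9.61),     # verbal learning percentile
    "VisL": (37.39, 14.52),    # visual learning percentile
    "R&PS": (34.42, 8.62),     # reasoning & problem solving percentile
    "SC": (32.79, 11.46),      # social cognition (emotion management)
    "MC": (15.20, 7.77),       # metacognition total
    "UoS": (2.91, 2.03),       # unawareness of symptoms
    "MoS": (3.44, 2.32),       # misattribution of symptoms
    "RLFunc": (181.27, 20.77),  # real-life functioning total
}

#: Directed effects of the preset with their structural coefficients.
#: The overlapping latent confounders below induce additional MAG
#: adjacencies through collider ("explaining-away") paths whose strength is
#: a high-order product of coefficients; uniform coefficient choices leave
#: some of those adjacencies with population partial correlations below
#: 0.01 — statistically invisible even at n = 50,000.  These values were
#: therefore calibrated against the model-implied covariance (no data
#: involved) to maximize the weakest partial correlation among
#: MAG-adjacent pairs; at the chosen values it is ≈ 0.037, strongly
#: detectable at n = 50,000 and far below detectability at the study scale
#: n = 215, which preserves the intended "recoverable in principle,
#: uncertain at cohort size" regime.
_PRESET_DIRECTED: dict[tuple[str, str], float] = {
    ("VisL", "Att"): 0.31, ("VisL", "WM"): 0.34, ("VerL", "WM"): 0.43,
    ("VerL", "SoP"): 0.41, ("WM", "SoP"): 0.65, ("WM", "MC"): 0.38,
    ("SoP", "R&PS"): 0.52, ("MC", "RLFunc"): 0.40, ("Dis", "RLFunc"): 0.61,
    ("Avl", "ExD"): 0.51, ("Avl", "RLFunc"): 0.69,
}

#: Pairs that (in addition to their direct edge) share a pure latent
#: confounder, with the loading of the latent on both children.
_PRESET_CONFOUNDED: dict[tuple[str, str], float] = {
    ("WM", "MC"): 0.75, ("Avl", "ExD"): 0.82, ("Avl", "RLFunc"): 0.88,
    ("VerL", "SoP"): 0.61, ("WM", "SoP"): 0.75, ("VerL", "WM"): 0.71,
}

#: Pairs associated through a latent common cause only (no direct edge).
_PRESET_LATENT_ONLY: dict[tuple[str, str], float] = {
    ("VisL", "VerL"): 0.57, ("MoS", "UoS"): 0.75,
}


def clinical_preset(rng: Optional[np.random.Generator] = None,
                    params: Optional[SearchParams] = None) -> GroundTruth:
    """Ground truth emulating the 16-variable clinical cohort.

    The structure and coefficients are fixed (``rng`` is accepted for
    interface symmetry but unused): directed effects among learning,
    working memory, processing speed, metacognition, symptoms and
    functioning; six of those pairs carry an additional pure latent
    confounder; two pairs are associated through a latent common cause
    only; positive symptoms, depression and social cognition are isolated.
    All noises are unit; see the module-level coefficient tables for the
    calibration rationale.
    """
    del rng  # deterministic preset
    g = MixedGraph(list(CLINICAL_SCALES), kind="DAG")
    coeffs: dict[tuple[str, str], float] = {}
    for (p, ch), b in _PRESET_DIRECTED.items():
        g.add_edge(p, ch, Mark.TAIL, Mark.ARROW)
        coeffs[(p, ch)] = b
    latent_pairs = {**_PRESET_CONFOUNDED, **_PRESET_LATENT_ONLY}
    for i, ((a, b2), loading) in enumerate(latent_pairs.items()):
        name = f"L{i + 1}"
        g.add_node(name, latent=True)
        for ch in (a, b2):
            g.add_edge(name, ch, Mark.TAIL, Mark.ARROW)
            coeffs[(name, ch)] = loading
    model = SemModel(
        graph=g, coefficients=coeffs,
        noise_sd={v: 1.0 for v in g.nodes},
        output_scale=dict(CLINICAL_SCALES),
    )
    return ground_truth(model, params)


def sample_clinical(n: int = 215,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Convenience: one synthetic cohort from the clinical preset."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return sample_sem(clinical_preset().model, n, rng)
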