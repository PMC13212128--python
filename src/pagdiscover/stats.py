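"""Gaussian sufficient statistics, the Fisher-Z test and the penalized BIC.

Everything works on the correlation scale: the clinical variables the
pipeline targets come from heterogeneous instruments, and both the
partial-correlation test and the Gaussian BIC decisions are invariant to
affine rescaling of the columns, so a correlation matrix plus the retained
sample size is a sufficient statistic for the whole search.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import MixedGraph, separated

log = logging.getLogger(__name__)


@dataclass
class SearchParams:
    """Knobs of the discovery pipeline.

    alpha
        Level of the Fisher-Z conditional-independence test (default 0.05).
    penalty_discount
        Multiplier *c* on the BIC complexity term; c=2 doubles the usual
        penalty, discouraging spurious edges in noisy observational data.
    bootstrap_count, subsample_fraction, retention_threshold
        Resampling protocol: B replicates, each a without-replacement
        subsample of the given fraction of rows; edges are kept in the
        consensus only if present in strictly more than the threshold
        fraction of replicates.
    max_cond_size
        Cap on conditioning-set size in the pruning phases (None = none).
    max_degree
        Cap on node degree during score search (None = none).
    faithfulness_assumed
        Heuristic single-edge shortcut in the forward phase; off by default.
    with_replacement
        Classic bootstrap resampling instead of subsampling.
    """

    alpha: float = 0.05
    penalty_discount: float = 2.0
    bootstrap_count: int = 1000
    subsample_fraction: float = 0.9
    retention_threshold: float = 0.5
    seed: int = 0
    max_cond_size: Optional[int] = None
    max_degree: Optional[int] = None
    faithfulness_assumed: bool = False
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.penalty_discount <= 0:
            raise ValueError("penalty_discount must be positive")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if not 0 <= self.retention_threshold < 1:
            raise ValueError("retention_threshold must lie in [0, 1)")
        if self.bootstrap_count < 1:
            raise ValueError("bootstrap_count must be >= 1")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    independent: bool

    __test__ = False  # keep pytest from collecting the class


@dataclass
class CovarianceModel:
    """Correlation matrix + retained sample size for a named variable set."""

    n: int
    variables: tuple[str, ...]
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.corr = np.asarray(self.corr, dtype=float)
        p = len(self.variables)
        if self.corr.shape != (p, p):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.corr) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variables)}

    def idx(self, *names: str) -> list[int]:
        try:
            return [self._index[v] for v in names]
        except KeyError as exc:
            raise KeyError(f"unknown variable {exc.args[0]!r}") from None

    # -- plain-text serialization --------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"n\t{self.n}\n")
        buf.write("\t".join(self.variables) + "\n")
        for row in self.corr:
            buf.write("\t".join(f"{v:.12g}" for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "CovarianceModel":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        n = int(lines[0].split("\t")[1])
        names = lines[1].split("\t")
        rows = [[float(v) for v in ln.split("\t")] for ln in lines[2:]]
        return cls(n=n, variables=tuple(names), corr=np.array(rows))


def covariance_from_table(
    table: pd.DataFrame, *, strict_singular: bool = False
) -> CovarianceModel:
    """Pearson correlation model from a numeric table, complete cases only.

    Rows with any missing value are dropped (count logged).  Constant
    columns are an error; perfectly collinear columns produce a warning
    unless ``strict_singular`` requests an error.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    complete = table.dropna(axis=0, how="any")
    dropped = len(table) - len(complete)
    if dropped:
        log.info("covariance: dropped %d incomplete rows of %d",
                 dropped, len(table))
    if len(complete) < 5:
        raise ValueError(
            f"only {len(complete)} complete rows; need at least 5"
        )
    values = complete.to_numpy(dtype=float)
    sds = values.std(axis=0, ddof=0)
    bad = [c for c, s in zip(table.columns, sds) if s == 0]
    if bad:
        raise ValueError(f"constant column(s): {bad}")
    corr = np.corrcoef(values, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    if np.any(np.abs(off) > 1 - 1e-12):
        msg = "perfectly collinear columns detected"
        if strict_singular:
            raise ValueError(msg)
        log.warning("covariance: %s", msg)
    return CovarianceModel(
        n=len(complete), variables=tuple(str(c) for c in table.columns),
        corr=corr,
    )


def partial_correlation(
    cov: CovarianceModel, x: str, y: str, S: Sequence[str] = ()
) -> float:
    """Partial correlation of x and y given S, via precision of the submatrix."""
    S = list(S)
    if x in S or y in S:
        raise ValueError("conditioning set must not contain x or y")
    sub = cov.corr[np.ix_(cov.idx(x, y, *S), cov.idx(x, y, *S))]
    try:
        omega = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"singular submatrix for ({x}, {y} | {S}); "
            "collinear conditioning set"
        ) from None
    return float(-omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1]))


def fisher_z_test(
    cov: CovarianceModel, x: str, y: str, S: Sequence[str] = (),
    alpha: float = 0.05,
) -> TestResult:
    """Fisher-Z test of the partial correlation of x and y given S.

    z = atanh(r)·sqrt(n − |S| − 3); two-sided normal p-value; ``independent``
    is ``p > alpha``.  Symmetric in x and y.
    """
    S = list(S)
    df = cov.n - len(S) - 3
    if df < 1:
        raise ValueError(
            f"sample size {cov.n} too small for |S|={len(S)} conditioning"
        )
    r = partial_correlation(cov, x, y, S)
    r = max(min(r, 1 - 1e-12), -(1 - 1e-12))
    z = 0.5 * math.log((1 + r) / (1 - r)) * math.sqrt(df)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=z, p=p, independent=p > alpha)


def local_bic(
    cov: CovarianceModel, y: str, parents: Sequence[str] = (),
    c: float = 2.0,
) -> float:
    """Penalized Gaussian BIC of node y given a parent set.

    score = −n·ln(σ̂²) − c·|parents|·ln(n), with σ̂² the maximum-likelihood
    residual variance of the regression of y on the parents, computed from
    the correlation matrix (so the empty-parent score is exactly 0).
    Higher is better; the score is decomposable and score-equivalent.
    """
    parents = list(parents)
    if y in parents:
        raise ValueError("y must not be its own parent")
    if not parents:
        return 0.0
    iy = cov.idx(y)[0]
    ip = cov.idx(*parents)
    r_yp = cov.corr[iy, ip]
    r_pp = cov.corr[np.ix_(ip, ip)]
    try:
        coef = np.linalg.solve(r_pp, r_yp)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"singular parent Gram matrix for {y} | {parents}"
        ) from None
    sigma2 = float(1.0 - r_yp @ coef)
    sigma2 = max(sigma2, 1e-300)
    return -cov.n * math.log(sigma2) - c * len(parents) * math.log(cov.n)


def total_bic(cov: CovarianceModel, dag: MixedGraph, c: float = 2.0) -> float:
    """Sum of local scores over a DAG's nodes."""
    return sum(local_bic(cov, v, dag.parents(v), c) for v in dag.nodes)


def oracle_independence(truth: MixedGraph, x: str, y: str,
                        S: Iterable[str] = ()) -> bool:
    """Ground-truth independence: delegates to graphical separation."""
    if truth.kind not in ("DAG", "MAG"):
        raise ValueError("oracle requires a DAG or MAG")
    return separated(truth, x, y, S)
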