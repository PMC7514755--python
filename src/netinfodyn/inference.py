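"""Significance testing of information transfer and consensus topology.

A directed link ``i -> j`` is declared for one subject when the
conditional transfer from ``i`` to ``j`` is significant by the nested-
regression F-test: the full model regresses the target's present on the
``m`` lags of all ``M`` processes, the restricted model omits the ``m``
lags of the removed source(s), and

    F = ((RSS_r - RSS_f) / q) / (RSS_f / d),   q = m * |removed|,
    d = N_eff - M * m,  N_eff = N - m,

is referred to the F(q, d) distribution.  Under Gaussian innovations
and a correct lag order this test is exact, which is what makes the
per-subject link decision trustworthy at nominal level.

Across subjects, links are aggregated into a consensus graph: a directed
pair is drawn as a (thin) edge when at least ``thin`` subjects show a
significant conditional transfer, and emphasized (thick) when more than
``thick`` subjects do.  No multiple-testing correction is applied within
a subject; the cross-subject consensus thresholds play that role.  An
optional Benjamini-Hochberg flag is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats as sst

from .preprocess import NetworkSeries
from .varss import _lag_design

__all__ = [
    "LinkTest",
    "SubjectGraph",
    "ConsensusGraph",
    "nested_f_test",
    "subject_link_graph",
    "consensus_graph",
]


@dataclass
class LinkTest:
    """One nested-regression F-test: target, removed sources, F, dof, p."""

    target: int
    removed: tuple[int, ...]
    F: float
    q: int
    d: int
    p: float

    def __post_init__(self) -> None:
        if self.F < 0:
            # numerically tiny negative differences can occur when the
            # restriction removes nothing; clamp at exact zero
            if self.F > -1e-10:
                self.F = 0.0
            else:
                raise ValueError(f"negative F statistic {self.F}")


@dataclass
class SubjectGraph:
    """Per-subject significance results for all directed pairs and targets.

    ``adjacency[i, j]`` is True when source ``i`` transfers significant
    information to target ``j`` conditionally on the rest; ``p_cond``
    holds the corresponding p-values (diagonal NaN).  ``total`` maps each
    target to the F-test of its joint transfer (all sources removed).
    """

    labels: list[str]
    adjacency: NDArray[np.bool_]
    p_cond: NDArray[np.float64]
    F_cond: NDArray[np.float64]
    total: dict[int, LinkTest]
    alpha: float
    m: int

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        M = len(self.labels)
        for i in range(M):
            for j in range(M):
                if i == j:
                    continue
                rows.append({
                    "source": self.labels[i],
                    "target": self.labels[j],
                    "F": self.F_cond[i, j],
                    "p": self.p_cond[i, j],
                    "significant": bool(self.adjacency[i, j]),
                })
        return pd.DataFrame(rows)


@dataclass
class ConsensusGraph:
    """Cross-subject counts of significant directed links.

    ``counts[i, j]`` is the number of subjects whose F-test flagged
    ``i -> j``.  Edge classes follow the display convention: absent
    below ``thin`` subjects, thin from ``thin`` to ``thick``, thick
    above ``thick``.  ``node_mean_T`` carries the across-subject mean
    joint transfer per node, the usual node color-coding.
    """

    labels: list[str]
    counts: NDArray[np.int_]
    n_subjects: int
    thin: int = 7
    thick: int = 12
    node_mean_T: NDArray[np.float64] | None = None

    def edge_class(self, i: int, j: int) -> str:
        c = int(self.counts[i, j])
        if c > self.thick:
            return "thick"
        if c >= self.thin:
            return "thin"
        return "absent"

    @property
    def adjacency(self) -> NDArray[np.bool_]:
        """Links drawn at all (thin or thick)."""
        a = self.counts >= self.thin
        np.fill_diagonal(a, False)
        return a

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        M = len(self.labels)
        for i in range(M):
            for j in range(M):
                if i == j:
                    continue
                rows.append({
                    "source": self.labels[i],
                    "target": self.labels[j],
                    "count": int(self.counts[i, j]),
                    "class": self.edge_class(i, j),
                })
        return pd.DataFrame(rows)

    def to_networkx(self):
        """Directed graph with per-node mean transfer and per-edge counts."""
        import networkx as nx

        g = nx.DiGraph()
        for k, lab in enumerate(self.labels):
            mean_t = None if self.node_mean_T is None else float(self.node_mean_T[k])
            g.add_node(lab, mean_T=mean_t)
        M = len(self.labels)
        for i in range(M):
            for j in range(M):
                if i != j and self.counts[i, j] >= self.thin:
                    g.add_edge(self.labels[i], self.labels[j],
                               count=int(self.counts[i, j]),
                               thick=bool(self.counts[i, j] > self.thick))
        return g


# ---------------------------------------------------------------------------


def _rss(Y_j: NDArray, Z: NDArray, cols: NDArray) -> float:
    g = Z[:, cols]
    b, *_ = np.linalg.lstsq(g, Y_j, rcond=None)
    r = Y_j - g @ b
    return float(r @ r)


def nested_f_test(
    X: NDArray[np.float64] | NetworkSeries,
    j: int,
    removed: int | tuple[int, ...] | list[int],
    m: int,
) -> LinkTest:
    """F-test comparing the full lag regression with a source-restricted one.

    Both models are estimated by OLS without intercept on the same
    ``N - m`` samples; the restricted model genuinely re-estimates all
    remaining coefficients.  ``removed`` may be one source or a set (the
    joint-transfer test removes all sources of target ``j``).
    """
    if isinstance(X, NetworkSeries):
        X = X.X
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    removed = (removed,) if np.isscalar(removed) else tuple(int(r) for r in removed)
    if j in removed:
        raise ValueError("cannot remove the target's own past")
    q = m * len(removed)
    d = (N - m) - M * m
    if d <= 0:
        raise ValueError(f"nonpositive denominator dof d={d}; series too short")

    Y, Z = _lag_design(X, m)
    y = Y[:, j]
    all_cols = np.arange(m * M)
    keep_cols = np.array([c for c in all_cols if (c % M) not in removed])
    rss_f = _rss(y, Z, all_cols)
    rss_r = _rss(y, Z, keep_cols)
    F = max((rss_r - rss_f), 0.0) / q / (rss_f / d)
    p = float(sst.f.sf(F, q, d))
    return LinkTest(target=j, removed=removed, F=float(F), q=q, d=d, p=p)


def subject_link_graph(
    X: NDArray[np.float64] | NetworkSeries,
    m: int,
    alpha: float = 0.05,
    labels: list[str] | None = None,
    fdr: bool = False,
) -> SubjectGraph:
    """All directed-pair F-tests for one subject, plus joint-transfer tests.

    ``adjacency[i, j]`` marks ``p < alpha`` for the conditional transfer
    ``i -> j``.  With ``fdr=True`` the 42 pairwise p-values are instead
    thresholded by Benjamini-Hochberg at level ``alpha`` (off by default:
    the cross-subject consensus is the intended multiplicity control).
    """
    if isinstance(X, NetworkSeries):
        if labels is None:
            labels = list(X.labels)
        X = X.X
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    labels = labels or [f"X{k + 1}" for k in range(M)]
    p_cond = np.full((M, M), np.nan)
    F_cond = np.full((M, M), np.nan)
    for jt in range(M):
        for i in range(M):
            if i == jt:
                continue
            lt = nested_f_test(X, jt, i, m)
            p_cond[i, jt] = lt.p
            F_cond[i, jt] = lt.F
    total = {
        jt: nested_f_test(X, jt, tuple(i for i in range(M) if i != jt), m)
        for jt in range(M)
    }
    if fdr:
        off = ~np.eye(M, dtype=bool)
        pv = p_cond[off]
        adj_flat = _bh_reject(pv, alpha)
        adjacency = np.zeros((M, M), dtype=bool)
        adjacency[off] = adj_flat
    else:
        adjacency = p_cond < alpha
        np.fill_diagonal(adjacency, False)
    return SubjectGraph(labels=labels, adjacency=adjacency, p_cond=p_cond,
                        F_cond=F_cond, total=total, alpha=alpha, m=m)


def _bh_reject(p: NDArray[np.float64], alpha: float) -> NDArray[np.bool_]:
    n = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    k = np.max(np.where(passed)[0]) + 1 if np.any(passed) else 0
    out = np.zeros(n, dtype=bool)
    out[order[:k]] = True
    return out


def consensus_graph(
    graphs: list[SubjectGraph],
    measures: list | None = None,
    thin: int = 7,
    thick: int = 12,
) -> ConsensusGraph:
    """Aggregate per-subject link graphs into the consensus topology.

    ``counts[i, j]`` is the number of subjects with a significant
    ``i -> j`` conditional transfer; edges are drawn when the count
    reaches ``thin`` and emphasized when it exceeds ``thick``.  When
    ``measures`` (per-subject :class:`~netinfodyn.infodyn.InfoMeasures`)
    are supplied, nodes carry the across-subject mean joint transfer.
    """
    if not graphs:
        raise ValueError("need at least one subject graph")
    labels = graphs[0].labels
    M = len(labels)
    for g in graphs:
        if g.adjacency.shape != (M, M) or g.labels != labels:
            raise ValueError("subject graphs have mismatching shapes or labels")
    counts = np.zeros((M, M), dtype=int)
    for g in graphs:
        counts += g.adjacency.astype(int)
    np.fill_diagonal(counts, 0)
    node_mean_T = None
    if measures:
        node_mean_T = np.mean([m.T for m in measures], axis=0)
    return ConsensusGraph(labels=labels, counts=counts, n_subjects=len(graphs),
                          thin=thin, thick=thick, node_mean_T=node_mean_T)
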