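"""Information decomposition of a stationary Gaussian network process.

For each node (target process) ``j`` of a jointly Gaussian network, the
information content of the present sample, ``H_j``, splits exactly into

    H_j = S_j + T_j + N_j

where ``S_j`` is the information storage (predictability from the
target's own past), ``T_j`` the joint transfer entropy (additional
predictability from the pasts of all other nodes), and ``N_j`` the new
information (the residual unpredictable part).  Under Gaussianity every
term is a log-ratio of partial variances:

    H_j          = 1/2 ln(2*pi*e * sigma_j^2)
    S_j          = 1/2 ln(sigma_j^2 / sigma_{j|j}^2)
    T_j          = 1/2 ln(sigma_{j|j}^2 / sigma_{j|j,s}^2)
    N_j          = 1/2 ln(2*pi*e * sigma_{j|j,s}^2)
    T_{i->j|k}   = 1/2 ln(sigma_{j|j,k}^2 / sigma_{j|j,s}^2)

with ``sigma_{j|A}^2`` the prediction-error variance of the present of
``j`` given the pasts in ``A`` (``s`` = all sources, ``k`` = all sources
except ``i``).  All measures are in nats.

Two backends compute the partial variances from data:

* ``"state-space"`` (default): fit one VAR model, derive every partial
  variance analytically through reduced state-space submodels and the
  Riccati equation.
* ``"regression"``: an explicit ordinary-least-squares regression of the
  target's present on each lag set; slower, but serves as a transparent
  finite-sample oracle.

Because the decomposition telescopes, ``H = S + T + N`` holds to
round-off for either backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import varss
from .varss import PartialVariances, VarModel

__all__ = [
    "InfoMeasures",
    "node_entropy",
    "node_new_information",
    "node_storage",
    "node_total_transfer",
    "conditional_transfer",
    "measures_from_partials",
    "model_implied_measures",
    "regression_partial_variances",
    "decompose_network",
]

LN_2PIE = float(np.log(2.0 * np.pi * np.e))

Backend = Literal["state-space", "regression"]


@dataclass
class InfoMeasures:
    """Per-node information measures and the conditional-transfer matrix.

    ``H``, ``S``, ``T``, ``N`` are length-M arrays (nats).  ``Tcond`` is
    an ``(M, M)`` matrix with ``Tcond[i, j] = T_{i->j|k}`` (information
    transferred from source ``i`` to target ``j`` conditioned on all
    other sources); the diagonal is NaN.  ``labels`` names the nodes.
    """

    labels: list[str]
    H: NDArray[np.float64]
    S: NDArray[np.float64]
    T: NDArray[np.float64]
    N: NDArray[np.float64]
    Tcond: NDArray[np.float64]
    backend: str = "model"
    m: int = 0
    n_samples: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.labels)

    @property
    def predictive_information(self) -> NDArray[np.float64]:
        return self.S + self.T

    def check_invariants(self, tol: float = 1e-8, nonneg_tol: float = 1e-10) -> None:
        resid = np.max(np.abs(self.H - (self.S + self.T + self.N)))
        if resid >= tol:
            raise AssertionError(f"decomposition identity violated: residual {resid:.3e}")
        if np.min(self.S) < -nonneg_tol or np.min(self.T) < -nonneg_tol:
            raise AssertionError("negative storage or transfer")
        off = self.Tcond[~np.eye(self.M, dtype=bool)]
        if np.min(off) < -nonneg_tol:
            raise AssertionError("negative conditional transfer")

    def to_frame(self, subject: str = "", state: str = "") -> pd.DataFrame:
        """Tidy table: one row per node with H, S, T, N."""
        return pd.DataFrame(
            {
                "subject": subject,
                "state": state,
                "node": self.labels,
                "H": self.H,
                "S": self.S,
                "T": self.T,
                "N": self.N,
            }
        )

    def tcond_frame(self) -> pd.DataFrame:
        """Square conditional-transfer matrix, rows = sources, cols = targets."""
        return pd.DataFrame(self.Tcond, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Scalar measures
# ---------------------------------------------------------------------------


def node_entropy(sigma2: float) -> float:
    """Entropy (nats) of a Gaussian variable with variance ``sigma2``."""
    if sigma2 <= 0:
        raise ValueError(f"variance must be positive, got {sigma2}")
    return 0.5 * (LN_2PIE + np.log(sigma2))


def node_new_information(pv: PartialVariances) -> float:
    """New information: entropy of the innovation given the whole network's past."""
    if pv.sigma2_full <= 0:
        raise ValueError("full-model partial variance must be positive")
    return 0.5 * (LN_2PIE + np.log(pv.sigma2_full))


def node_storage(pv: PartialVariances) -> float:
    """Information storage: predictability of the present from the own past."""
    if pv.sigma2 <= 0 or pv.sigma2_self <= 0:
        raise ValueError("variances must be positive")
    return 0.5 * np.log(pv.sigma2 / pv.sigma2_self)


def node_total_transfer(pv: PartialVariances) -> float:
    """Joint transfer entropy from all sources to the target."""
    if pv.sigma2_self <= 0 or pv.sigma2_full <= 0:
        raise ValueError("variances must be positive")
    return 0.5 * np.log(pv.sigma2_self / pv.sigma2_full)


def conditional_transfer(pv: PartialVariances, i: int) -> float:
    """Conditional transfer entropy from source ``i`` to the target of ``pv``."""
    if i == pv.target:
        raise ValueError("conditional transfer from a node to itself is undefined")
    s2 = pv.sigma2_minus[i]
    if s2 <= 0 or pv.sigma2_full <= 0:
        raise ValueError("variances must be positive")
    return 0.5 * np.log(s2 / pv.sigma2_full)


def measures_from_partials(
    partials: list[PartialVariances],
    labels: list[str] | None = None,
    sigma2_override: NDArray[np.float64] | None = None,
    **meta,
) -> InfoMeasures:
    """Assemble an :class:`InfoMeasures` from one ``PartialVariances`` per node.

    ``sigma2_override`` replaces the model-implied process variance in
    ``H`` and ``S`` (used with standardized data, where the sample
    variance is the natural choice); the decomposition identity is
    preserved because ``H`` and ``S`` shift together.
    """
    M = len(partials)
    labels = labels or [f"X{j + 1}" for j in range(M)]
    H = np.empty(M)
    S = np.empty(M)
    T = np.empty(M)
    N = np.empty(M)
    Tc = np.full((M, M), np.nan)
    for j, pv in enumerate(partials):
        s2 = float(sigma2_override[j]) if sigma2_override is not None else pv.sigma2
        H[j] = node_entropy(s2)
        S[j] = 0.5 * np.log(s2 / pv.sigma2_self)
        T[j] = node_total_transfer(pv)
        N[j] = node_new_information(pv)
        for i in pv.sigma2_minus:
            Tc[i, j] = conditional_transfer(pv, i)
    return InfoMeasures(labels=labels, H=H, S=S, T=T, N=N, Tcond=Tc, **meta)


def model_implied_measures(var: VarModel, labels: list[str] | None = None) -> InfoMeasures:
    """Exact information measures implied by a stable VAR model (no data)."""
    partials = [varss.partial_variances(var, j) for j in range(var.M)]
    return measures_from_partials(
        partials, labels=labels, backend="model", m=var.m, n_samples=0
    )


# ---------------------------------------------------------------------------
# Regression backend
# ---------------------------------------------------------------------------


def regression_partial_variances(
    X: NDArray[np.float64], m: int, lags: int | None = None
) -> list[PartialVariances]:
    """Finite-sample partial variances by explicit nested OLS regressions.

    For each target ``j`` the present sample is regressed on (a) its own
    past lags, (b) the past lags of every process, and (c) the past lags
    of every process except each source in turn.  Residual variances use
    the ``1/(N - lags)`` normalization, matching :func:`varss.fit_var`.

    ``lags`` is the regression depth for every lag set and defaults to
    ``m``, the truncated-past definition of the measures.  Reduced
    subsets of a VAR(m) network are generally *not* Markov of order m
    (their exact predictors involve the infinite past), so an oracle
    that must reproduce steady-state (Riccati) partial variances passes
    ``lags`` well above ``m`` — about 20 suffices for moderately
    coupled networks.

    All regressions share one Gram matrix, so the cost is one
    factorization per lag subset rather than per sample.
    """
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    L = m if lags is None else max(m, int(lags))
    Y, Z = varss._lag_design(X, L)
    n_eff = N - L
    G = Z.T @ Z  # (LM, LM)
    ZtY = Z.T @ Y  # (LM, M)
    yty = np.einsum("ij,ij->j", Y, Y)  # per-target sum of squares

    def rss(cols: np.ndarray, j: int) -> float:
        g = G[np.ix_(cols, cols)]
        b = np.linalg.solve(g, ZtY[cols, j])
        return float(yty[j] - ZtY[cols, j] @ b)

    lag_cols = {i: np.array([lag * M + i for lag in range(L)]) for i in range(M)}
    all_cols = np.arange(L * M)

    out: list[PartialVariances] = []
    for j in range(M):
        sigma2 = float(Y[:, j] @ Y[:, j]) / n_eff
        s_self = rss(lag_cols[j], j) / n_eff
        s_full = rss(all_cols, j) / n_eff
        minus: dict[int, float] = {}
        for i in range(M):
            if i == j:
                continue
            cols = np.concatenate([lag_cols[k] for k in range(M) if k != i])
            minus[i] = rss(np.sort(cols), j) / n_eff
        out.append(
            PartialVariances(
                target=j,
                sigma2=sigma2,
                sigma2_self=s_self,
                sigma2_full=s_full,
                sigma2_minus=minus,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end decomposition of an observed network
# ---------------------------------------------------------------------------


def decompose_network(
    X: NDArray[np.float64],
    m: int | None = None,
    labels: list[str] | None = None,
    backend: Backend = "state-space",
    max_order: int = 12,
) -> InfoMeasures:
    """Full information decomposition of an ``(M, N)`` standardized series.

    Fits a VAR model (order ``m``, or AIC-selected up to ``max_order``
    when ``m`` is None), computes every partial variance with the chosen
    backend, and returns all node measures plus the conditional-transfer
    matrix.  ``H`` uses the sample variance of each (standardized) row.

    An unstable fitted VAR is reported via :class:`varss.UnstableModelError`
    (state-space backend only; the regression backend needs no stability).
    """
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    if m is None:
        m = select_order_with_fallback(X, max_order)
    # variance of the same samples the regressions predict (no-intercept,
    # 1/(N-m) convention): keeps the finite-sample measures exactly nested
    sample_var = np.mean(X[:, m:] ** 2, axis=1)

    if backend == "regression":
        partials = regression_partial_variances(X, m)
    elif backend == "state-space":
        var = varss.fit_var(X, m)
        partials = [varss.partial_variances(var, j) for j in range(M)]
    else:
        raise ValueError(f"unknown backend {backend!r}")

    meas = measures_from_partials(
        partials,
        labels=labels,
        sigma2_override=sample_var,
        backend=backend,
        m=m,
        n_samples=N,
    )
    # identity is exact by telescoping; non-negativity is exact for the
    # regression backend and holds to numerical slack for state-space
    meas.check_invariants(
        tol=1e-8, nonneg_tol=1e-10 if backend == "regression" else 1e-6
    )
    return meas


def select_order_with_fallback(X: NDArray[np.float64], max_order: int) -> int:
    """AIC order selection, shrinking ``max_order`` if the series is short."""
    M, N = X.shape
    mo = max_order
    while mo > 1 and N <= M * mo + 10:
        mo -= 1
    return varss.select_order_aic(X, mo)
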