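"""Vector-autoregressive modelling and state-space partial variances.

This module provides the linear-Gaussian machinery on which every
information measure rests: least-squares VAR fitting with AIC order
selection, conversion of a VAR(m) to its innovations-form state space,
and the computation of *partial variances* — the prediction-error
variances of the target's present given selected past histories —
through submodel reduction and the discrete algebraic Riccati equation
(DARE).

Partial variances are defined with respect to a fitted (or specified)
VAR model of the whole network.  Removing processes from the
observation equation of the state-space form and re-solving for the
steady-state innovation covariance yields the prediction error of the
target given only the retained pasts, without re-fitting anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import linalg as sla

__all__ = [
    "VarModel",
    "StateSpaceModel",
    "PartialVariances",
    "select_order_aic",
    "fit_var",
    "var_to_ss",
    "reduced_innovation_variance",
    "partial_variances",
    "companion_matrix",
    "process_covariance",
]


class UnstableModelError(ValueError):
    """Raised when a VAR model is not stable (companion spectral radius >= 1)."""


class DareConvergenceError(RuntimeError):
    """Raised when the Riccati solver fails; carries the residual norm."""


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class VarModel:
    """A fitted or specified VAR(m) model ``X_n = sum_l A[l] X_{n-l} + U_n``.

    Attributes
    ----------
    m : model order (number of lags).
    M : process dimension.
    A : list of ``m`` coefficient blocks, each ``(M, M)``; ``A[l][j, i]``
        multiplies source ``i`` at lag ``l+1`` in the equation of target ``j``.
    Sigma : ``(M, M)`` innovation (residual) covariance.
    n_used : effective number of samples behind the fit (0 for specified models).
    """

    m: int
    M: int
    A: list[NDArray[np.float64]]
    Sigma: NDArray[np.float64]
    n_used: int = 0

    def __post_init__(self) -> None:
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if len(self.A) != self.m:
            raise ValueError(f"expected {self.m} coefficient blocks, got {len(self.A)}")
        for a in self.A:
            if a.shape != (self.M, self.M):
                raise ValueError(f"coefficient block shape {a.shape} != ({self.M}, {self.M})")
        if self.Sigma.shape != (self.M, self.M):
            raise ValueError("Sigma shape mismatch")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(self.A)))))

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "M": self.M,
            "A": [a.tolist() for a in self.A],
            "Sigma": self.Sigma.tolist(),
            "n_used": self.n_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VarModel":
        return cls(m=d["m"], M=d["M"], A=[np.array(a) for a in d["A"]],
                   Sigma=np.array(d["Sigma"]), n_used=d.get("n_used", 0))


@dataclass
class StateSpaceModel:
    """Innovations-form state space of a VAR(m).

    State ``Z_n = [X_{n-1}; ...; X_{n-m}]`` (dimension ``mM``), with

        Z_{n+1} = A_ss Z_n + K U_n,      X_n = C Z_n + U_n

    where ``C = [A_1 ... A_m]`` stacks the coefficient blocks,
    ``A_ss`` is the companion matrix, ``K = [I; 0; ...; 0]`` injects the
    innovation into the first block, and ``V = Sigma`` is the innovation
    covariance of the observed processes.
    """

    A_ss: NDArray[np.float64]
    C: NDArray[np.float64]
    K: NDArray[np.float64]
    V: NDArray[np.float64]
    M: int
    m: int


@dataclass
class PartialVariances:
    """All partial variances needed for one target's information measures.

    ``sigma2`` is the stationary process variance of the target;
    ``sigma2_self`` conditions on the target's own past only;
    ``sigma2_full`` conditions on the past of the whole network;
    ``sigma2_minus[i]`` conditions on everything except source ``i``.
    """

    target: int
    sigma2: float
    sigma2_self: float
    sigma2_full: float
    sigma2_minus: dict[int, float] = field(default_factory=dict)

    def validate(self, tol: float = 1e-10) -> None:
        if self.sigma2 < -tol or self.sigma2_self < -tol or self.sigma2_full < -tol:
            raise ValueError("negative partial variance")
        if self.sigma2_self > self.sigma2 + tol * max(1.0, self.sigma2):
            raise ValueError("sigma2_self exceeds process variance")
        for i, v in self.sigma2_minus.items():
            if not (self.sigma2_full <= v + tol and v <= self.sigma2 + tol):
                raise ValueError(
                    f"nesting violated for source {i}: "
                    f"{self.sigma2_full} <= {v} <= {self.sigma2} fails"
                )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _lag_design(X: NDArray[np.float64], m: int, start: int | None = None):
    """Build the regression of X_n on [X_{n-1}; ...; X_{n-m}].

    Returns (Y, Z): targets ``(N_eff, M)`` and design ``(N_eff, m*M)``,
    with rows starting at sample ``start`` (default ``m``).  The design
    columns are ordered lag-major: ``[X_{n-1}(all M), X_{n-2}(all M), ...]``.
    """
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    s = m if start is None else start
    if N - s < 1:
        raise ValueError("series too short for requested order")
    Y = X[:, s:].T
    Z = np.empty((N - s, m * M))
    for lag in range(1, m + 1):
        Z[:, (lag - 1) * M: lag * M] = X[:, s - lag: N - lag].T
    return Y, Z


def fit_var(X: NDArray[np.float64], m: int) -> VarModel:
    """Least-squares fit of a VAR(m) to an ``(M, N)`` zero-mean series.

    No intercept is included: the series are assumed standardized (or at
    least centred).  The residual covariance uses the ``1/(N - m)``
    normalization so that it matches plain regression residual variances.

    Raises
    ------
    ValueError
        If the sample is too short for identifiability (``N - m <= M*m``)
        or the design is rank deficient (collinear rows are named).
    """
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    if N - m <= M * m:
        raise ValueError(
            f"too few samples for identifiability: need N - m > M*m, "
            f"got N={N}, m={m}, M={M}"
        )
    Y, Z = _lag_design(X, m)
    G = Z.T @ Z
    rank = np.linalg.matrix_rank(G)
    if rank < m * M:
        # identify collinear rows for the error message
        row_ranks = [np.linalg.matrix_rank(np.corrcoef(X)) if M > 1 else 1]
        raise ValueError(
            f"rank-deficient lag design (rank {rank} < {m * M}); "
            f"check for collinear series (correlation-matrix rank {row_ranks[0]})"
        )
    B = np.linalg.solve(G, Z.T @ Y)  # (m*M, M): columns are per-target coefs
    resid = Y - Z @ B
    Sigma = resid.T @ resid / (N - m)
    A = [B[(lag - 1) * M: lag * M, :].T for lag in range(1, m + 1)]
    return VarModel(m=m, M=M, A=A, Sigma=Sigma, n_used=N - m)


def fit_var_residuals(X: NDArray[np.float64], m: int) -> NDArray[np.float64]:
    """Residual matrix ``(N - m, M)`` of the least-squares VAR(m) fit."""
    X = np.asarray(X, dtype=float)
    Y, Z = _lag_design(X, m)
    B = np.linalg.lstsq(Z, Y, rcond=None)[0]
    return Y - Z @ B


def select_order_aic(X: NDArray[np.float64], max_order: int = 12) -> int:
    """Select the VAR order by the Akaike information criterion.

    All candidate orders ``p = 1..max_order`` are fitted on the common
    sample that drops the first ``max_order`` points, so their
    likelihoods are comparable.  AIC(p) = N_eff * ln det(Sigma_hat(p))
    + 2 p M^2; ties resolve to the smallest order.
    """
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    if N <= M * max_order + 10:
        raise ValueError("series too short for the requested max_order")
    n_eff = N - max_order
    best_p, best_aic = None, np.inf
    for p in range(1, max_order + 1):
        Y, Z = _lag_design(X, p, start=max_order)
        B = np.linalg.lstsq(Z, Y, rcond=None)[0]
        resid = Y - Z @ B
        Sigma = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            continue
        aic = n_eff * logdet + 2.0 * p * M * M
        if aic < best_aic - 1e-12:
            best_aic, best_p = aic, p
    if best_p is None:
        raise ValueError("all candidate fits were singular")
    return best_p


# ---------------------------------------------------------------------------
# State-space form and partial variances
# ---------------------------------------------------------------------------


def companion_matrix(A: Sequence[NDArray[np.float64]]) -> NDArray[np.float64]:
    """Companion (block) matrix of the coefficient blocks ``A``."""
    A = [np.asarray(a, dtype=float) for a in A]
    m = len(A)
    M = A[0].shape[0]
    F = np.zeros((m * M, m * M))
    F[:M, :] = np.hstack(A)
    if m > 1:
        F[M:, :-M] = np.eye((m - 1) * M)
    return F


def var_to_ss(var: VarModel) -> StateSpaceModel:
    """Innovations-form state space of a stable VAR(m); see class docstring."""
    if not var.is_stable:
        raise UnstableModelError(
            f"VAR companion spectral radius {var.spectral_radius:.4f} >= 1; "
            "information measures are undefined for unstable models"
        )
    M, m = var.M, var.m
    A_ss = companion_matrix(var.A)
    C = np.hstack(var.A)  # (M, mM)
    K = np.zeros((m * M, M))
    K[:M, :] = np.eye(M)
    return StateSpaceModel(A_ss=A_ss, C=C, K=K, V=var.Sigma.copy(), M=M, m=m)


def process_covariance(var: VarModel) -> NDArray[np.float64]:
    """Stationary covariance of the VAR process via the discrete Lyapunov equation.

    Solves ``P = F P F' + Q`` for the companion-form state and returns the
    leading ``(M, M)`` block, the covariance of ``X_n``.
    """
    if not var.is_stable:
        raise UnstableModelError("process covariance undefined for unstable VAR")
    M, m = var.M, var.m
    F = companion_matrix(var.A)
    Q = np.zeros((m * M, m * M))
    Q[:M, :M] = var.Sigma
    P = sla.solve_discrete_lyapunov(F, Q)
    return P[:M, :M]


def _dare_fixed_point(A, C, Q, R, S, tol: float = 1e-12, max_iter: int = 10_000):
    """Riccati fixed-point iteration fallback (filtering form with cross term)."""
    P = Q.copy()
    for _ in range(max_iter):
        CPC = C @ P @ C.T + R
        G = (A @ P @ C.T + S) @ np.linalg.inv(CPC)
        P_new = A @ P @ A.T + Q - G @ (A @ P @ C.T + S).T
        P_new = 0.5 * (P_new + P_new.T)
        if np.max(np.abs(P_new - P)) < tol:
            return P_new
        P = P_new
    raise DareConvergenceError(
        f"Riccati iteration did not converge; last update norm "
        f"{np.max(np.abs(P_new - P)):.3e}"
    )


def reduced_innovation_variance(
    ss: StateSpaceModel, keep: Sequence[int]
) -> NDArray[np.float64]:
    """Innovation covariance of a reduced-observation submodel.

    The state equation is kept intact; only the observation rows of the
    processes *not* in ``keep`` are dropped.  The steady-state innovation
    covariance of the retained processes is found by solving the
    filtering DARE of the reduced model, whose state noise ``K U_n`` and
    observation noise ``U_keep,n`` are correlated.

    Parameters
    ----------
    ss : full-observation innovations-form model.
    keep : nonempty subset of process indices to retain (0-based).

    Returns
    -------
    ``(len(keep), len(keep))`` innovation covariance, rows/cols ordered
    as in ``keep``.
    """
    keep = sorted(set(int(k) for k in keep))
    if not keep:
        raise ValueError("keep must be a nonempty subset of process indices")
    if keep[0] < 0 or keep[-1] >= ss.M:
        raise ValueError("keep indices out of range")
    if len(keep) == ss.M:
        return ss.V.copy()

    A = ss.A_ss
    C = ss.C[keep, :]
    # state noise K U_n: cov Q; obs noise U_keep: cov R; cross-cov S
    Q = ss.K @ ss.V @ ss.K.T
    R = ss.V[np.ix_(keep, keep)]
    S = ss.K @ ss.V[:, keep]
    try:
        # control-form DARE with a=A', b=C', s=S solves the filtering DARE
        P = sla.solve_discrete_are(A.T, C.T, Q, R, s=S)
    except (np.linalg.LinAlgError, ValueError):
        P = _dare_fixed_point(A, C, Q, R, S)
    V_red = C @ P @ C.T + R
    # guard: solver must have actually solved the equation
    CPC = C @ P @ C.T + R
    G = (A @ P @ C.T + S) @ np.linalg.inv(CPC)
    resid = A @ P @ A.T + Q - G @ (A @ P @ C.T + S).T - P
    rnorm = float(np.max(np.abs(resid)))
    if rnorm > 1e-6 * max(1.0, float(np.max(np.abs(P)))):
        raise DareConvergenceError(f"DARE residual norm {rnorm:.3e} too large")
    return 0.5 * (V_red + V_red.T)


def partial_variances(var: VarModel, j: int) -> PartialVariances:
    """All partial variances of target ``j`` under a stable VAR model.

    * ``sigma2``      — stationary variance (discrete Lyapunov solution);
    * ``sigma2_self`` — innovation of the submodel observing only ``j``;
    * ``sigma2_minus[i]`` — innovation of the submodel dropping source ``i``;
    * ``sigma2_full`` — ``Sigma[j, j]`` of the full model (no reduction).
    """
    ss = var_to_ss(var)
    M = var.M
    sigma2 = float(process_covariance(var)[j, j])
    sigma2_self = float(reduced_innovation_variance(ss, [j])[0, 0])
    sigma2_full = float(var.Sigma[j, j])
    minus: dict[int, float] = {}
    for i in range(M):
        if i == j:
            continue
        kept = [k for k in range(M) if k != i]
        V = reduced_innovation_variance(ss, kept)
        minus[i] = float(V[kept.index(j), kept.index(j)])
    pv = PartialVariances(
        target=j,
        sigma2=sigma2,
        sigma2_self=sigma2_self,
        sigma2_full=sigma2_full,
        sigma2_minus=minus,
    )
    pv.validate()
    return pv
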