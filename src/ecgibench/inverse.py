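"""Regularized inverse solvers for epicardial potential reconstruction.

Fourteen regularization methods under a common scikit-learn-style
estimator interface: six Tikhonov variants (orders 0/1/2, with a global
or an instantaneous L-curve regularization parameter), three truncated
(generalized) SVD methods, damped SVD, total variation, Bayesian MAP with
an empirical spatial prior, Greensite spatio-temporal whitening, and
iteration-limited GMRES on the normal equations.

Every estimator follows ``fit(A, mesh=...)`` / ``predict(Y)``: ``fit``
precomputes the spectral factorization of the transfer operator together
with the regularization operator, ``predict`` maps body-surface
measurements to epicardial estimates. Module-level functions mirror the
estimators for one-shot use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
import scipy.linalg as sla
from sklearn.base import BaseEstimator

from .mesh import TriMesh
from .phantom import PotentialField

__all__ = [
    "RegularizationOperator",
    "regularization_operator",
    "SpectralFactorization",
    "tikhonov_instant",
    "tikhonov_global",
    "svd_filter_solve",
    "tsvd_higher_order",
    "tv_solve",
    "estimate_prior_covariance",
    "bayes_map",
    "greensite_solve",
    "gmres_solve",
    "lcurve_lambda",
    "lcurve_truncation",
    "oracle_lambda",
    "TikhonovInverse",
    "TSVDInverse",
    "DSVDInverse",
    "TVInverse",
    "BayesMAPInverse",
    "GreensiteInverse",
    "GMRESInverse",
    "SOLVER_REGISTRY",
    "make_solver",
]

_RANK_TOL = 1e-12


# ---------------------------------------------------------------------------
# regularization operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegularizationOperator:
    """Penalty operator L of order 0 (identity), 1 (gradient), 2 (Laplacian)."""

    kind: str
    matrix: np.ndarray
    order: int


def regularization_operator(mesh: Optional[TriMesh],
                            order: int) -> RegularizationOperator:
    """Build the order-0/1/2 regularization operator for a mesh.

    Order 0 is the N x N identity (``mesh`` may be None if N is supplied
    through the transfer matrix instead; see the estimators). Order 1 is
    the E x N edge-incidence difference operator with entries
    +-1/edge_length (a discrete gradient; only ``L^T L`` enters the normal
    equations, so the rectangular form is fine). Order 2 is the umbrella
    graph Laplacian ``diag(degree) - adjacency`` row-normalized by degree,
    whose rows sum to zero.
    """
    if order == 0:
        if mesh is None:
            raise ValueError("order 0 needs a mesh (or pass L explicitly)")
        n = mesh.n_nodes
        return RegularizationOperator("identity", np.eye(n), 0)
    if mesh is None:
        raise ValueError("orders 1 and 2 require a mesh")
    n = mesh.n_nodes
    edges = mesh.edges
    lengths = mesh.edge_lengths
    if order == 1:
        L = np.zeros((len(edges), n))
        rows = np.arange(len(edges))
        L[rows, edges[:, 0]] = -1.0 / lengths
        L[rows, edges[:, 1]] = 1.0 / lengths
        return RegularizationOperator("gradient", L, 1)
    if order == 2:
        adj = np.zeros((n, n))
        adj[edges[:, 0], edges[:, 1]] = 1.0
        adj[edges[:, 1], edges[:, 0]] = 1.0
        deg = adj.sum(axis=1)
        L = np.eye(n) - adj / deg[:, None]
        return RegularizationOperator("laplacian", L, 2)
    raise ValueError(f"order must be 0, 1 or 2, got {order}")


def _as_matrix(A) -> np.ndarray:
    from .forward import TransferMatrix
    if isinstance(A, TransferMatrix):
        return A.entries
    return np.atleast_2d(np.asarray(A, dtype=float))


def _as_operator(L, n: int) -> np.ndarray:
    if L is None:
        return np.eye(n)
    if isinstance(L, RegularizationOperator):
        return L.matrix
    return np.atleast_2d(np.asarray(L, dtype=float))


# ---------------------------------------------------------------------------
# spectral factorization (SVD for L = I, GSVD otherwise)
# ---------------------------------------------------------------------------

class SpectralFactorization:
    """(Generalized) SVD of the pair (A, L), supporting filtered solves.

    For ``L = I`` this is the plain SVD of A. Otherwise the GSVD is built
    via the QR of the stacked matrix [A; L] followed by an SVD of the
    upper orthonormal block (the cosine-sine route):
    ``A = U diag(c) Z`` and ``L = V diag(s) Z`` with ``c^2 + s^2 = 1``
    and generalized values ``gamma = c/s`` sorted in decreasing order.

    A filtered solution is ``x = sum_i f_i (u_i^T y / c_i) x_i`` over the
    components with ``c_i > 0``, where the ``x_i`` are the columns of
    ``Z^{-1}``.
    """

    def __init__(self, A, L=None):
        A = _as_matrix(A)
        m, n = A.shape
        self.m, self.n = m, n
        self.A = A
        identity = L is None or (
            isinstance(L, RegularizationOperator) and L.order == 0) or (
            not isinstance(L, RegularizationOperator)
            and np.asarray(L).shape == (n, n)
            and np.allclose(np.asarray(L), np.eye(n)))
        if identity:
            U, sv, Vt = np.linalg.svd(A, full_matrices=True)
            r = int(np.sum(sv > _RANK_TOL * max(sv[0], 1.0))) if len(sv) else 0
            self.U = U                        # m x m
            self.c = sv[:r]                   # "cosines" = singular values
            self.s = np.ones(r)               # unit seminorm weights
            self.gamma = sv[:r]
            self.basis = Vt[:r].T             # n x r
            self.rank = r
            self.is_svd = True
            self.sigma1 = sv[0] if len(sv) else 0.0
        else:
            Lm = _as_operator(L, n)
            M = np.vstack([A, Lm])
            Q, R = np.linalg.qr(M)            # Q: (m+p) x n, R: n x n
            Q1 = Q[:m]
            U, c, Wt = np.linalg.svd(Q1, full_matrices=True)
            c = np.clip(c, 0.0, 1.0)
            c_full = np.zeros(n)
            c_full[: len(c)] = c
            s_full = np.sqrt(np.clip(1.0 - c_full ** 2, 0.0, None))
            Z = Wt @ R                         # n x n
            X = np.linalg.solve(Z, np.eye(n))  # solution basis, columns x_i
            r = int(np.sum(c_full > _RANK_TOL))
            self.U = U                         # m x m
            self.c = c_full[:r]
            self.s = s_full[:r]
            with np.errstate(divide="ignore"):
                self.gamma = np.where(self.s > 0, self.c / self.s, np.inf)
            self.basis = X[:, :r]              # n x r
            self.rank = r
            self.is_svd = False
            self.sigma1 = float(np.linalg.svd(A, compute_uv=False)[0])

    # -- filter factors ----------------------------------------------------
    def filter_factors(self, lam: float, kind: str = "tik") -> np.ndarray:
        g = self.gamma
        fin = np.isfinite(g)
        f = np.ones_like(g)
        if kind == "tik":
            f[fin] = g[fin] ** 2 / (g[fin] ** 2 + lam)
        elif kind == "dsvd":
            f[fin] = g[fin] / (g[fin] + lam)
        else:
            raise ValueError(f"unknown filter kind {kind!r}")
        return f

    def coefficients(self, Y: np.ndarray) -> np.ndarray:
        """Generalized Fourier coefficients beta = U^T Y (m x T)."""
        Y = np.atleast_2d(np.asarray(Y, float))
        if Y.shape[0] != self.m:
            Y = Y.reshape(self.m, -1)
        return self.U.T @ Y

    def solve_filtered(self, Y, f: np.ndarray) -> np.ndarray:
        """x = basis @ diag(f/c) @ beta[:rank]; f may be (r,) or (r, T)."""
        beta = self.coefficients(Y)[: self.rank]
        q = (f.T / self.c).T * beta if f.ndim == 2 else (f / self.c)[:, None] * beta
        return self.basis @ q

    def solve_truncated(self, Y, k: int) -> np.ndarray:
        if not (1 <= k <= self.rank):
            raise ValueError(f"truncation k must be in [1, {self.rank}]")
        f = np.zeros(self.rank)
        f[:k] = 1.0
        return self.solve_filtered(Y, f)

    def rho2_eta2(self, beta: np.ndarray, f: np.ndarray):
        """Squared residual and seminorm for filter factors ``f``.

        ``beta`` is (m, T); ``f`` is (G, r) over a parameter grid.
        Returns (G, T) arrays (summed over columns if T is collapsed by
        the caller).
        """
        b = beta[: self.rank]                        # r x T
        tail = np.sum(beta[self.rank:] ** 2, axis=0)  # T
        rho2 = ((1.0 - f) ** 2) @ (b ** 2) + tail[None, :]
        w = (self.s / self.c) ** 2
        eta2 = (f ** 2 * w[None, :]) @ (b ** 2)
        return rho2, eta2

    def default_bounds(self):
        s1 = self.sigma1
        return ((1e-4 * s1) ** 2, s1 ** 2)


# ---------------------------------------------------------------------------
# L-curve and oracle parameter selection
# ---------------------------------------------------------------------------

def _menger_curvature(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed three-point circumscribed-circle curvature along a polyline.

    Positive where the curve turns counter-clockwise (the convex corner of
    an L-curve traversed from small to large lambda). Endpoints get -inf.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    kappa = np.full(x.shape, -np.inf)
    x0, x1, x2 = x[..., :-2], x[..., 1:-1], x[..., 2:]
    y0, y1, y2 = y[..., :-2], y[..., 1:-1], y[..., 2:]
    cross = (x1 - x0) * (y2 - y1) - (y1 - y0) * (x2 - x1)
    d01 = np.hypot(x1 - x0, y1 - y0)
    d12 = np.hypot(x2 - x1, y2 - y1)
    d02 = np.hypot(x2 - x0, y2 - y0)
    denom = d01 * d12 * d02
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, 2.0 * cross / denom, -np.inf)
    kappa[..., 1:-1] = k
    return kappa


def _lcurve_select(lams, rho2, eta2):
    """Pick lambda of maximum curvature on (log rho, log eta)."""
    with np.errstate(divide="ignore"):
        lr = 0.5 * np.log10(np.maximum(rho2, 1e-300))
        le = 0.5 * np.log10(np.maximum(eta2, 1e-300))
    kappa = _menger_curvature(lr, le)
    idx = int(np.argmax(kappa))          # ties -> smaller lambda (first)
    confident = np.isfinite(kappa[idx]) and kappa[idx] > 0
    if not confident:
        interior = kappa[1:-1] if len(lams) > 2 else kappa
        idx = 1 + int(np.argmax(interior)) if len(lams) > 2 else idx
    return idx, kappa, bool(confident)


def lcurve_lambda(A, L, Y, n_points: int = 50, bounds=None,
                  filter_kind: str = "tik", fact: "SpectralFactorization" = None):
    """L-curve choice of the regularization parameter.

    Evaluates (log residual, log seminorm) on a log-spaced lambda grid
    within constrained bounds (default ``[(1e-4 s1)^2, s1^2]`` with ``s1``
    the largest singular value of A) and returns the lambda of maximum
    discrete curvature together with a diagnostic dict. With matrix data
    ``Y`` the norms are Frobenius (the global variant).
    """
    if fact is None:
        fact = SpectralFactorization(A, L)
    lo, hi = bounds if bounds is not None else fact.default_bounds()
    if not (0 < lo <= hi):
        raise ValueError("need 0 < lambda_min <= lambda_max")
    lams = np.logspace(np.log10(lo), np.log10(hi), n_points)
    beta = fact.coefficients(np.atleast_2d(Y))
    f = np.stack([fact.filter_factors(l, filter_kind) for l in lams])
    rho2, eta2 = fact.rho2_eta2(beta, f)
    rho2 = rho2.sum(axis=1)
    eta2 = eta2.sum(axis=1)
    if len(lams) == 1:
        return lams[0], {"lambdas": lams, "rho": np.sqrt(rho2),
                         "eta": np.sqrt(eta2), "confident": True}
    idx, kappa, confident = _lcurve_select(lams, rho2, eta2)
    return lams[idx], {"lambdas": lams, "rho": np.sqrt(rho2),
                       "eta": np.sqrt(eta2), "curvature": kappa,
                       "confident": confident}


def lcurve_truncation(A, L, Y, fact: "SpectralFactorization" = None) -> int:
    """Discrete L-curve over the truncation index k for (G)SVD methods."""
    if fact is None:
        fact = SpectralFactorization(A, L)
    beta = fact.coefficients(np.atleast_2d(Y))
    ks = np.arange(1, fact.rank + 1)
    f = np.tril(np.ones((fact.rank, fact.rank)))   # row k-1: keep first k
    rho2, eta2 = fact.rho2_eta2(beta, f)
    rho2 = rho2.sum(axis=1)
    eta2 = eta2.sum(axis=1)
    if len(ks) < 3:
        return int(ks[-1])
    idx, _, _ = _lcurve_select(ks.astype(float), rho2[::-1], eta2[::-1])
    # curvature computed along increasing rho = decreasing k
    return int(ks[::-1][idx])


def oracle_lambda(A, L, y, x_true, n_points: int = 1000, bounds=None,
                  mode: str = "global", fact: "SpectralFactorization" = None):
    """Benchmark-mode parameter: argmin of RDMS(x_true, x(lambda)).

    ``mode='global'`` minimizes the RDMS of the stacked matrix over one
    shared lambda; ``mode='instant'`` returns one lambda per column.
    """
    from .metrics import rdms
    if fact is None:
        fact = SpectralFactorization(A, L)
    lo, hi = bounds if bounds is not None else fact.default_bounds()
    lams = np.logspace(np.log10(lo), np.log10(hi), n_points)
    Y = np.atleast_2d(np.asarray(y, float))
    Xt = np.atleast_2d(np.asarray(x_true, float))
    if mode == "global":
        vals = np.empty(n_points)
        for i, lam in enumerate(lams):
            Xh = fact.solve_filtered(Y, fact.filter_factors(lam))
            vals[i] = rdms(Xt.ravel(), Xh.ravel())
        return lams[int(np.argmin(vals))], vals
    if mode == "instant":
        T = Y.shape[1]
        best = np.empty(T)
        best_val = np.full(T, np.inf)
        for lam in lams:
            Xh = fact.solve_filtered(Y, fact.filter_factors(lam))
            num = Xh / np.maximum(np.linalg.norm(Xh, axis=0), 1e-300)
            tru = Xt / np.maximum(np.linalg.norm(Xt, axis=0), 1e-300)
            vals = np.linalg.norm(tru - num, axis=0)
            upd = vals < best_val
            best[upd] = lam
            best_val[upd] = vals[upd]
        return best, best_val
    raise ValueError(f"mode must be 'global' or 'instant', got {mode!r}")


# ---------------------------------------------------------------------------
# direct solver functions
# ---------------------------------------------------------------------------

def tikhonov_instant(A, L, y, lam: float) -> np.ndarray:
    """Single-instant Tikhonov: ``(A^T A + lam L^T L)^{-1} A^T y``."""
    A = _as_matrix(A)
    Lm = _as_operator(L, A.shape[1])
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(y, float)
    M = A.T @ A + lam * (Lm.T @ Lm)
    try:
        return sla.solve(M, A.T @ y, assume_a="pos")
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular normal equations; use lambda > 0 for a rank-deficient "
            "transfer matrix") from None


def tikhonov_global(A, L, Y, lam: float) -> np.ndarray:
    """Global Tikhonov: all instants solved with one shared lambda."""
    return tikhonov_instant(A, L, np.atleast_2d(np.asarray(Y, float)), lam)


def svd_filter_solve(A, y, method: str, parameter) -> np.ndarray:
    """Zero-order spectral filtering: Tikhonov, DSVD, or TSVD.

    Filter factors: ``s^2/(s^2+lam)`` (tik0), ``s/(s+lam)`` (dsvd),
    ``1{r <= k}`` (tsvd0).
    """
    fact = SpectralFactorization(A, None)
    if method in ("tik0", "dsvd"):
        if parameter < 0:
            raise ValueError("lambda must be >= 0")
        kind = "tik" if method == "tik0" else "dsvd"
        out = fact.solve_filtered(np.asarray(y, float),
                                  fact.filter_factors(parameter, kind))
    elif method == "tsvd0":
        out = fact.solve_truncated(np.asarray(y, float), int(parameter))
    else:
        raise ValueError(f"method must be tik0/dsvd/tsvd0, got {method!r}")
    return out[:, 0] if np.asarray(y).ndim == 1 else out


def tsvd_higher_order(A, L, y, k: int) -> np.ndarray:
    """Truncated GSVD of the pair (A, L), keeping the k dominant components."""
    fact = SpectralFactorization(A, L)
    out = fact.solve_truncated(np.asarray(y, float), k)
    return out[:, 0] if np.asarray(y).ndim == 1 else out


def tv_solve(A, L_gradient, y, lam: float, epsilon: float = None,
             max_iter: int = 50, tol: float = 1e-6):
    """Total-variation solve: ``||y - Ax||_2^2 + lam ||Lx||_1`` by IRLS.

    The L1 term is smoothed as ``sum_e sqrt((Lx)_e^2 + eps^2)`` and
    majorized by a weighted quadratic at each iterate, so the smoothed
    objective is non-increasing. Warm start: first-order Tikhonov at the
    same lambda. Returns ``(x, converged)``.
    """
    A = _as_matrix(A)
    Lm = _as_operator(L_gradient, A.shape[1])
    y = np.asarray(y, float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    AtA = A.T @ A
    Aty = A.T @ y
    if lam == 0:
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        return x, True
    x = tikhonov_instant(A, Lm, y, lam)
    g = Lm @ x
    if epsilon is None:
        med = np.median(np.abs(g))
        epsilon = 1e-6 * (med if med > 0 else 1.0)
    converged = False
    for _ in range(max_iter):
        w = 1.0 / np.sqrt(g ** 2 + epsilon ** 2)
        M = AtA + 0.5 * lam * (Lm.T @ (w[:, None] * Lm))
        x_new = sla.solve(M, Aty, assume_a="pos")
        delta = np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1e-300)
        x = x_new
        g = Lm @ x
        if delta < tol:
            converged = True
            break
    return x, converged


def tv_objective(A, L, y, x, lam, epsilon):
    """Smoothed TV objective (used by the monotonicity property test)."""
    A = _as_matrix(A)
    Lm = _as_operator(L, A.shape[1])
    r = np.asarray(y, float) - A @ x
    return float(r @ r + lam * np.sum(np.sqrt((Lm @ x) ** 2 + epsilon ** 2)))


def estimate_prior_covariance(training: PotentialField,
                              n_samples: int = 150,
                              seed: int = 0) -> np.ndarray:
    """Sample spatial covariance from a training window.

    Draws ``n_samples`` random time instants (columns) and forms the
    zero-mean sample covariance ``C_x = (1/n) sum x x^T``. The caller is
    responsible for keeping the training window disjoint from the
    estimation window.
    """
    X = training.values if isinstance(training, PotentialField) \
        else np.atleast_2d(np.asarray(training, float))
    T = X.shape[1]
    if n_samples > T:
        raise ValueError(f"n_samples={n_samples} exceeds the {T} available "
                         "time instants")
    rng = np.random.default_rng(seed)
    cols = rng.choice(T, size=n_samples, replace=False)
    S = X[:, cols]
    return (S @ S.T) / n_samples


def bayes_map(A, C_x, C_n, y) -> np.ndarray:
    """Bayesian MAP estimate ``(C_x A^T)(A C_x A^T + C_n)^{-1} y``."""
    A = _as_matrix(A)
    C_x = np.atleast_2d(np.asarray(C_x, float))
    C_n = np.atleast_2d(np.asarray(C_n, float))
    Y = np.asarray(y, float)
    S = A @ C_x @ A.T + C_n
    cond = np.linalg.cond(S)
    if cond > 1e12:
        warnings.warn(f"ill-conditioned Bayes system (cond={cond:.2e}); "
                      "solving via symmetric factorization")
    try:
        c, low = sla.cho_factor(S)
        sol = sla.cho_solve((c, low), np.atleast_2d(Y.T).T
                            if Y.ndim == 1 else Y)
    except np.linalg.LinAlgError:
        sol = sla.lstsq(S, Y if Y.ndim > 1 else Y[:, None])[0]
    out = C_x @ A.T @ sol
    return out[:, 0] if Y.ndim == 1 else out


def greensite_solve(A, L_order1, Y, k_temporal: int = None,
                    energy: float = 0.99, n_grid: int = 50,
                    lam: float = None,
                    fact: "SpectralFactorization" = None):
    """Spatio-temporal solve under the isotropy (Kronecker) assumption.

    The data matrix is whitened temporally by its SVD ``Y = Uy Sy Vy^T``;
    each of the leading ``k`` right singular directions defines a
    pseudo-measurement ``Y v_i`` solved by first-order Tikhonov with its
    own L-curve parameter; the estimates are rotated back,
    ``X = sum_i x_i v_i^T``. Default ``k``: smallest number of components
    carrying 99% of the data energy.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if not np.any(Y):
        return np.zeros((_as_matrix(A).shape[1], Y.shape[1]))
    Uy, sy, Vyt = np.linalg.svd(Y, full_matrices=False)
    if k_temporal is None:
        e = np.cumsum(sy ** 2) / np.sum(sy ** 2)
        k_temporal = int(np.searchsorted(e, energy) + 1)
    if not (1 <= k_temporal <= len(sy)):
        raise ValueError(f"k_temporal must be in [1, {len(sy)}]")
    if fact is None:
        fact = SpectralFactorization(A, L_order1)
    Xh = np.zeros((fact.n, Y.shape[1]))
    for i in range(k_temporal):
        z = Uy[:, i] * sy[i]          # = Y @ Vyt[i]
        if lam is None:
            lam_i, _ = lcurve_lambda(None, None, z[:, None],
                                     n_points=n_grid, fact=fact)
        else:
            lam_i = lam               # fixed parameter across components
        xi = fact.solve_filtered(z[:, None],
                                 fact.filter_factors(lam_i))[:, 0]
        Xh += np.outer(xi, Vyt[i])
    return Xh


def _gmres_iterates(B: np.ndarray, b: np.ndarray, max_iter: int):
    """Arnoldi GMRES from x0 = 0 recording every iterate.

    scipy's gmres only exposes the solution per restart cycle, while the
    benchmark needs the full iterate history to pick the minimal-residual
    solution, so the (standard) Arnoldi recurrence is spelled out here.
    """
    n = len(b)
    beta = np.linalg.norm(b)
    if beta == 0:
        return [np.zeros(n)], False
    Q = np.zeros((n, max_iter + 1))
    H = np.zeros((max_iter + 1, max_iter))
    Q[:, 0] = b / beta
    iterates = []
    breakdown = False
    for k in range(max_iter):
        v = B @ Q[:, k]
        for i in range(k + 1):
            H[i, k] = Q[:, i] @ v
            v -= H[i, k] * Q[:, i]
        H[k + 1, k] = np.linalg.norm(v)
        e1 = np.zeros(k + 2)
        e1[0] = beta
        yk, *_ = np.linalg.lstsq(H[: k + 2, : k + 1], e1, rcond=None)
        iterates.append(Q[:, : k + 1] @ yk)
        if H[k + 1, k] < 1e-14 * beta:
            breakdown = True          # happy breakdown: exact solve reached
            break
        Q[:, k + 1] = v / H[k + 1, k]
    return iterates, breakdown


def gmres_solve(A, y, max_iter: int = 30):
    """Iteration-limited GMRES on the normal equations ``A^T A x = A^T y``.

    Runs ``max_iter`` Arnoldi iterations from zero, records every iterate,
    and returns the one minimizing the data residual ``||y - A x_k||_2``
    together with an info dict (residual history, selected iteration,
    breakdown flag).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    A = _as_matrix(A)
    y = np.asarray(y, float)
    B = A.T @ A
    iterates, breakdown = _gmres_iterates(B, A.T @ y, max_iter)
    res = np.array([np.linalg.norm(y - A @ x) for x in iterates])
    best = int(np.argmin(res))
    info = {"residuals": res, "selected_iteration": best + 1,
            "breakdown": breakdown, "n_iterations": len(iterates)}
    return iterates[best], info


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class _BaseInverse(BaseEstimator):
    """Common fit/predict plumbing for the inverse estimators."""

    def _unwrap(self, Y):
        if isinstance(Y, PotentialField):
            return Y.values, Y
        return np.atleast_2d(np.asarray(Y, float)), None

    def _wrap(self, X, template):
        if template is not None:
            return PotentialField(X, template.fs, template.t0)
        return X

    def fit(self, A, mesh=None, **kw):
        raise NotImplementedError

    def predict(self, Y, **kw):
        raise NotImplementedError


class TikhonovInverse(_BaseInverse):
    """Tikhonov regularization of order 0, 1, or 2.

    Parameters
    ----------
    order : 0 | 1 | 2
        Penalty operator: identity, mesh gradient, or umbrella Laplacian.
    lambda_mode : 'global' | 'instantaneous' | 'fixed' | 'oracle'
        One L-curve lambda for the whole window, one per time instant, a
        user-fixed value (``lam``), or the RDMS-optimal value on a fine
        grid (needs ``X_true`` at predict time; benchmark mode only).
    """

    def __init__(self, order: int = 0, lambda_mode: str = "global",
                 lam: float = None, n_grid: int = 50, bounds=None,
                 oracle_mode: str = "instant", oracle_points: int = 1000):
        self.order = order
        self.lambda_mode = lambda_mode
        self.lam = lam
        self.n_grid = n_grid
        self.bounds = bounds
        self.oracle_mode = oracle_mode
        self.oracle_points = oracle_points

    def fit(self, A, mesh: TriMesh = None, L=None):
        Am = _as_matrix(A)
        if L is None:
            L = (None if self.order == 0
                 else regularization_operator(mesh, self.order))
        self.A_ = Am
        self.L_ = L
        self.factorization_ = SpectralFactorization(Am, L)
        return self

    def predict(self, Y, X_true=None):
        Yv, template = self._unwrap(Y)
        fact = self.factorization_
        mode = self.lambda_mode
        if mode == "fixed":
            if self.lam is None:
                raise ValueError("lambda_mode='fixed' requires lam")
            lam = float(self.lam)
            X = fact.solve_filtered(Yv, fact.filter_factors(lam))
            self.lambda_ = lam
        elif mode == "global":
            lam, diag = lcurve_lambda(None, None, Yv, n_points=self.n_grid,
                                      bounds=self.bounds, fact=fact)
            X = fact.solve_filtered(Yv, fact.filter_factors(lam))
            self.lambda_ = lam
            self.lcurve_ = diag
        elif mode == "instantaneous":
            lams = self._per_instant_lambdas(Yv)
            F = np.stack([fact.filter_factors(l) for l in lams])  # T x r
            X = fact.solve_filtered(Yv, F.T)
            self.lambda_ = lams
        elif mode == "oracle":
            if X_true is None:
                raise ValueError("oracle mode needs X_true")
            Xt = X_true.values if isinstance(X_true, PotentialField) else X_true
            lam, _ = oracle_lambda(None, None, Yv, Xt,
                                   n_points=self.oracle_points,
                                   bounds=self.bounds,
                                   mode=("instant" if self.oracle_mode ==
                                         "instant" else "global"), fact=fact)
            if np.ndim(lam) == 0:
                X = fact.solve_filtered(Yv, fact.filter_factors(float(lam)))
            else:
                F = np.stack([fact.filter_factors(l) for l in lam])
                X = fact.solve_filtered(Yv, F.T)
            self.lambda_ = lam
        else:
            raise ValueError(f"unknown lambda_mode {mode!r}")
        return self._wrap(X, template)

    def _per_instant_lambdas(self, Yv) -> np.ndarray:
        fact = self.factorization_
        lo, hi = (self.bounds if self.bounds is not None
                  else fact.default_bounds())
        lams = np.logspace(np.log10(lo), np.log10(hi), self.n_grid)
        beta = fact.coefficients(Yv)
        f = np.stack([fact.filter_factors(l) for l in lams])   # G x r
        rho2, eta2 = fact.rho2_eta2(beta, f)                   # G x T
        with np.errstate(divide="ignore"):
            lr = 0.5 * np.log10(np.maximum(rho2, 1e-300))
            le = 0.5 * np.log10(np.maximum(eta2, 1e-300))
        kappa = _menger_curvature(lr.T, le.T)                  # T x G
        return lams[np.argmax(kappa, axis=1)]


class TSVDInverse(_BaseInverse):
    """Truncated (generalized) SVD of order 0, 1, or 2.

    ``k`` components are kept; if ``k`` is None a discrete L-curve over
    the truncation index selects it from the data.
    """

    def __init__(self, order: int = 0, k: int = None):
        self.order = order
        self.k = k

    def fit(self, A, mesh: TriMesh = None, L=None):
        Am = _as_matrix(A)
        if L is None:
            L = (None if self.order == 0
                 else regularization_operator(mesh, self.order))
        self.A_ = Am
        self.factorization_ = SpectralFactorization(Am, L)
        return self

    def predict(self, Y):
        Yv, template = self._unwrap(Y)
        fact = self.factorization_
        k = self.k if self.k is not None else lcurve_truncation(
            None, None, Yv, fact=fact)
        self.k_ = int(k)
        return self._wrap(fact.solve_truncated(Yv, self.k_), template)


class DSVDInverse(_BaseInverse):
    """Damped SVD: filter factors ``s/(s+lambda)`` (zero order)."""

    def __init__(self, lam: float = None, n_grid: int = 50, bounds=None):
        self.lam = lam
        self.n_grid = n_grid
        self.bounds = bounds

    def fit(self, A, mesh: TriMesh = None):
        self.A_ = _as_matrix(A)
        self.factorization_ = SpectralFactorization(self.A_, None)
        return self

    def predict(self, Y):
        Yv, template = self._unwrap(Y)
        fact = self.factorization_
        if self.lam is not None:
            lam = float(self.lam)
        else:
            s1 = fact.sigma1
            bounds = self.bounds if self.bounds is not None \
                else (1e-4 * s1, s1)   # dsvd filter is linear in sigma
            lam, _ = lcurve_lambda(None, None, Yv, n_points=self.n_grid,
                                   bounds=bounds, filter_kind="dsvd",
                                   fact=fact)
        self.lambda_ = lam
        return self._wrap(
            fact.solve_filtered(Yv, fact.filter_factors(lam, "dsvd")),
            template)


class TVInverse(_BaseInverse):
    """Total-variation regularization (L1 penalty on the mesh gradient)."""

    def __init__(self, lam: float = None, epsilon: float = None,
                 max_iter: int = 50, tol: float = 1e-6, n_grid: int = 50):
        self.lam = lam
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.tol = tol
        self.n_grid = n_grid

    def fit(self, A, mesh: TriMesh = None, L=None):
        self.A_ = _as_matrix(A)
        self.L_ = L if L is not None else regularization_operator(mesh, 1)
        self.factorization_ = SpectralFactorization(self.A_, self.L_)
        return self

    def predict(self, Y):
        Yv, template = self._unwrap(Y)
        if self.lam is not None:
            lam = float(self.lam)
        else:
            lam, _ = lcurve_lambda(None, None, Yv, n_points=self.n_grid,
                                   fact=self.factorization_)
        self.lambda_ = lam
        X = np.empty((self.A_.shape[1], Yv.shape[1]))
        conv = np.empty(Yv.shape[1], bool)
        for t in range(Yv.shape[1]):
            X[:, t], conv[t] = tv_solve(self.A_, self.L_, Yv[:, t], lam,
                                        epsilon=self.epsilon,
                                        max_iter=self.max_iter, tol=self.tol)
        self.converged_ = conv
        return self._wrap(X, template)


class BayesMAPInverse(_BaseInverse):
    """Bayesian MAP with an empirical spatial prior.

    The prior covariance ``C_x`` is passed at fit time (typically from
    :func:`estimate_prior_covariance` on a disjoint training window) and
    the noise covariance ``C_n`` defaults to ``sigma^2 I`` from the known
    injected noise power in benchmark mode.
    """

    def __init__(self):
        pass

    def fit(self, A, mesh: TriMesh = None, C_x=None, C_n=None,
            noise_variance: float = None):
        self.A_ = _as_matrix(A)
        if C_x is None:
            raise ValueError("Bayes MAP requires a prior covariance C_x")
        self.C_x_ = np.atleast_2d(np.asarray(C_x, float))
        if C_n is None:
            if noise_variance is None:
                raise ValueError("provide C_n or noise_variance")
            C_n = noise_variance * np.eye(self.A_.shape[0])
        self.C_n_ = np.atleast_2d(np.asarray(C_n, float))
        return self

    def predict(self, Y):
        Yv, template = self._unwrap(Y)
        return self._wrap(bayes_map(self.A_, self.C_x_, self.C_n_, Yv),
                          template)


class GreensiteInverse(_BaseInverse):
    """Greensite spatio-temporal regularization (first-order Tikhonov)."""

    def __init__(self, k_temporal: int = None, energy: float = 0.99,
                 n_grid: int = 50):
        self.k_temporal = k_temporal
        self.energy = energy
        self.n_grid = n_grid

    def fit(self, A, mesh: TriMesh = None, L=None):
        self.A_ = _as_matrix(A)
        self.L_ = L if L is not None else regularization_operator(mesh, 1)
        self.factorization_ = SpectralFactorization(self.A_, self.L_)
        return self

    def predict(self, Y):
        Yv, template = self._unwrap(Y)
        X = greensite_solve(self.A_, self.L_, Yv,
                            k_temporal=self.k_temporal, energy=self.energy,
                            n_grid=self.n_grid, fact=self.factorization_)
        return self._wrap(X, template)


class GMRESInverse(_BaseInverse):
    """Iteration-limited GMRES on the normal equations, per time instant."""

    def __init__(self, max_iter: int = 30):
        self.max_iter = max_iter

    def fit(self, A, mesh: TriMesh = None):
        self.A_ = _as_matrix(A)
        self.B_ = self.A_.T @ self.A_
        return self

    def predict(self, Y):
        Yv, template = self._unwrap(Y)
        X = np.empty((self.A_.shape[1], Yv.shape[1]))
        sel = np.empty(Yv.shape[1], int)
        for t in range(Yv.shape[1]):
            x, info = gmres_solve(self.A_, Yv[:, t], self.max_iter)
            X[:, t] = x
            sel[t] = info["selected_iteration"]
        self.selected_iterations_ = sel
        return self._wrap(X, template)


#: Solver registry keyed by the benchmark's method names.
SOLVER_REGISTRY = {
    "Tik-g0": (TikhonovInverse, dict(order=0, lambda_mode="global")),
    "Tik-g1": (TikhonovInverse, dict(order=1, lambda_mode="global")),
    "Tik-g2": (TikhonovInverse, dict(order=2, lambda_mode="global")),
    "Tik-i0": (TikhonovInverse, dict(order=0, lambda_mode="instantaneous")),
    "Tik-i1": (TikhonovInverse, dict(order=1, lambda_mode="instantaneous")),
    "Tik-i2": (TikhonovInverse, dict(order=2, lambda_mode="instantaneous")),
    "TSVD-0": (TSVDInverse, dict(order=0)),
    "TSVD-1": (TSVDInverse, dict(order=1)),
    "TSVD-2": (TSVDInverse, dict(order=2)),
    "DSVD": (DSVDInverse, dict()),
    "TV": (TVInverse, dict()),
    "Bayes": (BayesMAPInverse, dict()),
    "GS": (GreensiteInverse, dict()),
    "GMRES": (GMRESInverse, dict(max_iter=30)),
}


def make_solver(name: str, **overrides) -> _BaseInverse:
    """Instantiate a registered solver by its benchmark name."""
    if name not in SOLVER_REGISTRY:
        raise KeyError(f"unknown solver {name!r}; known: "
                       f"{sorted(SOLVER_REGISTRY)}")
    cls, kw = SOLVER_REGISTRY[name]
    params = dict(kw)
    params.update(overrides)
    return cls(**params)
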