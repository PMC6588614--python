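"""Sparsity-promoting H2 optimal state feedback for Laplacian dynamics.

The open loop is the diffusion/consensus system ``dx/dt = -L x + B1 d + B2 u``
with ``L = D - A`` the combinatorial graph Laplacian.  Under state feedback
``u = -F x`` the closed loop is ``dx/dt = -(L + F) x + B1 d``; its H2
performance cost

    J(F) = trace(B1^T P B1),
    -(L+F)^T P - P (L+F) + (Qw + F^T Rw F) = 0,

measures the energy that white-noise disturbances inject into the states and
the control signal.  Every nonzero entry of F is a feedback channel (a
sensor-to-actuator link) with price ``gamma``, so the design problem is

    minimize  J(F) + gamma * card(F),

a nonconvex program solved by ADMM: the smooth H2 term is minimized by
Anderson-Moore iterations, the cardinality term by elementwise hard
thresholding, and the identified sparsity pattern is polished by projected
gradient descent.  All weight matrices (B1, B2, Qw, Rw) are identity in this
study; the types carry them anyway.

Because L is symmetric PSD and all weights are identity, the gamma = 0
(centralized LQR) problem has the closed form

    F* = -L + (L^2 + I)^{1/2},    J* = sum_i ( sqrt(lam_i^2 + 1) - lam_i )

over the eigenvalues ``lam_i`` of L, which serves both as the ADMM
initializer and as an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg

from .exceptions import ClosedLoopUnstableError, InfeasiblePatternError

__all__ = [
    "LaplacianSystem",
    "GainMatrix",
    "CostBreakdown",
    "SparseSolution",
    "AdmmOptions",
    "laplacian",
    "observability_gramian",
    "controllability_gramian",
    "h2_cost",
    "h2_gradient",
    "centralized_gain",
    "sparse_gain_admm",
    "polish_gain",
    "total_cost",
    "solve_gamma_path",
]

#: entries of F with magnitude above this count as feedback channels; hard
#: thresholding produces exact zeros, the tolerance guards polishing round-off
CARD_TOL = 1e-10

# closed-loop spectral abscissa must be below this for the H2 cost to converge
_HURWITZ_TOL = -1e-9


@dataclass(frozen=True)
class LaplacianSystem:
    """Laplacian dynamics with disturbance/input/weight matrices.

    ``L`` is symmetric PSD with zero row sums; ``B1``, ``B2``, ``Qw``, ``Rw``
    default to identity (the configuration studied here).
    """

    L: np.ndarray
    B1: np.ndarray = None  # type: ignore[assignment]
    B2: np.ndarray = None  # type: ignore[assignment]
    Qw: np.ndarray = None  # type: ignore[assignment]
    Rw: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.L.shape[0]
        if self.L.shape != (n, n):
            raise ValueError("L must be square")
        for name in ("B1", "B2", "Qw", "Rw"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, np.eye(n))

    @property
    def n(self) -> int:
        return self.L.shape[0]


# GainMatrix is a plain ndarray in practice; the alias documents intent.
GainMatrix = np.ndarray


@dataclass(frozen=True)
class CostBreakdown:
    """H2 cost, channel count, and their gamma-weighted total."""

    J: float
    card: int
    gamma: float

    @property
    def total(self) -> float:
        return self.J + self.gamma * self.card


@dataclass
class SparseSolution:
    """Result of one sparsity-promoting solve."""

    gain: np.ndarray
    pattern: np.ndarray  # boolean mask of nonzeros
    costs: CostBreakdown
    history: list[dict] = field(default_factory=list)
    converged: bool = True
    iterations: int = 0


@dataclass(frozen=True)
class AdmmOptions:
    """Solver knobs (defaults follow the LQRSP-style ADMM)."""

    rho: float = 100.0  # augmented-Lagrangian penalty
    eps_abs: float = 1e-4  # stop when ||F - G||_F <= eps_abs * N
    max_iter: int = 100
    fstep_tol: float = 1e-6  # Anderson-Moore inner tolerance
    fstep_max_iter: int = 30
    polish_tol: float = 1e-7
    polish_max_iter: int = 500


def laplacian(graph: nx.Graph) -> LaplacianSystem:
    """Build ``L = D - A`` (dense, float) with identity weights."""
    n = graph.number_of_nodes()
    L = nx.laplacian_matrix(graph, nodelist=range(n)).toarray().astype(float)
    return LaplacianSystem(L=L)


def _closed_loop(system: LaplacianSystem, gain: np.ndarray) -> np.ndarray:
    return -(system.L + system.B2 @ gain)


def is_stabilizing(system: LaplacianSystem, gain: np.ndarray) -> bool:
    """True when the closed loop ``-(L + B2 F)`` is Hurwitz."""
    acl = _closed_loop(system, gain)
    return float(np.linalg.eigvals(acl).real.max()) < _HURWITZ_TOL


def observability_gramian(system: LaplacianSystem, gain: np.ndarray) -> np.ndarray:
    """Closed-loop observability Gramian P.

    Solves ``-(L+F)^T P - P (L+F) + (Qw + F^T Rw F) = 0``.  Raises
    :class:`ClosedLoopUnstableError` when the closed loop is not Hurwitz
    (the defining integral, and hence the H2 cost, diverges).
    """
    acl = _closed_loop(system, gain)
    if float(np.linalg.eigvals(acl).real.max()) >= _HURWITZ_TOL:
        raise ClosedLoopUnstableError("closed loop -(L+F) is not Hurwitz")
    q = system.Qw + gain.T @ system.Rw @ gain
    p = scipy.linalg.solve_continuous_lyapunov(acl.T, -q)
    return 0.5 * (p + p.T)


def controllability_gramian(system: LaplacianSystem, gain: np.ndarray) -> np.ndarray:
    """Closed-loop controllability Gramian W: ``(L+F) W + W (L+F)^T = B1 B1^T``."""
    acl = _closed_loop(system, gain)
    if float(np.linalg.eigvals(acl).real.max()) >= _HURWITZ_TOL:
        raise ClosedLoopUnstableError("closed loop -(L+F) is not Hurwitz")
    w = scipy.linalg.solve_continuous_lyapunov(acl, -system.B1 @ system.B1.T)
    return 0.5 * (w + w.T)


def h2_cost(system: LaplacianSystem, gain: np.ndarray) -> float:
    """H2 performance cost ``J = trace(B1^T P B1)``."""
    p = observability_gramian(system, gain)
    return float(np.trace(system.B1.T @ p @ system.B1))


def h2_gradient(system: LaplacianSystem, gain: np.ndarray) -> np.ndarray:
    """Gradient of J with respect to F: ``2 (Rw F - B2^T P) W``."""
    p = observability_gramian(system, gain)
    w = controllability_gramian(system, gain)
    return 2.0 * (system.Rw @ gain - system.B2.T @ p) @ w


def centralized_gain(system: LaplacianSystem) -> tuple[np.ndarray, float]:
    """Closed-form gamma = 0 (dense LQR) optimum.

    With identity weights and symmetric L the Riccati equation diagonalizes
    in L's eigenbasis: ``F* = -L + (L^2 + I)^{1/2}`` and
    ``J* = sum_i (sqrt(lam_i^2 + 1) - lam_i)``.  The closed loop
    ``-(L^2 + I)^{1/2}`` is always Hurwitz, even on disconnected graphs.
    """
    lam, v = np.linalg.eigh(system.L)
    mu = np.sqrt(lam**2 + 1.0)
    f = (v * (mu - lam)) @ v.T
    return 0.5 * (f + f.T), float(np.sum(mu - lam))


def total_cost(
    system: LaplacianSystem, gain: np.ndarray, gamma: float, card_tol: float = CARD_TOL
) -> CostBreakdown:
    """Cost breakdown ``J + gamma * card(F)`` for a feasible gain."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    j = h2_cost(system, gain)
    card = int(np.count_nonzero(np.abs(gain) > card_tol))
    return CostBreakdown(J=j, card=card, gamma=gamma)


def _phi(system: LaplacianSystem, f: np.ndarray, u: np.ndarray, rho: float) -> float:
    """Augmented F-step objective J(F) + rho/2 ||F - U||_F^2 (inf if unstable)."""
    try:
        j = h2_cost(system, f)
    except ClosedLoopUnstableError:
        return np.inf
    return j + 0.5 * rho * float(np.linalg.norm(f - u) ** 2)


def _f_step(
    system: LaplacianSystem,
    f0: np.ndarray,
    u: np.ndarray,
    rho: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Anderson-Moore minimization of J(F) + rho/2 ||F - U||^2.

    The stationarity condition ``2(F - P)W + rho (F - U) = 0`` is linear in F
    for frozen Gramians, giving the update ``F (2W + rho I) = 2 P W + rho U``;
    a backtracking line search along the update direction keeps the iterate
    stabilizing and the objective decreasing.
    """
    n = system.n
    f = f0.copy()
    phi = _phi(system, f, u, rho)
    assert np.isfinite(phi), "F-step must start from a stabilizing gain"
    for _ in range(max_iter):
        p = observability_gramian(system, f)
        w = controllability_gramian(system, f)
        lhs = 2.0 * w + rho * np.eye(n)  # symmetric PD
        rhs = 2.0 * p @ w + rho * u
        f_bar = scipy.linalg.solve(lhs, rhs.T, assume_a="pos").T
        d = f_bar - f
        dn = float(np.linalg.norm(d))
        if dn <= tol * (1.0 + float(np.linalg.norm(f))):
            break
        grad = 2.0 * (f - p) @ w + rho * (f - u)
        slope = float(np.sum(grad * d))
        step = 1.0
        while step > 1e-10:
            cand = f + step * d
            phi_c = _phi(system, cand, u, rho)
            if phi_c <= phi + 1e-4 * step * min(slope, 0.0):
                f, phi = cand, phi_c
                break
            step *= 0.5
        else:
            break  # no progress possible along this direction
    return f


def polish_gain(
    system: LaplacianSystem,
    pattern: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Minimize J over gains supported on ``pattern`` by projected gradient.

    ``start`` (masked to the pattern) seeds the iteration; if it does not
    stabilize, diagonal loading ``start + c I`` is attempted for growing c
    (only when the diagonal lies inside the pattern).  Raises
    :class:`InfeasiblePatternError` when no stabilizing start is found.
    """
    pattern = pattern.astype(bool)
    if start is None:
        start, _ = centralized_gain(system)
    f = np.where(pattern, start, 0.0)
    if not is_stabilizing(system, f):
        f = _stabilize_on_pattern(system, pattern, f)
    j = h2_cost(system, f)
    step = 1.0
    for _ in range(max_iter):
        g = np.where(pattern, h2_gradient(system, f), 0.0)
        gn2 = float(np.sum(g * g))
        if np.sqrt(gn2) <= tol * (1.0 + abs(j)):
            break
        accepted = False
        while step > 1e-14:
            cand = f - step * g
            try:
                j_c = h2_cost(system, cand)
            except ClosedLoopUnstableError:
                j_c = np.inf
            if j_c <= j - 1e-4 * step * gn2:
                f, j = cand, j_c
                step *= 1.5
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return f, j


def _stabilize_on_pattern(
    system: LaplacianSystem, pattern: np.ndarray, f: np.ndarray
) -> np.ndarray:
    """Find any stabilizing gain on ``pattern`` by diagonal loading."""
    diag_ok = bool(np.all(np.diag(pattern)))
    if diag_ok:
        for c in (1.0, 10.0, 100.0, 1e4):
            cand = f + c * np.eye(system.n)
            if is_stabilizing(system, cand):
                return cand
    raise InfeasiblePatternError("no stabilizing gain found on the sparsity pattern")


def sparse_gain_admm(
    system: LaplacianSystem,
    gamma: float,
    opts: AdmmOptions | None = None,
    f_init: np.ndarray | None = None,
) -> SparseSolution:
    """ADMM for ``minimize J(F) + gamma * card(G)`` subject to ``F = G``.

    The F-step approximately minimizes the smooth augmented term
    (Anderson-Moore), the G-step is elementwise hard thresholding — an entry
    ``v`` survives iff ``|v| > sqrt(2 gamma / rho)`` — and the scaled dual
    update couples them.  Iteration stops when the primal residual
    ``||F - G||_F`` drops below ``eps_abs * N``.  The final pattern is
    polished (H2-optimal gain restricted to the pattern) and returned with
    its cost breakdown; ``f_init`` warm-starts the solve (default: the
    centralized closed form).
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if opts is None:
        opts = AdmmOptions()
    n = system.n
    f = centralized_gain(system)[0] if f_init is None else f_init.copy()
    if not is_stabilizing(system, f):
        f = centralized_gain(system)[0]
    g = f.copy()
    lam = np.zeros_like(f)
    threshold = np.sqrt(2.0 * gamma / opts.rho)
    history: list[dict] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        f = _f_step(
            system, f, g - lam / opts.rho, opts.rho, opts.fstep_tol, opts.fstep_max_iter
        )
        v = f + lam / opts.rho
        g = np.where(np.abs(v) > threshold, v, 0.0)
        lam = lam + opts.rho * (f - g)
        r = float(np.linalg.norm(f - g))
        obj = h2_cost(system, f) + gamma * int(np.count_nonzero(g))
        history.append({"iteration": it, "objective": obj, "primal_residual": r})
        if r <= opts.eps_abs * n:
            converged = True
            break
    pattern = np.abs(g) > 0
    if not pattern.any():
        # F = 0 is only feasible when -L itself is Hurwitz, which a Laplacian
        # never is; fall back to the cheapest nonempty pattern (diagonal).
        pattern = np.eye(n, dtype=bool)
    start = g if is_stabilizing(system, g) else np.where(pattern, f, 0.0)
    f_pol, j_pol = polish_gain(
        system, pattern, start=start, tol=opts.polish_tol, max_iter=opts.polish_max_iter
    )
    costs = total_cost(system, f_pol, gamma)
    return SparseSolution(
        gain=f_pol,
        pattern=np.abs(f_pol) > CARD_TOL,
        costs=costs,
        history=history,
        converged=converged,
        iterations=it,
    )


def solve_gamma_path(
    system: LaplacianSystem,
    gammas: list[float] | np.ndarray,
    opts: AdmmOptions | None = None,
) -> list[SparseSolution]:
    """Warm-started homotopy over an increasing gamma grid.

    Solves the smallest gamma first from the centralized initializer and
    each subsequent gamma from the previous solution — the strategy that
    makes the nonconvex cardinality objective tractable.  Input order of
    ``gammas`` is preserved in the output.
    """
    order = np.argsort(gammas)
    solutions: dict[int, SparseSolution] = {}
    f_prev: np.ndarray | None = None
    for idx in order:
        sol = sparse_gain_admm(system, float(gammas[idx]), opts=opts, f_init=f_prev)
        solutions[int(idx)] = sol
        f_prev = sol.gain
    return [solutions[i] for i in range(len(gammas))]
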