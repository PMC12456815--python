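"""Knight-Ruiz matrix balancing.

A symmetric non-negative contact matrix ``M`` is turned into a symmetric
doubly stochastic TPM ``P = D M D`` with ``D = diag(x*)``, ``x* > 0``, by
solving the nonlinear system ``x .* (M x) = 1``.  We use the Knight-Ruiz
inner-outer scheme: an inexact Newton method whose linear systems are
solved by conjugate gradients, with the iterates kept inside a positivity
cone by a simple step clamp.  For a fully supported symmetric matrix the
balancing is unique, so any convergent method yields the same ``P``.

All-zero rows (loci with no observed contacts) make balancing impossible;
following standard practice the diagonal entry of every such row is set to
1 first (:func:`repair_zero_rows`), which keeps the locus in the matrix
without inventing contacts to other loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ContactMatrix, StochasticMatrix, require_symmetric

__all__ = ["BalancingResult", "UnbalanceableError", "repair_zero_rows", "kr_normalize"]


class UnbalanceableError(ValueError):
    """The zero pattern of the matrix admits no positive balancing."""


@dataclass
class BalancingResult:
    """Outcome of a balancing run.

    ``matrix.values`` equals ``diag(scaling) @ M @ diag(scaling)`` up to the
    achieved tolerance; ``converged`` is False when the iteration budget ran
    out, in which case the best iterate is returned.
    """

    matrix: StochasticMatrix
    scaling: np.ndarray
    iterations: int
    converged: bool


def _repair_array(A: np.ndarray) -> np.ndarray:
    zero_rows = ~A.any(axis=1)
    if not zero_rows.any():
        return A
    repaired = A.copy()
    idx = np.flatnonzero(zero_rows)
    repaired[idx, idx] = 1
    return repaired


def repair_zero_rows(M: ContactMatrix) -> ContactMatrix:
    """Set the diagonal entry of every all-zero row to 1; identity otherwise."""
    counts = M.counts if isinstance(M, ContactMatrix) else np.asarray(M)
    require_symmetric(counts, name="contact matrix")
    repaired = _repair_array(counts)
    if repaired is counts:
        return M if isinstance(M, ContactMatrix) else ContactMatrix(counts)
    truth = M.truth if isinstance(M, ContactMatrix) else None
    return ContactMatrix(repaired, truth=truth)


def _bnewt(
    A: np.ndarray, tol: float, max_outer: int
) -> tuple[np.ndarray, int, bool]:
    """Inner-outer Newton/CG balancing of a symmetric non-negative matrix.

    Returns ``(x, outer_iterations, converged)`` where convergence means
    ``max |x .* (A x) - 1| <= tol``.  The CG search direction is clamped so
    the multiplicative update ``y`` stays in ``[delta, Delta]``, which keeps
    ``x`` positive throughout.
    """
    n = A.shape[0]
    # start near the solution: scale so row sums are ~1, fold the scale
    # back into x afterwards (balancing is scale-invariant in P)
    scale = A.sum(axis=1).mean()
    if scale <= 0 or not np.isfinite(scale):
        return np.ones(n), 0, False
    A = A / scale

    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5

    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rho_km2 = rho_km1
    rout = rold = rho_km1
    best_x, best_dev = x.copy(), np.abs(v - 1.0).max()
    outer = 0
    # the contract's tolerance is the infinity-norm deviation of the row
    # sums; the 2-norm residual rout only steers the inexact Newton solves
    while np.abs(v - 1.0).max() > tol and outer < max_outer:
        outer += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, stop_tol**2)
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            pw = p @ w
            if pw <= 0 or not np.isfinite(pw):
                break
            alpha = rho_km1 / pw
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                if not neg.any():
                    break
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 5 * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rho_km2 = rho_km1
        rout = rho_km1
        dev = np.abs(v - 1.0).max()
        if dev < best_dev:
            best_dev, best_x = dev, x.copy()
        if not np.isfinite(rout):
            break
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, stop_tol))
    dev = np.abs(x * (A @ x) - 1.0).max()
    if dev > best_dev:
        x, dev = best_x, best_dev
    return x / np.sqrt(scale), outer, dev <= tol


def kr_normalize(
    M: ContactMatrix | np.ndarray, tol: float = 1e-6, max_iter: int = 1000
) -> BalancingResult:
    """Balance a symmetric non-negative matrix into a doubly stochastic TPM.

    Zero rows are repaired first (diagonal set to 1), so the operation is
    safe to apply to sparse single-cell matrices directly.

    Raises
    ------
    ValueError
        for asymmetric or negative input, or non-positive ``tol``.
    UnbalanceableError
        when the support pattern provably admits no positive balancing
        (detected as a residual that stalls far from zero with vanishing
        scaling entries).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    truth = M.truth if isinstance(M, ContactMatrix) else None
    raw = M.counts if isinstance(M, ContactMatrix) else np.asarray(M, dtype=float)
    require_symmetric(raw, tol=1e-9, name="matrix")
    if raw.min() < 0:
        raise ValueError("matrix must be non-negative")
    A = _repair_array(raw.astype(float))

    x, outer, converged = _bnewt(A, tol=tol, max_outer=max_iter)
    P = (x[:, None] * A) * x[None, :]
    P = 0.5 * (P + P.T)
    dev = float(np.abs(P.sum(axis=1) - 1.0).max())
    if not converged and (x.min() <= 0 or not np.isfinite(x).all() or dev > 0.5):
        raise UnbalanceableError(
            "balancing stalled: the matrix support admits no positive "
            f"doubly stochastic scaling (residual {dev:g})"
        )
    matrix = StochasticMatrix(P, tolerance=max(dev, tol), truth=truth)
    return BalancingResult(matrix=matrix, scaling=x, iterations=outer, converged=converged)
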