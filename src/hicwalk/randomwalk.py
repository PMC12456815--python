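"""Random-walk smoothing of doubly stochastic Hi-C matrices.

Two families of smoothers operate on a symmetric doubly stochastic TPM
``P``:

* **RWS** (random walk with ``s`` steps): the ``s``-step TPM ``P^s``.
  For an irreducible chain ``P^s -> (1/N) J`` as ``s`` grows, so long walks
  flatten every domain into a uniform "monolith".

* **RWR** (random walk with restart): the recursion
  ``P(s) = (1 - alpha) P(s-1) P + alpha I`` started at ``P(0) = I`` with
  restart probability ``alpha``.  Its limit is the resolvent
  ``P* = alpha (I - (1 - alpha) P)^{-1}``, whose dominant feature is the
  main diagonal (every diagonal entry carries the restart mass ``alpha``).

For the idealized block TPM the RWR limit has a closed block form,
implemented in :func:`rwr_limit_ideal` and cross-checked against the
resolvent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
import scipy.linalg

from .synthetic import IdealizedSpec
from .types import StochasticMatrix

__all__ = [
    "SmoothingResult",
    "rws",
    "rwr_iterate",
    "rwr_iterate_to_convergence",
    "rwr_limit",
    "rwr_limit_ideal",
    "ideal_rwr_coefficients",
]

_ROW_SUM_TOL = 1e-6  # admissibility check on inputs claiming to be stochastic


@dataclass
class SmoothingResult:
    """A smoothed TPM with provenance of how it was produced."""

    matrix: StochasticMatrix
    method: Literal["RWS", "RWR"]
    steps: Union[int, Literal["limit"]]
    alpha: Optional[float] = None

    @property
    def label(self) -> str:
        if self.method == "RWS":
            return f"RWS{self.steps}s"
        return f"RWR{self.alpha:g}"


def _check_stochastic(P: StochasticMatrix) -> np.ndarray:
    dev = P.max_balance_deviation()
    if dev > _ROW_SUM_TOL:
        raise ValueError(f"input is not doubly stochastic (row-sum deviation {dev:g})")
    return P.values


def _as_result(values: np.ndarray, method, steps, alpha=None, truth=None) -> SmoothingResult:
    values = 0.5 * (values + values.T)  # kill rounding-level asymmetry
    np.clip(values, 0.0, None, out=values)
    mat = StochasticMatrix(values, tolerance=1e-9, truth=truth)
    return SmoothingResult(matrix=mat, method=method, steps=steps, alpha=alpha)


def rws(P: StochasticMatrix, s: int) -> SmoothingResult:
    """Random walk with ``s`` steps: the matrix power ``P^s``.

    Uses repeated squaring, so large ``s`` (e.g. the 500-step proxy for the
    limiting matrix) is cheap.
    """
    if s < 1:
        raise ValueError("step count s must be >= 1")
    A = _check_stochastic(P)
    power = np.linalg.matrix_power(A, s)
    return _as_result(power, "RWS", s, truth=P.truth)


def rwr_iterate(P: StochasticMatrix, alpha: float, s: int) -> SmoothingResult:
    """The ``s``-th iterate of the restart recursion, from ``P(0) = I``."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if s < 1:
        raise ValueError("step count s must be >= 1")
    A = _check_stochastic(P)
    N = A.shape[0]
    X = np.eye(N)
    for _ in range(s):
        X = (1.0 - alpha) * (X @ A) + alpha * np.eye(N)
    return _as_result(X, "RWR", s, alpha=alpha, truth=P.truth)


def rwr_iterate_to_convergence(
    P: StochasticMatrix,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> SmoothingResult:
    """Iterate the restart recursion until successive iterates differ by < ``tol``.

    Convergence is geometric at rate ``1 - alpha``; for ``alpha = 0`` on a
    periodic chain the recursion may not converge, in which case the
    iteration cap raises.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    A = _check_stochastic(P)
    N = A.shape[0]
    X = np.eye(N)
    for it in range(1, max_iter + 1):
        X_new = (1.0 - alpha) * (X @ A) + alpha * np.eye(N)
        delta = np.abs(X_new - X).max()
        X = X_new
        if delta < tol:
            return _as_result(X, "RWR", it, alpha=alpha, truth=P.truth)
    raise RuntimeError(
        f"restart recursion did not converge within {max_iter} iterations "
        f"(last delta {delta:g})"
    )


def rwr_limit(P: StochasticMatrix, alpha: float) -> SmoothingResult:
    """Closed-form RWR limit ``alpha (I - (1 - alpha) P)^{-1}``.

    Computed by a linear solve of ``(I - (1 - alpha) P) X = alpha I`` rather
    than explicit inversion.  The resolvent exists for every ``alpha`` in
    ``(0, 1]`` because the spectral radius of ``P`` is 1.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1] for the limit to exist")
    A = _check_stochastic(P)
    N = A.shape[0]
    lhs = np.eye(N) - (1.0 - alpha) * A
    try:
        X = scipy.linalg.solve(lhs, alpha * np.eye(N), assume_a="sym")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - alpha>0 keeps lhs SPD
        raise np.linalg.LinAlgError(f"resolvent solve is singular: {exc}") from exc
    return _as_result(X, "RWR", "limit", alpha=alpha, truth=P.truth)


def rwr_limit_ideal(spec: IdealizedSpec, alpha: float) -> SmoothingResult:
    """RWR limiting matrix of the idealized block TPM, in closed block form.

    Block ``i`` of the limit is ``alpha I + q_i J`` and every between-block
    entry is ``q_{k+1}``, with::

        q_i     = (1 - alpha) (d + alpha (1 - N d) / n_i) / (alpha + (1 - alpha) N d)
        q_{k+1} = (1 - alpha) d / (alpha + (1 - alpha) N d)

    Rows sum to 1 exactly in the algebra:
    ``alpha + n_i q_i + (N - n_i) q_{k+1} = 1``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie strictly in (0, 1)")
    N, d = spec.N, spec.d
    denom = alpha + (1.0 - alpha) * N * d
    q_out = (1.0 - alpha) * d / denom
    P = np.full((N, N), q_out)
    pos = 0
    for n in spec.block_sizes:
        q_i = (1.0 - alpha) * (d + alpha * (1.0 - N * d) / n) / denom
        P[pos : pos + n, pos : pos + n] = q_i
        pos += n
    P[np.diag_indices(N)] += alpha
    return _as_result(P, "RWR", "limit", alpha=alpha, truth=spec.truth())


def ideal_rwr_coefficients(spec: IdealizedSpec, alpha: float) -> tuple[np.ndarray, float]:
    """Return ``(q_1..q_k, q_{k+1})`` of the closed-form RWR limit."""
    N, d = spec.N, spec.d
    denom = alpha + (1.0 - alpha) * N * d
    q = np.array(
        [(1.0 - alpha) * (d + alpha * (1.0 - N * d) / n) / denom for n in spec.block_sizes]
    )
    return q, (1.0 - alpha) * d / denom
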