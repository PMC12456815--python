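"""Synthetic Hi-C generators with known domain structure.

Three generative settings feed the evaluation harness:

1. **Idealized TPM** (:func:`make_ideal_tpm`): a symmetric doubly stochastic
   block matrix with ``k`` diagonal blocks (TADs) of sizes ``n_1..n_k``.
   Within block ``i`` every entry (diagonal included) equals
   ``(1 - (N - n_i) d) / n_i`` and every between-block entry equals ``d``,
   so each row and column sums to 1 exactly.  Uniform noise can then be
   added (:func:`add_symmetric_noise`) to emulate an observed matrix.

2. **Power-decay count model** (:func:`simulate_biophysical`): expected
   counts follow the empirical distance-decay law
   ``log A_ij = c + d_exp * log(j - i)`` off the diagonal and
   ``log A_ii = c1`` on it; an over-dispersed negative-binomial background
   ``B`` (variance ``z * mean``, ``z > 1``) is boosted inside ``k`` random
   contiguous domains by Poisson effects with block-level intensity
   ``lambda_b ~ Unif(lambda_low, lambda_high)``, and sparsity is imposed by
   zeroing a ``pi1`` fraction of within-domain and ``pi2`` fraction of
   outside-domain cells.

3. **Multinomial subsampling** (:func:`subsample_counts`): thins a bulk
   matrix to a single-cell-like sequencing depth by redrawing a fixed
   number of contacts with cell probabilities proportional to the observed
   counts.

All randomness flows through an explicit integer seed; every output matrix
is exactly symmetric (sampled on the upper triangle and mirrored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ContactMatrix, DomainPartition, StochasticMatrix

__all__ = [
    "IdealizedSpec",
    "BiophysicalSpec",
    "make_ideal_tpm",
    "add_symmetric_noise",
    "simulate_biophysical",
    "random_contiguous_partition",
    "subsample_counts",
]


@dataclass(frozen=True)
class IdealizedSpec:
    """Parameters of the idealized block TPM.

    Attributes
    ----------
    N : total locus count.
    block_sizes : sizes ``n_1..n_k`` of the ``k`` diagonal blocks; must sum
        to ``N``.
    d : between-block transition probability (>= 0).  Feasibility requires
        ``1 - (N - n_i) d >= 0`` for every block.
    noise_high : upper bound of the Unif(0, noise_high) observation noise.
    """

    N: int
    block_sizes: tuple[int, ...]
    d: float = 0.0
    noise_high: float = 0.02

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(n) for n in self.block_sizes))
        if self.N < 1 or any(n < 1 for n in self.block_sizes):
            raise ValueError("N and every block size must be positive")
        if sum(self.block_sizes) != self.N:
            raise ValueError(
                f"block sizes sum to {sum(self.block_sizes)}, expected N = {self.N}"
            )
        if self.d < 0:
            raise ValueError("d must be non-negative")
        for n in self.block_sizes:
            if 1.0 - (self.N - n) * self.d < -1e-15:
                raise ValueError(
                    f"infeasible spec: block of size {n} would get negative "
                    f"within-block mass 1 - (N - n) d = {1 - (self.N - n) * self.d:g}"
                )
        if self.noise_high < 0:
            raise ValueError("noise_high must be non-negative")

    @property
    def k(self) -> int:
        return len(self.block_sizes)

    def truth(self) -> DomainPartition:
        return DomainPartition.from_block_sizes(self.block_sizes)


@dataclass(frozen=True)
class BiophysicalSpec:
    """Parameters of the power-decay count simulator.

    ``d_exp`` is the (negative) decay exponent of the distance law; the name
    avoids clashing with the idealized model's between-block probability.
    """

    N: int = 1000
    c: float = float(np.log(20.0))
    c1: float = float(np.log(20.0))
    d_exp: float = -0.4
    z: float = 1.2
    k: int = 20
    lambda_low: float = 0.5
    lambda_high: float = 1.0
    pi1: float = 0.1
    pi2: float = 0.2

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be positive")
        if self.c1 < self.c:
            raise ValueError("c1 must be at least c")
        if self.z <= 1.0:
            raise ValueError(
                "z must exceed 1 (over-dispersed background); a Poisson "
                "background (z = 1) is not supported"
            )
        if not (0 < self.lambda_low <= self.lambda_high):
            raise ValueError("require 0 < lambda_low <= lambda_high")
        if self.k > self.N or self.k < 1:
            raise ValueError("k must lie in 1..N")
        for name in ("pi1", "pi2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def make_ideal_tpm(spec: IdealizedSpec) -> StochasticMatrix:
    """Build the idealized doubly stochastic block TPM.

    Returns a :class:`StochasticMatrix` whose ``truth`` attribute carries
    the ``k``-block :class:`DomainPartition`.
    """
    N, d = spec.N, spec.d
    P = np.full((N, N), d, dtype=float)
    pos = 0
    for n in spec.block_sizes:
        val = (1.0 - (N - n) * d) / n
        if val < 0:
            raise ValueError("negative within-block value; spec infeasible")
        P[pos : pos + n, pos : pos + n] = val
        pos += n
    return StochasticMatrix(P, tolerance=1e-12, truth=spec.truth())


def add_symmetric_noise(P: StochasticMatrix, high: float, seed: int) -> np.ndarray:
    """Add i.i.d. Unif(0, high) noise, sampled on the upper triangle and mirrored.

    The result is symmetric and entrywise >= ``P`` but no longer stochastic;
    re-balancing is the next pipeline stage's job, so a plain array is
    returned.
    """
    if high < 0:
        raise ValueError("noise bound must be non-negative")
    N = P.N
    rng = np.random.default_rng(seed)
    R = np.zeros((N, N))
    iu = np.triu_indices(N)
    R[iu] = rng.uniform(0.0, high, size=len(iu[0]))
    R = R + np.triu(R, 1).T
    return P.values + R


def random_contiguous_partition(N: int, k: int, rng: np.random.Generator) -> DomainPartition:
    """Uniformly random partition of ``[0, N)`` into ``k`` contiguous blocks.

    Draws ``k - 1`` distinct interior cut points uniformly from the ``N - 1``
    possible boundaries.
    """
    if k > N:
        raise ValueError(f"cannot cut {N} loci into {k} blocks")
    cuts = rng.choice(N - 1, size=k - 1, replace=False) + 1 if k > 1 else np.array([], int)
    return DomainPartition.from_boundaries(N, sorted(int(c) for c in cuts))


def _domain_mask_upper(partition: DomainPartition, N: int) -> np.ndarray:
    """Boolean upper-triangle (incl. diagonal) mask of within-domain cells."""
    labels = np.empty(N, dtype=int)
    for b, seg in enumerate(partition.segments):
        labels[seg.start : seg.end] = b
    same = labels[:, None] == labels[None, :]
    return np.triu(same)


def simulate_biophysical(spec: BiophysicalSpec, seed: int) -> ContactMatrix:
    """Simulate an observed count matrix under the power-decay domain model.

    Stages (all sampled on the upper triangle and mirrored for symmetry):

    1. expected matrix ``A`` with ``A_ij = exp(c + d_exp log(j - i))`` for
       ``i < j`` and ``A_ii = exp(c1)``;
    2. background ``B_ij ~ NegBin(mean A_ij, variance z A_ij)``, using the
       size/probability parameterization ``r = mu / (z - 1)``, ``p = 1/z``
       (the unique negative binomial with the stated first two moments);
    3. a uniformly random contiguous partition into ``k`` blocks;
    4. domain boost ``D_ij ~ Poisson(lambda_b B_ij)`` inside block ``b``
       (``lambda_b ~ Unif(lambda_low, lambda_high)``, one draw per block),
       zero elsewhere;
    5. full matrix ``B + D``;
    6. structured zeros: a ``pi1`` fraction of within-domain and ``pi2``
       fraction of outside-domain upper-triangle cells are set to 0.

    Returns the observed matrix with the true partition attached.
    """
    rng = np.random.default_rng(seed)
    N = spec.N

    j, i = np.meshgrid(np.arange(N), np.arange(N))
    dist = (j - i).astype(float)
    A = np.zeros((N, N))
    off = np.triu(dist > 0)
    A[off] = np.exp(spec.c + spec.d_exp * np.log(dist[off]))
    np.fill_diagonal(A, np.exp(spec.c1))

    iu = np.triu_indices(N)
    mu = A[iu]
    r = mu / (spec.z - 1.0)
    B = np.zeros((N, N), dtype=np.int64)
    B[iu] = rng.negative_binomial(r, 1.0 / spec.z)
    B = B + np.triu(B, 1).T

    truth = random_contiguous_partition(N, spec.k, rng)
    lambdas = rng.uniform(spec.lambda_low, spec.lambda_high, size=spec.k)

    D = np.zeros((N, N), dtype=np.int64)
    for b, seg in enumerate(truth.segments):
        sl = slice(seg.start, seg.end)
        block = B[sl, sl]
        n = seg.width
        ui, uj = np.triu_indices(n)
        draws = rng.poisson(lambdas[b] * block[ui, uj])
        Db = np.zeros((n, n), dtype=np.int64)
        Db[ui, uj] = draws
        D[sl, sl] = Db + np.triu(Db, 1).T

    E = B + D
    assert (E >= 0).all()

    within = _domain_mask_upper(truth, N)
    upper = np.zeros((N, N), dtype=bool)
    upper[iu] = True
    for mask, rate in ((within & upper, spec.pi1), (~within & upper, spec.pi2)):
        cells = np.flatnonzero(mask)
        n_zero = int(round(rate * len(cells)))
        if n_zero:
            chosen = rng.choice(cells, size=n_zero, replace=False)
            E.flat[chosen] = 0
    E = np.triu(E) + np.triu(E, 1).T

    return ContactMatrix(E, truth=truth)


def subsample_counts(M: ContactMatrix, rate: float, seed: int) -> ContactMatrix:
    """Multinomially subsample a bulk matrix to a fraction of its depth.

    Draws ``round(rate * total)`` contacts (``total`` counted over the upper
    triangle including the diagonal) from a multinomial whose cell
    probabilities are proportional to the observed counts; the lower
    triangle is set by mirroring.  Sampling is with replacement, so at
    ``rate = 1`` the total is preserved but individual cells resample.
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must lie in (0, 1]")
    total = M.total_upper()
    if total <= 0:
        raise ValueError("cannot subsample an all-zero matrix")
    rng = np.random.default_rng(seed)
    N = M.N
    iu = np.triu_indices(N)
    probs = M.counts[iu].astype(float)
    probs /= probs.sum()
    n_draw = int(round(rate * total))
    sampled = rng.multinomial(n_draw, probs)
    out = np.zeros((N, N), dtype=np.int64)
    out[iu] = sampled
    out = out + np.triu(out, 1).T
    return ContactMatrix(out, truth=M.truth)
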