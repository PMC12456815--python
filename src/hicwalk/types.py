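"""Core data containers shared across the pipeline.

A Hi-C experiment is summarised as a symmetric ``N x N`` matrix of contact
counts between equal-sized genomic bins (loci).  The pipeline moves such a
matrix through three representations:

* :class:`ContactMatrix` — raw non-negative integer counts, optionally
  carrying the ground-truth domain structure used to generate it;
* :class:`StochasticMatrix` — a symmetric doubly stochastic transition
  probability matrix (TPM), the output of Knight-Ruiz balancing and of
  every random-walk smoothing step;
* :class:`DomainPartition` — an ordered tiling of the ``N`` loci into
  contiguous segments, each flagged as a domain (TAD) or a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "ContactMatrix",
    "StochasticMatrix",
    "DomainPartition",
    "Segment",
    "require_symmetric",
]

#: tolerance used when *validating* that a stored stochastic matrix is
#: balanced; balancing itself may achieve a tighter (recorded) tolerance.
DEFAULT_STOCHASTIC_TOL = 1e-6


def require_symmetric(values: np.ndarray, tol: float = 0.0, name: str = "matrix") -> None:
    """Raise ``ValueError`` unless ``values`` is square and symmetric within ``tol``."""
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be square, got shape {values.shape}")
    dev = np.abs(values - values.T).max() if values.size else 0.0
    if dev > tol:
        raise ValueError(f"{name} is asymmetric: max |M - M.T| = {dev:g} > {tol:g}")


@dataclass(frozen=True)
class Segment:
    """Half-open bin interval ``[start, end)`` flagged as domain or gap."""

    start: int
    end: int
    kind: Literal["domain", "gap"] = "domain"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"empty or negative segment [{self.start}, {self.end})")
        if self.kind not in ("domain", "gap"):
            raise ValueError(f"segment kind must be 'domain' or 'gap', got {self.kind!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DomainPartition:
    """Ordered contiguous segments tiling the ``N`` loci exactly.

    Coordinates are 0-based half-open throughout the package; conversion to
    1-based inclusive happens only at the I/O boundary.
    """

    N: int
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be positive")
        segs = tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        pos = 0
        for seg in segs:
            if seg.start != pos:
                raise ValueError(
                    f"segments must tile [0, {self.N}) without gaps/overlap; "
                    f"expected start {pos}, got {seg.start}"
                )
            pos = seg.end
        if pos != self.N:
            raise ValueError(f"segments cover [0, {pos}) but N = {self.N}")

    @classmethod
    def from_block_sizes(cls, sizes: Sequence[int], kind: str = "domain") -> "DomainPartition":
        """Partition built from consecutive block sizes (all same ``kind``)."""
        edges = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        segs = tuple(Segment(int(a), int(b), kind) for a, b in zip(edges[:-1], edges[1:]))
        return cls(N=int(edges[-1]), segments=segs)

    @classmethod
    def from_boundaries(
        cls, N: int, boundaries: Sequence[int], min_domain: int = 1
    ) -> "DomainPartition":
        """Partition from interior boundary positions (sorted, in ``1..N-1``).

        Intervals narrower than ``min_domain`` are emitted as gaps.
        """
        edges = [0, *sorted(int(b) for b in boundaries), N]
        segs = []
        for a, b in zip(edges[:-1], edges[1:]):
            kind = "domain" if (b - a) >= min_domain else "gap"
            segs.append(Segment(a, b, kind))
        return cls(N=N, segments=tuple(segs))

    @property
    def n_domains(self) -> int:
        return sum(1 for s in self.segments if s.kind == "domain")

    def boundaries(self) -> list[int]:
        """Interior segment edges, ascending."""
        return [s.end for s in self.segments[:-1]]

    def block_sizes(self) -> list[int]:
        return [s.width for s in self.segments]


@dataclass
class ContactMatrix:
    """Symmetric non-negative integer count matrix, with optional truth."""

    counts: np.ndarray
    truth: Optional[DomainPartition] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        require_symmetric(self.counts, name="contact matrix")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("contact matrix has negative entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.array_equal(rounded, self.counts):
                raise ValueError("contact matrix entries must be integer-valued")
            self.counts = rounded.astype(np.int64)
        if self.truth is not None and self.truth.N != self.counts.shape[0]:
            raise ValueError("truth partition size does not match matrix")

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    def zero_fraction(self) -> float:
        """Fraction of zero entries over the full matrix."""
        return float(np.mean(self.counts == 0))

    def total_upper(self) -> int:
        """Total count over the upper triangle including the diagonal."""
        iu = np.triu_indices(self.N)
        return int(self.counts[iu].sum())


@dataclass
class StochasticMatrix:
    """Symmetric doubly stochastic real matrix (a TPM).

    ``tolerance`` records the achieved balancing error, i.e. the maximum
    absolute deviation of any row/column sum from 1 at construction time.
    """

    values: np.ndarray
    tolerance: float = field(default=DEFAULT_STOCHASTIC_TOL)
    truth: Optional[DomainPartition] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        require_symmetric(self.values, tol=1e-9, name="stochastic matrix")
        if self.values.min() < 0:
            raise ValueError("stochastic matrix has negative entries")
        dev = self.max_balance_deviation()
        if dev > max(self.tolerance, DEFAULT_STOCHASTIC_TOL):
            raise ValueError(
                f"row/column sums deviate from 1 by {dev:g}, beyond tolerance "
                f"{self.tolerance:g}"
            )
        self.tolerance = max(self.tolerance, dev)

    @property
    def N(self) -> int:
        return self.values.shape[0]

    def max_balance_deviation(self) -> float:
        rows = np.abs(self.values.sum(axis=1) - 1.0).max()
        cols = np.abs(self.values.sum(axis=0) - 1.0).max()
        return float(max(rows, cols))
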