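"""Domain (TAD) callers producing contiguous partitions of the loci.

Three callers are provided:

* :func:`insulation_caller` — an insulation-score boundary finder: for each
  candidate boundary the mean contact intensity in a square window
  straddling the diagonal is computed; boundaries are strict local minima
  of this profile that dip below a data-driven threshold (profile mean
  minus one standard deviation).  The threshold is relative, so the caller
  is invariant to positive rescaling of the matrix.
* :func:`pair_caller` — deterministically declares every two consecutive
  loci a domain; reproduces a known degenerate failure mode of some
  published callers on smoothed matrices.
* :func:`single_domain_caller` — lumps all loci into one domain, the other
  degenerate failure mode (ARI 0 against any ground truth).

External TAD callers can be plugged in through :class:`ExternalCaller`,
which shells out to any program that reads a dense matrix file and writes a
partition file in the package's BED-like dialect.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np

from .types import DomainPartition, Segment, StochasticMatrix, require_symmetric

__all__ = [
    "insulation_profile",
    "insulation_caller",
    "pair_caller",
    "single_domain_caller",
    "InsulationCaller",
    "PairCaller",
    "SingleDomainCaller",
    "ExternalCaller",
    "Caller",
]


class Caller(Protocol):
    """Adapter contract: anything mapping a matrix to a partition.

    ``name`` labels the caller in evaluation reports.
    """

    name: str

    def __call__(self, M: np.ndarray) -> DomainPartition: ...


def _as_array(M) -> np.ndarray:
    if isinstance(M, StochasticMatrix):
        return M.values
    if hasattr(M, "counts"):
        return np.asarray(M.counts, dtype=float)
    return np.asarray(M, dtype=float)


def insulation_profile(M: np.ndarray, window: int) -> np.ndarray:
    """Insulation signal at every interior boundary ``b`` in ``1..N-1``.

    The signal is the mean of the ``window x window`` submatrix
    ``M[b-w:b, b:b+w]`` (rows upstream, columns downstream of the
    boundary), truncated at the matrix edges.  Low values mean little
    contact across the boundary — the signature of a domain edge.
    """
    A = _as_array(M)
    N = A.shape[0]
    w = int(window)
    sig = np.empty(N - 1)
    for b in range(1, N):
        rows = slice(max(0, b - w), b)
        cols = slice(b, min(N, b + w))
        sig[b - 1] = A[rows, cols].mean()
    return sig


def insulation_caller(
    M, window: int = 5, min_domain: int = 3
) -> DomainPartition:
    """Call domains from local minima of the insulation profile.

    A boundary at ``b`` is accepted when its signal is a strict local
    minimum of the profile and falls below ``mean(profile) - std(profile)``.
    Intervals between accepted boundaries narrower than ``min_domain`` bins
    are emitted as gaps; the output tiles ``[0, N)`` exactly.
    """
    A = _as_array(M)
    require_symmetric(A, tol=1e-8, name="input matrix")
    N = A.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= N / 2:
        raise ValueError(f"window {window} too large for N = {N} (need w < N/2)")
    sig = insulation_profile(A, window)
    threshold = sig.mean() - sig.std()
    boundaries = []
    for idx in range(len(sig)):
        left = sig[idx - 1] if idx > 0 else np.inf
        right = sig[idx + 1] if idx < len(sig) - 1 else np.inf
        if sig[idx] < left and sig[idx] < right and sig[idx] < threshold:
            boundaries.append(idx + 1)  # profile index idx is boundary b = idx+1
    return DomainPartition.from_boundaries(N, boundaries, min_domain=min_domain)


def pair_caller(N: int) -> DomainPartition:
    """Partition ``[0, N)`` into consecutive width-2 domains.

    For odd ``N`` the final width-1 segment is still emitted as a domain.
    """
    if N < 2:
        raise ValueError("pair caller needs at least 2 loci")
    edges = list(range(0, N, 2)) + [N]
    if edges[-2] == N:
        edges = edges[:-1]
    segs = tuple(Segment(a, b, "domain") for a, b in zip(edges[:-1], edges[1:]))
    return DomainPartition(N=N, segments=segs)


def single_domain_caller(N: int) -> DomainPartition:
    """One domain covering all loci — the 'no structure found' output."""
    if N < 1:
        raise ValueError("N must be positive")
    return DomainPartition(N=N, segments=(Segment(0, N, "domain"),))


@dataclass
class InsulationCaller:
    """Configured insulation caller usable wherever a :class:`Caller` is expected."""

    window: int = 5
    min_domain: int = 3
    name: str = "insulation"

    def __call__(self, M) -> DomainPartition:
        return insulation_caller(M, window=self.window, min_domain=self.min_domain)


@dataclass
class PairCaller:
    name: str = "pairs"

    def __call__(self, M) -> DomainPartition:
        return pair_caller(_as_array(M).shape[0])


@dataclass
class SingleDomainCaller:
    name: str = "single"

    def __call__(self, M) -> DomainPartition:
        return single_domain_caller(_as_array(M).shape[0])


@dataclass
class ExternalCaller:
    """Adapter to an external TAD caller executable.

    The command is invoked as ``cmd <matrix.tsv> <partition.bed>``: it must
    read a dense TSV matrix and write a partition in the package's BED-like
    format (see :mod:`hicwalk.io`).  This lets published callers be slotted
    into the evaluation harness without reimplementing them.
    """

    command: list[str]
    name: str = "external"

    def __call__(self, M) -> DomainPartition:
        from .io import read_partition, write_matrix

        A = _as_array(M)
        with tempfile.TemporaryDirectory() as tmp:
            mat_path = Path(tmp) / "matrix.tsv"
            part_path = Path(tmp) / "partition.bed"
            write_matrix(A, mat_path, fmt="dense-tsv")
            subprocess.run(
                [*self.command, str(mat_path), str(part_path)], check=True
            )
            return read_partition(part_path)
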