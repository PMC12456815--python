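"""Text formats for matrices, partitions, and pipeline configuration.

Two matrix dialects are supported:

* ``dense-tsv`` — tab-separated dense matrix with a header row of 0-based
  bin indices; floats are written at fixed precision so stochastic
  matrices round-trip within 1e-12 and integer matrices exactly.
* ``coo`` — three tab-separated columns ``i j value`` storing the upper
  triangle only (``i <= j``, 0-based), sorted; symmetry is structural.

Partitions are BED-like text: ``chrom  start  end  kind  id`` with 0-based
half-open bin intervals (the chrom column is a placeholder since the
package works on one intra-chromosomal matrix at a time).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .types import ContactMatrix, DomainPartition, Segment

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "PipelineConfig",
    "MATRIX_FORMATS",
]

MATRIX_FORMATS = ("dense-tsv", "coo")
_SYMMETRY_TOL = 1e-9
_CHROM_PLACEHOLDER = "bin"


class MatrixFormatError(ValueError):
    """File does not parse under the declared dialect."""


def _check_format(fmt: str) -> None:
    if fmt not in MATRIX_FORMATS:
        raise ValueError(
            f"unsupported matrix format {fmt!r}; supported: {', '.join(MATRIX_FORMATS)}"
        )


def _finalize(values: np.ndarray, path) -> ContactMatrix | np.ndarray:
    if values.size and values.min() < 0:
        raise ValueError(f"{path}: negative entries are not allowed")
    dev = np.abs(values - values.T).max() if values.size else 0.0
    if dev > _SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance (|dev| = {dev:g})")
    values = 0.5 * (values + values.T)
    if np.array_equal(values, np.rint(values)):
        return ContactMatrix(values.astype(np.int64))
    return values


def read_matrix(path, fmt: str = "dense-tsv", N: Optional[int] = None):
    """Read a symmetric matrix; integer-valued input becomes a ContactMatrix.

    COO input is mirrored from the stored upper triangle (``N`` may be given
    when trailing empty bins would otherwise be dropped); dense input is
    validated for symmetry within 1e-9 and symmetrized by averaging.
    """
    _check_format(fmt)
    path = Path(path)
    try:
        if fmt == "dense-tsv":
            raw = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
            if raw.shape[0] != raw.shape[1]:
                raise MatrixFormatError(
                    f"{path}: dense matrix is {raw.shape[0]}x{raw.shape[1]}, not square"
                )
            return _finalize(raw, path)
        triplets = np.loadtxt(path, delimiter="\t", ndmin=2)
        if triplets.size == 0:
            raise MatrixFormatError(f"{path}: empty COO file")
        if triplets.shape[1] != 3:
            raise MatrixFormatError(f"{path}: COO needs 3 columns, got {triplets.shape[1]}")
        i = triplets[:, 0].astype(int)
        j = triplets[:, 1].astype(int)
        v = triplets[:, 2]
        if (i > j).any():
            raise MatrixFormatError(f"{path}: COO must store the upper triangle (i <= j)")
        n = N if N is not None else int(j.max()) + 1
        M = np.zeros((n, n))
        M[i, j] = v
        M = M + np.triu(M, 1).T
        return _finalize(M, path)
    except (OSError, UnicodeDecodeError) as exc:
        raise MatrixFormatError(f"{path}: cannot read file ({exc})") from exc
    except ValueError as exc:
        if isinstance(exc, MatrixFormatError) or "asymmetric" in str(exc) or "negative" in str(exc):
            raise
        raise MatrixFormatError(f"{path}: parse failure ({exc})") from exc


def write_matrix(M, path, fmt: str = "dense-tsv") -> None:
    """Write a matrix in a canonical (diffable) serialization."""
    _check_format(fmt)
    path = Path(path)
    values = M.counts if isinstance(M, ContactMatrix) else getattr(M, "values", None)
    if values is None:
        values = np.asarray(M)
    integer = np.issubdtype(np.asarray(values).dtype, np.integer)
    fmt_token = "%d" if integer else "%.12e"
    try:
        if fmt == "dense-tsv":
            header = "\t".join(str(k) for k in range(values.shape[0]))
            np.savetxt(path, values, fmt=fmt_token, delimiter="\t", header=header, comments="")
            return
        iu, ju = np.triu_indices(values.shape[0])
        keep = values[iu, ju] != 0
        with open(path, "w") as fh:
            for a, b in zip(iu[keep], ju[keep]):
                fh.write(f"{a}\t{b}\t{fmt_token % values[a, b]}\n")
    except OSError as exc:
        raise OSError(f"failed writing matrix to {path}: {exc}") from exc


def write_partition(p: DomainPartition, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for idx, seg in enumerate(p.segments):
            fh.write(
                f"{_CHROM_PLACEHOLDER}\t{seg.start}\t{seg.end}\t{seg.kind}\t{idx}\n"
            )


def read_partition(path) -> DomainPartition:
    path = Path(path)
    segs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{line_no}: expected >= 4 columns (chrom start end kind)"
                )
            segs.append(Segment(int(parts[1]), int(parts[2]), parts[3]))
    if not segs:
        raise ValueError(f"{path}: empty partition file")
    return DomainPartition(N=segs[-1].end, segments=tuple(segs))


@dataclass
class PipelineConfig:
    """Fully materialized run configuration; round-trips through YAML.

    Every seed and grid is stored explicitly so a written config plus the
    package version pins a run exactly.
    """

    seed: int = 0
    matrix_format: str = "dense-tsv"
    ideal: dict = field(
        default_factory=lambda: {
            "N": 200,
            "block_sizes": [50, 30, 20, 90, 10],
            "d": 0.0,
            "noise_high": 0.02,
        }
    )
    biophysical: dict = field(
        default_factory=lambda: {
            "N": 1000,
            "c": float(np.log(20.0)),
            "c1": float(np.log(20.0)),
            "d_exp": -0.4,
            "z": 1.2,
            "k": 20,
            "lambda_low": 0.5,
            "lambda_high": 1.0,
            "pi1": 0.1,
            "pi2": 0.2,
        }
    )
    kr: dict = field(default_factory=lambda: {"tol": 1e-6, "max_iter": 1000})
    rws_steps: list = field(default_factory=lambda: [2, 3, 4, 5, 10])
    rwr_alphas: list = field(default_factory=lambda: [0.05, 0.1, 0.2, 0.5])
    caller: dict = field(
        default_factory=lambda: {"method": "insulation", "window": 5, "min_domain": 3}
    )
    gap_mode: str = "run"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
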