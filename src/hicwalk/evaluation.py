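"""Congruence scoring and the replicated study harnesses.

Partitions are compared with the Hubert-Arabie adjusted Rand index (ARI),
a chance-corrected pair-counting agreement measure in ``[-1, 1]`` that
equals 1 exactly when two partitions coincide up to relabeling.  Loci of a
domain form one cluster; how non-domain (gap) loci enter the clustering is
configurable (``gap_mode``), defaulting to one cluster per maximal gap run.

Three study designs wrap the full pipeline
(generate -> balance -> smooth -> call domains -> score):

* :func:`run_study1` — single idealized matrix plus uniform noise;
* :func:`run_study2` — replicated power-decay count simulations scored
  against the known generating domains;
* :func:`run_study3` — replicated multinomial subsamples of a bulk matrix
  scored against each caller's own partition of the full matrix;
* :func:`sparsity_sweep` — study 3 across a grid of subsampling rates,
  tracking the induced matrix sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .balance import kr_normalize
from .domains import Caller
from .randomwalk import rwr_limit, rws
from .synthetic import (
    BiophysicalSpec,
    IdealizedSpec,
    add_symmetric_noise,
    make_ideal_tpm,
    simulate_biophysical,
    subsample_counts,
)
from .types import ContactMatrix, DomainPartition, StochasticMatrix

__all__ = [
    "partition_to_labels",
    "adjusted_rand_index",
    "EvaluationReport",
    "run_study1",
    "run_study2",
    "run_study3",
    "sparsity_sweep",
    "DEFAULT_RWS_STEPS",
    "DEFAULT_RWR_ALPHAS",
]

#: smoothing grids used throughout the studies
DEFAULT_RWS_STEPS: tuple[int, ...] = (2, 3, 4, 5, 10)
DEFAULT_RWR_ALPHAS: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5)


def partition_to_labels(p: DomainPartition, gap_mode: str = "run") -> np.ndarray:
    """Cluster-label vector of length ``N`` for a partition.

    Domains each get a unique label.  Gap loci are labelled according to
    ``gap_mode``:

    * ``"run"`` (default): each maximal run of consecutive gap segments is
      one cluster;
    * ``"singleton"``: every gap locus is its own cluster;
    * ``"pooled"``: all gap loci share a single cluster.

    Labels are consecutive integers assigned in genomic order (for
    ``"pooled"``, the shared gap label is the first gap's position in that
    order).
    """
    if gap_mode not in ("run", "singleton", "pooled"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    labels = np.empty(p.N, dtype=int)
    next_label = 0
    pooled_label = None
    prev_gap = False
    for seg in p.segments:
        if seg.kind == "domain":
            labels[seg.start : seg.end] = next_label
            next_label += 1
            prev_gap = False
        elif gap_mode == "singleton":
            for pos in range(seg.start, seg.end):
                labels[pos] = next_label
                next_label += 1
            prev_gap = False
        elif gap_mode == "pooled":
            if pooled_label is None:
                pooled_label = next_label
                next_label += 1
            labels[seg.start : seg.end] = pooled_label
        else:  # run
            if prev_gap:
                labels[seg.start : seg.end] = next_label - 1
            else:
                labels[seg.start : seg.end] = next_label
                next_label += 1
            prev_gap = True
    return labels


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings.

    ``(Index - ExpectedIndex) / (MaxIndex - ExpectedIndex)`` over the
    ``C(n, 2)`` locus pairs.  The degenerate 0/0 case (e.g. both labelings a
    single cluster, or both all singletons) is defined as 1 when the
    labelings are identical up to relabeling and 0 otherwise.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items to compare partitions")
    table = _contingency(a, b)

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1.0) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    denom = max_index - expected
    if denom == 0.0:
        same = (np.count_nonzero(table, axis=1) == 1).all() and (
            np.count_nonzero(table, axis=0) == 1
        ).all()
        return 1.0 if same else 0.0
    return float((sum_cells - expected) / denom)


def ari_partitions(p: DomainPartition, q: DomainPartition, gap_mode: str = "run") -> float:
    """ARI between two partitions of the same loci."""
    if p.N != q.N:
        raise ValueError("partitions cover different locus counts")
    return adjusted_rand_index(
        partition_to_labels(p, gap_mode), partition_to_labels(q, gap_mode)
    )


@dataclass
class EvaluationReport:
    """Tidy per-replicate ARI table with summary accessors.

    ``table`` columns: ``replicate``, ``condition``, ``caller``, ``ari``.
    ``diagnostics`` (optional) carries per-replicate extras such as the
    zero percentage of a subsampled matrix.
    """

    table: pd.DataFrame
    n_reps: int
    seeds: tuple[int, ...]
    diagnostics: pd.DataFrame | None = None

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def medians(self) -> pd.DataFrame:
        """Median ARI per (condition, caller), conditions in pipeline order."""
        med = (
            self.table.groupby(["condition", "caller"], sort=False)["ari"]
            .median()
            .reset_index()
            .rename(columns={"ari": "median_ari"})
        )
        return med

    def median(self, condition: str, caller: str) -> float:
        sel = self.table[
            (self.table["condition"] == condition) & (self.table["caller"] == caller)
        ]["ari"]
        if sel.empty:
            raise KeyError(f"no rows for condition={condition!r}, caller={caller!r}")
        return float(sel.median())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        med = self.medians()
        return {
            "n_reps": self.n_reps,
            "seeds": list(self.seeds),
            "medians": {
                f"{row.condition}|{row.caller}": row.median_ari
                for row in med.itertuples()
            },
        }


def _spawn_seeds(master_seed: int, n: int) -> tuple[int, ...]:
    """Derive per-replicate seeds from one master seed, reproducibly."""
    ss = np.random.SeedSequence(master_seed)
    return tuple(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n))


def condition_matrices(
    PKR: StochasticMatrix,
    rws_steps: Iterable[int] = DEFAULT_RWS_STEPS,
    rwr_alphas: Iterable[float] = DEFAULT_RWR_ALPHAS,
) -> dict[str, np.ndarray]:
    """KR matrix plus the RWS power grid and RWR limit grid, labelled."""
    conds: dict[str, np.ndarray] = {"KR": PKR.values}
    for s in rws_steps:
        conds[f"RWS{s}s"] = rws(PKR, s).matrix.values
    for a in rwr_alphas:
        conds[f"RWR{a:g}"] = rwr_limit(PKR, a).matrix.values
    return conds


def _score_conditions(
    conds: dict[str, np.ndarray],
    callers: Sequence[Caller],
    truth_labels: dict[str, np.ndarray] | np.ndarray,
    replicate: int,
    gap_mode: str,
    rows: list,
) -> None:
    for cond, matrix in conds.items():
        for caller in callers:
            try:
                part = caller(matrix)
            except Exception as exc:
                raise RuntimeError(
                    f"caller {caller.name!r} failed on condition {cond!r}"
                ) from exc
            labels = partition_to_labels(part, gap_mode)
            ref = (
                truth_labels[caller.name]
                if isinstance(truth_labels, dict)
                else truth_labels
            )
            rows.append(
                {
                    "replicate": replicate,
                    "condition": cond,
                    "caller": caller.name,
                    "ari": adjusted_rand_index(ref, labels),
                }
            )


def run_study1(
    spec: IdealizedSpec,
    callers: Sequence[Caller],
    seed: int,
    rws_steps: Iterable[int] = DEFAULT_RWS_STEPS,
    rwr_alphas: Iterable[float] = DEFAULT_RWR_ALPHAS,
    gap_mode: str = "run",
) -> EvaluationReport:
    """Idealized-matrix study: one noisy realization through the pipeline.

    Conditions: the noise-free TPM (``ideal``), the noisy observation
    (``noisy``), its KR balancing (``KR``), and the RWS/RWR grids applied
    to the balanced matrix.  ARIs are against the spec's true blocks.
    """
    P = make_ideal_tpm(spec)
    truth = partition_to_labels(P.truth, gap_mode)
    Pobs = add_symmetric_noise(P, spec.noise_high, seed)
    PKR = kr_normalize(Pobs).matrix
    conds: dict[str, np.ndarray] = {"ideal": P.values, "noisy": Pobs}
    conds.update(condition_matrices(PKR, rws_steps, rwr_alphas))
    rows: list = []
    _score_conditions(conds, callers, truth, 0, gap_mode, rows)
    return EvaluationReport(table=pd.DataFrame(rows), n_reps=1, seeds=(seed,))


def run_study2(
    spec: BiophysicalSpec,
    callers: Sequence[Caller],
    n_reps: int,
    seed: int,
    rws_steps: Iterable[int] = DEFAULT_RWS_STEPS,
    rwr_alphas: Iterable[float] = DEFAULT_RWR_ALPHAS,
    gap_mode: str = "run",
) -> EvaluationReport:
    """Replicated power-decay simulations scored against the known domains."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = _spawn_seeds(seed, n_reps)
    rows: list = []
    for rep, rep_seed in enumerate(seeds):
        E = simulate_biophysical(spec, rep_seed)
        truth = partition_to_labels(E.truth, gap_mode)
        PKR = kr_normalize(E).matrix
        conds: dict[str, np.ndarray] = {"count": E.counts.astype(float)}
        conds.update(condition_matrices(PKR, rws_steps, rwr_alphas))
        _score_conditions(conds, callers, truth, rep, gap_mode, rows)
    return EvaluationReport(table=pd.DataFrame(rows), n_reps=n_reps, seeds=seeds)


def run_study3(
    M: ContactMatrix,
    rate: float,
    callers: Sequence[Caller],
    n_reps: int,
    seed: int,
    rws_steps: Iterable[int] = DEFAULT_RWS_STEPS,
    rwr_alphas: Iterable[float] = DEFAULT_RWR_ALPHAS,
    gap_mode: str = "run",
) -> EvaluationReport:
    """Subsampling study: each subsample scored against the bulk partition.

    There is no generative ground truth here; each caller's partition of
    the full matrix ``M`` serves as its own reference, so the ARI measures
    congruence of the thinned (and optionally smoothed) data with bulk.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    refs = {
        caller.name: partition_to_labels(caller(M.counts.astype(float)), gap_mode)
        for caller in callers
    }
    seeds = _spawn_seeds(seed, n_reps)
    rows: list = []
    diag_rows: list = []
    for rep, rep_seed in enumerate(seeds):
        sub = subsample_counts(M, rate, rep_seed)
        diag_rows.append(
            {"replicate": rep, "rate": rate, "zero_pct": 100.0 * sub.zero_fraction()}
        )
        PKR = kr_normalize(sub).matrix
        conds: dict[str, np.ndarray] = {"count": sub.counts.astype(float)}
        conds.update(condition_matrices(PKR, rws_steps, rwr_alphas))
        _score_conditions(conds, callers, refs, rep, gap_mode, rows)
    return EvaluationReport(
        table=pd.DataFrame(rows),
        n_reps=n_reps,
        seeds=seeds,
        diagnostics=pd.DataFrame(diag_rows),
    )


def sparsity_sweep(
    M: ContactMatrix,
    rates: Sequence[float],
    callers: Sequence[Caller],
    n_reps: int,
    seed: int,
    rws_steps: Iterable[int] = (),
    rwr_alphas: Iterable[float] = (),
    gap_mode: str = "run",
) -> pd.DataFrame:
    """Median sparsity and ARI across a grid of subsampling rates.

    Returns one row per (rate, condition, caller) with the median zero
    percentage of the subsampled matrices and the median ARI against the
    bulk partition.  Smoothing grids default to empty (count + KR only) to
    keep sweeps cheap; pass grids explicitly to include them.
    """
    rates = list(rates)
    if not rates:
        raise ValueError("rates list must be non-empty")
    if any(not (0.0 < r <= 1.0) for r in rates):
        raise ValueError("every rate must lie in (0, 1]")
    out_rows = []
    for idx, rate in enumerate(rates):
        report = run_study3(
            M,
            rate,
            callers,
            n_reps,
            seed + idx,
            rws_steps=rws_steps,
            rwr_alphas=rwr_alphas,
            gap_mode=gap_mode,
        )
        zero_med = float(report.diagnostics["zero_pct"].median())
        for row in report.medians().itertuples():
            out_rows.append(
                {
                    "rate": rate,
                    "median_zero_pct": zero_med,
                    "condition": row.condition,
                    "caller": row.caller,
                    "median_ari": row.median_ari,
                }
            )
    return pd.DataFrame(out_rows)
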