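"""Row-action solvers: Kaczmarz, relaxed ART, and the parallel-block (PB) scheme.

All solvers act on the sparse system ``A x = b`` built by
:mod:`blockart.geometry`.  One *iteration* is a full pass over all m rows
(all projections applied once).

* ``kaczmarz_step`` / ``kaczmarz_solve`` — plain orthogonal projection of
  the iterate onto the hyperplane of one equation at a time.  Kept as an
  independent, unrelaxed numpy implementation; with ``lam = 1`` and no
  constraint the ART path reproduces it exactly.
* ``art_solve`` — the relaxed update
  ``x <- x + lam * (b_i - a^i . x) / ||a^i||^2 * a^i`` with an optional
  non-negativity constraint (densities cannot be negative).  Convergent for
  a constant relaxation factor ``0 < lam < 2``; values outside that range
  trigger a warning, not an error, so divergence studies remain possible.
* ``pb_solve`` — the parallel-block scheme: rows are split into M
  contiguous, near-equal blocks; every block runs one full ART sweep from
  the shared iterate, and the block results ``y^(i)`` are merged as
  ``x <- sum_i W_i y^(i)`` with diagonal weights
  ``w_j^i = (column-j sum over block i) / (column-j sum over all rows)``,
  i.e. pixels are credited to each block in proportion to how much of the
  total ray coverage of that pixel the block owns.  The merge order and
  within-block row order are fixed, so the result is bit-identical for any
  number of worker threads, and M = 1 reduces to ART exactly.

Reconstruction quality is tracked per iteration as the max-abs pixel error
against the (optional) known truth and as the relative residual
``||A x - b|| / ||b||``.
"""

from __future__ import annotations

import time
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._kernels import sweep_rows
from .errors import DegenerateRowError
from .geometry import SystemMatrix

__all__ = [
    "SolverConfig",
    "BlockPartition",
    "BlockWeights",
    "ReconResult",
    "art_step",
    "kaczmarz_step",
    "constrain",
    "art_solve",
    "kaczmarz_solve",
    "partition_rows",
    "block_weights",
    "pb_iterate",
    "pb_solve",
]

_CONSTRAINTS = ("none", "nonneg")
_TIMINGS = ("per_step", "per_iteration")


@dataclass(frozen=True)
class SolverConfig:
    """Run parameters shared by the ART and PB solvers.

    Parameters
    ----------
    lam : float
        Relaxation factor; the sweep is convergent for ``0 < lam < 2``.
        Values outside that open interval raise a warning.
    constraint : {"nonneg", "none"}
        Whether to clamp negative pixel values to zero.
    constraint_timing : {"per_step", "per_iteration"}
        Apply the clamp after every row projection (default) or once per
        full iteration.
    max_iterations : int
        Hard cap on full sweeps.
    stop_delta : float, optional
        Stop once the max-abs error against the supplied truth drops below
        this value (checked at iteration boundaries; requires truth).
    stop_residual : float, optional
        Stop once the relative residual drops below this value.
    x0 : ndarray, optional
        Starting vector; defaults to zeros.
    record_residual : bool
        Compute the relative residual every iteration (one extra sparse
        matvec).  When off and no residual stop rule is set, the history
        column holds NaN; long parameter sweeps turn this off.
    """

    lam: float = 1.0
    constraint: str = "nonneg"
    constraint_timing: str = "per_step"
    max_iterations: int = 1000
    stop_delta: float | None = None
    stop_residual: float | None = None
    x0: np.ndarray | None = field(default=None, repr=False)
    record_residual: bool = True

    def __post_init__(self):
        if self.constraint not in _CONSTRAINTS:
            raise ValueError(f"constraint must be one of {_CONSTRAINTS}")
        if self.constraint_timing not in _TIMINGS:
            raise ValueError(f"constraint_timing must be one of {_TIMINGS}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.lam < 2.0:
            warnings.warn(
                f"relaxation lam={self.lam} lies outside (0, 2); the sweep is "
                "only guaranteed convergent for 0 < lam < 2",
                stacklevel=3,
            )


@dataclass(frozen=True)
class BlockPartition:
    """Contiguous, disjoint row ranges ``[start, stop)`` covering all rows."""

    m_rows: int
    blocks: tuple[tuple[int, int], ...]

    @property
    def M(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class BlockWeights:
    """Diagonal merge weights, one length-N vector per block.

    ``W[i, j]`` is block i's share of the total ray coverage of pixel j;
    for pixels no ray touches the share is ``1/M`` so the weights always
    sum to one and the merge leaves untouched pixels alone.
    """

    W: np.ndarray  # (M, N)


@dataclass
class ReconResult:
    """Final iterate plus the per-iteration convergence history."""

    x: np.ndarray
    iterations_run: int
    history: pd.DataFrame  # iteration, delta, relative_residual, seconds_elapsed
    config: SolverConfig
    partition: BlockPartition | None = None

    def min_delta(self) -> float:
        """Smallest max-abs error reached over the run (nan without truth)."""
        return float(np.nanmin(self.history["delta"].to_numpy())) if self.iterations_run else np.nan

    def iterations_to(self, target_delta: float) -> int | None:
        """First iteration whose max-abs error fell below ``target_delta``."""
        deltas = self.history["delta"].to_numpy()
        below = np.nonzero(deltas < target_delta)[0]
        return int(self.history["iteration"].iloc[below[0]]) if below.size else None


def _row_array(row) -> np.ndarray:
    if sp.issparse(row):
        return np.asarray(row.todense()).ravel()
    return np.asarray(row, dtype=float).ravel()


def art_step(x: np.ndarray, row, p: float, lam: float) -> np.ndarray:
    """One relaxed projection of ``x`` toward the hyperplane ``a . x = p``.

    With ``lam = 1`` the result lies exactly on the hyperplane (orthogonal
    projection).  ``row`` may be dense or a 1 x N sparse row.
    """
    a = _row_array(row)
    nrm2 = float(a @ a)
    if nrm2 <= 0.0:
        raise DegenerateRowError("cannot project onto an all-zero row")
    x = np.asarray(x, dtype=float)
    return x + lam * ((p - float(a @ x)) / nrm2) * a


def kaczmarz_step(x: np.ndarray, row, p: float) -> np.ndarray:
    """Orthogonal projection of ``x`` onto the hyperplane ``a . x = p``."""
    a = _row_array(row)
    nrm2 = float(a @ a)
    if nrm2 <= 0.0:
        raise DegenerateRowError("cannot project onto an all-zero row")
    x = np.asarray(x, dtype=float)
    return x + ((p - float(a @ x)) / nrm2) * a


def constrain(x: np.ndarray) -> np.ndarray:
    """Non-negativity operator: elementwise ``max(x, 0)``; idempotent."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def _as_csr(A) -> sp.csr_matrix:
    if isinstance(A, SystemMatrix):
        return A.csr
    return sp.csr_matrix(A)


def _prepare(A, b, config: SolverConfig, truth):
    csr = _as_csr(A)
    b = np.asarray(b, dtype=float).ravel()
    if b.shape[0] != csr.shape[0]:
        raise ValueError(f"projection vector length {b.shape[0]} != matrix rows {csr.shape[0]}")
    if truth is not None:
        truth = np.asarray(truth, dtype=float).ravel()
        if truth.shape[0] != csr.shape[1]:
            raise ValueError("truth length does not match the number of pixels")
    if config.stop_delta is not None and truth is None:
        raise ValueError("stop_delta requires a truth vector")
    if config.x0 is not None:
        x = np.array(config.x0, dtype=float).ravel().copy()
        if x.shape[0] != csr.shape[1]:
            raise ValueError("x0 length does not match the number of pixels")
    else:
        x = np.zeros(csr.shape[1])
    row_norm2 = np.asarray(csr.multiply(csr).sum(axis=1)).ravel()
    b_norm = float(np.linalg.norm(b))
    return csr, b, truth, x, row_norm2, b_norm


def _record(history, k, x, truth, csr, b, b_norm, t0, config):
    delta = float(np.max(np.abs(x - truth))) if truth is not None else np.nan
    if config.record_residual or config.stop_residual is not None:
        res = float(np.linalg.norm(csr @ x - b))
        rel = res / b_norm if b_norm > 0 else res
    else:
        rel = np.nan
    history.append((k, delta, rel, time.perf_counter() - t0))
    return delta, rel


def _should_stop(config: SolverConfig, delta: float, rel: float) -> bool:
    if config.stop_delta is not None and delta < config.stop_delta:
        return True
    if config.stop_residual is not None and rel < config.stop_residual:
        return True
    return False


def _finish(x, history, config, partition=None) -> ReconResult:
    frame = pd.DataFrame(
        history, columns=["iteration", "delta", "relative_residual", "seconds_elapsed"]
    )
    return ReconResult(x=x, iterations_run=len(history), history=frame,
                       config=config, partition=partition)


def art_solve(A, b, config: SolverConfig, truth: np.ndarray | None = None) -> ReconResult:
    """Relaxed ART over all rows in matrix order.

    With ``lam = 1`` and ``constraint = "none"`` this is exactly the
    Kaczmarz algorithm.  Stop rules are evaluated at iteration boundaries.
    """
    csr, b, truth, x, row_norm2, b_norm = _prepare(A, b, config, truth)
    clamp_step = config.constraint == "nonneg" and config.constraint_timing == "per_step"
    clamp_iter = config.constraint == "nonneg" and config.constraint_timing == "per_iteration"
    history: list[tuple] = []
    t0 = time.perf_counter()
    for k in range(1, config.max_iterations + 1):
        sweep_rows(csr.indptr, csr.indices, csr.data, row_norm2, b, x,
                   config.lam, 0, csr.shape[0], clamp_step)
        if clamp_iter:
            np.maximum(x, 0.0, out=x)
        delta, rel = _record(history, k, x, truth, csr, b, b_norm, t0, config)
        if _should_stop(config, delta, rel):
            break
    return _finish(x, history, config)


def kaczmarz_solve(A, b, max_iterations: int = 100,
                   truth: np.ndarray | None = None,
                   x0: np.ndarray | None = None) -> ReconResult:
    """Pure Kaczmarz: cyclic orthogonal projections, no relaxation, no clamp.

    Implemented independently of the compiled ART path (plain numpy row
    loop); intended for small systems and as a cross-check oracle.
    """
    config = SolverConfig(lam=1.0, constraint="none", max_iterations=max_iterations, x0=x0)
    csr, b, truth, x, row_norm2, b_norm = _prepare(A, b, config, truth)
    history: list[tuple] = []
    t0 = time.perf_counter()
    indptr, indices, data = csr.indptr, csr.indices, csr.data
    for k in range(1, max_iterations + 1):
        for r in range(csr.shape[0]):
            lo, hi = indptr[r], indptr[r + 1]
            if row_norm2[r] <= 0.0:
                continue
            cols = indices[lo:hi]
            vals = data[lo:hi]
            coef = (b[r] - vals @ x[cols]) / row_norm2[r]
            x[cols] += coef * vals
        delta, rel = _record(history, k, x, truth, csr, b, b_norm, t0, config)
        if _should_stop(config, delta, rel):
            break
    return _finish(x, history, config)


def partition_rows(m_rows: int, M: int) -> BlockPartition:
    """Split rows into M contiguous blocks whose sizes differ by at most 1.

    The first ``m_rows mod M`` blocks get the extra row.
    """
    if M < 1 or M > m_rows:
        raise ValueError(f"M must satisfy 1 <= M <= m_rows={m_rows}, got {M}")
    base, extra = divmod(m_rows, M)
    blocks, start = [], 0
    for i in range(M):
        size = base + (1 if i < extra else 0)
        blocks.append((start, start + size))
        start += size
    return BlockPartition(m_rows=m_rows, blocks=tuple(blocks))


def block_weights(A, partition: BlockPartition) -> BlockWeights:
    """Per-block diagonal merge weights from block-wise column sums.

    The total column sum is accumulated as the sum of the per-block sums, so
    for M = 1 every hit column gets the weight exactly 1.0.  Columns with a
    zero total (pixels no ray touches) get ``1/M`` in every block, keeping
    ``sum_i W_i = I`` globally.
    """
    csr = _as_csr(A)
    if partition.m_rows != csr.shape[0]:
        raise ValueError("partition does not match the matrix row count")
    M = partition.M
    block_cs = np.empty((M, csr.shape[1]))
    for i, (lo, hi) in enumerate(partition.blocks):
        block_cs[i] = np.asarray(csr[lo:hi].sum(axis=0)).ravel()
    total = block_cs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(total > 0.0, block_cs / total, 1.0 / M)
    return BlockWeights(W=W)


def _block_sweep(csr, row_norm2, b, x, lam, lo, hi, clamp_step):
    y = x.copy()
    sweep_rows(csr.indptr, csr.indices, csr.data, row_norm2, b, y, lam, lo, hi, clamp_step)
    return y


def _combine(ys: Sequence[np.ndarray], W: np.ndarray) -> np.ndarray:
    x_new = W[0] * ys[0]
    for i in range(1, W.shape[0]):
        x_new += W[i] * ys[i]
    return x_new


def pb_iterate(x, A, b, partition: BlockPartition, weights: BlockWeights,
               config: SolverConfig) -> np.ndarray:
    """One PB iteration: per-block ART sweeps from shared x, weighted merge.

    Blocks are swept in ascending row order and merged in ascending block
    order, so the result does not depend on how the block sweeps are
    scheduled across workers.
    """
    csr = _as_csr(A)
    b = np.asarray(b, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != csr.shape[1] or b.shape[0] != csr.shape[0]:
        raise ValueError("dimension mismatch between x, A and b")
    row_norm2 = np.asarray(csr.multiply(csr).sum(axis=1)).ravel()
    clamp_step = config.constraint == "nonneg" and config.constraint_timing == "per_step"
    ys = [_block_sweep(csr, row_norm2, b, x, config.lam, lo, hi, clamp_step)
          for lo, hi in partition.blocks]
    x_new = _combine(ys, weights.W)
    if config.constraint == "nonneg" and config.constraint_timing == "per_iteration":
        np.maximum(x_new, 0.0, out=x_new)
    return x_new


def pb_solve(A, b, M: int, config: SolverConfig,
             truth: np.ndarray | None = None, workers: int = 1) -> ReconResult:
    """Parallel-block reconstruction with M blocks.

    ``workers`` only controls how many threads execute the independent
    block sweeps between barriers; the numbers produced are identical for
    any worker count, and ``M = 1`` reproduces :func:`art_solve` bitwise.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    csr, b, truth, x, row_norm2, b_norm = _prepare(A, b, config, truth)
    partition = partition_rows(csr.shape[0], M)
    weights = block_weights(csr, partition)
    clamp_step = config.constraint == "nonneg" and config.constraint_timing == "per_step"
    clamp_iter = config.constraint == "nonneg" and config.constraint_timing == "per_iteration"
    history: list[tuple] = []
    t0 = time.perf_counter()
    pool = ThreadPoolExecutor(max_workers=workers) if workers > 1 else None
    try:
        for k in range(1, config.max_iterations + 1):
            if pool is None:
                ys = [_block_sweep(csr, row_norm2, b, x, config.lam, lo, hi, clamp_step)
                      for lo, hi in partition.blocks]
            else:
                ys = list(pool.map(
                    lambda blk: _block_sweep(csr, row_norm2, b, x, config.lam,
                                             blk[0], blk[1], clamp_step),
                    partition.blocks))
            x = _combine(ys, weights.W)
            if clamp_iter:
                np.maximum(x, 0.0, out=x)
            delta, rel = _record(history, k, x, truth, csr, b, b_norm, t0, config)
            if _should_stop(config, delta, rel):
                break
    finally:
        if pool is not None:
            pool.shutdown()
    return _finish(x, history, config, partition=partition)
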