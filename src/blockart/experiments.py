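"""Convergence experiments: the max-abs error metric, relaxation sweeps and
the block-scaling study.

Reconstruction quality is judged by the worst pixel,
``Delta = max_i |f(pix_i) - f~(pix_i)|``, the maximum absolute difference
between the true and the reconstructed density.  Experiments count the
iterations needed to push Delta below a target; wall time is logged for
reference but never used as a result, since at fixed problem size time is
proportional to the iteration count while iteration counts are
hardware-independent.

``sweep`` scans a (pkt, lam) grid on the limited-angle problem and records
iterations-to-target per cell, censored at an iteration cap (the portable
analogue of a wall-clock cutoff).  ``optimal_lambda`` reads the argmin off a
sweep.  ``block_scaling`` runs the PB solver for M = 1..M_max blocks and
fits iterations(M) by ordinary least squares: splitting the rows into more
blocks leaves each block with poorer information, so the iteration count
grows (near-linearly) with M; the headline number is the fitted slope
divided by the single-block iteration count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NoConvergenceError
from .geometry import build_grid, build_system, make_one_by_one
from .phantom import Phantom, forward_project, phantom_f1, rasterize
from .solvers import SolverConfig, art_solve, pb_solve

__all__ = [
    "max_abs_error",
    "SweepResult",
    "sweep",
    "optimal_lambda",
    "BlockScaling",
    "block_scaling",
    "fit_iteration_line",
]


def max_abs_error(recon: np.ndarray, truth: np.ndarray) -> float:
    """Worst-pixel error ``max_i |truth_i - recon_i|``."""
    recon = np.asarray(recon, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if recon.shape != truth.shape:
        raise ValueError(f"length mismatch: {recon.shape[0]} vs {truth.shape[0]}")
    return float(np.max(np.abs(recon - truth)))


@dataclass
class SweepResult:
    """Grid of iterations-to-target over (pkt, lam); censored cells hold NaN."""

    table: pd.DataFrame  # columns: pkt, lam, iterations, censored, seconds
    target_delta: float
    iter_cap: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _iterations_or_censored(result, target_delta: float):
    it = result.iterations_to(target_delta)
    return (it, False) if it is not None else (None, True)


def sweep(
    grid_n: int,
    pkt_values: Sequence[int],
    lam_values: Sequence[float],
    algorithm: str = "art",
    M: int = 1,
    target_delta: float = 0.05,
    iter_cap: int = 5000,
    phantom: Phantom | None = None,
    constraint: str = "nonneg",
    workers: int = 1,
) -> SweepResult:
    """Iterations-to-target over the Cartesian (pkt, lam) grid.

    For each pkt the (1 x 1) system is built once and projections are
    synthesised noiselessly from the rasterized phantom (default ``f1``);
    each lam cell then runs the requested solver until Delta < target_delta
    or the iteration cap.
    """
    if not len(pkt_values) or not len(lam_values):
        raise ValueError("pkt_values and lam_values must be non-empty")
    if target_delta <= 0:
        raise ValueError("target_delta must be positive")
    if algorithm not in ("art", "pb"):
        raise ValueError("algorithm must be 'art' or 'pb'")
    grid = build_grid(grid_n)
    truth = rasterize(phantom if phantom is not None else phantom_f1(), grid)
    rows = []
    for pkt in pkt_values:
        A = build_system(make_one_by_one(pkt), grid)
        b = forward_project(A, truth)
        for lam in lam_values:
            config = SolverConfig(
                lam=float(lam),
                constraint=constraint,
                max_iterations=iter_cap,
                stop_delta=target_delta,
                record_residual=False,
            )
            t0 = time.perf_counter()
            if algorithm == "pb":
                result = pb_solve(A, b, M=M, config=config, truth=truth, workers=workers)
            else:
                result = art_solve(A, b, config=config, truth=truth)
            seconds = time.perf_counter() - t0
            iterations, censored = _iterations_or_censored(result, target_delta)
            rows.append((pkt, float(lam), iterations, censored, seconds))
    table = pd.DataFrame(rows, columns=["pkt", "lam", "iterations", "censored", "seconds"])
    return SweepResult(table=table, target_delta=target_delta, iter_cap=iter_cap)


def optimal_lambda(sweep_result: SweepResult) -> float:
    """Relaxation factor minimising iterations-to-target; ties to smallest lam.

    With several pkt values per lam, the best (smallest) iteration count
    across pkt represents each lam.
    """
    ok = sweep_result.table[~sweep_result.table["censored"]]
    if ok.empty:
        raise NoConvergenceError("every sweep cell was censored")
    per_lam = ok.groupby("lam")["iterations"].min()
    best = per_lam.min()
    return float(min(lam for lam, it in per_lam.items() if it == best))


def fit_iteration_line(m_values: Sequence[int], iterations: Sequence[float]):
    """OLS fit ``iterations = intercept + slope * M``; returns (slope, intercept)."""
    m_values = np.asarray(m_values, dtype=float)
    iterations = np.asarray(iterations, dtype=float)
    if m_values.shape[0] < 2:
        raise ValueError("need at least two points to fit a line")
    slope, intercept = np.polyfit(m_values, iterations, 1)
    return float(slope), float(intercept)


@dataclass
class BlockScaling:
    """Iterations-to-target per block count and the fitted linear growth."""

    iterations: dict[int, int]      # M -> iterations (uncensored only)
    excluded: list[int]             # M values that failed to converge in cap
    slope: float
    intercept: float
    ratio: float                    # slope / iterations at M = 1
    target_delta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"M": list(self.iterations), "iterations": list(self.iterations.values())}
        )


def block_scaling(
    grid_n: int,
    pkt: int,
    lam: float,
    phantom: Phantom | None = None,
    M_max: int = 10,
    target_delta: float = 0.1,
    iter_cap: int = 12000,
    constraint: str = "nonneg",
) -> BlockScaling:
    """PB iteration growth with the number of blocks M = 1..M_max.

    The cap is a safety net, not a study parameter: it is set high enough
    (12,000 by default) that every block count of the shipped study
    conditions converges, because censored runs would contradict the point
    of measuring iterations *until* the target.  Any M that still fails is
    excluded from the fit and reported in ``excluded``.  Requires
    M_max >= 3 so a slope is meaningful.
    """
    if M_max < 3:
        raise ValueError("M_max must be >= 3 to report a slope")
    grid = build_grid(grid_n)
    truth = rasterize(phantom if phantom is not None else phantom_f1(), grid)
    A = build_system(make_one_by_one(pkt), grid)
    b = forward_project(A, truth)
    iterations: dict[int, int] = {}
    excluded: list[int] = []
    for M in range(1, M_max + 1):
        config = SolverConfig(
            lam=lam, constraint=constraint, max_iterations=iter_cap,
            stop_delta=target_delta, record_residual=False,
        )
        result = pb_solve(A, b, M=M, config=config, truth=truth)
        it, censored = _iterations_or_censored(result, target_delta)
        if censored:
            excluded.append(M)
        else:
            iterations[M] = it
    if 1 not in iterations:
        raise NoConvergenceError("the single-block run did not reach the target")
    slope, intercept = fit_iteration_line(list(iterations), list(iterations.values()))
    return BlockScaling(
        iterations=iterations,
        excluded=excluded,
        slope=slope,
        intercept=intercept,
        ratio=slope / iterations[1],
        target_delta=target_delta,
    )
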