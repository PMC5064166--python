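# Methods

This note records the models, numerical choices and limitations behind
`ecgibench`, in the order of the processing chain.

## Activation phantoms

Activity is **kinematic**: a phase field `phi(n, t)` is prescribed on the
atrial mesh and mapped to potentials through a fixed waveform template.
No ionic or reaction–diffusion model is solved. This is deliberate: the
inverse/targets/metrics chain only requires signals with a known spectral
and phase structure, and a prescribed field provides an *exact* ground
truth for the dominant frequency, the phase map, and the rotor core —
something a biophysical simulation cannot.

* **Waveform.** `w(phi) = cos(phi + beta (cos phi - 1))` with `beta = 0.6`.
  The warp is monotone for `beta < 1`, so `w` is 2π-periodic and smooth,
  attains exactly [-1, 1], and is time-asymmetric (fast rise toward the
  depolarization peak, slower decay). Its harmonic amplitudes decay like
  Bessel functions of `beta`, so the fundamental dominates; the Hilbert
  phase of `w(2 pi f t)` advances at `2 pi f` to machine precision over an
  integer number of cycles.
* **Sinus rhythm (SR).** Plane wave `phi = 2 pi f (t - s_n / c)` along the
  +x axis at `f = 1.2` Hz with conduction velocity `c = 1000` mm/s (a
  physiological atrial value; it sets the spatial wavelength, nothing
  downstream is sensitive to it).
* **Simple AF (SAF).** Inside a geodesic ball (default radius 25 mm)
  around the rotor core: `phi = 2 pi f_rot t - theta(n)` with
  `theta(n)` the azimuth of node `n` about the core in its tangent plane
  and `f_rot = 7.3` Hz; outside, a plane wave at 4.7 Hz. The default core
  is the +x extreme of the mesh ("right-atrial" end). The rotor-region
  radius is not dictated by the source problem; 25 mm makes the region a
  realistic ~10% of a human-sized atrial surface and is configurable.
* **Complex AF (CAF).** Same construction at 6.8 / 5.4 Hz, plus fibrosis
  emulation: a seeded random 25% of nodes get amplitude x0.1 and a fixed
  activation-time offset drawn uniformly within ±10% of their local cycle
  length. This reproduces the *statistical* footprint of fibrotic dropout
  (weak, desynchronized nodes), not its electrophysiology.
* **Region boundary.** The frequency transition is a hard geodesic ball by
  default; a logistic blend of the two phase fields on the unit circle
  (width parameter `boundary_blend_mm`) is available for boundary-effect
  studies. Nodes within 5 mm of the boundary are excluded from
  DF-recovery scoring, since their compartment is ambiguous.
* **Topology.** On a *closed* surface the sum of one-ring topological
  charges of any phase field is identically zero, so the rotor's ±2π
  charge is always balanced by an opposite charge that sits on the
  region boundary where the two phase fields meet. A single isolated
  singularity is only realizable on an open patch; tests that require
  "exactly one" singularity therefore use a planar disk mesh whose
  compensating charge falls outside the patch.

What passing phantom-based tests do **not** show: robustness to rotor
meander, wavebreak, restitution, broadband fibrillatory spectra, or real
torso geometry. The phantom emits two narrowband tones; consequences of
that are noted under "Benchmark findings" below.

## Forward problem

* **Transfer operator.** Either loaded from file (MatrixMarket / HDF5) or
  synthesized as the infinite-medium monopole kernel
  `A'[m, n] = A_n / (4 pi sigma ||e_m - v_n||)` with `A_n` the barycentric
  node area and `sigma = 0.2` S/m. The kernel has the correct 1/r
  structure and severe ill-conditioning (effective numerical rank ~81 of
  162 at the tiny scale), which is what the inverse methods need to be
  exercised; it is a physically simple volume conductor, not a
  boundary-element model.
* **Referencing.** `A = (I - (1/|W|) 1 w^T) A'` maps the raw operator to
  the Wilson-Central-Terminal-referenced one; the mean of `A x` over the
  WCT lead set is exactly zero. The default WCT set is *all leads*
  (configurable); which electrodes form the physical WCT is a modeling
  choice the benchmark does not depend on.
* **Noise.** White Gaussian at a global SNR (signal power pooled over all
  leads and samples). A per-lead convention would change little here
  because the synthetic leads are statistically similar.
* **Filtering.** 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`), band 3–30 Hz for fibrillatory runs and 0–30 Hz
  (low-pass) for sinus rhythm. Zero phase is essential: phase maps and SP
  trajectories are extracted downstream and a causal filter would bias
  them. The gold standard for potential metrics is the *true* epicardial
  field passed through the same filter.
* **SER perturbation.** Per-row i.i.d. Gaussian error scaled so each row
  attains the requested signal-to-error ratio, emulating imperfect
  volume-conductor knowledge.

## Inverse solvers

All spectral solvers share one factorization: plain SVD when the penalty
is the identity, otherwise a generalized SVD of the pair `(A, L)` built
from the QR of the stacked matrix `[A; L]` followed by an SVD of the
upper orthonormal block. Filtered solutions, residuals and seminorms are
then O(rank) per parameter value, which is what makes per-instant L-curve
selection affordable.

* **Regularization operators.** Order 0: identity. Order 1: E x N
  edge-incidence differences scaled by 1/edge-length (a discrete
  gradient; only `L^T L` enters the normal equations, so the rectangular
  form is exact). Order 2: umbrella graph Laplacian
  `I - D^{-1} Adjacency` (rows sum to zero).
* **L-curve.** `(log rho, log eta)` on a log-spaced grid of 50 points
  within constrained bounds `[(1e-4 s1)^2, s1^2]` (`s1` = largest
  singular value of `A`); the corner is the maximum of the three-point
  circumscribed-circle (Menger) curvature, ties toward smaller lambda; a
  non-positive maximum is flagged low-confidence. The bounds implement
  the usual "avoid extreme values" constraint; the exact constants are a
  package choice.
* **Oracle parameter.** For benchmark diagnostics only: lambda minimizing
  the RDMS against the known truth on a 1000-point logarithmic grid,
  per instant or globally.
* **TSVD/DSVD.** Truncation index via a discrete L-curve over k; DSVD
  filter `s/(s + lambda)` with lambda from the L-curve on a linear-in-s
  bound. Known behavior: on spectra with clustered generalized singular
  values the discrete corner can snap to a cluster edge and over-fit at
  intermediate SNR (see "Benchmark findings").
* **TV.** `||y - A x||^2 + lambda ||L x||_1` with the L1 term smoothed as
  `sum_e sqrt(g_e^2 + eps^2)`, `eps = 1e-6 * median|L x0|` from a
  first-order Tikhonov warm start, minimized by IRLS (majorize–minimize,
  so the smoothed objective is non-increasing); 50 iterations, relative
  tolerance 1e-6, convergence flag returned. The data term is squared,
  the standard convex formulation; an unsquared residual norm only
  rescales the trade-off curve.
* **Bayes MAP.** `x = C_x A^T (A C_x A^T + C_n)^{-1} y` via Cholesky;
  `C_x` is the zero-mean sample covariance of 150 random time instants
  drawn from a 1 s training window disjoint from the estimation window;
  `C_n = sigma^2 I` with `sigma^2` the known injected noise power in
  benchmark mode. Because the prior is sampled from the true epicardial
  signal, Bayes is an upper bound, not a clinically available method.
* **Greensite.** SVD-whitening of the data matrix; each retained right
  singular direction is solved as a first-order Tikhonov problem with its
  own L-curve parameter and rotated back. The temporal truncation keeps
  the components carrying 99% of the data energy (configurable).
* **GMRES.** Arnoldi iteration on the normal equations `A^T A x = A^T y`
  from zero, 30 iterations, every iterate recorded, the iterate of
  minimal *data* residual returned. Since the data residual decreases
  with iteration on these problems, this rule effectively selects the
  least-regularized iterate — GMRES is accordingly the weakest method on
  noisy runs, which is the expected semi-convergence behavior of the
  selection rule, faithfully implemented.

## Target extraction

* **DF.** Welch periodogram per node: 2 s Hamming segments, 50% overlap,
  FFT zero-padded until the grid spacing is <= 0.1 Hz (0.0625 Hz at
  500 Hz sampling — the raw 2 s window alone would only give 0.5 Hz, too
  coarse to represent rates like 7.3 Hz). Peaks inside the analysis band
  (3–15 Hz for fibrillatory runs; lowered to 0.5 Hz for sinus rhythm,
  whose fundamental sits near 1 Hz) are screened by a harmonic-discard
  rule: a peak at `f` is discarded when a peak within 0.25 Hz of `f/2`
  carries at least 30% of its power. The two constants are package
  choices of the conventional screen.
* **Phase.** Per node: zero-phase band-pass from 3 Hz (or half the DF
  when the DF itself is below 3 Hz) to DF + 2 Hz, then the analytic
  signal's argument, wrapped to (-π, π].
* **SP detection.** Per node, the wrapped phase differences along the
  *ordered* one-ring cycle are summed; the discrete charge is an exact
  multiple of 2π, and |charge| = 2π marks a singularity (tolerance 0.5
  rad guards floating point). Adjacent same-chirality detections are one
  vortex seen by several rings and are merged; the representative is the
  node with the most uniform one-ring phase increments (the ring closest
  to the vortex center), ties toward the smallest index. Boundary nodes
  (open fans) are skipped.
* **Tracking.** Greedy nearest-neighbor linking of detections across
  frames within a 10 mm geodesic radius, gaps up to 2 frames tolerated;
  a track is kept iff it persists for at least 2 rotations at its core's
  local DF. The radius and gap are package choices. The SMF is the
  normalized spatial histogram of kept per-frame SP locations; the
  dominant SP is the kept track in the highest-DF area (ties: longest,
  then earliest).

## Metrics

RDMS and CC are applied per node over time (temporal version, the
default) or per instant over nodes; phases are scored on wrapped values
(a circular alternative — CC on `exp(i phi)` — is available behind a
flag but is not the default). RAE averages `|F_n - Fhat_n| / F_n` in
percent over nodes with a valid true DF. The SMF support is the exact
non-zero set (an epsilon threshold is available for noisy histograms).
Node areas in WUI/WOI use the barycentric convention (one third of the
incident-face area sum), which conserves total surface area — the raw
incident sum is available behind a flag; the two conventions shift the
weighted indicators slightly. The Wilcoxon helper is the two-sample
rank-sum test (the samples being compared are per-node metric
distributions from different solvers, which are unpaired in general).

## Benchmark findings (computed by the test suite)

On the tiny standard geometry (162-node atria / 42-lead torso, 500 Hz,
4 s estimation window, SAF pattern, SNR 10–40 dB, 5 seeds) — sizes chosen
so the whole grid runs in minutes on one CPU:

* Bayes MAP attains the best potential CC in every grid cell.
* The inter-solver spread in DF RAE (as a fraction of its percent scale)
  is far below the spread in potential CC: DF is robust where potentials
  are not, even though DF is computed *from* the reconstructed
  potentials.
* Instantaneous vs global zero-order Tikhonov: the selected lambdas
  differ by about a decade across time instants, yet the mean relative
  RDMS difference is ~5%.
* Metrics degrade as SNR drops from 40 to 10 dB for all solvers except
  TSVD-0, whose discrete truncation corner over-fits at 30 dB (RDMS
  0.394 at 30 dB vs 0.363 at 20 dB) — a genuine property of discrete
  L-curve selection on this kernel's clustered spectrum, documented
  rather than patched.
* Transfer-matrix error (SER 40 / 20 dB) degrades potential CC strictly
  and monotonically; the DF RAE, by contrast, is *invariant* down to
  about SER 5 dB, because every reconstructed node signal remains a
  mixture of the phantom's two narrowband tones and its dominant peak
  rarely flips. This is the phantom's cleanliness speaking: with
  broadband fibrillatory signals the DF error would respond sooner.

## Known limitations

* Kinematic phantoms: no meander, no wavebreak, two-line spectra.
* Monopole-kernel forward model: no torso inhomogeneity, no BEM.
* Graph (Dijkstra) geodesics on mesh edges, not exact polyhedral
  geodesics; distances are slightly overestimated on coarse meshes.
* The Bayes prior is an oracle prior; its results bound, rather than
  estimate, clinical performance.
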