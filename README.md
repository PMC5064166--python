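# ecgibench

Benchmarking framework for **electrocardiographic imaging (ECGI) during
atrial fibrillation**: synthetic epicardial activity phantoms, a pluggable
forward pipeline, fourteen regularized inverse solvers behind a
scikit-learn-style estimator interface, clinical-target extraction
(dominant frequency, phase maps, phase-singularity location), and a metric
suite for scoring reconstructions.

## The problem

ECGI reconstructs heart-surface potentials `x_t` from body-surface
potentials (BSPs) `y_t` through the linear volume-conductor model

    y_t = A x_t + eps,

where `A` is the leads-by-nodes transfer matrix. The problem is severely
ill-posed, so every practical method regularizes: penalized least squares
(Tikhonov of order 0/1/2, total variation), spectral truncation/damping
(TSVD, DSVD), statistical priors (Bayesian MAP, Greensite spatio-temporal
whitening), or iteration limits (GMRES). During fibrillation the clinically
relevant outputs are usually not the raw potentials but quantities derived
from them: per-node **dominant frequency (DF)** maps, instantaneous
**phase** maps, and the location of **phase singularities (SPs)** — the
cores of reentrant "rotor" activity and candidate ablation targets.

This package provides the full chain needed to benchmark solvers for those
targets on synthetic data where an exact ground truth exists:

1. **Phantoms** (`ecgibench.phantom`) — kinematic activation patterns on an
   arbitrary triangulated atrial surface: sinus rhythm (plane wave, 1.2 Hz),
   simple AF (one 7.3 Hz rotor in a geodesic region, 4.7 Hz remote tissue),
   and complex AF (6.8 Hz rotor region, 5.4 Hz remote, 25% fibrotic node
   dropout).
2. **Forward problem** (`ecgibench.forward`) — transfer matrix from file or
   from an area-weighted infinite-medium monopole kernel
   `A'[m,n] = A_n / (4 pi sigma r)`, Wilson-Central-Terminal referencing,
   projection, calibrated Gaussian noise (global SNR in dB), zero-phase
   4th-order Butterworth band filtering, and per-row transfer-matrix
   perturbation at a prescribed signal-to-error ratio (SER).
3. **Inverse solvers** (`ecgibench.inverse`) — Tik-g0/g1/g2, Tik-i0/i1/i2
   (global vs per-instant L-curve parameter), TSVD-0/1/2 (generalized SVD
   for orders 1–2), DSVD, TV (IRLS), Bayes MAP with an empirical spatial
   prior, Greensite (GS), and GMRES — all `fit(A, mesh=...)` /
   `predict(Y)` estimators registered by name in `SOLVER_REGISTRY`.
4. **Targets** (`ecgibench.targets`) — Welch-periodogram DF (2 s Hamming
   windows, 50% overlap, zero-padded to a <= 0.1 Hz grid, harmonic-discard
   rule), Hilbert phase after DF-adapted band-passing, topological-charge
   SP detection on one-ring cycles, persistence-filtered SP tracking, and
   the spatial mass function (SMF) of SP location.
5. **Metrics** (`ecgibench.metrics`) — Pearson CC and RDMS
   (`|| x/||x|| - xhat/||xhat|| ||`, range [0, 2]) for potentials and
   phases, relative absolute DF error (RAE, %), and the SMF suite: WUI and
   WOI (area-and-probability-weighted missed / spurious SP-region
   percentages), CC_SMF, and the geodesic mode distance (MD); plus a
   rank-sum Wilcoxon comparison helper.
6. **Benchmark runner + CLI** (`ecgibench.bench`, `ecgibench.cli`) — a
   config-driven grid (solvers x SNR x patterns) returning tidy pandas
   tables, and `ecgibench` subcommands `fixtures`, `simulate`, `forward`,
   `solve`, `targets`, `evaluate`, `bench`.

## Worked example

Simple-AF phantom on the standard tiny geometry, forward projection at
20 dB SNR, reconstruction with per-instant zero-order Tikhonov and with
the prior-informed Bayes MAP (prior from a disjoint 1 s training window):

```python
import numpy as np
from ecgibench import (make_pattern, simulate_pattern, kernel_transfer_matrix,
                       apply_wct_reference, forward_project, add_noise,
                       bandpass_filter, NoiseSpec, make_solver,
                       estimate_prior_covariance, df_map, potential_metrics, rae)
from ecgibench.bench import default_geometry

atria, torso = default_geometry("tiny")            # 162-node atria, 42-lead torso
pattern = make_pattern("SAF", seed=0)              # 7.3 Hz rotor, 4.7 Hz remote
x_true, truth = simulate_pattern(atria, pattern, duration=6.0, fs=500.0)

A = apply_wct_reference(kernel_transfer_matrix(atria, torso))
y_clean = forward_project(A, x_true)
y = bandpass_filter(add_noise(y_clean, NoiseSpec(snr_db=20, seed=1)), 3.0, 30.0)
x_gold = bandpass_filter(x_true, 3.0, 30.0).window(2.0, 6.0)

noise_var = np.mean(y_clean.values**2) / 10**2.0   # injected power at 20 dB
C_x = estimate_prior_covariance(x_true.window(0.5, 1.5), n_samples=150, seed=0)

for name in ("Tik-i0", "Bayes"):
    solver = make_solver(name)
    if name == "Bayes":
        solver.fit(A, C_x=C_x, noise_variance=noise_var)
    else:
        solver.fit(A, mesh=atria)
    x_hat = solver.predict(y.window(2.0, 6.0))
    rep = potential_metrics(x_gold.values, x_hat.values, "temporal")
    r = rae(df_map(x_gold), df_map(x_hat))
    rotor_df = np.median(df_map(x_hat).values[truth["region"]])
    print(f"{name:7s} CC {rep['CC'].mean:.3f}  RDMS {rep['RDMS'].mean:.3f}  "
          f"RAE {r:.2f} %  rotor-region DF {rotor_df:.2f} Hz")
```

Output:

```
Tik-i0  CC 0.879  RDMS 0.391  RAE 4.21 %  rotor-region DF 4.69 Hz
Bayes   CC 0.984  RDMS 0.149  RAE 0.00 %  rotor-region DF 7.31 Hz
```

Read: purely non-invasive Tikhonov reconstructs potentials only bluntly
(CC 0.88) and its spatial blur swallows the small fast-rotor region, yet
the node-averaged DF error stays small (4.2%) because most tissue is
classified correctly — DF is far more robust than the raw potentials. The
Bayes MAP solver, which is granted second-order statistics of the true
epicardial signal, recovers both the potentials and the full DF gradient
(rotor region at 7.31 Hz, i.e. within one spectral bin of the generating
7.3 Hz); it is an upper bound rather than a clinically available method.

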