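"""Forward problem: transfer matrix, referencing, projection, noise, filtering.

The forward pipeline maps epicardial potentials to body-surface potentials
(BSPs): ``Y' = A X``, referencing of ``A`` to the Wilson Central Terminal
(WCT), additive white Gaussian noise at a prescribed SNR, and zero-phase
Butterworth band filtering. A per-row transfer-matrix perturbation at a
given signal-to-error ratio (SER) supports sensitivity experiments.

The transfer operator is pluggable: load a matrix from file or synthesize
an infinite-medium monopole kernel between two meshes. Boundary-element
assembly is deliberately out of scope — the inverse methods are agnostic
to how ``A`` was produced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional
import warnings

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial import ConvexHull

from .mesh import TriMesh, node_areas
from .phantom import PotentialField

__all__ = [
    "TransferMatrix",
    "NoiseSpec",
    "kernel_transfer_matrix",
    "apply_wct_reference",
    "forward_project",
    "add_noise",
    "bandpass_filter",
    "perturb_transfer_matrix",
]


@dataclass(frozen=True)
class TransferMatrix:
    """Dense leads x nodes linear operator.

    ``referenced`` distinguishes the raw operator A' from the
    WCT-referenced A actually used for measurements.
    """

    entries: np.ndarray
    referenced: bool = False
    lead_positions: Optional[np.ndarray] = None

    def __post_init__(self):
        e = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if not np.isfinite(e).all():
            raise ValueError("transfer matrix entries must be finite")
        if e.shape[0] < 1 or e.shape[1] < 1:
            raise ValueError("transfer matrix must be at least 1x1")
        object.__setattr__(self, "entries", e)

    @property
    def n_leads(self) -> int:
        return self.entries.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise level: SNR in dB (np.inf = noiseless)."""

    snr_db: float
    seed: int = 0


def kernel_transfer_matrix(atria: TriMesh, torso: TriMesh,
                           conductivity: float = 0.2) -> TransferMatrix:
    """Infinite-medium monopole kernel between two surfaces.

    ``A'[m, n] = A_n / (4 pi sigma ||e_m - v_n||)`` with ``A_n`` the
    barycentric node area of atrial node ``n`` and ``e_m`` the torso lead
    positions. A physically simple volume-conductor stand-in with the
    correct 1/r structure and severe ill-conditioning, suitable for
    benchmarking the inverse chain on synthetic geometry.
    """
    if conductivity <= 0:
        raise ValueError("conductivity must be positive")
    leads = torso.vertices
    src = atria.vertices
    hull = ConvexHull(torso.vertices)
    # every atrial vertex must lie inside the torso hull (warning only)
    inside = np.all(
        src @ hull.equations[:, :3].T + hull.equations[:, 3][None, :]
        <= 1e-9, axis=1)
    if not inside.all():
        warnings.warn(f"{(~inside).sum()} atrial vertices outside the torso "
                      "hull; kernel may be non-physical")
    d = np.linalg.norm(leads[:, None, :] - src[None, :, :], axis=2)
    if np.any(d < 1e-9):
        raise ValueError("coincident lead and source points")
    areas = node_areas(atria)
    entries = areas[None, :] / (4 * np.pi * conductivity * d)
    return TransferMatrix(entries, referenced=False, lead_positions=leads)


def apply_wct_reference(A_raw: TransferMatrix,
                        wct_lead_indices=None) -> TransferMatrix:
    """Reference A' to the mean of the WCT lead set.

    ``A = (I - (1/|W|) 1 w^T) A'`` so that for any source x, the mean of
    ``A x`` over the WCT leads is exactly zero. Default WCT set: all leads.
    """
    if A_raw.referenced:
        raise ValueError("transfer matrix is already WCT-referenced")
    m = A_raw.n_leads
    if wct_lead_indices is None:
        wct = np.arange(m)
    else:
        wct = np.unique(np.asarray(wct_lead_indices, dtype=np.int64))
        if wct.size == 0 or wct.min() < 0 or wct.max() >= m:
            raise ValueError("invalid WCT lead index set")
    mean_rows = A_raw.entries[wct].mean(axis=0)
    return replace(A_raw, entries=A_raw.entries - mean_rows[None, :],
                   referenced=True)


def forward_project(A: TransferMatrix, X: PotentialField) -> PotentialField:
    """Project epicardial potentials to the torso: ``Y' = A X``."""
    if A.n_nodes != X.n_nodes:
        raise ValueError(f"A has {A.n_nodes} columns but the field has "
                         f"{X.n_nodes} nodes")
    return PotentialField(A.entries @ X.values, X.fs, X.t0)


def add_noise(Y: PotentialField, spec: NoiseSpec) -> PotentialField:
    """Add white Gaussian noise at a global SNR (all leads pooled)."""
    if np.isinf(spec.snr_db):
        return PotentialField(Y.values.copy(), Y.fs, Y.t0)
    p_signal = np.mean(Y.values ** 2)
    if p_signal == 0:
        raise ValueError("zero-power signal with finite SNR")
    p_noise = p_signal / 10 ** (spec.snr_db / 10)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, np.sqrt(p_noise), size=Y.values.shape)
    return PotentialField(Y.values + noise, Y.fs, Y.t0)


def _butter_sos(low_hz: float, high_hz: float, fs: float):
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low < high")
    if high_hz >= fs / 2:
        raise ValueError("high cutoff must be below Nyquist")
    if low_hz == 0:
        return butter(4, high_hz, btype="low", fs=fs, output="sos")
    return butter(4, [low_hz, high_hz], btype="band", fs=fs, output="sos")


def bandpass_filter(Y: PotentialField, low_hz: float,
                    high_hz: float) -> PotentialField:
    """4th-order Butterworth band filter, forward-backward (zero phase).

    ``low_hz = 0`` selects a pure low-pass. Zero-phase filtering is used
    because phase maps are extracted downstream and a causal filter would
    bias singularity-point trajectories.
    """
    sos = _butter_sos(low_hz, high_hz, Y.fs)
    return PotentialField(sosfiltfilt(sos, Y.values, axis=1), Y.fs, Y.t0)


def perturb_transfer_matrix(A: TransferMatrix, ser_db: float,
                            seed: int = 0) -> TransferMatrix:
    """Per-row i.i.d. Gaussian perturbation at a given SER (dB).

    Each row receives noise with power ``row power / 10**(ser/10)``,
    emulating imperfect knowledge of the volume conductor.
    """
    if np.isinf(ser_db):
        return A
    row_power = np.mean(A.entries ** 2, axis=1)
    if np.any(row_power == 0):
        raise ValueError("all-zero row with finite SER")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(row_power / 10 ** (ser_db / 10))
    err = rng.normal(size=A.entries.shape) * sigma[:, None]
    return replace(A, entries=A.entries + err)
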