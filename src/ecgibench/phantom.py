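"""Synthetic epicardial activity phantoms.

Kinematic (prescribed-phase) generators for the three activation patterns
used throughout the benchmark:

* ``SR``  — sinus rhythm: a plane wave sweeping the atria at the pacing
  rate (default 1.2 Hz).
* ``SAF`` — simple fibrillation: one functional reentry (rotor) spinning
  at 7.3 Hz inside a geodesic ball, with the remaining tissue activated
  as a plane wave at 4.7 Hz (a right-to-left frequency gradient).
* ``CAF`` — complex fibrillation: a rotor region at 6.8 Hz, remote tissue
  at 5.4 Hz, and 25% of nodes under fibrosis emulation (amplitude x0.1
  plus activation-time jitter up to 10% of the local cycle length).

Activity is kinematic, not reaction-diffusion: the inverse/targets/metrics
chain only needs signals with the stated spectral and phase structure, and
a prescribed phase field provides an exact ground truth for the dominant
frequency, the phase maps, and the rotor core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mesh import TriMesh, geodesic_distances_from

__all__ = [
    "ActivityPattern",
    "PotentialField",
    "action_potential_waveform",
    "simulate_pattern",
    "SR_RATE_HZ",
    "SAF_ROTOR_HZ",
    "SAF_REMOTE_HZ",
    "CAF_ROTOR_HZ",
    "CAF_REMOTE_HZ",
    "CAF_FIBROTIC_FRACTION",
]

# Default activation rates of the three patterns (Hz) and the fibrotic
# node fraction of the complex-AF pattern.
SR_RATE_HZ = 1.2
SAF_ROTOR_HZ = 7.3
SAF_REMOTE_HZ = 4.7
CAF_ROTOR_HZ = 6.8
CAF_REMOTE_HZ = 5.4
CAF_FIBROTIC_FRACTION = 0.25

#: Skew of the phase-warped cosine waveform (0 = pure cosine).
_WAVEFORM_SKEW = 0.6

#: Default conduction velocity for plane-wave activation (mm/s); sets the
#: spatial wavelength of the SR/remote wavefronts at about 1 m/s, a
#: physiological atrial value.
CONDUCTION_VELOCITY_MM_S = 1000.0


@dataclass(frozen=True)
class ActivityPattern:
    """Parameters of one activation pattern.

    ``remote_rate_hz`` is the pacing rate for ``SR`` and the
    remote-tissue rate for the fibrillatory kinds.
    """

    kind: str
    remote_rate_hz: float
    rotor_rate_hz: Optional[float] = None
    rotor_core: Optional[tuple] = None   # 3-D point, snapped to a node
    rotor_radius_mm: float = 25.0        # geodesic extent of the rotor region
    fibrotic_fraction: float = 0.0
    boundary_blend_mm: float = 0.0       # 0 = hard boundary; >0 logistic blend
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("SR", "SAF", "CAF"):
            raise ValueError(f"kind must be SR/SAF/CAF, got {self.kind!r}")
        if self.remote_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.kind == "SR":
            if self.fibrotic_fraction != 0:
                raise ValueError("fibrotic_fraction only applies to CAF")
        else:
            if self.rotor_rate_hz is None or self.rotor_rate_hz <= 0:
                raise ValueError(f"{self.kind} needs a positive rotor rate")
            if self.rotor_rate_hz < self.remote_rate_hz:
                raise ValueError("rotor rate must be >= remote rate")
            if self.kind == "SAF" and self.fibrotic_fraction != 0:
                raise ValueError("fibrotic_fraction only applies to CAF")
        if not (0 <= self.fibrotic_fraction < 1):
            raise ValueError("fibrotic_fraction must be in [0, 1)")

    @classmethod
    def sr(cls, **kw) -> "ActivityPattern":
        kw.setdefault("remote_rate_hz", SR_RATE_HZ)
        return cls(kind="SR", **kw)

    @classmethod
    def saf(cls, **kw) -> "ActivityPattern":
        kw.setdefault("remote_rate_hz", SAF_REMOTE_HZ)
        kw.setdefault("rotor_rate_hz", SAF_ROTOR_HZ)
        return cls(kind="SAF", **kw)

    @classmethod
    def caf(cls, **kw) -> "ActivityPattern":
        kw.setdefault("remote_rate_hz", CAF_REMOTE_HZ)
        kw.setdefault("rotor_rate_hz", CAF_ROTOR_HZ)
        kw.setdefault("fibrotic_fraction", CAF_FIBROTIC_FRACTION)
        return cls(kind="CAF", **kw)


@dataclass
class PotentialField:
    """Node x time matrix of potentials (mV) with its sampling rate."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("potential values must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def window(self, t_start: float, t_stop: float) -> "PotentialField":
        """Sub-field covering [t_start, t_stop) seconds."""
        i0 = int(round((t_start - self.t0) * self.fs))
        i1 = int(round((t_stop - self.t0) * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError("window outside the recorded interval")
        return PotentialField(self.values[:, i0:i1], self.fs, t_start)


def action_potential_waveform(phase) -> np.ndarray:
    """Map phase (radians) to a normalized action-potential-like amplitude.

    A phase-warped cosine ``cos(phi + beta*(cos(phi) - 1))``: the warp is
    monotone for ``beta < 1``, so the template is 2*pi-periodic, smooth,
    attains the exact range [-1, 1], and is time-asymmetric -- the rise
    toward the depolarization peak is faster than the repolarization
    decay.
    """
    phi = np.asarray(phase, dtype=float)
    return np.cos(phi + _WAVEFORM_SKEW * (np.cos(phi) - 1.0))


def _tangent_azimuth(mesh: TriMesh, core: int, nodes) -> np.ndarray:
    """Azimuthal angle of ``nodes`` about the core in its tangent plane."""
    n = mesh.vertex_normals[core]
    # orthonormal tangent basis at the core
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    d = mesh.vertices[nodes] - mesh.vertices[core]
    return np.arctan2(d @ e2, d @ e1)


def _phase_fields(mesh: TriMesh, pattern: ActivityPattern, t: np.ndarray):
    """Return (phase N x T, rate per node, region mask, core node).

    The phase field is the analytic ground truth: a plane wave outside the
    rotor region and a vortex ``2*pi*f_rot*t - azimuth`` inside it.
    """
    n = mesh.n_nodes
    verts = mesh.vertices
    axis_pos = verts[:, 0] - verts[:, 0].min()   # pacing along +x
    k = 2 * np.pi * pattern.remote_rate_hz / CONDUCTION_VELOCITY_MM_S
    plane = (2 * np.pi * pattern.remote_rate_hz * t[None, :]
             - k * axis_pos[:, None])

    if pattern.kind == "SR":
        rates = np.full(n, pattern.remote_rate_hz)
        return plane, rates, np.zeros(n, bool), None

    core_pt = pattern.rotor_core
    if core_pt is None:
        core = int(np.argmax(verts[:, 0]))  # rotor in the "right atrium" end
    else:
        core = mesh.nearest_node(core_pt)
        if np.linalg.norm(verts[core] - np.asarray(core_pt, float)) > 1e-9:
            import warnings
            warnings.warn("rotor core snapped to nearest mesh node")
    gdist = geodesic_distances_from(mesh, core)
    region = gdist <= pattern.rotor_radius_mm
    theta = _tangent_azimuth(mesh, core, np.arange(n))
    theta[core] = 0.0
    vortex = 2 * np.pi * pattern.rotor_rate_hz * t[None, :] - theta[:, None]
    if pattern.boundary_blend_mm > 0:
        # logistic cross-fade of the two phase fields (on the unit circle)
        # over ~boundary_blend_mm around the region boundary
        w = pattern.boundary_blend_mm
        b = 1.0 / (1.0 + np.exp(-(gdist - pattern.rotor_radius_mm) / (w / 4)))
        z = ((1 - b)[:, None] * np.exp(1j * vortex)
             + b[:, None] * np.exp(1j * plane))
        phase = np.angle(np.where(np.abs(z) < 1e-12, np.exp(1j * plane), z))
    else:
        phase = np.where(region[:, None], vortex, plane)
    rates = np.where(region, pattern.rotor_rate_hz, pattern.remote_rate_hz)
    return phase, rates, region, core


def simulate_pattern(mesh: TriMesh, pattern: ActivityPattern,
                     duration: float, fs: float):
    """Simulate an activation pattern on ``mesh``.

    Returns
    -------
    field : PotentialField
        N x round(duration*fs) epicardial potentials (mV).
    truth : dict
        ``df`` true per-node dominant frequency (Hz); ``phase`` analytic
        phase field; ``region`` rotor-region mask; ``core`` rotor core
        node (or None); ``core_trajectory`` per-frame core node;
        ``fibrotic`` fibrotic-node mask; ``boundary_dist`` geodesic
        distance to the rotor-region boundary (signed, mm; None for SR).
    """
    if duration < 4.0:
        raise ValueError("duration must be >= 4 s (Welch windows need 2 s)")
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    n_t = int(round(duration * fs))
    t = np.arange(n_t) / fs
    phase, rates, region, core = _phase_fields(mesh, pattern, t)

    rng = np.random.default_rng(pattern.seed)
    amp = np.ones(mesh.n_nodes)
    fibrotic = np.zeros(mesh.n_nodes, bool)
    if pattern.kind == "CAF" and pattern.fibrotic_fraction > 0:
        n_fib = int(round(pattern.fibrotic_fraction * mesh.n_nodes))
        fib_idx = rng.choice(mesh.n_nodes, size=n_fib, replace=False)
        fibrotic[fib_idx] = True
        amp[fibrotic] = 0.1
        # activation-time jitter up to 10% of the local cycle length
        jitter_t = rng.uniform(-0.1, 0.1, size=n_fib) / rates[fib_idx]
        phase = phase.copy()
        phase[fib_idx] += (2 * np.pi * rates[fib_idx] * jitter_t)[:, None]

    values = amp[:, None] * action_potential_waveform(phase)
    field = PotentialField(values, fs)
    truth = {
        "df": rates.copy(),
        "phase": np.angle(np.exp(1j * phase)),
        "region": region,
        "core": core,
        "core_trajectory": (None if core is None
                            else np.full(n_t, core, dtype=np.int64)),
        "fibrotic": fibrotic,
        "boundary_dist": None,
    }
    if core is not None:
        gdist = geodesic_distances_from(mesh, core)
        truth["boundary_dist"] = gdist - pattern.rotor_radius_mm
    return field, truth
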