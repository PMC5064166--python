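"""Clinical target extraction: dominant frequency, phase, singularity points.

From any potential field (ground truth or reconstruction) this module
computes the three derived clinical targets:

* per-node dominant frequency (DF) via a Welch periodogram (2 s Hamming
  windows, 50% overlap, zero-padded to a <= 0.1 Hz grid) with a
  harmonic-discard rule;
* per-node instantaneous phase via a narrow band-pass around the DF
  followed by the Hilbert transform;
* phase singularity points (SPs) by the topological charge of the phase
  along each node's ordered one-ring, tracked over time, filtered by a
  two-rotation persistence rule, and summarized as a spatial mass
  function (SMF) of SP location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt, welch
from scipy.sparse.csgraph import dijkstra

from .mesh import TriMesh, MeshError, one_ring_cycle
from .phantom import PotentialField

__all__ = [
    "DFMap",
    "PhaseMap",
    "SPTrack",
    "SMF",
    "welch_psd",
    "dominant_frequency",
    "df_map",
    "phase_map",
    "detect_sps_frame",
    "track_sps",
    "sp_smf",
    "dominant_sp",
]

#: Sentinel DF for nodes where no spectral peak was found in the band.
DF_SENTINEL = np.nan

#: Tolerance on the one-ring topological charge (radians): guards
#: floating-point error; the discrete charge is an exact multiple of 2*pi.
CHARGE_TOL = 0.5


@dataclass
class DFMap:
    """Per-node dominant frequency (Hz) with its spectral grid resolution."""

    values: np.ndarray
    resolution_hz: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution_hz <= 0:
            raise ValueError("spectral resolution must be positive")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class PhaseMap:
    """Node x time instantaneous phase (radians, wrapped to (-pi, pi])."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def valid_nodes(self) -> np.ndarray:
        return np.all(np.isfinite(self.values), axis=1)


@dataclass
class SPTrack:
    """One tracked singularity point."""

    frames: List[int]
    nodes: List[int]
    chirality: int
    core_df_hz: float = np.nan

    @property
    def start(self) -> int:
        return self.frames[0]

    @property
    def end(self) -> int:
        return self.frames[-1]

    def duration_s(self, fs: float) -> float:
        return (self.end - self.start) / fs

    @property
    def modal_node(self) -> int:
        nodes, counts = np.unique(self.nodes, return_counts=True)
        return int(nodes[np.argmax(counts)])


@dataclass
class SMF:
    """Spatial mass function of SP location: p(n) >= 0, sum = 1 (or all
    zero with ``empty`` set when no SP was detected)."""

    p: np.ndarray
    empty: bool = False

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("SMF entries must be non-negative")
        tot = self.p.sum()
        if self.empty:
            if tot != 0:
                raise ValueError("empty SMF must be all-zero")
        elif not np.isclose(tot, 1.0, atol=1e-9):
            raise ValueError(f"SMF must sum to 1, got {tot}")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.p > 0)

    @property
    def mode(self) -> Optional[int]:
        if self.empty:
            return None
        return int(np.argmax(self.p))   # ties -> smallest index


# ---------------------------------------------------------------------------
# spectra and dominant frequency
# ---------------------------------------------------------------------------

def welch_psd(signal, fs: float, window_s: float = 2.0,
              grid_hz: float = 0.1):
    """Welch power spectral density of one or many node signals.

    2 s Hamming segments with 50% overlap; the FFT is zero-padded so the
    frequency grid spacing is at most ``grid_hz``.

    Returns ``(freqs, psd)``; ``psd`` has the node axis first when the
    input is 2-D.
    """
    x = np.asarray(signal, float)
    n = x.shape[-1]
    nperseg = int(round(window_s * fs))
    if n < nperseg:
        raise ValueError(f"signal shorter than one {window_s} s Welch window")
    nfft = nperseg
    while fs / nfft > grid_hz:
        nfft *= 2
    freqs, psd = welch(x, fs=fs, window="hamming", nperseg=nperseg,
                       noverlap=nperseg // 2, nfft=nfft, axis=-1,
                       detrend="constant")
    return freqs, psd


def dominant_frequency(freqs, psd, band=(3.0, 15.0),
                       harmonic_tol_hz: float = 0.25,
                       harmonic_power_frac: float = 0.30) -> float:
    """Highest non-harmonic spectral peak within ``band`` (Hz).

    A local maximum at ``f`` is discarded as a harmonic when another peak
    exists near ``f/2`` (within ``harmonic_tol_hz``) carrying at least
    ``harmonic_power_frac`` of its power. Returns NaN when no peak
    survives in the band.
    """
    freqs = np.asarray(freqs, float)
    psd = np.asarray(psd, float)
    if freqs[-1] < band[1]:
        raise ValueError("spectral grid does not cover the analysis band")
    peaks, _ = find_peaks(psd)
    if len(peaks) == 0:
        return DF_SENTINEL
    in_band = peaks[(freqs[peaks] >= band[0]) & (freqs[peaks] <= band[1])]
    if len(in_band) == 0:
        return DF_SENTINEL
    surviving = []
    for p in in_band:
        f = freqs[p]
        near_half = peaks[np.abs(freqs[peaks] - f / 2.0) <= harmonic_tol_hz]
        if len(near_half) and psd[near_half].max() >= \
                harmonic_power_frac * psd[p]:
            continue
        surviving.append(p)
    if not surviving:
        return DF_SENTINEL
    best = surviving[int(np.argmax(psd[surviving]))]
    return float(freqs[best])


def df_map(X: PotentialField, band=(3.0, 15.0), window_s: float = 2.0,
           grid_hz: float = 0.1) -> DFMap:
    """Per-node dominant frequency map of a potential field."""
    freqs, psd = welch_psd(X.values, X.fs, window_s=window_s, grid_hz=grid_hz)
    vals = np.array([dominant_frequency(freqs, psd[i], band=band)
                     for i in range(X.n_nodes)])
    return DFMap(vals, resolution_hz=float(freqs[1] - freqs[0]))


# ---------------------------------------------------------------------------
# phase maps
# ---------------------------------------------------------------------------

def phase_map(X: PotentialField, df: DFMap, low_hz: float = 3.0) -> PhaseMap:
    """Instantaneous phase via DF-adapted band-pass plus Hilbert transform.

    Each node is band-passed (zero phase, 4th-order Butterworth) between
    ``low_hz`` and ``DF_n + 2`` Hz before the analytic signal is formed.
    When the node's DF sits below the default 3 Hz edge (sinus rhythm),
    the low edge drops to half the DF so the fundamental is preserved.
    Nodes with a sentinel DF get an all-NaN phase row.
    """
    out = np.full(X.values.shape, np.nan)
    dfv = df.values
    # group nodes by rounded DF so each distinct band is designed once
    for f in np.unique(np.round(dfv[np.isfinite(dfv)], 3)):
        nodes = np.flatnonzero(np.isfinite(dfv) & (np.round(dfv, 3) == f))
        lo = low_hz if f > low_hz else 0.5 * f
        hi = min(f + 2.0, X.fs / 2 * 0.99)
        sos = butter(4, [lo, hi], btype="band", fs=X.fs, output="sos")
        filtered = sosfiltfilt(sos, X.values[nodes], axis=1)
        out[nodes] = np.angle(hilbert(filtered, axis=1))
    return PhaseMap(out, X.fs)


# ---------------------------------------------------------------------------
# singularity points
# ---------------------------------------------------------------------------

def _wrap(a):
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2 * np.pi)


def _ring_cache(mesh: TriMesh):
    rings = []
    for n in range(mesh.n_nodes):
        try:
            rings.append(one_ring_cycle(mesh, n))
        except MeshError:
            rings.append(None)     # boundary node: skipped by detection
    return rings


def detect_sps_frame(mesh: TriMesh, phase_t, rings=None):
    """Detect phase singularities in one phase frame.

    For each node the wrapped phase differences along its ordered one-ring
    are summed; a topological charge of +-2*pi marks a singularity.
    Adjacent charged nodes of equal chirality (a vortex centered inside a
    face charges the whole surrounding ring) are merged into one
    detection; the representative is the node whose one-ring phase
    increments are most uniform, i.e. closest to the vortex center.

    Returns a list of ``(node, chirality)`` pairs.
    """
    phase_t = np.asarray(phase_t, float)
    if rings is None:
        rings = _ring_cache(mesh)
    charged = {}
    uniformity = {}
    for n, ring in enumerate(rings):
        if ring is None or not np.isfinite(phase_t[n]):
            continue
        ph = phase_t[ring]
        if not np.isfinite(ph).all():
            continue
        diffs = _wrap(np.diff(np.r_[ph, ph[0]]))
        charge = diffs.sum()
        if abs(abs(charge) - 2 * np.pi) < CHARGE_TOL:
            chir = 1 if charge > 0 else -1
            charged[n] = chir
            uniformity[n] = float(np.var(diffs))
    if not charged:
        return []
    # merge adjacent same-chirality detections (connected components)
    adj = mesh.adjacency
    unvisited = set(charged)
    detections = []
    while unvisited:
        seed = min(unvisited)
        comp = [seed]
        unvisited.discard(seed)
        stack = [seed]
        while stack:
            cur = stack.pop()
            for nb in adj.indices[adj.indptr[cur]:adj.indptr[cur + 1]]:
                nb = int(nb)
                if nb in unvisited and charged[nb] == charged[seed]:
                    unvisited.discard(nb)
                    comp.append(nb)
                    stack.append(nb)
        rep = min(comp, key=lambda n: (uniformity[n], n))
        detections.append((int(rep), charged[seed]))
    return detections


def track_sps(frames, mesh: TriMesh, df: DFMap, fs: float,
              linking_radius_mm: float = 10.0, min_rotations: float = 2.0,
              max_gap_frames: int = 2) -> List[SPTrack]:
    """Link per-frame SP detections into persistent tracks.

    Greedy nearest-neighbor linking across consecutive frames within a
    geodesic radius, tolerating gaps of up to ``max_gap_frames``. A track
    is kept iff its duration reaches ``min_rotations`` rotations at the
    local dominant frequency of its core.
    """
    gdist = dijkstra(mesh.adjacency, directed=False)
    active = []      # (track, last_frame, last_node)
    done = []
    for fi, dets in enumerate(frames):
        # retire stale tracks
        still = []
        for tr, lf, ln in active:
            if fi - lf > max_gap_frames + 1:
                done.append(tr)
            else:
                still.append((tr, lf, ln))
        active = still
        unmatched = list(dets)
        # match detections to active tracks, nearest first
        pairs = []
        for ai, (tr, lf, ln) in enumerate(active):
            for di, (node, chir) in enumerate(unmatched):
                if chir == tr.chirality:
                    d = gdist[ln, node]
                    if d <= linking_radius_mm:
                        pairs.append((d, ai, di))
        pairs.sort()
        used_a, used_d = set(), set()
        for d, ai, di in pairs:
            if ai in used_a or di in used_d:
                continue
            used_a.add(ai)
            used_d.add(di)
            tr, lf, ln = active[ai]
            node, chir = unmatched[di]
            tr.frames.append(fi)
            tr.nodes.append(node)
            active[ai] = (tr, fi, node)
        for di, (node, chir) in enumerate(unmatched):
            if di not in used_d:
                tr = SPTrack(frames=[fi], nodes=[node], chirality=chir)
                active.append((tr, fi, node))
    done.extend(tr for tr, _, _ in active)
    kept = []
    for tr in done:
        core = tr.modal_node
        core_df = df.values[core]
        tr.core_df_hz = float(core_df)
        if not np.isfinite(core_df) or core_df <= 0:
            continue
        if tr.duration_s(fs) >= min_rotations / core_df:
            kept.append(tr)
    return kept


def sp_smf(tracks: List[SPTrack], n_nodes: int) -> SMF:
    """Spatial mass function of SP location over all kept tracks."""
    counts = np.zeros(n_nodes)
    for tr in tracks:
        for node in tr.nodes:
            if node >= n_nodes:
                raise ValueError("track node index out of range")
            counts[node] += 1
    tot = counts.sum()
    if tot == 0:
        return SMF(counts, empty=True)
    return SMF(counts / tot)


def dominant_sp(tracks: List[SPTrack], df: DFMap) -> Optional[SPTrack]:
    """The kept track located in the highest-DF area (None if no track).

    Ties on mean core DF break toward the longest duration, then the
    earliest start.
    """
    if not tracks:
        return None
    def key(tr):
        mean_df = np.nanmean(df.values[np.asarray(tr.nodes)])
        return (-mean_df, -(tr.end - tr.start), tr.start)
    return sorted(tracks, key=key)[0]
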