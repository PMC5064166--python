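"""Performance metrics for the benchmark.

Potential metrics (CC, RDMS), dominant-frequency error (RAE), and the
singularity-point location suite comparing spatial mass functions (SMFs):
the weighted under/over-estimation indicators (WUI, WOI), the SMF
correlation (CC_SMF), and the geodesic mode distance (MD). A rank-based
two-sample Wilcoxon comparison rounds out the suite.

RDMS (relative difference measurement star) is the Euclidean distance
between unit-normalized signals,

    RDMS = || x/||x|| - xhat/||xhat|| ||_2 ,

bounded in [0, 2]; it relates to the cosine similarity by
``RDMS^2 = 2 (1 - cos)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import stats

from .mesh import TriMesh, geodesic_distance
from .targets import SMF, DFMap

__all__ = [
    "MetricsReport",
    "rdms",
    "correlation",
    "potential_metrics",
    "rae",
    "wui",
    "woi",
    "cc_smf",
    "mode_distance",
    "wilcoxon_compare",
]


@dataclass
class MetricsReport:
    """Per-node values and summary statistics for one metric run."""

    metric: str
    per_item: np.ndarray
    mean: float
    std: float
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"metric": self.metric, "mean": self.mean, "std": self.std}
        row.update(self.metadata)
        return row


def rdms(x, x_hat) -> float:
    """Relative difference measurement star between two signals."""
    x = np.asarray(x, float).ravel()
    x_hat = np.asarray(x_hat, float).ravel()
    nx, nh = np.linalg.norm(x), np.linalg.norm(x_hat)
    if nx == 0 or nh == 0:
        raise ValueError("RDMS undefined for a zero vector")
    return float(np.linalg.norm(x / nx - x_hat / nh))


def correlation(x, x_hat) -> float:
    """Pearson correlation coefficient (NaN sentinel for constant input)."""
    x = np.asarray(x, float).ravel()
    x_hat = np.asarray(x_hat, float).ravel()
    if np.ptp(x) == 0 or np.ptp(x_hat) == 0:
        return np.nan
    return float(np.corrcoef(x, x_hat)[0, 1])


def potential_metrics(X, X_hat, mode: str = "temporal",
                      metadata: dict = None, circular: bool = False):
    """CC and RDMS between two node x time fields.

    ``temporal`` (default): per-node over time, summarized across nodes.
    ``spatial``: per-instant over nodes, summarized across instants.
    ``circular=True`` scores phase fields on the unit circle (the values
    are mapped to stacked cos/sin components before correlating), which
    removes the wrap-around discontinuity at +-pi; the default scores the
    wrapped values directly. Returns ``{"CC": ..., "RDMS": ...}`` reports.
    """
    X = np.atleast_2d(np.asarray(X, float))
    X_hat = np.atleast_2d(np.asarray(X_hat, float))
    if circular:
        ax = 0 if mode == "spatial" else 1
        X = np.concatenate([np.cos(X), np.sin(X)], axis=ax)
        X_hat = np.concatenate([np.cos(X_hat), np.sin(X_hat)], axis=ax)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    if mode == "temporal":
        items = range(X.shape[0])
        get = lambda M, i: M[i, :]
    elif mode == "spatial":
        items = range(X.shape[1])
        get = lambda M, i: M[:, i]
    else:
        raise ValueError(f"mode must be temporal/spatial, got {mode!r}")
    ccs, rds = [], []
    for i in items:
        a, b = get(X, i), get(X_hat, i)
        ccs.append(correlation(a, b))
        try:
            rds.append(rdms(a, b))
        except ValueError:
            rds.append(np.nan)
    ccs, rds = np.asarray(ccs), np.asarray(rds)
    md = dict(metadata or {}, mode=mode)
    return {
        "CC": MetricsReport("CC", ccs, float(np.nanmean(ccs)),
                            float(np.nanstd(ccs)), md),
        "RDMS": MetricsReport("RDMS", rds, float(np.nanmean(rds)),
                              float(np.nanstd(rds)), md),
    }


def rae(F, F_hat) -> float:
    """Node-averaged relative absolute DF error, in percent.

    Nodes with a non-positive or undefined true DF are excluded with a
    warning; estimated-DF sentinels count as their full relative error
    would be undefined, so those nodes are excluded too (warned).
    """
    Fv = F.values if isinstance(F, DFMap) else np.asarray(F, float)
    Fh = F_hat.values if isinstance(F_hat, DFMap) else np.asarray(F_hat, float)
    valid = np.isfinite(Fv) & (Fv > 0) & np.isfinite(Fh)
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} nodes excluded from RAE "
                      "(zero/undefined DF)")
    if not valid.any():
        raise ValueError("no valid nodes for RAE")
    return float(100.0 * np.mean(np.abs(Fv[valid] - Fh[valid]) / Fv[valid]))


def _support(p: SMF, eps: float = 0.0) -> np.ndarray:
    return np.flatnonzero(p.p > eps)


def wui(p: SMF, p_hat: SMF, areas, eps: float = 0.0) -> float:
    """Weighted under-estimation indicator (percent of the true SP region
    missed, probability-and-area weighted)."""
    areas = np.asarray(areas, float)
    s_true = set(_support(p, eps).tolist())
    s_est = set(_support(p_hat, eps).tolist())
    if not s_true:
        return np.nan
    fn = np.array(sorted(s_true - s_est), int)
    tp = np.array(sorted(s_true & s_est), int)
    num = np.sum(p.p[fn] * areas[fn]) if len(fn) else 0.0
    den = num + (np.sum(p.p[tp] * areas[tp]) if len(tp) else 0.0)
    return float(100.0 * num / den) if den > 0 else np.nan


def woi(p: SMF, p_hat: SMF, areas, eps: float = 0.0) -> float:
    """Weighted over-estimation indicator (percent of the estimated SP
    region that is spurious, probability-and-area weighted)."""
    areas = np.asarray(areas, float)
    s_true = set(_support(p, eps).tolist())
    s_est = set(_support(p_hat, eps).tolist())
    if not s_est:
        return np.nan
    fp = np.array(sorted(s_est - s_true), int)
    tp = np.array(sorted(s_est & s_true), int)
    num = np.sum(p_hat.p[fp] * areas[fp]) if len(fp) else 0.0
    den = num + (np.sum(p_hat.p[tp] * areas[tp]) if len(tp) else 0.0)
    return float(100.0 * num / den) if den > 0 else np.nan


def cc_smf(p: SMF, p_hat: SMF) -> float:
    """Pearson correlation between the two spatial mass functions."""
    if len(p.p) != len(p_hat.p):
        raise ValueError("SMFs must live on the same mesh")
    return correlation(p.p, p_hat.p)


def mode_distance(p: SMF, p_hat: SMF, mesh: TriMesh) -> float:
    """Geodesic (Dijkstra) distance between the SMF modes, in mm."""
    if p.empty or p_hat.empty:
        return np.nan
    return geodesic_distance(mesh, p.mode, p_hat.mode)


def wilcoxon_compare(sample_a, sample_b, alpha: float = 0.05):
    """Two-sided rank-sum comparison of two metric samples.

    Returns ``(p_value, significant)``; NaN sentinel for degenerate
    all-tied samples.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be nonempty")
    if np.ptp(np.r_[a, b]) == 0:
        return np.nan, False
    stat = stats.ranksums(a, b)
    return float(stat.pvalue), bool(stat.pvalue < alpha)
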