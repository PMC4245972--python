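"""Structural deviation metrics on the nucleobase representation.

The central quantity is the eRMSD: each ordered base pair (j, k) contributes
a scaled relative-position vector r̃_jk, which is mapped to a 4-vector

    G(r̃) = ( sin(γ r̃) r̃_x / r̃,
              sin(γ r̃) r̃_y / r̃,
              sin(γ r̃) r̃_z / r̃,
              1 + cos(γ r̃) ) · Θ(r̃_cutoff − r̃) / γ,       γ = π / r̃_cutoff

G is continuous, vanishes beyond the cutoff (making the metric local), and
is approximately an isometry for r̃ well below the cutoff.  The eRMSD
between structures α and β is then

    eRMSD = sqrt( (1/N) Σ_{j≠k} |G(r̃_jk^α) − G(r̃_jk^β)|² )

with N the number of nucleotides.  Both orderings of every pair enter the
sum.  A scalar variant replaces G with G_s(r̃) = (r̃_cutoff − r̃)·Θ(·), and
the cutoff-free "naive" distance uses r̃ itself.

Baselines on the same footing: optimal-superposition RMSD, distance-matrix
dRMSD over ring centroids, and the interaction network fidelity (INF)
computed from the internal annotator.  The kinetic-proximity analysis
computes the coefficient of variation CV_d(τ) = σ_d(τ)/⟨d(τ)⟩ of any of
these metrics over trajectory frame pairs at fixed time lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .errors import CorrespondenceError, InputError
from .geometry import (
    DEFAULT_PARAMS,
    PairAnnotation,
    ScalingParams,
    Zone,
    pair_matrices,
)
from .io import RnaStructure, Trajectory, check_correspondence

__all__ = [
    "GVector", "CVCurve", "gvector", "gscalar", "g_matrix", "ermsd",
    "ermsd_scalar", "naive_distance", "rmsd", "drmsd", "inf_score",
    "cv_curve", "METRICS",
]


@dataclass
class GVector:
    """4-D mapped pair vector together with the mapping constants."""

    components: np.ndarray
    gamma: float
    r_cutoff: float


def gvector(r_tilde: np.ndarray,
            params: ScalingParams = DEFAULT_PARAMS) -> GVector:
    """Map one scaled pair vector to its 4-D G form."""
    r_tilde = np.asarray(r_tilde, float)
    gamma = params.gamma
    norm = float(np.linalg.norm(r_tilde))
    if norm >= params.r_cutoff:
        comp = np.zeros(4)
    elif norm < 1e-12:
        comp = np.array([0.0, 0.0, 0.0, 2.0 / gamma])
    else:
        s = math.sin(gamma * norm) / norm
        comp = np.array([s * r_tilde[0], s * r_tilde[1], s * r_tilde[2],
                         1.0 + math.cos(gamma * norm)]) / gamma
    return GVector(components=comp, gamma=gamma, r_cutoff=params.r_cutoff)


def gscalar(r_tilde: np.ndarray,
            params: ScalingParams = DEFAULT_PARAMS) -> float:
    """Scalar contact-map-like variant G_s(r̃) = (r̃_cutoff − r̃)·Θ(·)."""
    norm = float(np.linalg.norm(np.asarray(r_tilde, float)))
    return max(params.r_cutoff - norm, 0.0)


def g_matrix(structure: RnaStructure,
             params: ScalingParams = DEFAULT_PARAMS) -> np.ndarray:
    """(N, N, 4) array of G vectors over all ordered pairs; diagonal zero."""
    _, r_tilde, norms = pair_matrices(structure, params)
    return _g_from_scaled(r_tilde, norms, params)


def _g_from_scaled(r_tilde: np.ndarray, norms: np.ndarray,
                   params: ScalingParams) -> np.ndarray:
    gamma = params.gamma
    inside = norms < params.r_cutoff          # diagonal has norm=inf -> False
    safe = np.where(norms > 1e-12, norms, 1.0)
    s = np.where(inside, np.sin(gamma * np.minimum(norms, params.r_cutoff)) / safe,
                 0.0)
    g = np.empty(norms.shape + (4,))
    g[..., :3] = s[..., None] * r_tilde
    g[..., 3] = np.where(inside, 1.0 + np.cos(gamma * np.minimum(
        norms, params.r_cutoff)), 0.0)
    return g / gamma


def _gs_matrix(structure: RnaStructure, params: ScalingParams) -> np.ndarray:
    _, _, norms = pair_matrices(structure, params)
    gs = np.maximum(params.r_cutoff - norms, 0.0)
    np.fill_diagonal(gs, 0.0)
    return gs


def ermsd(a: RnaStructure, b: RnaStructure,
          params: ScalingParams = DEFAULT_PARAMS) -> float:
    """eRMSD between two structures in positional correspondence."""
    n = check_correspondence(a, b)
    ga, gb = g_matrix(a, params), g_matrix(b, params)
    return float(np.sqrt(np.sum((ga - gb) ** 2) / n))


def ermsd_scalar(a: RnaStructure, b: RnaStructure,
                 params: ScalingParams = DEFAULT_PARAMS) -> float:
    """Scalar-variant eRMSD (G_s in place of G)."""
    n = check_correspondence(a, b)
    ga, gb = _gs_matrix(a, params), _gs_matrix(b, params)
    return float(np.sqrt(np.sum((ga - gb) ** 2) / n))


def naive_distance(a: RnaStructure, b: RnaStructure,
                   params: ScalingParams = DEFAULT_PARAMS) -> float:
    """Cutoff-free deviation over raw scaled pair vectors (highly non-local)."""
    n = check_correspondence(a, b)
    _, ra, _ = pair_matrices(a, params)
    _, rb, _ = pair_matrices(b, params)
    return float(np.sqrt(np.sum((ra - rb) ** 2) / n))


def _selected_coords(s: RnaStructure, atom_selection: str) -> np.ndarray:
    if atom_selection == "heavy":
        return s.heavy_coords()
    if atom_selection == "ring":
        return np.concatenate([nt.ring_coords for nt in s])
    if atom_selection == "centers":
        return s.ring_centers()
    raise InputError(f"unknown atom selection {atom_selection!r}")


def rmsd(a: RnaStructure, b: RnaStructure,
         atom_selection: str = "heavy") -> float:
    """Heavy-atom RMSD (Å) after optimal proper-rotation superposition."""
    xa = _selected_coords(a, atom_selection)
    xb = _selected_coords(b, atom_selection)
    if xa.shape != xb.shape:
        raise CorrespondenceError(
            f"atom counts differ: {xa.shape[0]} vs {xb.shape[0]}")
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    # align_vectors solves min_R Σ|xa - R xb|² over proper rotations (Kabsch)
    _, rssd = Rotation.align_vectors(xa, xb)
    return float(rssd / math.sqrt(xa.shape[0]))


def drmsd(a: RnaStructure, b: RnaStructure,
          atom_selection: str = "centers") -> float:
    """RMS difference of internal pairwise distance matrices (Å).

    Defaults to one bead per nucleotide (ring centroids), keeping the
    baseline on the same representation as the eRMSD; pass
    ``atom_selection='heavy'`` for the all-heavy-atom variant.
    """
    xa = _selected_coords(a, atom_selection)
    xb = _selected_coords(b, atom_selection)
    if xa.shape != xb.shape:
        raise CorrespondenceError(
            f"bead counts differ: {xa.shape[0]} vs {xb.shape[0]}")
    if xa.shape[0] < 2:
        raise InputError("dRMSD needs at least two beads")
    da, db = pdist(xa), pdist(xb)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def _interaction_set(annotations: Sequence[PairAnnotation],
                     use_sectors: bool) -> set:
    out = set()
    for ann in annotations:
        if ann.zone == Zone.NONE:
            continue
        key = (ann.j, ann.k, ann.zone)
        if use_sectors:
            key = key + (ann.edge_sector,)
        out.add(key)
    return out


def inf_score(ref_ann: Sequence[PairAnnotation],
              cmp_ann: Sequence[PairAnnotation],
              use_sectors: bool = False) -> float:
    """Interaction network fidelity: sqrt(PPV × sensitivity) in [0, 1].

    Interactions match when the unordered pair indices and the zone
    (PAIRING/STACKING) agree; edge sectors are ignored unless requested.
    """
    ref = _interaction_set(ref_ann, use_sectors)
    cmp_ = _interaction_set(cmp_ann, use_sectors)
    if not ref:
        raise InputError("INF is undefined for an empty reference annotation")
    tp = len(ref & cmp_)
    if tp == 0:
        return 0.0
    ppv = tp / len(cmp_)
    sty = tp / len(ref)
    return math.sqrt(ppv * sty)


@dataclass
class CVCurve:
    """Coefficient of variation of a deviation metric versus time lag."""

    lags: list[int]
    mean_d: list[float]
    sd_d: list[float]
    cv: list[float]
    cv_error: list[float]
    metric: str = "ermsd"


def _metric_ermsd(params):
    def prep(frame):
        return g_matrix(frame, params)

    def dist(ga, gb, n):
        return math.sqrt(np.sum((ga - gb) ** 2) / n)

    return prep, dist


def _metric_ermsd_scalar(params):
    def prep(frame):
        return _gs_matrix(frame, params)

    def dist(ga, gb, n):
        return math.sqrt(np.sum((ga - gb) ** 2) / n)

    return prep, dist


def _metric_naive(params):
    def prep(frame):
        _, r_tilde, _ = pair_matrices(frame, params)
        return r_tilde

    def dist(ra, rb, n):
        return math.sqrt(np.sum((ra - rb) ** 2) / n)

    return prep, dist


def _metric_drmsd(params):
    def prep(frame):
        return pdist(frame.ring_centers())

    def dist(da, db, n):
        return math.sqrt(np.mean((da - db) ** 2))

    return prep, dist


def _metric_rmsd(params):
    def prep(frame):
        x = frame.heavy_coords()
        return x - x.mean(axis=0)

    def dist(xa, xb, n):
        _, rssd = Rotation.align_vectors(xa, xb)
        return rssd / math.sqrt(xa.shape[0])

    return prep, dist


METRICS: dict[str, Callable] = {
    "ermsd": _metric_ermsd,
    "ermsd-scalar": _metric_ermsd_scalar,
    "naive": _metric_naive,
    "drmsd": _metric_drmsd,
    "rmsd": _metric_rmsd,
}


def _blocking_error(series: np.ndarray) -> float:
    """CV standard error by block-doubling on a correlated distance series.

    The series is cut into consecutive blocks of size 2^ℓ at the largest
    doubling level that still leaves at least 8 blocks; the CV is computed
    inside each block and the error is the standard error of those
    per-block CVs.  Returns NaN when fewer than 8 blocks of size ≥ 2 exist.
    """
    n = len(series)
    level = 0
    while n // (2 ** (level + 1)) >= 8:
        level += 1
    size = 2 ** level
    nb = n // size
    if nb < 8 or size < 2:
        return float("nan")
    cvs = []
    for b in range(nb):
        block = series[b * size:(b + 1) * size]
        m = block.mean()
        if m <= 0:
            return float("nan")
        cvs.append(block.std(ddof=1) / m)
    cvs = np.asarray(cvs)
    return float(cvs.std(ddof=1) / math.sqrt(nb))


def cv_curve(traj: Trajectory, metric: str | Callable = "ermsd",
             lags: Sequence[int] = (1, 2, 5, 10),
             params: ScalingParams = DEFAULT_PARAMS) -> CVCurve:
    """Coefficient of variation CV_d(τ) = σ_d(τ)/⟨d(τ)⟩ over frame pairs.

    For each lag τ the metric d is evaluated on every frame pair
    (t, t + τ); the curve reports the mean, standard deviation, their ratio
    and a blocking-based error of the ratio.  ``metric`` is one of the names
    in :data:`METRICS` or any callable ``d(frame_a, frame_b) -> float``.
    ``cv`` is defined as 0 when the mean distance is 0 (identical frames).
    """
    lags = [int(t) for t in lags]
    if not lags or min(lags) < 1:
        raise InputError("lags must be positive integers")
    if len(traj) <= max(lags) + 1:
        raise InputError(
            f"trajectory has {len(traj)} frames; need > max(lags)+1 = "
            f"{max(lags) + 1}")
    n_nt = len(traj[0])
    if callable(metric):
        name = getattr(metric, "__name__", "custom")
        series_for = {
            tau: np.array([metric(traj[t], traj[t + tau])
                           for t in range(len(traj) - tau)])
            for tau in lags
        }
    else:
        if metric not in METRICS:
            raise InputError(f"unknown metric {metric!r}; "
                             f"choose from {sorted(METRICS)}")
        name = metric
        prep, dist = METRICS[metric](params)
        cache = [prep(frame) for frame in traj]
        series_for = {
            tau: np.array([dist(cache[t], cache[t + tau], n_nt)
                           for t in range(len(traj) - tau)])
            for tau in lags
        }
    mean_d, sd_d, cv, cv_err = [], [], [], []
    for tau in lags:
        s = series_for[tau]
        m = float(s.mean())
        sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
        mean_d.append(m)
        sd_d.append(sd)
        cv.append(sd / m if m > 0 else 0.0)
        cv_err.append(_blocking_error(s))
    return CVCurve(lags=lags, mean_d=mean_d, sd_d=sd_d, cv=cv,
                   cv_error=cv_err, metric=name)
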