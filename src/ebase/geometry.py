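"""Local nucleobase frames, pair vectors and base-contact annotation.

Every nucleobase carries an orthonormal frame anchored at the centroid of its
six-membered ring: x̂ points from the centroid toward C2, ẑ is the ring-plane
normal (sign fixed by an ordered cross product that differs between purines
and pyrimidines so that both base classes present their Watson-Crick edge at
the same angle θ), and ŷ = ẑ × x̂.  The position of base *k* seen from base
*j* is the vector r_jk of frame-*j* coordinates of *k*'s ring centroid,
reported in cylindrical coordinates (ρ, θ, z) and in the anisotropically
scaled form r̃ = (r_x/a, r_y/a, r_z/b) with a = 5 Å (in plane) and
b = 3 Å (normal).

In scaled units, essentially all pairing and stacking contacts observed in
crystal structures fall in the ellipsoidal shell 1 < r̃ < √2.5; within it,
|z| ≤ 2 Å separates the pairing zone from the stacking zone, and θ locates
the interacting edge (Watson-Crick near 60°, Hoogsteen beyond 100°, sugar in
190°–290°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
import numpy as np

from .errors import GeometryError, InputError
from .io import RnaStructure

__all__ = [
    "ScalingParams", "NucleobaseFrame", "PairVector", "PairAnnotation",
    "Zone", "EdgeSector", "build_frame", "structure_frames", "pair_vector",
    "scale_vector", "pair_matrices", "enumerate_shell_pairs",
    "classify_pair", "annotate_structure",
]


@dataclass(frozen=True)
class ScalingParams:
    """Geometric constants of the nucleobase representation.

    Attributes
    ----------
    a, b:
        Ellipsoidal scaling semi-axes (Å): in-plane and normal.
    shell_min, shell_max:
        Interaction-shell bounds in scaled units (1 and √2.5).
    z_split:
        |z| boundary (Å) between pairing and stacking zones.
    r_cutoff:
        Scaled-space cutoff of the G mapping used by the eRMSD.
    kde_bandwidth:
        Default Gaussian kernel bandwidth (Å) for the scoring density.
    """

    a: float = 5.0
    b: float = 3.0
    shell_min: float = 1.0
    shell_max: float = math.sqrt(2.5)
    z_split: float = 2.0
    r_cutoff: float = 2.4
    kde_bandwidth: float = 0.25
    # edge sectors within the pairing zone, degrees; only the sugar span
    # (190-290) and the WC peak near 60 are anchored in crystal data
    wc_sector: tuple[float, float] = (30.0, 100.0)
    hoogsteen_sector: tuple[float, float] = (100.0, 190.0)
    sugar_sector: tuple[float, float] = (190.0, 290.0)

    def __post_init__(self):
        if min(self.a, self.b, self.shell_min, self.shell_max, self.z_split,
               self.r_cutoff, self.kde_bandwidth) <= 0:
            raise InputError("all scaling parameters must be positive")
        if not (self.shell_min < self.shell_max < self.r_cutoff):
            raise InputError("need shell_min < shell_max < r_cutoff")

    @property
    def gamma(self) -> float:
        return math.pi / self.r_cutoff

    @property
    def scale(self) -> np.ndarray:
        return np.array([self.a, self.a, self.b])


DEFAULT_PARAMS = ScalingParams()


class Zone(str, Enum):
    PAIRING = "PAIRING"
    STACKING = "STACKING"
    NONE = "NONE"


class EdgeSector(str, Enum):
    WC = "WC"
    HOOGSTEEN = "HOOGSTEEN"
    SUGAR = "SUGAR"
    UNASSIGNED = "UNASSIGNED"


@dataclass
class NucleobaseFrame:
    """Origin and orthonormal axes (rows x̂, ŷ, ẑ) of one base."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float)
        if self.axes.shape != (3, 3):
            raise GeometryError("axes must be 3x3")


@dataclass
class PairVector:
    """Position of base k's ring centroid expressed in base j's frame."""

    j: int
    k: int
    r: np.ndarray
    rho: float
    theta: float  # degrees in [0, 360)
    z: float
    r_tilde: np.ndarray
    r_tilde_norm: float


@dataclass
class PairAnnotation:
    """Zone/edge classification of one unordered base pair."""

    j: int
    k: int
    zone: Zone
    edge_sector: EdgeSector = EdgeSector.UNASSIGNED
    mutual: bool = False
    rho: float = 0.0
    theta: float = 0.0
    z: float = 0.0
    r_tilde_norm: float = 0.0


def build_frame(nucleotide) -> NucleobaseFrame:
    """Local frame of a nucleobase from its C2/C4/C6 ring atoms.

    The origin is the centroid; x̂ points toward C2.  The normal ẑ is the
    unit cross product of the ordered atom pair (C2, C4) for pyrimidines and
    (C2, C6) for purines, which makes the Watson-Crick edge of both classes
    fall near θ ≈ +60°.
    """
    c2 = np.asarray(nucleotide.heavy_atoms["C2"], float)
    c4 = np.asarray(nucleotide.heavy_atoms["C4"], float)
    c6 = np.asarray(nucleotide.heavy_atoms["C6"], float)
    origin = (c2 + c4 + c6) / 3.0
    v2, v4, v6 = c2 - origin, c4 - origin, c6 - origin
    area = 0.5 * np.linalg.norm(np.cross(v4 - v2, v6 - v2))
    if area <= 1e-3:
        raise GeometryError("ring atoms are collinear; no frame can be built")
    x = v2 / np.linalg.norm(v2)
    second = v4 if nucleotide.base_class == "pyrimidine" else v6
    z = np.cross(v2, second)
    nz = np.linalg.norm(z)
    if nz <= 1e-9:
        raise GeometryError("degenerate ring geometry")
    z = z / nz
    y = np.cross(z, x)
    return NucleobaseFrame(origin=origin, axes=np.array([x, y, z]))


def structure_frames(structure: RnaStructure) -> tuple[np.ndarray, np.ndarray]:
    """All frames of a structure: origins (N,3) and axes (N,3,3)."""
    frames = [build_frame(nt) for nt in structure]
    return (np.array([f.origin for f in frames]),
            np.array([f.axes for f in frames]))


def scale_vector(r: np.ndarray, params: ScalingParams = DEFAULT_PARAMS) -> np.ndarray:
    """Anisotropic scaling (r_x/a, r_y/a, r_z/b)."""
    return np.asarray(r, float) / params.scale


def _cylindrical(r: np.ndarray) -> tuple[float, float, float]:
    rho = math.hypot(r[0], r[1])
    theta = math.degrees(math.atan2(r[1], r[0])) % 360.0
    return rho, theta, float(r[2])


def pair_vector(frame_j: NucleobaseFrame, frame_k: NucleobaseFrame,
                params: ScalingParams = DEFAULT_PARAMS,
                j: int = -1, k: int = -1) -> PairVector:
    """Vector r_jk of base k's origin in base j's frame, with derived forms."""
    r = frame_j.axes @ (frame_k.origin - frame_j.origin)
    rho, theta, z = _cylindrical(r)
    r_tilde = r / params.scale
    return PairVector(j=j, k=k, r=r, rho=rho, theta=theta, z=z,
                      r_tilde=r_tilde, r_tilde_norm=float(np.linalg.norm(r_tilde)))


def pair_matrices(structure: RnaStructure,
                  params: ScalingParams = DEFAULT_PARAMS
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense ordered-pair geometry of a structure.

    Returns ``(r, r_tilde, norms)`` where ``r[j, k]`` is r_jk in Å in frame j
    (diagonal zero), ``r_tilde`` the scaled form and ``norms[j, k]`` its
    scaled norm.  This is the fast path shared by annotation, scoring and the
    deviation metrics.
    """
    origins, axes = structure_frames(structure)
    diff = origins[None, :, :] - origins[:, None, :]          # (j,k,3)
    r = np.einsum("jab,jkb->jka", axes, diff)
    r_tilde = r / params.scale
    norms = np.linalg.norm(r_tilde, axis=-1)
    np.fill_diagonal(norms, np.inf)  # exclude self-pairs from shell tests
    return r, r_tilde, norms


def enumerate_shell_pairs(structure: RnaStructure,
                          params: ScalingParams = DEFAULT_PARAMS
                          ) -> list[PairVector]:
    """All ordered pairs (j, k), j ≠ k, with scaled norm below the shell max.

    Both (j, k) and (k, j) appear independently whenever each qualifies.
    """
    if len(structure) < 2:
        return []
    r, r_tilde, norms = pair_matrices(structure, params)
    out = []
    for j, k in zip(*np.nonzero(norms < params.shell_max)):
        rho, theta, z = _cylindrical(r[j, k])
        out.append(PairVector(j=int(j), k=int(k), r=r[j, k], rho=rho,
                              theta=theta, z=z, r_tilde=r_tilde[j, k],
                              r_tilde_norm=float(norms[j, k])))
    return out


def _sector(theta: float, params: ScalingParams) -> EdgeSector:
    lo, hi = params.wc_sector
    if lo <= theta < hi:
        return EdgeSector.WC
    lo, hi = params.hoogsteen_sector
    if lo <= theta < hi:
        return EdgeSector.HOOGSTEEN
    lo, hi = params.sugar_sector
    if lo <= theta < hi:
        return EdgeSector.SUGAR
    return EdgeSector.UNASSIGNED


def classify_pair(v_jk: PairVector, v_kj: PairVector,
                  params: ScalingParams = DEFAULT_PARAMS) -> PairAnnotation:
    """Zone and edge classification for one pair given both ordered vectors.

    The pair is in the shell if either ordered norm is below √2.5; the
    pairing/stacking decision (|z| against 2 Å) and the θ sector are taken on
    the ordering with the smaller scaled norm, which is the better-defined
    view.  ``mutual`` records whether both orderings are inside the shell,
    the stricter criterion used for annotation statistics.
    """
    if {v_jk.j, v_jk.k} != {v_kj.j, v_kj.k}:
        raise InputError("classify_pair needs the two orderings of one pair")
    inside_jk = v_jk.r_tilde_norm < params.shell_max
    inside_kj = v_kj.r_tilde_norm < params.shell_max
    j, k = min(v_jk.j, v_jk.k), max(v_jk.j, v_jk.k)
    if not (inside_jk or inside_kj):
        return PairAnnotation(j=j, k=k, zone=Zone.NONE)
    best = v_jk if v_jk.r_tilde_norm <= v_kj.r_tilde_norm else v_kj
    if abs(best.z) <= params.z_split:
        zone = Zone.PAIRING
        sector = _sector(best.theta, params)
    else:
        zone = Zone.STACKING
        sector = EdgeSector.UNASSIGNED
    return PairAnnotation(j=j, k=k, zone=zone, edge_sector=sector,
                          mutual=inside_jk and inside_kj, rho=best.rho,
                          theta=best.theta, z=best.z,
                          r_tilde_norm=best.r_tilde_norm)


def annotate_structure(structure: RnaStructure,
                       params: ScalingParams = DEFAULT_PARAMS
                       ) -> list[PairAnnotation]:
    """One annotation per unordered pair inside the shell, ordered by (j, k)."""
    if len(structure) < 2:
        return []
    r, r_tilde, norms = pair_matrices(structure, params)
    n = len(structure)
    out = []
    for j in range(n):
        for k in range(j + 1, n):
            if norms[j, k] >= params.shell_max and norms[k, j] >= params.shell_max:
                continue
            v_jk = _pv(j, k, r, r_tilde, norms)
            v_kj = _pv(k, j, r, r_tilde, norms)
            ann = classify_pair(v_jk, v_kj, params)
            if ann.zone != Zone.NONE:
                out.append(ann)
    return out


def _pv(j: int, k: int, r, r_tilde, norms) -> PairVector:
    rho, theta, z = _cylindrical(r[j, k])
    return PairVector(j=j, k=k, r=r[j, k], rho=rho, theta=theta, z=z,
                      r_tilde=r_tilde[j, k], r_tilde_norm=float(norms[j, k]))
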