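"""Synthetic structure generators with exactly known geometry.

Everything here is deterministic given its arguments (and seed, where one is
taken), so the rest of the package is testable without downloading any
experimental structure: ideal A-form duplexes, register-shifted duplexes,
stem-loops, Gaussian noise decoys and diffusive toy trajectories.

Base geometry comes from idealized planar nucleobase templates expressed in
the standard nucleic-acid base reference frame (origin on the pseudo-dyad,
base in the x-y plane, C1' at negative x / positive y).  A Watson-Crick pair
is formed by rotating the complementary base's template 180° about the pair
x-axis; the pair is then displaced, inclined and stacked on an ideal helix
with fiber-model A-RNA parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io import Nucleotide, RnaStructure, Trajectory

__all__ = [
    "HelixParams", "BASE_TEMPLATES", "make_aform_duplex",
    "make_register_shift", "make_stem_loop", "perturb", "make_trajectory",
]

# Idealized planar base templates, Å, standard base reference frame (z = 0).
# Heavy base atoms plus the glycosidic C1'.  Values are idealized in-package
# geometry, not taken from any single crystal structure.
BASE_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.0),
        "N9": (-1.291, 4.498, 0.0), "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0), "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0), "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0), "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0), "C4": (-1.267, 3.124, 0.0),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.0),
        "N9": (-1.289, 4.551, 0.0), "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0), "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0), "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0), "C2": (-1.999, 1.087, 0.0),
        "N2": (-2.949, 0.139, 0.0), "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.0),
        "N1": (-1.285, 4.542, 0.0), "C2": (-1.472, 3.158, 0.0),
        "O2": (-2.628, 2.709, 0.0), "N3": (-0.391, 2.344, 0.0),
        "C4": (0.837, 2.868, 0.0), "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0), "C6": (-0.023, 5.068, 0.0),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.0),
        "N1": (-1.284, 4.500, 0.0), "C2": (-1.462, 3.131, 0.0),
        "O2": (-2.563, 2.608, 0.0), "N3": (-0.302, 2.397, 0.0),
        "C4": (0.989, 2.884, 0.0), "O4": (1.935, 2.094, 0.0),
        "C5": (1.089, 4.311, 0.0), "C6": (-0.024, 5.053, 0.0),
    },
}

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# 180° rotation about the pair x-axis maps the complement onto strand II
_FLIP = np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class HelixParams:
    """Fiber-model A-RNA helix parameters.

    twist (deg/step) and rise (Å/step) set the screw; x_displacement (Å)
    pushes the base pair off the helix axis into the deep-major-groove
    geometry characteristic of A-form; inclination (deg) tilts the pair
    about its pseudo-dyad.
    """

    twist: float = 32.7
    rise: float = 2.81
    x_displacement: float = -4.36
    inclination: float = 16.9


DEFAULT_HELIX = HelixParams()


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if not seq or any(c not in COMPLEMENT for c in seq):
        raise InputError(f"sequence must be non-empty over A/C/G/U, got {seq!r}")
    return seq


def _place(base: str, step: int, strand: int, helix: HelixParams
           ) -> dict[str, np.ndarray]:
    """Atoms of one base placed at a helical step (strand 0 or 1)."""
    eta = math.radians(helix.inclination)
    rx = np.array([[1, 0, 0],
                   [0, math.cos(eta), -math.sin(eta)],
                   [0, math.sin(eta), math.cos(eta)]])
    om = math.radians(helix.twist) * step
    rz = np.array([[math.cos(om), -math.sin(om), 0],
                   [math.sin(om), math.cos(om), 0],
                   [0, 0, 1]])
    shift = np.array([helix.x_displacement, 0.0, 0.0])
    lift = np.array([0.0, 0.0, helix.rise * step])
    flip = np.eye(3) if strand == 0 else _FLIP
    out = {}
    for name, xyz in BASE_TEMPLATES[base].items():
        v = flip @ np.asarray(xyz, float)
        out[name] = rz @ (rx @ (v + shift)) + lift
    return out


def _nt(base: str, chain: str, resnum: int, atoms: dict[str, np.ndarray]
        ) -> Nucleotide:
    return Nucleotide(base_identity=base, chain_id=chain, resnum=resnum,
                      heavy_atoms=atoms)


def make_aform_duplex(seq: str, helix: HelixParams = DEFAULT_HELIX
                      ) -> RnaStructure:
    """Ideal A-form duplex of ``seq`` and its reverse complement.

    Chain A carries ``seq`` 5'→3' on helical steps 0..n-1; chain B carries
    the complement, antiparallel, listed in its own 5'→3' order.
    """
    seq = _check_sequence(seq)
    n = len(seq)
    nts = [_nt(b, "A", i + 1, _place(b, i, 0, helix))
           for i, b in enumerate(seq)]
    # strand II 5'->3' runs from step n-1 down to 0
    for r, step in enumerate(range(n - 1, -1, -1)):
        b = COMPLEMENT[seq[step]]
        nts.append(_nt(b, "B", r + 1, _place(b, step, 1, helix)))
    return RnaStructure(nts, source=f"aform:{seq}")


def make_register_shift(duplex_seq: str, shift: int,
                        helix: HelixParams = DEFAULT_HELIX) -> RnaStructure:
    """The same two strands re-paired with a ``shift``-step register offset.

    The complementary strand is slid along the same ideal helix by ``shift``
    helical steps, giving single-strand overhangs at both ends.  Nucleotide
    count, identities and ordering match :func:`make_aform_duplex`, so the
    two structures are in positional correspondence.
    """
    seq = _check_sequence(duplex_seq)
    n = len(seq)
    if abs(int(shift)) >= n:
        raise InputError(f"|shift| must be < strand length {n}")
    nts = [_nt(b, "A", i + 1, _place(b, i, 0, helix))
           for i, b in enumerate(seq)]
    for r, step in enumerate(range(n - 1, -1, -1)):
        b = COMPLEMENT[seq[step]]
        nts.append(_nt(b, "B", r + 1, _place(b, step + int(shift), 1, helix)))
    return RnaStructure(nts, source=f"aform:{seq}:shift{shift}")


def make_stem_loop(stem_seq: str, loop_seq: str,
                   helix: HelixParams = DEFAULT_HELIX) -> RnaStructure:
    """Single-chain hairpin: A-form stem capped by an arc of loop bases.

    The loop bases are laid out on a quadratic Bézier arc bridging the two
    stem strand ends, each base plane perpendicular to the local arc tangent.
    The loop is a deterministic geometric cap, not an energy-minimized loop
    conformation; it keeps consecutive ring centers well under backbone-gap
    distance so the hairpin segments as a single strand.
    """
    stem_seq = _check_sequence(stem_seq)
    loop_seq = _check_sequence(loop_seq)
    duplex = make_aform_duplex(stem_seq, helix)
    n = len(stem_seq)
    up = duplex.nucleotides[:n]                # chain A, steps 0..n-1
    down = duplex.nucleotides[n:]              # chain B, steps n-1..0
    e1 = up[-1].ring_center
    e2 = down[0].ring_center
    apex = (e1 + e2) / 2.0 + np.array([0.0, 0.0, 6.0 + 1.2 * len(loop_seq)])
    loop_nts = []
    for i, b in enumerate(loop_seq):
        t = (i + 1) / (len(loop_seq) + 1)
        center = (1 - t) ** 2 * e1 + 2 * (1 - t) * t * apex + t ** 2 * e2
        tangent = 2 * (1 - t) * (apex - e1) + 2 * t * (e2 - apex)
        tangent /= np.linalg.norm(tangent)
        rot = _rotation_taking_z_to(tangent)
        template = {k: np.asarray(v, float) for k, v in BASE_TEMPLATES[b].items()}
        ring_centroid = np.mean(
            [template[a] for a in ("C2", "C4", "C6")], axis=0)
        atoms = {k: rot @ (v - ring_centroid) + center
                 for k, v in template.items()}
        loop_nts.append(_nt(b, "A", 0, atoms))
    nts = []
    for i, nt in enumerate(up + loop_nts + list(down)):
        c = nt.copy()
        c.chain_id = "A"
        c.resnum = i + 1
        nts.append(c)
    return RnaStructure(nts, source=f"stemloop:{stem_seq}/{loop_seq}")


def _rotation_taking_z_to(v: np.ndarray) -> np.ndarray:
    """Minimal rotation mapping the +z axis onto unit vector v."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, v)
    s = np.linalg.norm(axis)
    axis /= s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def perturb(structure: RnaStructure, sigma: float, seed: int) -> RnaStructure:
    """Independent Gaussian displacement of every heavy atom (decoy maker)."""
    if sigma < 0:
        raise InputError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for nt in structure:
        c = nt.copy()
        c.heavy_atoms = {k: v + rng.normal(0.0, sigma, 3) if sigma > 0 else v
                         for k, v in c.heavy_atoms.items()}
        out.append(c)
    return RnaStructure(out, model_index=structure.model_index,
                        source=structure.source)


def make_trajectory(base: RnaStructure, n_frames: int, step_sigma: float,
                    seed: int) -> Trajectory:
    """Diffusive toy trajectory: per-frame accumulated Gaussian random walk."""
    if n_frames < 2:
        raise InputError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    frames = [base.subset(range(len(base)))]
    current = frames[0]
    for _ in range(n_frames - 1):
        nts = []
        for nt in current:
            c = nt.copy()
            if step_sigma > 0:
                c.heavy_atoms = {k: v + rng.normal(0.0, step_sigma, 3)
                                 for k, v in c.heavy_atoms.items()}
            nts.append(c)
        current = RnaStructure(nts, source=base.source)
        frames.append(current)
    return Trajectory(frames)
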