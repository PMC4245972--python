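"""3D motif search by windowed eRMSD.

A query structure (hairpin loop, internal loop, ...) is segmented at chain
boundaries and backbone gaps.  The target is scanned with contiguous windows
matching the segment lengths — optionally allowing bulged nucleotides, i.e.
windows one nucleotide longer with one internal position deleted — and every
window set whose eRMSD to the query falls below the threshold is reported.
Because the eRMSD only sees relative nucleobase arrangement, matches are
invariant under rigid motion of the target and do not require superposition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .geometry import DEFAULT_PARAMS, ScalingParams, structure_frames
from .io import RnaStructure, read_structure

logger = logging.getLogger(__name__)

__all__ = ["MotifQuery", "MotifMatch", "segment_query", "search",
           "batch_search", "BACKBONE_GAP"]

#: consecutive ring centroids farther apart than this (Å) break a segment
BACKBONE_GAP = 12.0


@dataclass
class MotifQuery:
    """Query structure split into contiguous strand segments."""

    structure: RnaStructure
    segments: list[tuple[int, int]]  # half-open [start, stop) index ranges

    @property
    def length(self) -> int:
        return len(self.structure)

    @property
    def segment_lengths(self) -> list[int]:
        return [stop - start for start, stop in self.segments]


@dataclass
class MotifMatch:
    """One placement of the query inside a target."""

    target_id: str
    window: list[int]            # target nucleotide indices, query order
    residues: list[str]          # author labels chain:resnum[icode]
    ermsd: float
    bulged: list[int] = field(default_factory=list)


def _breakpoints(structure: RnaStructure) -> list[int]:
    """Indices i with a strand break between nucleotides i and i+1."""
    centers = structure.ring_centers()
    gaps = {
        i for i in range(len(structure) - 1)
        if np.linalg.norm(centers[i + 1] - centers[i]) > BACKBONE_GAP
    }
    return sorted(gaps.union(structure.chain_breaks()))


def segment_query(structure: RnaStructure) -> MotifQuery:
    """Split a query at chain boundaries and backbone gaps."""
    breaks = _breakpoints(structure)
    starts = [0] + [b + 1 for b in breaks]
    stops = [b + 1 for b in breaks] + [len(structure)]
    segments = list(zip(starts, stops))
    for start, stop in segments:
        if stop - start < 2:
            raise InputError(
                f"query segment [{start},{stop}) has fewer than 2 nucleotides")
    return MotifQuery(structure=structure, segments=segments)


def _segment_windows(seg_len: int, runs: list[tuple[int, int]],
                     allow_bulge: bool) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (window indices, bulged indices) placements for one segment.

    ``runs`` are the target's own contiguous [start, stop) stretches; windows
    never span a target strand break.
    """
    out = []
    for start, stop in runs:
        for w0 in range(start, stop - seg_len + 1):
            out.append((tuple(range(w0, w0 + seg_len)), ()))
        if allow_bulge:
            for w0 in range(start, stop - seg_len):
                full = range(w0, w0 + seg_len + 1)
                for cut in list(full)[1:-1]:  # only internal deletions
                    keep = tuple(i for i in full if i != cut)
                    out.append((keep, (cut,)))
    return out


def _g_for_indices(origins: np.ndarray, axes: np.ndarray,
                   idx: np.ndarray, params: ScalingParams) -> np.ndarray:
    """G matrix of the sub-structure given precomputed target frames."""
    o, a = origins[idx], axes[idx]
    diff = o[None, :, :] - o[:, None, :]
    r = np.einsum("jab,jkb->jka", a, diff)
    r_tilde = r / params.scale
    norms = np.linalg.norm(r_tilde, axis=-1)
    np.fill_diagonal(norms, np.inf)
    gamma = params.gamma
    inside = norms < params.r_cutoff
    safe = np.where(norms > 1e-12, norms, 1.0)
    capped = np.minimum(norms, params.r_cutoff)
    s = np.where(inside, np.sin(gamma * capped) / safe, 0.0)
    g = np.empty(norms.shape + (4,))
    g[..., :3] = s[..., None] * r_tilde
    g[..., 3] = np.where(inside, 1.0 + np.cos(gamma * capped), 0.0)
    return g / gamma


def _author_label(nt) -> str:
    return f"{nt.chain_id}:{nt.resnum}{nt.icode}"


def search(query: MotifQuery, target: RnaStructure, threshold: float = 0.7,
           max_bulges: int = 1, params: ScalingParams = DEFAULT_PARAMS,
           max_combinations: int = 200_000) -> list[MotifMatch]:
    """All placements of the query in the target with eRMSD below threshold.

    Single-segment queries slide a window of the segment length (and, with
    ``max_bulges >= 1``, length+1 windows with each internal deletion tried).
    Multi-segment queries enumerate ordered, non-overlapping window sets, one
    per segment, with at most ``max_bulges`` bulges in total.  Overlapping
    matches (sharing at least half of the query length) are deduplicated
    keeping the lowest eRMSD; results are sorted by eRMSD ascending.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    if len(target) < query.length:
        return []
    # precompute query and target geometry once
    q_g = _g_for_indices(*structure_frames(query.structure),
                         np.arange(query.length), params)
    t_origins, t_axes = structure_frames(target)
    t_breaks = _breakpoints(target)
    starts = [0] + [b + 1 for b in t_breaks]
    stops = [b + 1 for b in t_breaks] + [len(target)]
    runs = list(zip(starts, stops))

    per_segment = [
        _segment_windows(seg_len, runs, max_bulges >= 1)
        for seg_len in query.segment_lengths
    ]
    n_combos = int(np.prod([len(p) for p in per_segment]))
    if n_combos > max_combinations:
        logger.warning("window combinations capped at %d (of %d)",
                       max_combinations, n_combos)

    candidates: list[MotifMatch] = []
    tried = 0
    n = query.length
    for combo in itertools.product(*per_segment):
        tried += 1
        if tried > max_combinations:
            break
        windows = [c[0] for c in combo]
        bulges = [i for c in combo for i in c[1]]
        if len(bulges) > max_bulges:
            continue
        if len(windows) > 1:
            # ordered, non-overlapping segment placement
            ok = all(windows[i][-1] < windows[i + 1][0]
                     for i in range(len(windows) - 1))
            if not ok:
                continue
        idx = np.array([i for w in windows for i in w])
        g = _g_for_indices(t_origins, t_axes, idx, params)
        val = float(np.sqrt(np.sum((q_g - g) ** 2) / n))
        if val < threshold:
            candidates.append(MotifMatch(
                target_id=target.source,
                window=[int(i) for i in idx],
                residues=[_author_label(target[i]) for i in idx],
                ermsd=val, bulged=[int(b) for b in bulges]))

    candidates.sort(key=lambda m: (m.ermsd, m.window))
    kept: list[MotifMatch] = []
    min_shared = max(1, query.length // 2)
    for cand in candidates:
        cset = set(cand.window)
        if any(len(cset & set(k.window)) >= min_shared for k in kept):
            continue
        kept.append(cand)
    return kept


def batch_search(query: MotifQuery, targets, threshold: float = 0.7,
                 max_bulges: int = 1,
                 params: ScalingParams = DEFAULT_PARAMS) -> list[MotifMatch]:
    """Run :func:`search` over many target files with per-target provenance.

    Unreadable targets are skipped with a logged warning; targets may be file
    paths or already-loaded structures.
    """
    targets = list(targets)
    if not targets:
        raise InputError("need at least one target")
    matches: list[MotifMatch] = []
    for item in targets:
        if isinstance(item, RnaStructure):
            structure = item
        else:
            try:
                structure = read_structure(item)
            except Exception as exc:
                logger.warning("skipping target %s: %s", item, exc)
                continue
            structure.source = str(item)
        for m in search(query, structure, threshold, max_bulges, params):
            m.target_id = structure.source
            matches.append(m)
    return matches
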