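"""Knowledge-based scoring of RNA conformations (eSCORE).

The score of a structure is the sum, over all ordered base pairs (j, k), of
the empirical probability density p(r_jk) of relative nucleobase positions:

    eSCORE = Σ_{j,k} p(r_jk)

p is learned from reference structures as a Gaussian kernel density estimate
(isotropic bandwidth, default 0.25 Å) over the frame-coordinate vectors r of
all ordered base pairs inside the interaction shell (r̃ < √2.5).  Sequence
identity is ignored: the molecule is treated as a homopolymer.  The sum of
probabilities — rather than their product — keeps sparsely populated regions
from dominating the score; geometries unseen in the training set, including
steric clashes, simply contribute ≈ 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neighbors import KernelDensity

from .errors import EmptyStructureError, InputError
from .geometry import DEFAULT_PARAMS, ScalingParams, pair_matrices
from .io import RnaStructure

__all__ = ["ScoreModel", "DecoyRanking", "fit_score_model",
           "evaluate_density", "escore", "rank_decoys",
           "save_model", "load_model"]


@dataclass
class ScoreModel:
    """Gaussian-KDE density over shell pair vectors (Å, frame coordinates)."""

    training_vectors: np.ndarray
    bandwidth: float = 0.25
    params: ScalingParams = field(default_factory=ScalingParams)
    metadata: str = ""

    def __post_init__(self):
        self.training_vectors = np.atleast_2d(
            np.asarray(self.training_vectors, float))
        if self.bandwidth <= 0:
            raise InputError("bandwidth must be positive")
        if self.training_vectors.size == 0:
            raise EmptyStructureError("score model has no training vectors")
        self._kde = KernelDensity(kernel="gaussian",
                                  bandwidth=self.bandwidth)
        self._kde.fit(self.training_vectors)

    @property
    def n_vectors(self) -> int:
        return self.training_vectors.shape[0]

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return np.exp(self._kde.score_samples(pts))


def fit_score_model(structures: Sequence[RnaStructure],
                    bandwidth: float = 0.25,
                    params: ScalingParams = DEFAULT_PARAMS,
                    mutual: bool = False,
                    metadata: str = "") -> ScoreModel:
    """Train the density p(r) on the shell pair vectors of the inputs.

    Every ordered pair vector r_jk with its own scaled norm inside the shell
    is a training point; with ``mutual=True`` the stricter rule is applied
    instead (both r̃_jk and r̃_kj inside the shell).
    """
    vecs = []
    for s in structures:
        if len(s) < 2:
            continue
        r, _, norms = pair_matrices(s, params)
        inside = norms < params.shell_max
        if mutual:
            inside = inside & inside.T
        vecs.append(r[inside])
    if not vecs or sum(v.shape[0] for v in vecs) == 0:
        raise EmptyStructureError(
            "no base pair inside the interaction shell; cannot fit a model")
    return ScoreModel(training_vectors=np.concatenate(vecs),
                      bandwidth=bandwidth, params=params, metadata=metadata)


def evaluate_density(model: ScoreModel, r: np.ndarray) -> float:
    """Density p(r) at one frame-coordinate position (Å⁻³)."""
    return float(model.density(np.asarray(r, float).reshape(1, 3))[0])


def escore(structure: RnaStructure, model: ScoreModel) -> float:
    """Sum of p(r_jk) over all ordered base pairs of a structure.

    Pairs far outside the shell (scaled norm beyond shell_max plus three
    bandwidths) contribute numerically nothing and are skipped.
    """
    if len(structure) < 2:
        return 0.0
    p = model.params
    r, _, norms = pair_matrices(structure, p)
    margin = p.shell_max + 3.0 * model.bandwidth / min(p.a, p.b)
    query = r[norms < margin]
    if query.shape[0] == 0:
        return 0.0
    return float(model.density(query).sum())


@dataclass
class DecoyRanking:
    """Native score against a decoy ensemble and the normalized rank."""

    native_score: float
    decoy_scores: list[float]
    normalized_rank: float


def rank_decoys(native: RnaStructure, decoys: Sequence[RnaStructure],
                model: ScoreModel) -> DecoyRanking:
    """Normalized rank: fraction of decoys scoring strictly above the native.

    0 means perfect recognition of the native; ties count as not-better.
    """
    if not decoys:
        raise InputError("need at least one decoy")
    native_score = escore(native, model)
    decoy_scores = [escore(d, model) for d in decoys]
    better = sum(1 for s in decoy_scores if s > native_score)
    return DecoyRanking(native_score=native_score, decoy_scores=decoy_scores,
                        normalized_rank=better / len(decoy_scores))


def save_model(model: ScoreModel, path) -> None:
    """Serialize a model to portable JSON (exact re-evaluation guaranteed)."""
    payload = {
        "format": "ebase-score-model",
        "version": 1,
        "bandwidth": model.bandwidth,
        "metadata": model.metadata,
        "params": {
            "a": model.params.a, "b": model.params.b,
            "shell_min": model.params.shell_min,
            "shell_max": model.params.shell_max,
            "z_split": model.params.z_split,
            "r_cutoff": model.params.r_cutoff,
            "kde_bandwidth": model.params.kde_bandwidth,
        },
        "training_vectors": model.training_vectors.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ScoreModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ebase-score-model":
        raise InputError(f"{path} is not an ebase score model")
    params = ScalingParams(**payload["params"])
    return ScoreModel(training_vectors=np.array(payload["training_vectors"]),
                      bandwidth=payload["bandwidth"], params=params,
                      metadata=payload.get("metadata", ""))
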