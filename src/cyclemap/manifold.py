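"""Latent embedding of trajectories and 2-D projection of the manifold.

Downstream analysis uses the posterior *mean* of each frame — a
deterministic embedding — and a UMAP projection to two dimensions fitted on
training-set latents only.  Because the sign of a UMAP axis is arbitrary
from run to run, projections are orientation-normalised so that
mitosis-like reference frames (divisions) sit at the minimum end of the
first axis; every trajectory-level rule downstream assumes that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CellTrajectory, LatentSequence
from .model import ManifoldModel, encode

__all__ = ["Projection2D", "embed_trajectory", "CyclePlaneProjector",
           "orient_projection", "orientation_sign"]


@dataclass
class Projection2D:
    """Per-frame 2-D coordinates of one trajectory on the manifold."""

    cell_id: str
    coords: np.ndarray            # (T, 2): UMAP1, UMAP2
    orientation_sign: int = 1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (T, 2)")

    @property
    def umap1(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def umap2(self) -> np.ndarray:
        return self.coords[:, 1]


def embed_trajectory(model: ManifoldModel, traj: CellTrajectory,
                     batch_size: int = 256) -> LatentSequence:
    """Encode every frame to its posterior mean (deterministic)."""
    mus = [encode(model, traj.images[k:k + batch_size]).mu
           for k in range(0, len(traj), batch_size)]
    return LatentSequence(cell_id=traj.cell_id, latents=np.concatenate(mus),
                          times_min=traj.times_min, stages=traj.stages)


class CyclePlaneProjector(BaseEstimator, TransformerMixin):
    """UMAP reduction of the latent space to the 2-D cycle plane.

    Fitted on pooled training latents; held-out latents are projected with
    the same fitted mapping (no refitting).  A fixed seed makes the
    embedding reproducible.
    """

    def __init__(self, n_neighbors: int = 30, min_dist: float = 0.1,
                 metric: str = "euclidean", seed: int = 0):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.metric = metric
        self.seed = seed

    def fit(self, X: np.ndarray, y=None) -> "CyclePlaneProjector":
        import umap

        X = np.asarray(X, dtype=np.float64)
        if len(X) < 10:
            raise ValueError("need at least 10 latent vectors to fit")
        self.umap_ = umap.UMAP(
            n_components=2, n_neighbors=min(self.n_neighbors, len(X) - 1),
            min_dist=self.min_dist, metric=self.metric,
            random_state=self.seed)
        self.umap_.fit(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.umap_.transform(np.asarray(X, dtype=np.float64)),
                          dtype=np.float64)

    def project(self, seq: LatentSequence) -> Projection2D:
        return Projection2D(cell_id=seq.cell_id,
                            coords=self.transform(seq.latents))


def canonical_rotation(coords: np.ndarray,
                       reference_idx: np.ndarray) -> np.ndarray:
    """Rotation matrix normalising the arbitrary pose of the 2-D plane.

    The embedding returned by the projector is defined only up to a rigid
    transform, so trajectory-level rules need a convention.  The returned
    2x2 rotation places the centroid of the reference (mitosis/division)
    frames, relative to the overall centroid, in the lower-left diagonal
    direction: mitosis then sits at the minimum end of UMAP1 (the landscape
    reading) and cycle starts at troughs of UMAP2 (the oscillation reading).
    Apply as ``coords @ R.T``.
    """
    coords = np.asarray(coords, dtype=np.float64)
    ref = np.asarray(reference_idx, dtype=int)
    if ref.size == 0:
        warnings.warn("no reference frames; leaving the plane unrotated")
        return np.eye(2)
    v = coords[ref].mean(axis=0) - coords.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        return np.eye(2)
    v = v / norm
    target = np.array([-1.0, -1.0]) / np.sqrt(2.0)
    c = float(v @ target)
    s = float(v[0] * target[1] - v[1] * target[0])
    return np.array([[c, -s], [s, c]])


def orientation_sign(umap1: np.ndarray, reference_frames: np.ndarray) -> int:
    """+1 if reference (M-like) frames already sit at the low end of UMAP1,
    else -1."""
    ref = np.asarray(reference_frames, dtype=int)
    return 1 if np.mean(umap1[ref]) <= np.mean(umap1) else -1


def orient_projection(proj: Projection2D,
                      reference_frames: np.ndarray) -> Projection2D:
    """Normalise axis polarity so M-like frames are at the UMAP1 minimum.

    Idempotent; with no reference frames the projection is returned
    unchanged with a warning.
    """
    ref = np.asarray(reference_frames, dtype=int)
    if ref.size == 0:
        warnings.warn("no reference frames; leaving orientation unchanged")
        return proj
    if np.any(ref < 0) or np.any(ref >= len(proj.coords)):
        raise ValueError("reference frames out of range")
    sign = orientation_sign(proj.umap1, ref)
    if sign == 1:
        return replace(proj, orientation_sign=proj.orientation_sign)
    coords = proj.coords.copy()
    coords[:, 0] *= -1
    return Projection2D(cell_id=proj.cell_id, coords=coords,
                        orientation_sign=-proj.orientation_sign)
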