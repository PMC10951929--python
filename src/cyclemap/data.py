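"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["STAGES", "CellTrajectory", "LatentSequence"]

#: Canonical biological stage order, phase 0 = cell birth (post-mitosis).
STAGES: tuple[str, ...] = ("G1", "earlyS", "midS", "lateS", "G2", "M")


@dataclass
class CellTrajectory:
    """One cell's ordered patch stack with timestamps.

    ``images`` is (T, H, W) with pixels in [0, 1]; ``stages`` are optional
    per-frame labels used only for evaluation and cluster naming, never for
    training.
    """

    cell_id: str
    images: np.ndarray
    times_min: np.ndarray
    stages: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.times_min = np.asarray(self.times_min, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be (T, H, W)")
        if len(self.times_min) != len(self.images):
            raise ValueError("timestamps must match frame count")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError(f"non-monotone timestamps for cell {self.cell_id}")
        if self.stages is not None:
            self.stages = np.asarray(self.stages)
            if len(self.stages) != len(self.images):
                raise ValueError("stage labels must match frame count")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def patch_size(self) -> int:
        return self.images.shape[1]


@dataclass
class LatentSequence:
    """Per-frame posterior means of one trajectory in the learned latent space."""

    cell_id: str
    latents: np.ndarray
    times_min: np.ndarray
    stages: np.ndarray | None = None

    def __post_init__(self):
        self.latents = np.asarray(self.latents, dtype=np.float64)
        self.times_min = np.asarray(self.times_min, dtype=np.float64)
        if self.latents.ndim != 2 or len(self.latents) != len(self.times_min):
            raise ValueError("latents must be (T, d) aligned with timestamps")
        if not np.isfinite(self.latents).all():
            raise ValueError("non-finite latent values")

    def __len__(self) -> int:
        return len(self.latents)
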