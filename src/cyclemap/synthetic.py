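"""Synthetic single-channel nucleus movies with known cycle phase.

The generator emulates the statistical character of PCNA-marked live-cell
trajectories: a centred nucleus whose size grows through interphase, punctate
replication foci whose number and size change across early/mid/late S phase,
chromatin condensation into a small bright object at mitosis, additive camera
noise and slow photobleaching.  Every frame carries ground truth — the
continuous cycle phase, the discrete stage label and the division times — so
the whole downstream pipeline (manifold training, staging, duration
estimation) can be validated without any external data.

It is an appearance caricature, not a photorealistic simulation: foci are
Gaussian blobs redrawn per frame, illumination is uniform, and there is a
single cell per patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import STAGES, CellTrajectory

__all__ = ["SyntheticConfig", "GroundTruth", "phase_to_stage",
           "phases_to_stages", "render_cell", "simulate_trajectory",
           "simulate_dataset", "DEFAULT_STAGE_FRACTIONS"]

#: Typical HeLa stage occupancy as fractions of the cycle (configurable).
DEFAULT_STAGE_FRACTIONS: dict[str, float] = {
    "G1": 0.35, "earlyS": 0.12, "midS": 0.12, "lateS": 0.12,
    "G2": 0.21, "M": 0.08,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic movie generator.

    ``period_frames`` is the number of frames per full cycle;
    ``period_jitter`` the fractional standard deviation of the per-frame
    phase increment; ``initial_phase`` the rough synchronisation point at
    trajectory start (defaults to late G2, just before mitosis).
    """

    patch_size: int = 64
    n_frames: int = 255
    frame_interval: float = 5.9           # minutes
    period_frames: int = 200
    period_jitter: float = 0.02
    stage_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS))
    noise_sigma: float = 0.03
    photobleach_rate: float = 0.0005      # per-frame fractional decay
    initial_phase: float = 0.85
    initial_phase_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.patch_size < 16:
            raise ValueError("patch_size must be at least 16")
        if self.period_frames < 8:
            raise ValueError("period_frames must be at least 8")
        if set(self.stage_fractions) != set(STAGES):
            raise ValueError(f"stage_fractions must cover exactly {STAGES}")
        total = sum(self.stage_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage fractions must sum to 1, got {total}")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative stage boundaries over [0, 1] in canonical order."""
        fr = [self.stage_fractions[s] for s in STAGES]
        return np.concatenate([[0.0], np.cumsum(fr)])


@dataclass
class GroundTruth:
    """Per-frame truth emitted alongside a synthetic trajectory."""

    phase: np.ndarray
    stage: np.ndarray
    division_frames: np.ndarray
    true_period_minutes: float


def phase_to_stage(phase: float, stage_fractions: dict[str, float] | None = None
                   ) -> str:
    """Map a cycle fraction in [0, 1) to its stage label.

    Stages partition [0, 1) into half-open intervals in the canonical order
    G1 -> earlyS -> midS -> lateS -> G2 -> M, with phase 0 at cell birth.
    """
    return str(phases_to_stages(np.array([phase]), stage_fractions)[0])


def phases_to_stages(phase: np.ndarray,
                     stage_fractions: dict[str, float] | None = None
                     ) -> np.ndarray:
    """Vectorised :func:`phase_to_stage`."""
    fractions = dict(stage_fractions or DEFAULT_STAGE_FRACTIONS)
    cfg_bounds = SyntheticConfig(stage_fractions=fractions).boundaries
    phase = np.asarray(phase, dtype=np.float64)
    if np.any(phase < 0) or np.any(phase >= 1):
        raise ValueError("phase must lie in [0, 1)")
    idx = np.clip(np.searchsorted(cfg_bounds, phase, side="right") - 1,
                  0, len(STAGES) - 1)
    return np.array(STAGES)[idx]


def _soft_disk(p: int, radius: float, edge: float = 1.5) -> np.ndarray:
    ax = np.arange(p) - (p - 1) / 2.0
    d = np.hypot(ax[:, None], ax[None, :])
    return 1.0 / (1.0 + np.exp((d - radius) / edge))


def _add_foci(img: np.ndarray, rng: np.random.Generator, n: int,
              sigma: float, amp: float, r_lo: float, r_hi: float) -> None:
    p = img.shape[0]
    c = (p - 1) / 2.0
    ax = np.arange(p)
    for _ in range(n):
        rad = rng.uniform(r_lo, r_hi)
        ang = rng.uniform(0, 2 * np.pi)
        y, x = c + rad * np.sin(ang), c + rad * np.cos(ang)
        img += amp * np.exp(-(((ax[:, None] - y) ** 2 + (ax[None, :] - x) ** 2)
                              / (2 * sigma**2)))


def render_cell(phase: float, config: SyntheticConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Render one nucleus patch at the given cycle phase; pixels in [0, 1].

    Interphase nuclei grow in radius from birth towards mitosis; S-phase
    nuclei carry punctate foci (many small ones early, most numerous mid-S,
    fewer but larger ones late); the mitotic cell is a small, condensed,
    bright object.  Identical (phase, rng state) pairs render identically.
    """
    if not 0 <= phase < 1:
        raise ValueError("phase must lie in [0, 1)")
    p = config.patch_size
    stage = phase_to_stage(phase, config.stage_fractions)
    m_start = config.boundaries[-2]  # where mitosis begins
    growth = min(phase / m_start, 1.0) if m_start > 0 else 1.0

    if stage == "M":
        radius = 0.16 * p
        amp = 0.95
        img = amp * _soft_disk(p, radius, edge=1.0)
    else:
        radius = (0.18 + 0.10 * growth) * p
        amp = 0.42 + 0.10 * growth
        img = amp * _soft_disk(p, radius)
        # mild within-nucleus texture so interphase frames are not flat disks
        img *= 1.0 + 0.05 * np.cos(
            np.linspace(0, 3 * np.pi, p))[:, None] * _soft_disk(p, radius)
        if stage == "earlyS":
            _add_foci(img, rng, n=20, sigma=0.02 * p, amp=0.25,
                      r_lo=0.0, r_hi=0.7 * radius)
        elif stage == "midS":
            _add_foci(img, rng, n=35, sigma=0.02 * p, amp=0.25,
                      r_lo=0.0, r_hi=0.9 * radius)
        elif stage == "lateS":
            _add_foci(img, rng, n=8, sigma=0.045 * p, amp=0.35,
                      r_lo=0.5 * radius, r_hi=0.95 * radius)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def simulate_trajectory(config: SyntheticConfig,
                        rng: np.random.Generator
                        ) -> tuple[CellTrajectory, GroundTruth]:
    """Simulate one cell: phase advances ~1/period per frame; crossing 1
    is a division and resets the cycle."""
    inc_mean = 1.0 / config.period_frames
    start = config.initial_phase
    if config.initial_phase_jitter > 0:
        start = start + rng.normal(0.0, config.initial_phase_jitter)
    start = start % 1.0
    incs = inc_mean * (1.0 + config.period_jitter
                       * rng.standard_normal(config.n_frames - 1))
    incs = np.maximum(incs, 0.2 * inc_mean)  # phase must strictly increase
    unwrapped = start + np.concatenate([[0.0], np.cumsum(incs)])
    phase = unwrapped % 1.0
    division_frames = np.flatnonzero(np.diff(np.floor(unwrapped + 1e-12)) > 0) + 1
    stage = phases_to_stages(phase, config.stage_fractions)

    frames = np.empty((config.n_frames, config.patch_size, config.patch_size),
                      dtype=np.float32)
    bleach = (1.0 - config.photobleach_rate) ** np.arange(config.n_frames)
    for t in range(config.n_frames):
        img = render_cell(float(phase[t]), config, rng)
        frames[t] = (img * bleach[t]).astype(np.float32)
    times = np.arange(config.n_frames) * config.frame_interval
    truth = GroundTruth(
        phase=phase, stage=stage, division_frames=division_frames,
        true_period_minutes=config.period_frames * config.frame_interval)
    traj = CellTrajectory(cell_id="", images=frames, times_min=times,
                          stages=stage.copy())
    return traj, truth


def simulate_dataset(config: SyntheticConfig, n_cells: int
                     ) -> list[tuple[CellTrajectory, GroundTruth]]:
    """Simulate independent cells with per-cell RNG streams spawned from the
    master seed; the same (seed, n_cells) reproduces the dataset bit-exactly."""
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    out = []
    for i, ss in enumerate(np.random.SeedSequence(config.seed).spawn(n_cells)):
        traj, truth = simulate_trajectory(config, np.random.default_rng(ss))
        traj.cell_id = f"cell{i:04d}"
        out.append((traj, truth))
    return out
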