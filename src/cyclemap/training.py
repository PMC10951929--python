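"""Three-stage optimisation of the cell-cycle manifold.

Stage 1 warms up reconstruction: the KL term is held at a small constant
weight so the autoencoder focuses on pixel error and the learned similarity
metric.  Stage 2 anneals the KL weight up linearly to constrain the latent
space and avoid posterior collapse.  Stage 3 adds the temporal
cycle-consistency loss between pairs of trajectories to align the cycle in
latent space.  All modules are optimised with Adam; checkpoints and an
early-stopping check run on a held-out validation split every few epochs and
the best checkpoint of each stage is restored before moving on.

The ``CycleManifoldVAEGAN`` estimator wraps the procedure in the
scikit-learn fit/transform idiom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._autodiff import Tensor
from ._nn import Adam
from .data import CellTrajectory, LatentSequence
from .model import ManifoldModel
from .tcc import tcc_loss_graph

__all__ = ["TrainingSchedule", "kl_annealing_weight", "total_loss", "train",
           "CycleManifoldVAEGAN"]


@dataclass
class TrainingSchedule:
    """Hyperparameters of the three training stages.

    ``epochs_per_stage`` may be one integer or a (stage1, stage2, stage3)
    triple.  ``kl_anneal_epochs=None`` anneals over the first half of stage
    2.  ``early_stop_patience`` counts checkpoints (not epochs) without
    validation improvement.
    """

    epochs_per_stage: int | tuple[int, int, int] = 1000
    lr: float = 1e-4
    kl_weight_initial: float = 1e-3
    kl_weight_final: float = 1.0
    kl_anneal_epochs: int | None = None
    tcc_weight: float = 0.1
    tcc_temperature: float = 1.0
    tcc_window: int = 64
    lambda_feat: float = 1.0
    adv_weight: float = 0.1
    disc_lr_factor: float = 1.0
    checkpoint_every: int = 10
    early_stop_patience: int = 20
    batch_size: int = 64
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        for w in (self.kl_weight_initial, self.kl_weight_final,
                  self.tcc_weight, self.lambda_feat, self.adv_weight):
            if w < 0:
                raise ValueError("loss weights must be non-negative")
        if min(self.stage_epochs) < 1:
            raise ValueError("each stage needs at least one epoch")

    @property
    def stage_epochs(self) -> tuple[int, int, int]:
        e = self.epochs_per_stage
        return (e, e, e) if isinstance(e, int) else tuple(e)


def kl_annealing_weight(epoch: int, schedule: TrainingSchedule) -> float:
    """KL weight at a stage-2 epoch: linear ramp, then constant.

    Monotone non-decreasing from ``kl_weight_initial`` to ``kl_weight_final``
    over ``kl_anneal_epochs`` (default: half the stage-2 epochs).
    """
    anneal = schedule.kl_anneal_epochs
    if anneal is None:
        anneal = max(1, schedule.stage_epochs[1] // 2)
    if anneal <= 0 or epoch >= anneal:
        return schedule.kl_weight_final
    frac = epoch / anneal
    return (schedule.kl_weight_initial
            + frac * (schedule.kl_weight_final - schedule.kl_weight_initial))


def total_loss(stage: int, schedule: TrainingSchedule, epoch: int,
               recon, kl, gen_adv, tcc=0.0):
    """Weighted stage loss and its additive breakdown.

    Works on floats and on autodiff tensors alike.  Stage 1 uses the initial
    KL weight, stage 2 the annealed weight, stage 3 the final weight plus the
    TCC term.  Breakdown values sum to the total.
    """
    if stage not in (1, 2, 3):
        raise ValueError(f"unknown training stage {stage!r}")
    if stage == 1:
        kl_w = schedule.kl_weight_initial
    elif stage == 2:
        kl_w = kl_annealing_weight(epoch, schedule)
    else:
        kl_w = schedule.kl_weight_final
    terms = {"recon": recon, "kl": kl_w * kl,
             "gen_adv": schedule.adv_weight * gen_adv}
    if stage == 3:
        terms["tcc"] = schedule.tcc_weight * tcc
    total = None
    for v in terms.values():
        total = v if total is None else total + v
    return total, terms, kl_w


def _pool_frames(trajs: list[CellTrajectory]) -> np.ndarray:
    return np.concatenate([t.images for t in trajs], axis=0)


def _split(trajs, val_fraction, rng):
    idx = rng.permutation(len(trajs))
    n_val = int(round(val_fraction * len(trajs)))
    if len(trajs) - n_val < 2:       # TCC needs at least a pair to train on
        n_val = max(0, len(trajs) - 2)
    val = [trajs[i] for i in idx[:n_val]]
    tr = [trajs[i] for i in idx[n_val:]]
    return tr, val


class _Trainer:
    def __init__(self, model: ManifoldModel, schedule: TrainingSchedule):
        self.model = model
        self.schedule = schedule
        self.rng = np.random.default_rng(schedule.seed)
        nets = (model.encoder, model.generator, model.discriminator)
        self.nets = nets
        self.opt_vae = Adam(model.encoder.parameters()
                            + model.generator.parameters(), lr=schedule.lr)
        self.opt_gen = Adam(model.generator.parameters(), lr=schedule.lr)
        self.opt_disc = Adam(model.discriminator.parameters(),
                             lr=schedule.lr * schedule.disc_lr_factor)
        self.log: list[dict] = []

    # ------------------------------------------------------------- helpers
    def _zero(self):
        for net in self.nets:
            net.zero_grad()

    def _vae_terms(self, x: Tensor, sample: bool, train_mode: bool):
        model, sch = self.model, self.schedule
        for net in self.nets:
            net.train(train_mode)
        mu, logvar = model.encoder(x)
        if sample:
            eps = self.rng.standard_normal(mu.shape).astype(model.dtype)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        else:
            z = mu
        x_rec = model.generator(z)
        logit_real, feat_real = model.discriminator(x)
        logit_fake, feat_fake = model.discriminator(x_rec)
        recon = ((x - x_rec) ** 2).mean() \
            + sch.lambda_feat * ((feat_real - feat_fake) ** 2).mean()
        # per-dimension-normalised KL so annealing weights are scale-free
        kl = (0.5 * (mu**2 + logvar.exp() - logvar - 1.0)
              ).sum(axis=1).mean() / model.latent_dim
        gen_adv = (-logit_fake).softplus().mean()   # -log D(fake)
        return mu, x_rec, logit_real, logit_fake, recon, kl, gen_adv

    def _tcc_term(self, trajs: list[CellTrajectory]) -> Tensor:
        sch, model = self.schedule, self.model
        i, j = self.rng.choice(len(trajs), size=2, replace=False)
        seqs = []
        for traj in (trajs[i], trajs[j]):
            t = len(traj)
            w = min(sch.tcc_window, t)
            start = self.rng.integers(0, t - w + 1)
            x = Tensor(traj.images[start:start + w, None].astype(model.dtype))
            mu, _ = model.encoder(x)
            seqs.append(mu)
        return tcc_loss_graph(seqs[0], seqs[1], sch.tcc_temperature)

    def _validation_loss(self, stage, epoch, val_frames) -> dict:
        sch = self.schedule
        out = {}
        bs = sch.batch_size
        totals = []
        for k in range(0, len(val_frames), bs):
            x = Tensor(val_frames[k:k + bs, None].astype(self.model.dtype))
            *_, recon, kl, gen_adv = self._vae_terms(x, sample=False,
                                                     train_mode=False)
            tot, _, _ = total_loss(stage, sch, epoch, recon.item(), kl.item(),
                                   gen_adv.item())
            totals.append((tot, x.shape[0]))
        tot = sum(t * n for t, n in totals) / sum(n for _, n in totals)
        out["val_total"] = tot
        return out

    def _snapshot(self):
        return {name + "." + k: v.copy()
                for name, net in zip(("encoder", "generator", "discriminator"),
                                     self.nets)
                for k, v in net.named_state().items()}

    def _restore(self, snap):
        for name, net in zip(("encoder", "generator", "discriminator"),
                             self.nets):
            net.load_state(snap, name + ".")

    # -------------------------------------------------------------- stages
    def run_stage(self, stage: int, trajs: list[CellTrajectory],
                  val: list[CellTrajectory]) -> None:
        sch, model = self.schedule, self.model
        frames = _pool_frames(trajs)
        val_frames = _pool_frames(val) if val else frames
        n_epochs = sch.stage_epochs[stage - 1]
        best = (np.inf, None)
        misses = 0
        for epoch in range(n_epochs):
            order = self.rng.permutation(len(frames))
            sums: dict[str, float] = {}
            n_batches = 0
            for k in range(0, len(frames), sch.batch_size):
                x_np = frames[order[k:k + sch.batch_size], None]
                x = Tensor(x_np.astype(model.dtype))
                self._zero()
                (mu, x_rec, logit_real, logit_fake, recon, kl,
                 gen_adv) = self._vae_terms(x, sample=True, train_mode=True)
                tcc = self._tcc_term(trajs) if stage == 3 else 0.0
                tot, terms, kl_w = total_loss(stage, sch, epoch, recon, kl,
                                              gen_adv, tcc)
                if not np.isfinite(tot.data):
                    raise RuntimeError(
                        f"non-finite loss at stage {stage}, epoch {epoch}: "
                        + str({k: float(np.asarray(v.data if isinstance(v, Tensor) else v))
                               for k, v in terms.items()}))
                # VAE path: reconstruction + KL (+ TCC) update encoder+generator
                vae_loss = tot - terms["gen_adv"]
                vae_loss.backward()
                self.opt_vae.step()
                # adversarial generator update
                self._zero()
                terms["gen_adv"].backward()
                self.opt_gen.step()
                # discriminator update on real vs (detached) reconstructions
                self._zero()
                logit_fake_d, _ = model.discriminator(x_rec.detach())
                disc_loss = ((-logit_real).softplus().mean()
                             + logit_fake_d.softplus().mean())
                disc_loss.backward()
                self.opt_disc.step()
                rec = {"recon": recon.item(), "kl": kl.item(),
                       "kl_weight": kl_w, "gen_adv": gen_adv.item(),
                       "disc": disc_loss.item(), "total": tot.item()}
                if stage == 3:
                    rec["tcc"] = float(tcc.data)
                for key, v in rec.items():
                    sums[key] = sums.get(key, 0.0) + v
                n_batches += 1
            entry = {"stage": stage, "epoch": epoch}
            entry.update({k: v / n_batches for k, v in sums.items()})
            entry["kl_weight"] = kl_w
            if (epoch + 1) % sch.checkpoint_every == 0 or epoch == n_epochs - 1:
                entry.update(self._validation_loss(stage, epoch, val_frames))
                if entry["val_total"] < best[0]:
                    best = (entry["val_total"], self._snapshot())
                    misses = 0
                else:
                    misses += 1
            self.log.append(entry)
            if misses > sch.early_stop_patience:
                break
        if best[1] is not None:
            self._restore(best[1])
        model.stage_reached = stage


def train(trajectories: list[CellTrajectory], schedule: TrainingSchedule,
          model: ManifoldModel | None = None
          ) -> tuple[ManifoldModel, list[dict]]:
    """Run the three-stage schedule on a list of trajectories.

    Returns the trained model (best checkpoint of the last stage) and the
    per-epoch training log.  Fully reproducible for a fixed
    ``schedule.seed`` on fixed hardware.
    """
    if len(trajectories) < 2:
        raise ValueError("training requires at least two trajectories")
    patch = trajectories[0].patch_size
    if model is None:
        model = ManifoldModel(patch_size=patch, seed=schedule.seed)
    if model.patch_size != patch:
        raise ValueError("trajectory patch size does not match the model")
    trainer = _Trainer(model, schedule)
    tr, val = _split(trajectories, schedule.val_fraction, trainer.rng)
    for stage in (1, 2, 3):
        trainer.run_stage(stage, tr, val)
    return model, trainer.log


class CycleManifoldVAEGAN(BaseEstimator, TransformerMixin):
    """Scikit-learn style front end for the manifold model.

    ``fit`` expects a list of :class:`CellTrajectory`; ``transform`` returns
    the stacked per-frame posterior means (the deterministic embedding used
    by all downstream analysis).

    Parameters mirror the network and schedule defaults; pass a custom
    :class:`TrainingSchedule` for full control.
    """

    def __init__(self, patch_size: int = 64, latent_dim: int = 16,
                 enc_channels: tuple = (32, 64, 128),
                 disc_channels: tuple = (32, 64, 128, 256),
                 dense: int = 256,
                 schedule: TrainingSchedule | None = None,
                 seed: int = 0):
        self.patch_size = patch_size
        self.latent_dim = latent_dim
        self.enc_channels = enc_channels
        self.disc_channels = disc_channels
        self.dense = dense
        self.schedule = schedule
        self.seed = seed

    def fit(self, X: list[CellTrajectory], y=None) -> "CycleManifoldVAEGAN":
        schedule = self.schedule or TrainingSchedule(seed=self.seed)
        model = ManifoldModel(
            patch_size=self.patch_size, latent_dim=self.latent_dim,
            enc_channels=tuple(self.enc_channels),
            disc_channels=tuple(self.disc_channels), dense=self.dense,
            seed=self.seed)
        self.model_, self.log_ = train(X, schedule, model)
        return self

    def embed(self, traj: CellTrajectory) -> LatentSequence:
        """Per-frame posterior means of one trajectory."""
        from .manifold import embed_trajectory
        return embed_trajectory(self.model_, traj)

    def transform(self, X: list[CellTrajectory]) -> np.ndarray:
        return np.concatenate([self.embed(t).latents for t in X], axis=0)
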