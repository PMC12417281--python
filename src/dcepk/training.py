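"""Loss and training loop for the two-stage network.

The objective is ELBO-style: a reconstruction term between the decoded PK
maps and the target maps (both normalised per parameter) plus
``beta * KL(posterior || prior)`` over the latent space, with a linear beta
warm-up.  In ``tcn_only`` mode (the ablation of the spatial stage) only the
reconstruction term over the 1x1-head output is used.

Training targets default to conventional-pathway fits (the route a clinical
dataset would provide); the simulator's true maps can be used instead for
oracle experiments.
"""
from __future__ import annotations

import gc
from dataclasses import dataclass, field

import numpy as np

from dcepk.autodiff import DTYPE, Tensor
from dcepk.nets import ModelConfig, TwoStageNet, kl_divergence
from dcepk.nn import Adam
from dcepk.physics import PKMaps

__all__ = ["TrainConfig", "loss", "train"]


@dataclass(frozen=True)
class TrainConfig:
    mode: str = "full"  # "full" | "tcn_only"
    epochs: int = 30
    batch_size: int = 5
    lr: float = 3e-3
    beta: float = 1.0
    kl_warmup_epochs: int = 5
    recon: str = "mse"  # "mse" | "l1"
    seed: int = 0
    patience: int = 0  # 0 disables early stopping
    target_clip: float = 5.0  # cap on normalised targets (vessel vp would
    # otherwise dominate the objective); <= 0 disables
    clip_norm: float = 10.0  # global gradient-norm clip; <= 0 disables
    lr_decay_at: float = 0.7  # fraction of epochs after which lr drops 10x
    freeze_stage1: bool = False  # full mode: keep the (warm-started) TCN and
    # regression head fixed and train only the spatial/probabilistic stage
    augment: bool = True  # full mode: random flips/rotations of each slice
    # (the spatial-denoising task is symmetry-invariant; the per-voxel
    # temporal stage is unaffected by orientation)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.mode not in ("full", "tcn_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.recon not in ("mse", "l1"):
            raise ValueError(f"unknown reconstruction loss {self.recon!r}")


def _recon_term(pred: Tensor, gt: Tensor, kind: str) -> Tensor:
    """Per-slice sum over channels and pixels, averaged over the batch."""
    d = pred - gt
    if kind == "mse":
        e = d * d
    else:
        e = d.relu() + (-d).relu()  # |d|
    B = pred.shape[0]
    return e.sum() * (1.0 / B)


def loss(pred, gt, prior=None, posterior=None, beta: float = 1.0, recon: str = "mse"):
    """Total training loss and its components.

    ``pred``/``gt`` are (B, 3, H, W) normalised maps (Tensors or arrays).
    With ``prior``/``posterior`` given, adds ``beta * KL(posterior || prior)``.
    Returns ``(total Tensor, components dict of floats)``.
    """
    pred = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=DTYPE))
    gt = gt if isinstance(gt, Tensor) else Tensor(np.asarray(gt, dtype=DTYPE))
    if pred.shape != gt.shape:
        raise ValueError("pred and gt shapes differ")
    total = _recon_term(pred, gt, recon)
    comps = {"recon": float(total.data)}
    if prior is not None and posterior is not None:
        kl = kl_divergence(posterior, prior)
        comps["kl"] = float(kl.data)
        total = total + kl * beta
    comps["total"] = float(total.data)
    return total, comps


def _norm_targets(maps, scales, clip: float = 0.0) -> np.ndarray:
    """PKMaps (or (3,H,W) stack) -> normalised (3, H, W) float32."""
    arr = maps.stack() if isinstance(maps, PKMaps) else np.asarray(maps)
    if arr.ndim == 4:  # (3, H, W, 1) single-slice volume
        arr = arr[..., 0]
    out = arr / np.asarray(scales)[:, None, None]
    if clip > 0:
        out = np.clip(out, 0.0, clip)
    return out.astype(DTYPE)


def train(
    train_data: list,
    config: TrainConfig,
    valid_data: list | None = None,
    model: TwoStageNet | None = None,
    log=None,
):
    """Train on (x_norm, target) pairs; deterministic for a given config.

    ``train_data``/``valid_data`` are lists of ``(x, maps)`` where ``x`` is a
    normalised (H, W, T) slice and ``maps`` the target :class:`PKMaps` (or a
    (3, H, W) stack in parameter units).  Returns ``(model, history)`` with
    per-epoch loss records; the best-validation weights are restored at the
    end when validation data is given.
    """
    if not train_data:
        raise ValueError("empty training split")
    cfg = config
    model = model or TwoStageNet(cfg.model)
    rng = np.random.default_rng(cfg.seed)
    trainable = model.parameters()
    if cfg.freeze_stage1 and cfg.mode == "full":
        frozen = {id(p) for name, p in model.named_parameters()
                  if name.startswith(("tcn.", "ablation_head."))}
        trainable = [p for p in trainable if id(p) not in frozen]
    opt = Adam(trainable, lr=cfg.lr, clip_norm=cfg.clip_norm)
    scales = cfg.model.scales
    xs = [np.asarray(x, dtype=DTYPE) for x, _ in train_data]
    ys = [_norm_targets(m, scales, cfg.target_clip) for _, m in train_data]
    vxs = [np.asarray(x, dtype=DTYPE) for x, _ in (valid_data or [])]
    vys = [_norm_targets(m, scales, cfg.target_clip) for _, m in (valid_data or [])]

    history = []
    best = (np.inf, None)
    bad_epochs = 0
    n = len(xs)
    frozen = cfg.freeze_stage1 and cfg.mode == "full"
    feat_cache = vfeat_cache = None
    if frozen:
        # stage 1 is fixed: temporal features are constant per subject, and
        # spatial augmentation commutes with the per-voxel TCN, so features
        # are computed once and augmented directly
        feat_cache = [model.temporal_features(x[None]).data[0] for x in xs]
        vfeat_cache = [model.temporal_features(x[None]).data for x in vxs]
    for epoch in range(1, cfg.epochs + 1):
        warm = min(1.0, epoch / max(cfg.kl_warmup_epochs, 1))
        beta_t = cfg.beta * warm
        opt.lr = cfg.lr * (0.1 if epoch > cfg.lr_decay_at * cfg.epochs else 1.0)
        order = rng.permutation(n)
        ep = {"recon": 0.0, "kl": 0.0, "total": 0.0}
        nb = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            bx, by = [], []
            for i in sel:
                x = feat_cache[i] if frozen else xs[i]
                y = ys[i]
                if cfg.augment and cfg.mode == "full":
                    k = int(rng.integers(4))
                    flip = bool(rng.integers(2))
                    sp = (1, 2) if frozen else (0, 1)
                    x = np.rot90(x, k, axes=sp)
                    y = np.rot90(y, k, axes=(1, 2))
                    if flip:
                        x = x[:, ::-1] if frozen else x[::-1]
                        y = y[:, ::-1]
                bx.append(np.ascontiguousarray(x))
                by.append(np.ascontiguousarray(y))
            xb = np.stack(bx)
            yb = Tensor(np.stack(by))
            model.zero_grad()
            feats = Tensor(xb) if frozen else model.temporal_features(xb)
            if cfg.mode == "full":
                prior = model.prior_encode(feats)
                post = model.posterior_encode(feats, yb)
                z = post.sample(rng)
                pred = model.decode(feats, z)
                total, comps = loss(pred, yb, prior, post, beta_t, cfg.recon)
            else:
                pred = model.ablation_maps(feats)
                total, comps = loss(pred, yb, recon=cfg.recon)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (components {comps})"
                )
            total.backward()
            opt.step()
            for k in ep:
                ep[k] += comps.get(k, 0.0)
            nb += 1
        gc.collect()  # forward-only graphs (validation/predict) are cyclic
        rec = {"epoch": epoch, **{f"train_{k}": v / nb for k, v in ep.items()}}
        if vxs:
            rec["valid_loss"] = _validate(model, vxs, vys, cfg, vfeats=vfeat_cache)
            if rec["valid_loss"] < best[0] - 1e-9:
                best = (rec["valid_loss"], model.state_dict())
                bad_epochs = 0
            else:
                bad_epochs += 1
        history.append(rec)
        if log is not None:
            log(rec)
        if cfg.patience and bad_epochs >= cfg.patience:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def _validate(model: TwoStageNet, vxs, vys, cfg: TrainConfig, vfeats=None) -> float:
    """Deterministic validation reconstruction (latent at the prior mean).

    ``vfeats`` optionally supplies precomputed stage-1 features (frozen
    stage 1 keeps them constant across epochs).
    """
    tot = 0.0
    for i, (x, y) in enumerate(zip(vxs, vys)):
        if vfeats is not None:
            feats = Tensor(vfeats[i])
        else:
            feats = model.temporal_features(x[None])
        if cfg.mode == "full":
            prior = model.prior_encode(feats)
            pred = model.decode(feats, prior.mu)
        else:
            pred = model.ablation_maps(feats)
        t, _ = loss(pred, y[None], recon=cfg.recon)
        tot += float(t.data)
    return tot / len(vxs)
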