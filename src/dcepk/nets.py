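"""The two-stage spatiotemporal architecture.

Stage 1 is a temporal convolutional network (TCN): stacked dilated 1-D
convolutions with residual connections, applied independently to every
voxel's signal-time curve, condensing the 60-frame series into three
temporal feature maps (one per PK parameter).  Stage 2 is a probabilistic
U-Net: a small encoder-decoder over the feature maps with a diagonal-Gaussian
latent space (prior net at inference, posterior net during training), whose
samples yield multiple plausible PK map triplets and hence voxelwise
uncertainty maps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from hashlib import sha256

import numpy as np

from dcepk.autodiff import DTYPE, Tensor, avg_pool2d, concat, conv2d, upsample2d
from dcepk.nn import Adam, Conv1d, Conv2d, Linear, Module
from dcepk.physics import PKMaps

__all__ = [
    "ModelConfig",
    "LatentDistribution",
    "PredictionSet",
    "TwoStageNet",
    "receptive_field",
    "kl_divergence",
]


def receptive_field(kernel: int, dilations: tuple) -> int:
    """Frames seen by a stack of one dilated conv per level: (k-1)*sum(d)+1."""
    return (kernel - 1) * int(sum(dilations)) + 1


@dataclass(frozen=True)
class ModelConfig:
    """All architecture sizes; defaults are desk-scale (one CPU).

    ``scales`` are per-parameter normalisation constants (ktrans, ve, vp) in
    parameter units: outputs and targets are divided by them so the loss
    weighs the three maps comparably.
    """

    n_frames: int = 60
    tcn_channels: int = 8
    tcn_kernel: int = 3
    tcn_dilations: tuple = (1, 2, 4, 8, 16)
    unet_channels: int = 8
    latent_dim: int = 6
    sigma_floor: float = 1e-6
    n_samples: int = 4
    scales: tuple = (0.1, 0.3, 0.05)
    seed: int = 0

    def __post_init__(self):
        rf = receptive_field(self.tcn_kernel, self.tcn_dilations)
        if rf < self.n_frames:
            raise ValueError(
                f"TCN receptive field {rf} does not cover {self.n_frames} frames"
            )

    def hash(self) -> str:
        return sha256(json.dumps(asdict(self), sort_keys=True, default=list).encode()).hexdigest()[:12]


@dataclass
class LatentDistribution:
    """Diagonal Gaussian over the latent space; sigma strictly positive."""

    mu: Tensor
    sigma: Tensor

    def sample(self, rng: np.random.Generator) -> Tensor:
        eps = Tensor(rng.standard_normal(self.mu.shape).astype(DTYPE))
        return self.mu + self.sigma * eps


@dataclass
class PredictionSet:
    """N decoded samples plus voxelwise mean and standard-deviation maps."""

    samples: np.ndarray  # (n_samples, 3, H, W)
    mean_maps: PKMaps
    uncertainty_maps: PKMaps
    n_samples: int
    seeds: tuple

    @classmethod
    def from_samples(cls, samples: np.ndarray, seeds: tuple) -> "PredictionSet":
        samples = np.asarray(samples, dtype=np.float64)
        n = samples.shape[0]
        if n < 2:
            raise ValueError("uncertainty needs n_samples >= 2")
        mean = samples.mean(axis=0)
        sd = samples.std(axis=0, ddof=0)
        to_maps = lambda a: PKMaps(ktrans=a[0][..., None], ve=a[1][..., None], vp=a[2][..., None])
        return cls(samples=samples, mean_maps=to_maps(mean),
                   uncertainty_maps=to_maps(sd), n_samples=n, seeds=tuple(seeds))


def kl_divergence(q: LatentDistribution, p: LatentDistribution) -> Tensor:
    """KL(q || p) for diagonal Gaussians:

    sum_i [ log(sp/sq) + (sq^2 + (mq - mp)^2) / (2 sp^2) - 1/2 ].
    Batched inputs (..., L) are summed over the latent axis and averaged over
    leading axes.
    """
    lq = (p.sigma / q.sigma).log()
    num = q.sigma * q.sigma + (q.mu - p.mu) * (q.mu - p.mu)
    per = lq + num / (p.sigma * p.sigma * 2.0) - 0.5
    if per.ndim == 1:
        return per.sum()
    return per.sum(axis=-1).mean()


class _TCNBlock(Module):
    def __init__(self, cin, cout, kernel, dilation, rng):
        self.conv = Conv1d(cin, cout, kernel, dilation, rng)
        self.skip = Conv1d(cin, cout, 1, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(x).relu()
        s = self.skip(x) if self.skip is not None else x
        return y + s


class _TCN(Module):
    def __init__(self, cfg: ModelConfig, rng):
        c = cfg.tcn_channels
        self.blocks = [
            _TCNBlock(1 if i == 0 else c, c, cfg.tcn_kernel, d, rng)
            for i, d in enumerate(cfg.tcn_dilations)
        ]
        self.head = Conv1d(c, 3, 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(1, N, T) channel-first -> (3, N): time axis averaged out."""
        h = x
        for blk in self.blocks:
            h = blk(h)
        return self.head(h).mean(axis=2)


class TwoStageNet(Module):
    """TCN + probabilistic U-Net, with a 1x1 ablation head (stage 1 only)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.unet_channels
        L = cfg.latent_dim
        self.tcn = _TCN(cfg, rng)
        # ablation head: per-voxel linear regression on the 3 feature maps
        self.ablation_head = Conv2d(3, 3, 1, rng)
        # prior / posterior encoders
        self.prior_c1 = Conv2d(3, c, 3, rng)
        self.prior_c2 = Conv2d(c, c, 3, rng)
        self.prior_fc = Linear(c, 2 * L, rng)
        self.post_c1 = Conv2d(6, c, 3, rng)
        self.post_c2 = Conv2d(c, c, 3, rng)
        self.post_fc = Linear(c, 2 * L, rng)
        # U-Net decoder over the feature maps
        self.enc1 = Conv2d(3, c, 3, rng)
        self.enc2 = Conv2d(c, 2 * c, 3, rng)
        self.bott = Conv2d(2 * c, 2 * c, 3, rng)
        self.dec2 = Conv2d(4 * c, c, 3, rng)
        self.dec1 = Conv2d(2 * c, c, 3, rng)
        self.final = Conv2d(c + 3 + L, 3, 1, rng)
        # voxelwise nonlinear refinement: the stage-1 head is linear in the
        # three temporal features, so a per-voxel MLP (1x1 convs, latent
        # appended) can correct its systematic residual with no spatial mixing
        self.refine1 = Conv2d(3 + L, 32, 1, rng)
        self.refine1.w.data[:, 3:] = 0.0  # latent columns start closed: the
        # voxelwise branch admits z only as far as training finds it useful
        self.refine2 = Conv2d(32, 32, 1, rng)
        self.refine3 = Conv2d(32, 3, 1, rng)
        # per-parameter zero-initialised gates, one per correction branch:
        # the decoder starts as the stage-1 head exactly, and each output
        # channel admits the voxelwise and spatial corrections independently,
        # only as far as each reduces that channel's own reconstruction error
        # (the loss is channel-separable)
        self.gate_vox = Tensor(np.zeros((1, 3, 1, 1), dtype=DTYPE), requires_grad=True)
        self.gate_sp = Tensor(np.zeros((1, 3, 1, 1), dtype=DTYPE), requires_grad=True)

    # -- stage 1 -----------------------------------------------------------
    def temporal_features(self, x: np.ndarray | Tensor) -> Tensor:
        """(B, H, W, T) normalised signal -> (B, 3, H, W) feature maps.

        Purely voxelwise: each output voxel depends only on its own curve.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=DTYPE))
        B, H, W, T = x.shape
        if T != self.cfg.n_frames:
            raise ValueError(f"expected {self.cfg.n_frames} frames, got {T}")
        flat = x.reshape(1, B * H * W, T)
        feats = self.tcn(flat)  # (3, BHW)
        return feats.transpose(1, 0).reshape(B, H, W, 3).transpose(0, 3, 1, 2)

    def ablation_maps(self, features: Tensor) -> Tensor:
        """Stage-1-only PK maps: 1x1 head, no spatial mixing; (B, 3, H, W)."""
        return self.ablation_head(features).softplus()

    # -- latent encoders ---------------------------------------------------
    def load_temporal_stage(self, other: "TwoStageNet") -> None:
        """Warm-start the TCN and regression head from a trained stage-1
        model (serial two-stage training)."""
        state = other.state_dict()
        own = dict(self.named_parameters())
        for k, v in state.items():
            if k.startswith(("tcn.", "ablation_head.")):
                own[k].data = v.copy()

    def prior_encode(self, features: Tensor) -> LatentDistribution:
        return self._encode_heads(features, self.prior_c1, self.prior_c2, self.prior_fc)

    def posterior_encode(self, features: Tensor, gt_norm: Tensor) -> LatentDistribution:
        x = concat([features, gt_norm], axis=1)
        return self._encode_heads(x, self.post_c1, self.post_c2, self.post_fc)

    def _encode_heads(self, x, c1, c2, fc) -> LatentDistribution:
        h = c1(x).relu()
        h = avg_pool2d(h)
        h = c2(h).relu()
        h = h.mean(axis=(2, 3))
        out = fc(h)  # (B, 2L)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite activations in latent encoder")
        L = self.cfg.latent_dim
        B = out.shape[0]
        cube = out.reshape(B, 2, L)
        mu = _slice_axis1(cube, 0)
        sigma = _slice_axis1(cube, 1).softplus() + self.cfg.sigma_floor
        return LatentDistribution(mu=mu, sigma=sigma)

    # -- decoder -----------------------------------------------------------
    def decode(self, features: Tensor, z: Tensor) -> Tensor:
        """U-Net over features with z broadcast into the final 1x1 block.

        The decoder is residual on the stage-1 regression head: the U-Net
        (and the latent) contribute a spatial correction to the per-voxel
        logits, so the serial two-stage model can only refine — never
        discard — the temporal stage.  Returns normalised PK maps
        (B, 3, H, W), non-negative via softplus.
        """
        B, _, H, W = features.shape
        if z.shape != (B, self.cfg.latent_dim):
            raise ValueError("latent sample has wrong shape")
        e1 = self.enc1(features).relu()          # (B, c, H, W)
        e2 = self.enc2(avg_pool2d(e1)).relu()    # (B, 2c, H/2, W/2)
        bt = self.bott(avg_pool2d(e2)).relu()    # (B, 2c, H/4, W/4)
        d2 = self.dec2(concat([upsample2d(bt), e2], axis=1)).relu()
        d1 = self.dec1(concat([upsample2d(d2), e1], axis=1)).relu()
        zb = _broadcast_latent(z, H, W)
        h = concat([d1, features, zb], axis=1)
        vox = self.refine3(self.refine2(self.refine1(concat([features, zb], axis=1)).relu()).relu())
        logits = (self.ablation_head(features)
                  + vox * self.gate_vox
                  + self.final(h) * self.gate_sp)
        return logits.softplus()

    # -- inference ---------------------------------------------------------
    def predict(
        self,
        x_norm: np.ndarray,
        n_samples: int | None = None,
        seed: int = 0,
        mode: str = "full",
    ) -> PredictionSet:
        """Sample ``n_samples`` PK map triplets for one normalised slice.

        ``x_norm`` is (H, W, T); outputs are in parameter units (scales
        re-applied).  ``mode='tcn_only'`` repeats the deterministic ablation
        output (its uncertainty is identically zero).
        """
        n = self.cfg.n_samples if n_samples is None else int(n_samples)
        if n < 1:
            raise ValueError("n_samples must be >= 1")
        feats = self.temporal_features(x_norm[None])
        scales = np.asarray(self.cfg.scales, dtype=np.float64)[:, None, None]
        seeds = tuple(seed + i for i in range(max(n, 2)))
        samples = []
        if mode == "tcn_only":
            out = self.ablation_maps(feats).numpy()[0] * scales
            samples = [out] * max(n, 2)
        else:
            prior = self.prior_encode(feats)
            for s in seeds:
                rng = np.random.default_rng(s)
                z = prior.sample(rng)
                out = self.decode(feats, z).numpy()[0] * scales
                samples.append(out)
        return PredictionSet.from_samples(np.stack(samples), seeds)


def _slice_axis1(t: Tensor, idx: int) -> Tensor:
    """Select index ``idx`` along axis 1 of a (B, 2, L) tensor."""
    out = Tensor(t.data[:, idx, :], t.requires_grad, (t,))

    def bwd():
        if t.requires_grad:
            g = np.zeros_like(t.data)
            g[:, idx, :] = out.grad
            t._accum(g)
    out._backward = bwd
    return out


def _broadcast_latent(z: Tensor, H: int, W: int) -> Tensor:
    """(B, L) -> (B, L, H, W) spatial broadcast (autograd-aware)."""
    B, L = z.shape
    out = Tensor(np.broadcast_to(z.data[:, :, None, None], (B, L, H, W)).copy(),
                 z.requires_grad, (z,))

    def bwd():
        if z.requires_grad:
            z._accum(out.grad.sum(axis=(2, 3)))
    out._backward = bwd
    return out


def normalize_series(data: np.ndarray, n_baseline: int, center: bool = True) -> np.ndarray:
    """Per-subject normalisation: divide by the mean baseline signal.

    With ``center`` (default), 1 is subtracted afterwards so pre-contrast
    frames sit near zero — this removes the large constant offset that
    otherwise slows optimisation without changing the information content.
    """
    base = float(np.mean(data[..., :n_baseline]))
    if base <= 0:
        raise ValueError("mean baseline signal must be positive")
    out = data / base
    if center:
        out = out - 1.0
    return out.astype(np.float32)


def save_checkpoint(model: TwoStageNet, path) -> None:
    """Weights + config (with config hash) in a single npz."""
    state = model.state_dict()
    cfg = asdict(model.cfg)
    cfg["tcn_dilations"] = list(cfg["tcn_dilations"])
    cfg["scales"] = list(cfg["scales"])
    meta = json.dumps({"config": cfg, "config_hash": model.cfg.hash()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> TwoStageNet:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg_d = meta["config"]
    cfg_d["tcn_dilations"] = tuple(cfg_d["tcn_dilations"])
    cfg_d["scales"] = tuple(cfg_d["scales"])
    cfg = ModelConfig(**cfg_d)
    if cfg.hash() != meta["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    model = TwoStageNet(cfg)
    model.load_state_dict(state)
    return model
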