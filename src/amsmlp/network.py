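"""Full segmentation network: encoder, AM-MLP skips, MPAM, MCRD decoder.

The backbone is a five-level U-shaped encoder-decoder. Each encoder level is
two 3x3 conv + batch-norm + ReLU bricks; 2x max-pooling sits between levels,
so widths double while extents halve. The four skip connections optionally
pass through AM-MLP blocks, the five-level pyramid optionally feeds the MPAM
mask module, and the three deepest decoder junctions optionally apply MCRD
refinement to the skip feature before fusion — the deepest junction consumes
the MPAM mask (upsampled 2x to the skip's extent) when MPAM is enabled.
Decoder upsampling is a learned kernel-2/stride-2 transposed convolution; a
1x1 convolution plus sigmoid produces the foreground probability map.

Toggling {use_am_mlp, use_mpam, use_mcrd} yields the ablation lattice:
all off = plain U-shaped baseline ("bunet"); AM-MLP only ("bam_mlp");
AM-MLP + MPAM ("bmam_mlp"); AM-MLP + MCRD ("bmrd_mlp"); all on ("ams_mlp").
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .am_mlp import AMMLP, AMMLPConfig
from .autodiff import Tensor
from .decoders import MCRD, MCRDMaskHead, MPAM
from .losses_metrics import (
    LossConfig,
    combined_loss,
    confusion_counts,
    evaluate_dataset,
)
from .nn import (
    ConvBNReLU,
    ConvTranspose2x,
    Conv2d,
    Module,
    ModuleList,
    SGD,
    poly_lr,
)

NUM_LEVELS = 5

VARIANTS = {
    "bunet": dict(use_am_mlp=False, use_mpam=False, use_mcrd=False),
    "bam_mlp": dict(use_am_mlp=True, use_mpam=False, use_mcrd=False),
    "bmam_mlp": dict(use_am_mlp=True, use_mpam=True, use_mcrd=False),
    "bmrd_mlp": dict(use_am_mlp=True, use_mpam=False, use_mcrd=True),
    "ams_mlp": dict(use_am_mlp=True, use_mpam=True, use_mcrd=True),
}


@dataclass
class ModelConfig:
    base_width: int = 32
    input_size: tuple = (512, 512)
    in_channels: int = 3
    use_am_mlp: bool = True
    use_mpam: bool = True
    use_mcrd: bool = True
    hidden_expansion: float = 1.0
    use_stage_residual: bool = True
    attention_applies_to: str = "mlp"
    mcrd_literal_mask_order: bool = False
    seed: int = 0

    def __post_init__(self):
        self.input_size = tuple(self.input_size)
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 16 (four 2x poolings)"
            )
        if h != w:
            raise ValueError(
                f"square inputs required for the AM-MLP grids, got {h}x{w}"
            )

    @classmethod
    def variant(cls, name, **kwargs):
        if name not in VARIANTS:
            raise ValueError(f"unknown variant {name!r}; one of {sorted(VARIANTS)}")
        return cls(**{**VARIANTS[name], **kwargs})


@dataclass
class TrainConfig:
    batch_size: int = 2
    epochs: int = 60
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 0.0
    schedule: str = "poly"  # "poly" | "constant" | "step"
    poly_power: float = 0.9
    step_every: int = 20
    step_gamma: float = 0.5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)


class _DoubleConv(Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.c1 = ConvBNReLU(in_ch, out_ch, rng)
        self.c2 = ConvBNReLU(out_ch, out_ch, rng)

    def __call__(self, x):
        return self.c2(self.c1(x))


class SegModel(Module):
    """The assembled network; construction is deterministic in cfg.seed."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [cfg.base_width * 2**i for i in range(NUM_LEVELS)]
        self.widths = widths

        self.encoder = ModuleList()
        in_ch = cfg.in_channels
        for w in widths:
            self.encoder.append(_DoubleConv(in_ch, w, rng))
            in_ch = w

        if cfg.use_am_mlp:
            side = cfg.input_size[0]
            self.skips = ModuleList(
                AMMLP(
                    AMMLPConfig(
                        channels=widths[i],
                        spatial_size=side // 2**i,
                        hidden_expansion=cfg.hidden_expansion,
                        use_stage_residual=cfg.use_stage_residual,
                        attention_applies_to=cfg.attention_applies_to,
                    ),
                    rng,
                )
                for i in range(NUM_LEVELS - 1)
            )

        if cfg.use_mpam:
            self.mpam = MPAM(cfg.base_width, NUM_LEVELS, rng)

        # decoder: junctions j = 4, 3, 2, 1 (deep -> shallow)
        self.deconvs = ModuleList(
            ConvTranspose2x(widths[j], widths[j - 1], rng)
            for j in range(NUM_LEVELS - 1, 0, -1)
        )
        self.dec_blocks = ModuleList(
            _DoubleConv(2 * widths[j - 1], widths[j - 1], rng)
            for j in range(NUM_LEVELS - 1, 0, -1)
        )
        if cfg.use_mcrd:
            self.mcrd_junctions = (4, 3, 2)
            self.mcrds = ModuleList(
                MCRD(widths[j - 1], widths[j - 1], rng)
                for j in self.mcrd_junctions
            )
            self.mask_heads = ModuleList()
            for j in self.mcrd_junctions:
                if j == 4 and cfg.use_mpam:
                    continue  # deepest junction consumes the MPAM mask
                self.mask_heads.append(
                    MCRDMaskHead(widths[j], rng, cfg.mcrd_literal_mask_order)
                )
        self.head = Conv2d(widths[0], 1, 1, rng)

    # -- passes -----------------------------------------------------------
    def _check_input(self, x):
        b, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels}-channel input, got {c}")
        if (h, w) != self.cfg.input_size:
            raise ValueError(
                f"input extent {h}x{w} does not match configured "
                f"{self.cfg.input_size}"
            )

    def encoder_forward(self, x):
        """Five-level feature pyramid: widths C1*2^(i-1), extents H/2^(i-1)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_input(x)
        pyramid = []
        h = x
        for i, block in enumerate(self.encoder):
            h = block(h)
            pyramid.append(h)
            if i < NUM_LEVELS - 1:
                h = ad.maxpool2x(h)
        return pyramid

    def __call__(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        pyramid = self.encoder_forward(x)

        skips = list(pyramid[: NUM_LEVELS - 1])
        if self.cfg.use_am_mlp:
            skips = [blk(s) for blk, s in zip(self.skips, skips)]

        mpam_mask = self.mpam(pyramid) if self.cfg.use_mpam else None

        h = pyramid[-1]
        heads = iter(self.mask_heads) if self.cfg.use_mcrd else None
        for idx, j in enumerate(range(NUM_LEVELS - 1, 0, -1)):
            skip = skips[j - 1]
            if self.cfg.use_mcrd and j in self.mcrd_junctions:
                if j == 4 and mpam_mask is not None:
                    mask = ad.upsample2x_bilinear(mpam_mask)
                else:
                    mask = next(heads)(h)
                skip = self.mcrds[self.mcrd_junctions.index(j)](skip, mask)
            up = self.deconvs[idx](h)
            h = self.dec_blocks[idx](ad.concat([up, skip], axis=1))
        return self.head(h).sigmoid()


def build_model(cfg: ModelConfig) -> SegModel:
    return SegModel(cfg)


def count_parameters(model) -> int:
    return model.num_parameters()


# ---------------------------------------------------------------------------
# inference and evaluation helpers
# ---------------------------------------------------------------------------

def predict(model, images, batch_size=4):
    """Probability maps for a stack of images [N, 3, H, W] (eval mode)."""
    model.eval()
    out = []
    with ad.no_grad():
        for i in range(0, len(images), batch_size):
            out.append(model(Tensor(images[i : i + batch_size])).data)
    return np.concatenate(out, axis=0)


def _stack(samples):
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return imgs, masks


def evaluate_model(model, samples, batch_size=4, threshold=0.5):
    """Dataset-aggregated six metrics + mIoU for a list of samples."""
    imgs, masks = _stack(samples)
    probs = predict(model, imgs, batch_size)
    counts = [
        confusion_counts(probs[i], masks[i].astype(np.uint8), threshold)
        for i in range(len(samples))
    ]
    metrics, total = evaluate_dataset(counts)
    return metrics, total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_rng(seed, epoch):
    return np.random.default_rng([seed, epoch])


def _lr_at(cfg, step, total_steps, epoch):
    if cfg.schedule == "poly":
        return poly_lr(cfg.lr, step, total_steps, cfg.poly_power)
    if cfg.schedule == "step":
        return cfg.lr * cfg.step_gamma ** (epoch // cfg.step_every)
    return cfg.lr


def train_loop(model, train_samples, val_samples, cfg: TrainConfig,
               start_epoch=0, end_epoch=None, optimizer_state=None,
               history=None):
    """SGD training with per-epoch validation; returns (model, history, best).

    ``best`` is the state dict at the epoch with the highest validation
    foreground IoU. Per-epoch shuffling is seeded by (cfg.seed, epoch), and
    the optimizer state can be restored, so an interrupted run resumed from a
    checkpoint continues on the exact same trajectory.
    """
    train_samples = list(train_samples)
    if not train_samples:
        raise ValueError("train_loop: empty training dataset")
    imgs, masks = _stack(train_samples)
    n = len(train_samples)
    bs = cfg.batch_size
    steps_per_epoch = (n + bs - 1) // bs
    total_steps = cfg.epochs * steps_per_epoch

    opt = SGD(model.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    if optimizer_state is not None:
        opt.load_state_dict(optimizer_state)
    history = list(history or [])
    best_iou, best_state = -1.0, None
    for row in history:  # recover best-so-far when resuming
        if row["val_iou"] > best_iou:
            best_iou = row["val_iou"]

    end_epoch = cfg.epochs if end_epoch is None else min(end_epoch, cfg.epochs)
    for epoch in range(start_epoch, end_epoch):
        model.train()
        order = _epoch_rng(cfg.seed, epoch).permutation(n)
        losses = []
        for b in range(steps_per_epoch):
            idx = order[b * bs : (b + 1) * bs]
            x = Tensor(imgs[idx])
            y = masks[idx]
            prob = model(x)
            loss = combined_loss(prob, y, cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.lr = _lr_at(cfg, epoch * steps_per_epoch + b, total_steps, epoch)
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if val_samples:
            metrics, _ = evaluate_model(model, val_samples, batch_size=bs)
            row.update({f"val_{k}": v for k, v in metrics.items()})
        else:
            row["val_iou"] = float("nan")
        history.append(row)
        if val_samples and row["val_iou"] >= best_iou:
            best_iou = row["val_iou"]
            best_state = model.state_dict()
    if best_state is None:
        best_state = model.state_dict()
    return model, history, best_state, opt.state_dict()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model_cfg, state, epoch=None, optimizer_state=None):
    """Serialize parameters + config + seed; round-trips bitwise."""
    payload = {f"param/{k}": v for k, v in state.items()}
    if optimizer_state is not None:
        for i, v in enumerate(optimizer_state["velocity"]):
            payload[f"opt/velocity/{i}"] = v
        payload["opt/lr"] = np.float64(optimizer_state["lr"])
    meta = {"model_cfg": asdict(model_cfg), "epoch": epoch}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path):
    """Returns (ModelConfig, state dict, epoch, optimizer state or None)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        state = {
            k[len("param/") :]: z[k] for k in z.files if k.startswith("param/")
        }
        vel_keys = sorted(
            (k for k in z.files if k.startswith("opt/velocity/")),
            key=lambda k: int(k.rsplit("/", 1)[1]),
        )
        opt_state = None
        if vel_keys:
            opt_state = {
                "velocity": [z[k] for k in vel_keys],
                "lr": float(z["opt/lr"]),
            }
    cfg = ModelConfig(**meta["model_cfg"])
    return cfg, state, meta["epoch"], opt_state
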