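"""End-to-end trainer: a compact fully convolutional encoder-decoder
implemented directly in NumPy (im2col convolutions, hand-written backprop,
Adam), trained on precomputed soft labels with the uncertainty-masked
consistency objective.

The network is a small U-Net: ``depth`` levels of two 3x3 conv + ReLU
blocks with 2x2 max pooling, a bottleneck, and a mirrored decoder with
nearest-neighbour upsampling and skip concatenation, ending in a 1x1
conv and per-pixel softmax.  It is deliberately non-equivariant to flips
(zero padding plus asymmetric learned kernels), which is what makes the
flip-consistency term a non-trivial constraint.

Arrays are NHWC throughout; parameters and activations are float32, loss
and gradient-on-probability computations are float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .fusion import FusionConfig, SoftLabel, fuse
from .losses import (
    DICE_SMOOTH,
    LOG_FLOOR,
    FlipTransform,
    LossWeights,
    Prediction,
    apply_flip,
)
from .metrics import evaluate_masks
from .synthetic import ImageSample, RaterStack, build_default_panel
from .uncertainty import MaskPair, interclass_variance, make_masks

# ---------------------------------------------------------------------------
# layers


def _conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 correlation.  x (N,H,W,Cin), w (3,3,Cin,Cout)."""
    n, h, wd, cin = x.shape
    cout = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,Cin,3,3)
    cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n, h, wd, 9 * cin)
    out = cols @ w.reshape(9 * cin, cout) + b
    return out, cols


def _conv3x3_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray):
    n, h, wd, cout = dout.shape
    cin = w.shape[2]
    dw = (cols.reshape(-1, 9 * cin).T @ dout.reshape(-1, cout)).reshape(w.shape)
    db = dout.sum(axis=(0, 1, 2))
    # grad wrt input = correlation of dout with the spatially flipped kernel,
    # in/out channels swapped
    w_back = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,Cout,Cin)
    dx, _ = _conv3x3_forward(dout, np.ascontiguousarray(w_back), np.zeros(cin, dtype=w.dtype))
    return dx, dw, db


def _maxpool2_forward(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    return out, (xr, out)


def _maxpool2_backward(dout: np.ndarray, cache):
    xr, out = cache
    mask = xr == out[:, :, None, :, None, :]
    dxr = mask * dout[:, :, None, :, None, :]
    n, h2, _, w2, _, c = dxr.shape
    return dxr.reshape(n, h2 * 2, w2 * 2, c)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# network


@dataclass
class NetworkConfig:
    depth: int = 2
    base_channels: int = 8
    num_classes: int = 2
    in_channels: int = 1


class UNet:
    """Small from-scratch U-Net; forward returns per-pixel softmax."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        ch = cfg.in_channels
        self._enc_channels = []
        for lvl in range(cfg.depth + 1):  # last level is the bottleneck
            out_ch = cfg.base_channels * 2**lvl
            self._add_conv(rng, f"enc{lvl}a", ch, out_ch)
            self._add_conv(rng, f"enc{lvl}b", out_ch, out_ch)
            self._enc_channels.append(out_ch)
            ch = out_ch
        for lvl in reversed(range(cfg.depth)):
            out_ch = cfg.base_channels * 2**lvl
            self._add_conv(rng, f"dec{lvl}a", ch + self._enc_channels[lvl], out_ch)
            self._add_conv(rng, f"dec{lvl}b", out_ch, out_ch)
            ch = out_ch
        # 1x1 head stored as a (1,1,Cin,Cout)-like dense matrix
        self.params["head_w"] = (
            rng.standard_normal((ch, cfg.num_classes)) * np.sqrt(2.0 / ch)
        ).astype(np.float32)
        self.params["head_b"] = np.zeros(cfg.num_classes, dtype=np.float32)

    def _add_conv(self, rng, name: str, cin: int, cout: int) -> None:
        std = np.sqrt(2.0 / (9 * cin))
        self.params[f"{name}_w"] = (rng.standard_normal((3, 3, cin, cout)) * std).astype(
            np.float32
        )
        self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[1:3]
        f = 2**self.cfg.depth
        if h % f or w % f:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2^depth={f}")
        if x.shape[3] != self.cfg.in_channels:
            raise ValueError("input channel count does not match the network")

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x (N,H,W,Cin) float32 -> softmax probs (N,H,W,C)."""
        self._check_input(x)
        p = self.params
        cache: dict = {"acts": {}}
        skips = []
        h = x.astype(np.float32, copy=False)
        for lvl in range(self.cfg.depth + 1):
            for sub in "ab":
                name = f"enc{lvl}{sub}"
                z, cols = _conv3x3_forward(h, p[f"{name}_w"], p[f"{name}_b"])
                h = np.maximum(z, 0.0)
                if want_cache:
                    cache["acts"][name] = (cols, z)
            if lvl < self.cfg.depth:
                skips.append(h)
                h, pc = _maxpool2_forward(h)
                if want_cache:
                    cache["acts"][f"pool{lvl}"] = pc
        for lvl in reversed(range(self.cfg.depth)):
            h = _upsample2(h)
            skip = skips[lvl]
            if want_cache:
                cache["acts"][f"cat{lvl}"] = (h.shape[-1], skip.shape[-1])
            h = np.concatenate([h, skip], axis=-1)
            for sub in "ab":
                name = f"dec{lvl}{sub}"
                z, cols = _conv3x3_forward(h, p[f"{name}_w"], p[f"{name}_b"])
                h = np.maximum(z, 0.0)
                if want_cache:
                    cache["acts"][name] = (cols, z)
        logits = h @ p["head_w"] + p["head_b"]
        probs = softmax(logits.astype(np.float64))
        if want_cache:
            cache["head_in"] = h
            return probs, cache
        return probs

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop from d(loss)/d(logits); returns grads keyed like params."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dlogits = dlogits.astype(np.float32)
        hin = cache["head_in"]
        grads["head_w"] = hin.reshape(-1, hin.shape[-1]).T @ dlogits.reshape(
            -1, dlogits.shape[-1]
        )
        grads["head_b"] = dlogits.sum(axis=(0, 1, 2))
        dh = dlogits @ p["head_w"].T
        for lvl in range(self.cfg.depth):
            for sub in "ba":
                name = f"dec{lvl}{sub}"
                cols, z = cache["acts"][name]
                dz = dh * (z > 0)
                dh, grads[f"{name}_w"], grads[f"{name}_b"] = _conv3x3_backward(
                    dz, cols, p[f"{name}_w"]
                )
            up_ch, skip_ch = cache["acts"][f"cat{lvl}"]
            d_up, d_skip = dh[..., :up_ch], dh[..., up_ch:]
            cache.setdefault("skip_grads", {})[lvl] = d_skip
            dh = _upsample2_backward(d_up)
        for lvl in reversed(range(self.cfg.depth + 1)):
            if lvl < self.cfg.depth:
                dh = _maxpool2_backward(dh, cache["acts"][f"pool{lvl}"])
                dh = dh + cache["skip_grads"][lvl]
            for sub in "ba":
                name = f"enc{lvl}{sub}"
                cols, z = cache["acts"][name]
                dz = dh * (z > 0)
                dh, grads[f"{name}_w"], grads[f"{name}_b"] = _conv3x3_backward(
                    dz, cols, p[f"{name}_w"]
                )
        return grads


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        b1, b2 = self.betas
        self.t += 1
        for k in params:
            g = grads[k].astype(params[k].dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# loss gradients with respect to the softmax probabilities


def _grad_probs_supervised(kind: str, t, p, w, npix: int, gamma: float = 2.0):
    """d(weighted mean loss)/dp for the supervised losses; all float64."""
    pc = np.maximum(p, LOG_FLOOR)
    if kind == "ce":
        return -(w[..., None] * t / pc) / npix
    if kind == "focal":
        logp = np.log(pc)
        return (
            w[..., None]
            * t
            * (gamma * (1 - p) ** (gamma - 1) * logp - (1 - p) ** gamma / pc)
        ) / npix
    if kind == "dice":
        c = t.shape[-1]
        axes = tuple(range(t.ndim - 1))
        inter = (t * p).sum(axis=axes)
        denom = t.sum(axis=axes) + p.sum(axis=axes) + DICE_SMOOTH
        num = 2.0 * inter + DICE_SMOOTH
        return -(2.0 * t * denom - num) / denom**2 / c
    raise ValueError(kind)


def _softmax_chain(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Map d(loss)/dprobs to d(loss)/dlogits through the softmax Jacobian."""
    inner = (probs * dprobs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - inner)


# ---------------------------------------------------------------------------
# configuration and data plumbing


@dataclass
class TrainConfig:
    """All knobs of one training run.

    Optimizer defaults (Adam, lr 1e-4, batch 4, 60 epochs) follow the
    standard recipe for this objective; ``mu`` and ``lambda2`` default to
    the best-performing combination (0.005, 0.5) for the CE+CE loss pair.
    """

    mu: float = 0.005
    lambda2: float = 0.5
    supervised_loss: str = "ce"
    consistency_loss: str = "ce"
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 60
    seed: int = 0
    flip_set: tuple[str, ...] = ("horizontal", "vertical", "both")
    depth: int = 2
    base_channels: int = 8
    num_classes: int = 2
    in_channels: int = 1
    cr_mask_mode: str = "additive"
    detach_target: bool = False
    focal_gamma: float = 2.0
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda2 <= 1.0:
            raise ValueError("lambda2 must be in [0, 1]")
        if self.lambda2 > 0 and not self.flip_set:
            raise ValueError("flip_set must be non-empty when lambda2 > 0")
        for v, name in ((self.learning_rate, "learning_rate"), (self.batch_size, "batch_size"), (self.epochs, "epochs")):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    def network(self) -> NetworkConfig:
        return NetworkConfig(
            depth=self.depth,
            base_channels=self.base_channels,
            num_classes=self.num_classes,
            in_channels=self.in_channels,
        )


@dataclass
class TrainingExample:
    """One image with its precomputed supervision targets."""

    image: np.ndarray  # (H, W) or (H, W, L)
    soft_label: SoftLabel
    masks: MaskPair
    gt_mask: np.ndarray | None = None
    id: str = ""


def make_training_set(
    samples: list[ImageSample],
    cfg: TrainConfig,
    fusion_cfg: FusionConfig | None = None,
    rater_seed: int = 0,
    stacks: list[RaterStack] | None = None,
) -> list[TrainingExample]:
    """Simulate (or accept) rater panels, fuse them, and derive masks once.

    Soft labels and uncertainty masks depend only on the annotations, so
    they are computed a single time before training, never per step.
    """
    fusion_cfg = fusion_cfg or FusionConfig(method="svls")
    root = np.random.default_rng(rater_seed)
    out = []
    for i, s in enumerate(samples):
        stack = (
            stacks[i]
            if stacks is not None
            else build_default_panel(
                s.gt_mask, seed=int(root.integers(0, 2**31 - 1)), num_classes=cfg.num_classes
            )
        )
        soft = fuse(stack, fusion_cfg)
        masks = make_masks(interclass_variance(soft), cfg.mu, mode=cfg.cr_mask_mode)
        out.append(
            TrainingExample(image=s.image, soft_label=soft, masks=masks, gt_mask=s.gt_mask, id=s.id)
        )
    return out


# ---------------------------------------------------------------------------
# trainer


@dataclass
class ModelState:
    """Trained network with enough context to resume or predict."""

    net: UNet
    config: TrainConfig
    epoch: int = 0
    optimizer: Adam | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        blobs = {f"param_{k}": v for k, v in self.net.params.items()}
        if self.optimizer is not None:
            blobs.update({f"adam_m_{k}": v for k, v in self.optimizer.m.items()})
            blobs.update({f"adam_v_{k}": v for k, v in self.optimizer.v.items()})
            blobs["adam_t"] = np.array(self.optimizer.t)
        blobs["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        blobs["epoch"] = np.array(self.epoch)
        np.savez(path, **blobs)

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with np.load(Path(path), allow_pickle=False) as z:
            cfg_d = json.loads(bytes(z["config_json"].tobytes()).decode())
            cfg_d["flip_set"] = tuple(cfg_d["flip_set"])
            cfg = TrainConfig(**cfg_d)
            state = cls(net=build_network(cfg), config=cfg, epoch=int(z["epoch"]))
            for k in state.net.params:
                state.net.params[k] = z[f"param_{k}"].copy()
            if "adam_t" in z:
                opt = Adam(state.net.params, lr=cfg.learning_rate)
                opt.t = int(z["adam_t"])
                for k in state.net.params:
                    opt.m[k] = z[f"adam_m_{k}"].copy()
                    opt.v[k] = z[f"adam_v_{k}"].copy()
                state.optimizer = opt
        return state


def build_network(cfg: TrainConfig) -> UNet:
    """Seeded construction of the segmentation network."""
    return UNet(cfg.network(), seed=cfg.seed)


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    arrs = []
    for im in images:
        a = np.asarray(im, dtype=np.float32)
        if a.ndim == 2:
            a = a[..., None]
        arrs.append(a)
    return np.stack(arrs)


def predict(state: ModelState, image: np.ndarray) -> tuple[Prediction, np.ndarray]:
    """Per-pixel class probabilities and their argmax for one image."""
    x = _to_batch([image])
    probs = state.net.forward(x)[0]
    pred = Prediction(probs=probs)
    return pred, pred.hard_mask()


def _validation_dice(state: ModelState, examples: list[TrainingExample]) -> float:
    scores = []
    for ex in examples:
        ref = ex.gt_mask if ex.gt_mask is not None else ex.soft_label.argmax()
        _, hard = predict(state, ex.image)
        rep = evaluate_masks(hard, ref, state.config.num_classes)
        scores.append(rep.mean_dsc)
    return float(np.mean(scores)) if scores else float("nan")


def train(
    dataset: list[TrainingExample],
    cfg: TrainConfig,
    val_dataset: list[TrainingExample] | None = None,
) -> tuple[ModelState, pd.DataFrame]:
    """Minimise the masked combined objective with Adam.

    One flip is sampled per batch (shared across the batch); the original
    and flipped mini-batches are pushed through the network as a single
    doubled batch, so the consistency pair costs one extra forward/backward
    half.  Returns the final state and a per-epoch log with columns
    (epoch, loss_total, loss_gt, loss_cr, val_dice).

    With ``lambda2 = 0`` and ``mu = 0`` this reduces exactly to plain
    soft-label cross-entropy training (the averaging baseline).
    """
    if not dataset:
        raise ValueError("empty dataset")
    if val_dataset is None:
        rng_split = np.random.default_rng(cfg.seed + 1)
        idx = rng_split.permutation(len(dataset))
        n_val = max(1, int(round(cfg.val_fraction * len(dataset))))
        val_dataset = [dataset[i] for i in idx[:n_val]]
        dataset = [dataset[i] for i in idx[n_val:]]

    net = build_network(cfg)
    opt = Adam(net.params, lr=cfg.learning_rate)
    state = ModelState(net=net, config=cfg, optimizer=opt)
    rng = np.random.default_rng(cfg.seed + 2)
    # separate stream for flip choices so the data order is identical
    # between runs with and without the consistency term
    flip_rng = np.random.default_rng(cfg.seed + 3)
    weights = LossWeights(lambda2=cfg.lambda2)
    flips = [FlipTransform(f) for f in cfg.flip_set] or [FlipTransform.HORIZONTAL]

    images = _to_batch([ex.image for ex in dataset])
    targets = np.stack([ex.soft_label.probs for ex in dataset])
    gt_masks = np.stack([ex.masks.gt_mask for ex in dataset])
    cr_masks = np.stack([ex.masks.cr_mask for ex in dataset])

    n = len(dataset)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_tot, ep_sup, ep_cons, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            x = images[sel]
            t = targets[sel]
            w_gt = gt_masks[sel]
            w_cr = cr_masks[sel]
            bsz = x.shape[0]
            npix = int(np.prod(w_gt.shape))

            use_cr = cfg.lambda2 > 0
            if use_cr:
                flip = flips[int(flip_rng.integers(len(flips)))]
                x_in = np.concatenate([x, apply_flip(x, flip, axes=(1, 2))], axis=0)
            else:
                flip = None
                x_in = x
            probs, cache = net.forward(x_in, want_cache=True)
            p1 = probs[:bsz]  # prediction on originals
            # supervised gradient
            g = _grad_probs_supervised(
                cfg.supervised_loss, t, p1, w_gt, npix, gamma=cfg.focal_gamma
            )
            dprobs = np.zeros_like(probs)
            dprobs[:bsz] += weights.lambda1 * g
            sup_val = _loss_value(cfg.supervised_loss, t, p1, w_gt, cfg.focal_gamma)

            cons_val = 0.0
            if use_cr:
                p2 = probs[bsz:]  # prediction on flipped inputs = target branch
                q = apply_flip(p1, flip, axes=(1, 2))  # flipped prediction branch
                cw = w_cr if cfg.consistency_loss != "dice" else np.ones_like(w_cr)
                cons_val = _loss_value(cfg.consistency_loss, p2, q, cw, cfg.focal_gamma)
                dq = _grad_probs_supervised(
                    cfg.consistency_loss, p2, q, cw, npix, gamma=cfg.focal_gamma
                )
                dprobs[:bsz] += weights.lambda2 * apply_flip(dq, flip, axes=(1, 2))
                if not cfg.detach_target:
                    dp2 = _grad_probs_target(
                        cfg.consistency_loss, p2, q, cw, npix, gamma=cfg.focal_gamma
                    )
                    dprobs[bsz:] += weights.lambda2 * dp2

            total = weights.lambda1 * sup_val + weights.lambda2 * cons_val
            if not np.isfinite(total):
                bad = [dataset[i].id for i in sel]
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}; ids={bad}"
                )
            dlogits = _softmax_chain(probs, dprobs)
            grads = net.backward(cache, dlogits)
            opt.step(net.params, grads)
            ep_tot += total
            ep_sup += sup_val
            ep_cons += cons_val
            nb += 1
        state.epoch = epoch + 1
        val_dice = _validation_dice(state, val_dataset)
        rows.append(
            {
                "epoch": epoch + 1,
                "loss_total": ep_tot / nb,
                "loss_gt": ep_sup / nb,
                "loss_cr": ep_cons / nb,
                "val_dice": val_dice,
            }
        )
    return state, pd.DataFrame(rows)


def _loss_value(kind: str, t, p, w, gamma: float) -> float:
    """Scalar loss matching the gradients above (weighted pixel mean)."""
    pc = np.maximum(p, LOG_FLOOR)
    if kind == "ce":
        return float((w * -(t * np.log(pc)).sum(axis=-1)).mean())
    if kind == "focal":
        per = -(t * (1 - p) ** gamma * np.log(pc)).sum(axis=-1)
        return float((w * per).mean())
    if kind == "dice":
        axes = tuple(range(t.ndim - 1))
        inter = (t * p).sum(axis=axes)
        denom = t.sum(axis=axes) + p.sum(axis=axes)
        return float(1.0 - ((2 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)).mean())
    raise ValueError(kind)


def _grad_probs_target(kind: str, t, p, w, npix: int, gamma: float = 2.0):
    """Gradient of the consistency loss with respect to its *target* branch
    (the prediction on the flipped image), which is not detached by default."""
    pc = np.maximum(p, LOG_FLOOR)
    if kind in ("ce", "focal"):
        if kind == "ce":
            gamma = 0.0
        return -(w[..., None] * (1 - p) ** gamma * np.log(pc)) / npix
    if kind == "dice":
        axes = tuple(range(t.ndim - 1))
        inter = (t * p).sum(axis=axes)
        denom = t.sum(axis=axes) + p.sum(axis=axes) + DICE_SMOOTH
        num = 2.0 * inter + DICE_SMOOTH
        return -(2.0 * p * denom - num) / denom**2 / t.shape[-1]
    raise ValueError(kind)
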