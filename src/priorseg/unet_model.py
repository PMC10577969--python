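"""Two-channel 3D U-Net segmentation model, Dice loss, training and folds.

The network takes two 3D input channels — the enhanced preoperative and
postoperative CT — and produces one per-voxel probability channel for the
CTV-TB label. It is a standard encoder/decoder U-Net with 3D convolutions,
3D max-pooling, nearest-neighbor up-sampling, leaky-ReLU activations
and skip connections, built on
the in-repo NumPy backend (:mod:`priorseg.nn`), so training is deterministic
and runs on a single CPU.

Training follows the clinical study schedule: Adam, batch size 4, weight
decay 3e-5, initial learning rate 5e-4 multiplied by 0.95 once per epoch,
soft-Dice loss, at most 50 epochs, with validation-loss monitoring every 20
iterations. Cross-validation folds are produced by :func:`make_folds`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .enhancement import normalize_for_network
from .volumes import BinaryMask, ImageVolume

log = logging.getLogger(__name__)

EPS = 1.0  # soft-Dice smoothing term


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclasses.dataclass
class TrainConfig:
    """Optimization schedule and architecture scale.

    The schedule defaults (learning rate 5e-4, drop factor 0.95 per epoch,
    weight decay 3e-5, batch size 4, max 50 epochs, validation every 20
    iterations) are the clinical study's settings; ``base_channels``/
    ``depth``/``input_shape`` control the U-Net size and default to a
    configuration suitable for the full 256x256x32 grid. Desk-scale
    experiments shrink them (see :mod:`priorseg.pipeline`).
    """

    learning_rate: float = 5e-4
    lr_drop_factor: float = 0.95
    weight_decay: float = 3e-5
    batch_size: int = 4
    max_epochs: int = 50
    validation_frequency: int = 20
    seed: int = 0
    base_channels: int = 16
    depth: int = 3
    input_shape: tuple[int, int, int] = (256, 256, 32)

    def __post_init__(self):
        if not (0 < self.lr_drop_factor <= 1):
            raise ValueError("lr_drop_factor must be in (0, 1]")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate during 1-indexed ``epoch``: lr0 * factor^(epoch-1)."""
        return self.learning_rate * self.lr_drop_factor ** (epoch - 1)


@dataclasses.dataclass
class FoldSplit:
    """Assignment of case ids to cross-validation folds."""

    assignments: dict
    k: int

    def fold_ids(self, fold: int) -> list:
        return [cid for cid, f in self.assignments.items() if f == fold]


def make_folds(case_ids: Sequence, k: int, seed: int) -> FoldSplit:
    """Deterministically partition ``case_ids`` into ``k`` near-equal folds.

    Ids are shuffled with the seed and dealt round-robin, so fold sizes
    differ by at most one; 110 ids with k=5 give five folds of exactly 22.
    """
    case_ids = list(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(case_ids):
        raise ValueError(f"k={k} exceeds number of cases ({len(case_ids)})")
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("case ids must be unique")
    order = np.random.default_rng(seed).permutation(len(case_ids))
    return FoldSplit({case_ids[j]: i % k for i, j in enumerate(order)}, k)


# ---------------------------------------------------------------------------
# Dice loss


def soft_dsc(pred: np.ndarray, target: np.ndarray, eps: float = EPS) -> float:
    """Soft Dice similarity: (2 Σ p·t + ε) / (Σp + Σt + ε)."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float((2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps))


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = EPS) -> float:
    """Dice loss = 1 − soft DSC, in [0, 1]."""
    return 1.0 - soft_dsc(pred, target, eps)


def _dice_loss_grad(p: np.ndarray, t: np.ndarray, eps: float = EPS) -> np.ndarray:
    """d(dice_loss)/d(pred) for one sample."""
    p = p.astype(np.float64)
    t = t.astype(np.float64)
    denom = p.sum() + t.sum() + eps
    num = 2.0 * (p * t).sum() + eps
    return (-(2.0 * t * denom - num) / (denom * denom)).astype(np.float32)


# ---------------------------------------------------------------------------
# Network


def _pool_factors(input_shape, depth):
    """Per-level pooling factors.

    In-plane axes pool by 2 at every level and must divide evenly; the
    (thick-slice) z axis pools only while it stays at least 4 slices, so
    deep networks on shallow stacks pool anisotropically.
    """
    shape = list(input_shape)
    factors = []
    for _ in range(depth):
        f = []
        for ax in range(3):
            limit = 4 if ax == 2 else 8
            if shape[ax] >= limit:
                if shape[ax] % 2:
                    raise ValueError(
                        f"input shape {tuple(input_shape)} is not divisible by the "
                        f"pooling schedule at depth {depth} (axis {ax})"
                    )
                f.append(2)
                shape[ax] //= 2
            else:
                f.append(1)
        factors.append(tuple(f))
    return factors


class SegmentationNetwork:
    """3D U-Net mapping (2, D, H, W) inputs to (D, H, W) probabilities."""

    def __init__(self, config: TrainConfig, in_channels: int = 2):
        self.config = config
        self.in_channels = in_channels
        self.depth = config.depth
        self.pool_factors = _pool_factors(config.input_shape, config.depth)
        for f, shape_ax in zip(
            np.prod(self.pool_factors, axis=0), config.input_shape
        ):
            if shape_ax % f:
                raise ValueError(
                    f"input shape {config.input_shape} not divisible by pooling {self.pool_factors}"
                )
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(config.seed)
        ch = in_channels
        enc_channels = []
        for lvl in range(self.depth):
            cout = config.base_channels * 2 ** lvl
            self._add_conv(rng, f"enc{lvl}", ch, cout)
            enc_channels.append(cout)
            ch = cout
        cbott = config.base_channels * 2 ** self.depth
        self._add_conv(rng, "bottleneck", ch, cbott)
        ch = cbott
        for lvl in reversed(range(self.depth)):
            cout = enc_channels[lvl]
            self._add_conv(rng, f"dec{lvl}", ch + enc_channels[lvl], cout)
            ch = cout
        # weights drawn from a normal distribution (He-scaled)
        self.params["head.w"] = rng.normal(0.0, np.sqrt(2.0 / ch), (1, ch)).astype(
            np.float32
        )
        self.params["head.b"] = np.zeros(1, dtype=np.float32)

    def _add_conv(self, rng, name, cin, cout):
        std = np.sqrt(2.0 / (cin * 27))
        self.params[f"{name}.w"] = rng.normal(0.0, std, (cout, cin, 3, 3, 3)).astype(
            np.float32
        )
        self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)
        # instance-norm scale/shift for the conv -> norm -> activation block
        self.params[f"{name}.gamma"] = np.ones(cout, dtype=np.float32)
        self.params[f"{name}.beta"] = np.zeros(cout, dtype=np.float32)

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Return per-voxel probabilities (D, H, W) for a (2, D, H, W) input."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != self.in_channels:
            raise ValueError(f"expected ({self.in_channels}, D, H, W) input, got {x.shape}")
        p = self.params
        cache = {"x": x}
        h = x
        skips = []
        def block(name, xin):
            conv = nn.conv3x3(xin, p[f"{name}.w"], p[f"{name}.b"])
            normed, ncache = nn.instance_norm(
                conv, p[f"{name}.gamma"], p[f"{name}.beta"]
            )
            cache[f"{name}.in"] = xin
            cache[f"{name}.pre"] = normed
            cache[f"{name}.norm"] = ncache
            return nn.leaky_relu(normed)

        for lvl in range(self.depth):
            a = block(f"enc{lvl}", h)
            skips.append(a)
            h, idx = nn.maxpool(a, self.pool_factors[lvl])
            cache[f"pool{lvl}.idx"] = idx
        h = block("bottleneck", h)
        for lvl in reversed(range(self.depth)):
            up = nn.upsample(h, self.pool_factors[lvl])
            cat = np.concatenate([skips[lvl], up], axis=0)
            h = block(f"dec{lvl}", cat)
        logits = nn.conv1x1(h, p["head.w"], p["head.b"])
        cache["head.in"] = h
        prob = nn.sigmoid(logits[0])
        if keep_cache:
            cache["prob"] = prob
            self._cache = cache
        return prob

    def backward(self, dprob: np.ndarray) -> dict:
        """Gradients of all parameters given d(loss)/d(probabilities)."""
        c = self._cache
        p = self.params
        grads = {}
        prob = c["prob"]
        dlogits = (dprob * prob * (1.0 - prob)).astype(np.float32)[None]
        dh, grads["head.w"], grads["head.b"] = nn.conv1x1_backward(
            c["head.in"], p["head.w"], dlogits
        )
        def block_backward(name, dact):
            dact = dact * nn.leaky_relu_grad(c[f"{name}.pre"])
            dconv, grads[f"{name}.gamma"], grads[f"{name}.beta"] = (
                nn.instance_norm_backward(dact, c[f"{name}.norm"])
            )
            dx, grads[f"{name}.w"], grads[f"{name}.b"] = nn.conv3x3_backward(
                c[f"{name}.in"], p[f"{name}.w"], dconv
            )
            return dx

        dskips = {}
        for lvl in range(self.depth):
            dcat = block_backward(f"dec{lvl}", dh)
            # cat = [skip (enc{lvl} channels) | upsampled deeper features]
            n_skip = p[f"enc{lvl}.w"].shape[0]
            dskips[lvl] = dcat[:n_skip]
            dh = nn.upsample_backward(dcat[n_skip:], self.pool_factors[lvl])
        dh = block_backward("bottleneck", dh)
        for lvl in reversed(range(self.depth)):
            da = nn.maxpool_backward(dh, c[f"pool{lvl}.idx"], self.pool_factors[lvl])
            da += dskips[lvl]
            dh = block_backward(f"enc{lvl}", da)
        self._cache = None
        return grads

    # -- persistence --------------------------------------------------------

    def save(self, path: str):
        """Checkpoint: weights as .npz plus a JSON sidecar of the config."""
        np.savez(path, **self.params)
        with open(str(path) + ".json", "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "SegmentationNetwork":
        with open(str(path) + ".json") as fh:
            cfg = json.load(fh)
        cfg["input_shape"] = tuple(cfg["input_shape"])
        net = cls(TrainConfig(**cfg))
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
            for k in net.params:
                net.params[k] = data[k].astype(np.float32)
        return net


def build_unet(config: TrainConfig) -> SegmentationNetwork:
    """Construct the two-channel 3D U-Net for the configured input shape."""
    return SegmentationNetwork(config, in_channels=2)


# ---------------------------------------------------------------------------
# Training and prediction


def train(
    network: SegmentationNetwork,
    cases: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    val_cases: Sequence[tuple[np.ndarray, np.ndarray]] = (),
) -> tuple[SegmentationNetwork, dict]:
    """Optimize the network with Adam on the soft-Dice loss.

    ``cases`` is a sequence of ``(input (2,D,H,W), target (D,H,W))`` pairs.
    The learning rate is multiplied by ``lr_drop_factor`` once per epoch.
    Returns the trained network and a history dict with the per-epoch mean
    training loss and (if ``val_cases`` given) validation losses sampled
    every ``validation_frequency`` iterations.
    """
    if len(cases) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(network.params, weight_decay=config.weight_decay)
    lr = config.learning_rate
    history = {"epoch_loss": [], "lr": [], "val": []}
    iteration = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(cases))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = None
            loss_sum = 0.0
            for i in batch:
                x, t = cases[i]
                prob = network.forward(x, keep_cache=True)
                loss = dice_loss(prob, t)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch}, iteration {iteration}"
                    )
                loss_sum += loss
                g = network.backward(_dice_loss_grad(prob, t))
                if grads is None:
                    grads = g
                else:
                    for k in grads:
                        grads[k] += g[k]
            for k in grads:
                grads[k] /= len(batch)
            opt.step(grads, lr)
            batch_losses.append(loss_sum / len(batch))
            iteration += 1
            if val_cases and iteration % config.validation_frequency == 0:
                vloss = float(
                    np.mean([dice_loss(network.forward(x), t) for x, t in val_cases])
                )
                history["val"].append((iteration, vloss))
        history["epoch_loss"].append(float(np.mean(batch_losses)))
        history["lr"].append(lr)
        lr *= config.lr_drop_factor
    return network, history


def predict(
    network: SegmentationNetwork,
    pre_enhanced: ImageVolume,
    post_enhanced: ImageVolume,
    threshold: float = 0.5,
) -> BinaryMask:
    """Predict the CTV-TB mask from the two enhanced channels.

    Channels are min–max normalized, stacked, and passed through the
    network; the probability map is thresholded (p >= threshold) and only
    the largest 26-connected component is kept, since a single tumor bed
    is anatomically expected. An all-background prediction is returned
    empty (and logged).
    """
    if pre_enhanced.shape != post_enhanced.shape:
        raise ValueError(
            f"channel shapes differ: {pre_enhanced.shape} vs {post_enhanced.shape}"
        )
    x = np.stack(
        [
            normalize_for_network(pre_enhanced).voxels,
            normalize_for_network(post_enhanced).voxels,
        ]
    )
    prob = network.forward(x)
    fg = prob >= threshold
    if fg.any():
        labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3)))
        if n > 1:
            sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
            fg = labels == (1 + int(np.argmax(sizes)))
    else:
        log.warning("prediction is empty (no voxel above threshold %.2f)", threshold)
    return BinaryMask(fg, post_enhanced.spacing, post_enhanced.origin, label="PREDICTED")
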