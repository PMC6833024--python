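"""Training strategies: average-loss (ALM), top-k maximal-loss (MLM), and
mixed-maximum-loss minimisation (MMLM).

MMLM re-weights hard examples.  At round ``t`` the per-sample Dice losses
under the frozen previous-round parameters are sorted from largest to
smallest; the round's loss is

    L_t = lambda1 * sum_i l(f(X_i), Y_i)
        + lambda2 * sum_{k<=K_t} sum_{j<=N_t} l(f(R_k(Xbar_j)), R_k(Ybar_j))

where Xbar_j is the sample with the j-th largest loss and R_k is the k-th
random rotation/translation.  The schedules

    N_t = max(N_max - t, N_min)        (clamped to the dataset size)
    K_t = max(K_max - floor(0.25 t), K_min)

shrink the hard-example set as training progresses.  Setting lambda2 = 0
recovers plain average-loss training; lambda1 = 0 with identity
augmentation and K_t = 1 recovers top-N_t maximal-loss training.

One round is realised as one epoch of mini-batch Adam over the weighted
multiset (all m originals at weight lambda1 plus K_t augmented copies of
each of the top N_t samples at weight lambda2); ranking uses the frozen
parameters from the end of the previous round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .metrics import dice_loss, dice_loss_grad, evaluate_masks
from .network import MSMKU, NetworkConfig, build_msmku, prepare_image
from .nn import Adam

__all__ = [
    "TrainingPair",
    "MMLMConfig",
    "AugmentOp",
    "RoundRecord",
    "schedule_n",
    "schedule_k",
    "rank_by_loss",
    "per_sample_losses",
    "make_augment_ops",
    "apply_augment",
    "mixed_loss",
    "train_mmlm",
    "train_alm",
    "train_mlm",
]


@dataclass(frozen=True)
class TrainingPair:
    """An image with its binary ground-truth mask."""

    image: np.ndarray  # (H, W, 3)
    mask: np.ndarray  # (H, W) values {0, 1}
    index: int = 0

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must share spatial size")


@dataclass(frozen=True)
class MMLMConfig:
    """Hyper-parameters of the mixed-maximum-loss training loop.

    The defaults are the working values of the method: lambda1=1,
    lambda2=2, N_max=40, N_min=5, K_max=15, K_min=4, Adam with
    lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-4.  Augmentation draws
    rotations within +/-20 degrees and translations within +/-5% of the
    image side.
    """

    lambda1: float = 1.0
    lambda2: float = 2.0
    n_max: int = 40
    n_min: int = 5
    k_max: int = 15
    k_min: int = 4
    epochs: int = 30
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-4
    batch_size: int = 4
    seed: int = 0
    aug_rotation_deg: float = 20.0
    aug_translate_frac: float = 0.05

    def __post_init__(self):
        if self.n_min > self.n_max or self.k_min > self.k_max:
            raise ValueError("schedule floors must not exceed their ceilings")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class AugmentOp:
    """A rotation (degrees) plus an integer-free pixel translation."""

    angle: float = 0.0
    shift: tuple = (0.0, 0.0)  # (row, col)

    @property
    def is_identity(self) -> bool:
        return self.angle == 0.0 and self.shift == (0.0, 0.0)


@dataclass
class RoundRecord:
    t: int
    n_t: int
    k_t: int
    sorted_indices: list
    mean_loss: float
    mean_f: float
    min_f: float


def schedule_n(t: int, n_max: int, n_min: int, m: int) -> int:
    """Number of hard examples at round t: max(n_max - t, n_min), clamped to m."""
    if t < 1:
        raise ValueError("rounds are 1-based")
    return min(max(n_max - t, n_min), m)


def schedule_k(t: int, k_max: int, k_min: int) -> int:
    """Augmentation folds at round t: max(k_max - floor(0.25 t), k_min)."""
    if t < 1:
        raise ValueError("rounds are 1-based")
    return max(k_max - math.floor(0.25 * t), k_min)


def evaluate_pairs(net: MSMKU, pairs: Sequence[TrainingPair], batch_size: int = 8):
    """Per-pair Dice losses and binarised F-scores in one evaluation pass."""
    losses = np.empty(len(pairs))
    fscores = np.empty(len(pairs))
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        x = np.stack([prepare_image(p.image) for p in chunk])
        probs = net.forward_batch(x, train=False)
        for i, pair in enumerate(chunk):
            prob = probs[i, :, :, 0].astype(np.float64)
            losses[start + i] = dice_loss(prob, pair.mask)
            fscores[start + i] = evaluate_masks((prob >= 0.5).astype(np.uint8), pair.mask).f_score
    return losses, fscores


def per_sample_losses(net: MSMKU, pairs: Sequence[TrainingPair], batch_size: int = 8) -> np.ndarray:
    """Dice loss of each pair under the current parameters (evaluation mode)."""
    losses = np.empty(len(pairs))
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        x = np.stack([prepare_image(p.image) for p in chunk])
        probs = net.forward_batch(x, train=False)
        for i, pair in enumerate(chunk):
            losses[start + i] = dice_loss(probs[i, :, :, 0].astype(np.float64), pair.mask)
    return losses


def rank_by_loss(net: MSMKU, pairs: Sequence[TrainingPair]) -> list:
    """Indices into ``pairs`` ordered by descending Dice loss (stable)."""
    if len(pairs) == 0:
        raise ValueError("cannot rank an empty sample list")
    losses = per_sample_losses(net, pairs)
    return list(np.argsort(-losses, kind="stable"))


def _op_rng(seed: int, t: int, k: int, j: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, t, k, j)))


def make_augment_ops(t: int, k_t: int, n_t: int, cfg: MMLMConfig, side: int) -> list:
    """A k_t x n_t grid of augmentation ops, reproducible from (seed, t, k, j)."""
    ops = []
    max_shift = cfg.aug_translate_frac * side
    for k in range(1, k_t + 1):
        row = []
        for j in range(1, n_t + 1):
            rng = _op_rng(cfg.seed, t, k, j)
            angle = rng.uniform(-cfg.aug_rotation_deg, cfg.aug_rotation_deg)
            dr = rng.uniform(-max_shift, max_shift)
            dc = rng.uniform(-max_shift, max_shift)
            if cfg.aug_rotation_deg == 0:
                angle = 0.0
            if cfg.aug_translate_frac == 0:
                dr = dc = 0.0
            row.append(AugmentOp(angle=angle, shift=(dr, dc)))
        ops.append(row)
    return ops


def apply_augment(op: AugmentOp, image: np.ndarray, mask: np.ndarray):
    """Apply the same rotation-about-centre + translation to image and mask.

    The image is interpolated bilinearly and the mask by nearest
    neighbour (so it stays binary); pixels entering from outside the
    frame are filled by reflection.
    """
    if op.is_identity:
        return image, mask
    h, w = mask.shape
    theta = np.deg2rad(op.angle)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.asarray(op.shift, dtype=float)
    # output coord y maps to input coord rot^-1 @ (y - shift - centre) + centre
    matrix = rot.T
    offset = centre - matrix @ (centre + shift)
    img = np.asarray(image)
    matrix3 = np.eye(3)
    matrix3[:2, :2] = matrix
    out_img = ndimage.affine_transform(
        img.astype(np.float64), matrix3, offset=(*offset, 0.0), order=1, mode="reflect"
    )
    if np.issubdtype(img.dtype, np.integer):
        out_img = np.clip(np.rint(out_img), 0, 255)
    out_img = out_img.astype(img.dtype)
    out_mask = ndimage.affine_transform(
        mask.astype(np.float64), matrix, offset=offset, order=0, mode="reflect"
    )
    return out_img, (out_mask > 0.5).astype(mask.dtype)


def mixed_loss(
    net: MSMKU,
    pairs: Sequence[TrainingPair],
    sorted_idx: Sequence[int],
    n_t: int,
    k_t: int,
    lambda1: float,
    lambda2: float,
    ops: Sequence[Sequence[AugmentOp]],
) -> float:
    """Evaluate the round loss L_t under the current parameters."""
    if n_t > len(pairs):
        raise ValueError("n_t exceeds the number of samples; clamp via schedule_n")
    if len(ops) != k_t or any(len(row) != n_t for row in ops):
        raise ValueError("ops must be a k_t x n_t grid")
    losses = per_sample_losses(net, pairs)
    total = lambda1 * float(losses.sum())
    if lambda2 > 0:
        for k in range(k_t):
            for j in range(n_t):
                pair = pairs[sorted_idx[j]]
                img, msk = apply_augment(ops[k][j], pair.image, pair.mask)
                prob = net.predict(img)
                total += lambda2 * dice_loss(prob, msk)
    return total


def train_mmlm(
    pairs: Sequence[TrainingPair],
    net_cfg: NetworkConfig,
    cfg: MMLMConfig,
    callback: Callable | None = None,
):
    """Train an MSMKU with mixed-maximum-loss minimisation.

    Returns ``(net, history)`` where history is a list of
    :class:`RoundRecord` (one per round, statistics measured with the
    frozen parameters used for that round's ranking).
    """
    return _train(pairs, net_cfg, cfg, strategy="mmlm", callback=callback)


def train_alm(pairs, net_cfg, cfg: MMLMConfig, callback=None):
    """Plain average-loss training: the lambda2 = 0 degeneration."""
    cfg = replace(cfg, lambda2=0.0)
    return _train(pairs, net_cfg, cfg, strategy="alm", callback=callback)


def train_mlm(pairs, net_cfg, cfg: MMLMConfig, callback=None):
    """Top-N_t maximal-loss training: lambda1 = 0, identity ops, K_t = 1."""
    cfg = replace(cfg, lambda1=0.0, aug_rotation_deg=0.0, aug_translate_frac=0.0)
    return _train(pairs, net_cfg, cfg, strategy="mlm", callback=callback)


def _train(pairs, net_cfg, cfg, strategy, callback=None):
    if len(pairs) < 2:
        raise ValueError("need at least two training pairs")
    m = len(pairs)
    net = build_msmku(net_cfg)
    opt = Adam(net.params(), lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.epsilon)
    history = []
    prepared = [prepare_image(p.image) for p in pairs]
    masks = [p.mask.astype(np.float64) for p in pairs]
    for t in range(1, cfg.epochs + 1):
        # rank with frozen previous-round parameters
        losses, fs = evaluate_pairs(net, pairs)
        sorted_idx = list(np.argsort(-losses, kind="stable"))
        n_t = schedule_n(t, cfg.n_max, cfg.n_min, m)
        k_t = 1 if strategy == "mlm" else schedule_k(t, cfg.k_max, cfg.k_min)
        # build the weighted multiset for this round
        entries = []  # (prepared_image, mask, weight)
        if cfg.lambda1 > 0:
            entries.extend((prepared[i], masks[i], cfg.lambda1) for i in range(m))
        if cfg.lambda2 > 0:
            side = net_cfg.input_side
            ops = make_augment_ops(t, k_t, n_t, cfg, side)
            for k in range(k_t):
                for j in range(n_t):
                    pair = pairs[sorted_idx[j]]
                    img, msk = apply_augment(ops[k][j], pair.image, pair.mask)
                    entries.append((prepare_image(img), msk.astype(np.float64), cfg.lambda2))
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, t, 0xE90C)))
        order = rng.permutation(len(entries))
        for start in range(0, len(entries), cfg.batch_size):
            batch = [entries[i] for i in order[start : start + cfg.batch_size]]
            x = np.stack([b[0] for b in batch])
            probs = net.forward_batch(x, train=True)
            dp = np.empty_like(probs)
            for i, (_, msk, weight) in enumerate(batch):
                grad = dice_loss_grad(probs[i, :, :, 0].astype(np.float64), msk)
                dp[i, :, :, 0] = (weight * grad).astype(probs.dtype)
            net.zero_grad()
            net.backward_batch(dp)
            opt.step()
        rec = RoundRecord(
            t=t,
            n_t=n_t,
            k_t=k_t,
            sorted_indices=sorted_idx,
            mean_loss=float(losses.mean()),
            mean_f=float(np.mean(fs)),
            min_f=float(np.min(fs)),
        )
        history.append(rec)
        if callback is not None:
            callback(net, rec)
    return net, history
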