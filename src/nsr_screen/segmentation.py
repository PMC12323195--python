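"""Flushing-area segmentation: model, patient-level splits, Dice/IoU.

The segmenter is a configurable-depth U-Net mapping a calibrated
128 x 512 RGB image to a per-pixel flushing probability, trained with a
Dice + binary-cross-entropy loss and runtime paired augmentation.  Data are
always split at the participant level so that no person's images appear in
more than one of train/validation/test.  Predicted probability maps are
thresholded at 0.5 with no morphological post-processing, so evaluation
reflects the raw model output.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adam, UNet, dice_bce_loss
from .io_consensus import BinaryMask, NsrImage
from .preprocess import AugmentParams, augment_pair


@dataclass
class SegModelConfig:
    """Architecture and optimisation settings for the segmenter."""

    encoder_depth: int = 3
    base_channels: int = 16
    input_hw: tuple[int, int] = (128, 512)
    loss: str = "dice+bce"  # one of dice+bce, bce, dice
    lr: float = 1e-3
    epochs: int = 10
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_depth < 2:
            raise ValueError("encoder_depth must be >= 2")
        h, w = self.input_hw
        if h % 2 ** self.encoder_depth or w % 2 ** self.encoder_depth:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{self.encoder_depth}"
            )
        if self.loss not in ("dice+bce", "bce", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class SplitSpec:
    """Disjoint participant-id sets covering the cohort."""

    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.train_ids & self.val_ids or self.train_ids & self.test_ids
                or self.val_ids & self.test_ids):
            raise ValueError("split sets must be pairwise disjoint")

    def split_of(self, participant_id: str) -> str:
        for name, ids in (("train", self.train_ids), ("val", self.val_ids),
                          ("test", self.test_ids)):
            if participant_id in ids:
                return name
        raise KeyError(participant_id)


@dataclass
class SegMetrics:
    dice: float
    iou: float
    per_image: list[tuple[float, float]] = field(default_factory=list)


def split_by_participant(
    participant_ids: Sequence[str],
    fractions: tuple[int, int, int] = (90, 10, 20),
    seed: int = 0,
) -> SplitSpec:
    """Deterministic participant-level train/val/test split.

    ``fractions`` are relative weights (the reference cohort of 120 splits
    90/10/20); other cohort sizes are scaled proportionally with
    largest-remainder rounding so the three sizes sum to the cohort size and
    every part with a positive weight gets at least one participant.
    """
    ids = list(dict.fromkeys(participant_ids))
    n = len(ids)
    if n < 3:
        raise ValueError(f"cohort of {n} too small to split three ways")
    total = sum(fractions)
    exact = [n * f / total for f in fractions]
    sizes = [int(e) for e in exact]
    # largest remainder, then guarantee non-empty parts
    order = np.argsort([s - e for s, e in zip(sizes, exact)])
    for i in order[: n - sum(sizes)]:
        sizes[int(i)] += 1
    for i in range(3):
        if sizes[i] == 0 and fractions[i] > 0:
            j = int(np.argmax(sizes))
            sizes[j] -= 1
            sizes[i] += 1
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitSpec(
        train_ids=frozenset(shuffled[:a]),
        val_ids=frozenset(shuffled[a:b]),
        test_ids=frozenset(shuffled[b:]),
        seed=seed,
    )


# --------------------------------------------------------------------------
# metrics


def _counts(pred: BinaryMask, gt: BinaryMask) -> tuple[int, int, int]:
    if pred.pixels.shape != gt.pixels.shape:
        raise ValueError(
            f"mask shapes differ: {pred.pixels.shape} vs {gt.pixels.shape}"
        )
    inter = int(np.logical_and(pred.pixels, gt.pixels).sum())
    return inter, pred.area_px, gt.area_px


def dice(pred: BinaryMask, gt: BinaryMask) -> float:
    """Dice overlap 2|P∩G| / (|P|+|G|); 1.0 when both masks are empty."""
    inter, p, g = _counts(pred, gt)
    if p + g == 0:
        return 1.0
    return 2.0 * inter / (p + g)


def iou(pred: BinaryMask, gt: BinaryMask) -> float:
    """Intersection over union |P∩G| / |P∪G|; 1.0 when both masks are empty."""
    inter, p, g = _counts(pred, gt)
    union = p + g - inter
    if union == 0:
        return 1.0
    return inter / union


# --------------------------------------------------------------------------
# model


class Segmenter:
    """Handle pairing a U-Net with its configuration."""

    def __init__(self, config: SegModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.net = UNet(depth=config.encoder_depth,
                        base_channels=config.base_channels, rng=rng)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def _to_batch(self, images: Sequence[NsrImage]) -> np.ndarray:
        h, w = self.config.input_hw
        batch = np.empty((len(images), h, w, 3), dtype=np.float32)
        for i, img in enumerate(images):
            if img.shape_hw != (h, w):
                raise ValueError(
                    f"image {img.participant_id} t{img.time_min} has shape "
                    f"{img.shape_hw}, expected {(h, w)}"
                )
            batch[i] = img.pixels.astype(np.float32) / 255.0
        return batch

    def predict_proba(self, images: Sequence[NsrImage]) -> np.ndarray:
        return self.net.forward(self._to_batch(images))[..., 0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "state": self.net.state_dict()}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "Segmenter":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["config"])
        model.net.load_state_dict(blob["state"])
        return model


def build_segmenter(config: SegModelConfig) -> Segmenter:
    """Instantiate a segmenter; weights are seeded from ``config.seed``."""
    return Segmenter(config)


def predict_mask(model: Segmenter, image: NsrImage, threshold: float = 0.5) -> BinaryMask:
    """Threshold the probability map at ``threshold`` (>= counts as foreground)."""
    proba = model.predict_proba([image])[0]
    return BinaryMask(pixels=proba >= threshold, kind="flush")


def evaluate(model: Segmenter, images: Sequence[NsrImage],
             masks: Sequence[BinaryMask], threshold: float = 0.5,
             batch_size: int = 8) -> SegMetrics:
    """Macro-averaged Dice/IoU: computed per image, then averaged."""
    per_image: list[tuple[float, float]] = []
    for start in range(0, len(images), batch_size):
        chunk = list(images[start:start + batch_size])
        probs = model.predict_proba(chunk)
        for proba, gt in zip(probs, masks[start:start + batch_size]):
            pred = BinaryMask(pixels=proba >= threshold, kind="flush")
            per_image.append((dice(pred, gt), iou(pred, gt)))
    arr = np.asarray(per_image, dtype=float)
    return SegMetrics(dice=float(arr[:, 0].mean()), iou=float(arr[:, 1].mean()),
                      per_image=per_image)


def train_segmenter(
    model: Segmenter,
    train_images: Sequence[NsrImage],
    train_masks: Sequence[BinaryMask],
    val_images: Sequence[NsrImage] = (),
    val_masks: Sequence[BinaryMask] = (),
    augment: AugmentParams | None = None,
    max_steps: int | None = None,
) -> dict:
    """Train with Adam, tracking validation Dice; keeps the best-val weights.

    Augmentation, when given, applies a fresh paired draw to every sample at
    every epoch; draws derive from ``config.seed`` so training is
    deterministic.  Returns a history dict with per-epoch mean loss and
    validation Dice.  Aborts on non-finite loss.
    """
    if len(train_images) == 0:
        raise ValueError("empty training set")
    if len(train_images) != len(train_masks):
        raise ValueError("images and masks must pair up")
    cfg = model.config
    opt = Adam(model.net.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history: dict = {"loss": [], "val_dice": [], "epochs_run": 0}
    best = {"dice": -1.0, "state": model.net.state_dict()}

    def val_dice() -> float:
        if len(val_images) == 0:
            return float("nan")
        return evaluate(model, val_images, val_masks).dice

    steps = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_images))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            ims, msks = [], []
            for i in idx:
                img, msk = train_images[i], train_masks[i]
                if augment is not None:
                    img, msk = augment_pair(img, msk, augment,
                                            draw_seed=int(rng.integers(2 ** 31)))
                ims.append(img)
                msks.append(msk)
            x = model._to_batch(ims)
            y = np.stack([m.pixels for m in msks]).astype(np.float32)[..., None]
            p, cache = model.net.forward(x, want_cache=True)
            loss, dz = dice_bce_loss(p, cache[4], y, mode=cfg.loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch} step {steps}"
                )
            grads = model.net.backward(dz, cache)
            opt.step(model.net.params, grads)
            losses.append(loss)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        vd = val_dice()
        history["loss"].append(float(np.mean(losses)))
        history["val_dice"].append(vd)
        history["epochs_run"] = epoch + 1
        if not np.isnan(vd) and vd > best["dice"]:
            best = {"dice": vd, "state": model.net.state_dict()}
        if max_steps is not None and steps >= max_steps:
            break
    if best["dice"] >= 0:
        model.net.load_state_dict(best["state"])
        history["best_val_dice"] = best["dice"]
    return history
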