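"""Class-balanced sampling, augmentation, training loop, and prediction."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from ..labels import LabelTrack, to_onehot
from ..preprocess import BinaryDiffStack, GroupedImage
from .arch import ModelConfig, build_model
from .nn import AMSGrad, Sequential, softmax, softmax_cross_entropy

ROTATION_STEP_DEG = 20


@dataclass(frozen=True)
class EpochPlan:
    """How many grouped images of each class one epoch draws (with replacement)."""

    n_not: int = 1000
    n_face: int = 200
    n_body: int = 400
    batch_size: int = 8
    replace: bool = True

    def __post_init__(self) -> None:
        if min(self.n_not, self.n_face, self.n_body) <= 0:
            raise ValueError("per-class epoch counts must be positive")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")

    @property
    def per_class(self) -> dict[int, int]:
        return {0: self.n_not, 1: self.n_face, 2: self.n_body}

    @property
    def total(self) -> int:
        return self.n_not + self.n_face + self.n_body


class SamplingError(ValueError):
    pass


def sample_epoch(labels: np.ndarray | LabelTrack, plan: EpochPlan,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw one epoch's worth of indices, class-balanced per the plan.

    Returns a shuffled array of ``plan.total`` indices into the pool; each
    class contributes exactly its planned count, duplicates allowed.
    """
    pool = labels.values if isinstance(labels, LabelTrack) else np.asarray(labels)
    parts = []
    class_names = {0: "not grooming", 1: "facial grooming", 2: "body grooming"}
    for cls, n in plan.per_class.items():
        candidates = np.flatnonzero(pool == cls)
        if candidates.size == 0:
            raise SamplingError(f"no '{class_names[cls]}' (label {cls}) samples in pool")
        parts.append(rng.choice(candidates, size=n, replace=plan.replace))
    idx = np.concatenate(parts)
    rng.shuffle(idx)
    return idx


def rotate_stack(stack: np.ndarray, k: int) -> np.ndarray:
    """Rotate all frames of a (D, S, S) binary stack by k*20 degrees.

    Nearest-neighbor resampling keeps the stack binary; k = 0 is identity.
    """
    if k % 18 == 0:
        return stack
    rot = ndimage.rotate(stack, angle=k * ROTATION_STEP_DEG, axes=(1, 2),
                         order=0, reshape=False, mode="constant", cval=0)
    return (rot > 0.5).astype(stack.dtype)


def augment(stack: GroupedImage | np.ndarray, rng: np.random.Generator):
    """Random rotation by a multiple of 20 degrees plus independent H/V flips."""
    arr = stack.stack if isinstance(stack, GroupedImage) else np.asarray(stack)
    k = int(rng.integers(0, 18))
    flip_h = bool(rng.integers(0, 2))
    flip_v = bool(rng.integers(0, 2))
    out = rotate_stack(arr, k)
    if flip_h:
        out = out[:, :, ::-1]
    if flip_v:
        out = out[:, ::-1, :]
    if isinstance(stack, GroupedImage):
        return GroupedImage(np.ascontiguousarray(out), t=stack.t, w=stack.w)
    return np.ascontiguousarray(out)


@dataclass
class TrainedModel:
    net: Sequential
    config: ModelConfig
    loss_history: list[float] = field(default_factory=list)
    val_history: list[tuple[int, float]] = field(default_factory=list)


def _as_batch(stacks, idx) -> np.ndarray:
    mats = [np.asarray(s.stack if isinstance(s, GroupedImage) else s) for s in
            (stacks[i] for i in idx)]
    x = np.stack(mats).astype(np.float32)
    return x[..., None]  # (N, D, S, S, 1)


def train(
    model: Sequential | TrainedModel,
    data: tuple[Sequence, np.ndarray],
    plan: EpochPlan,
    config: ModelConfig,
    epochs: int,
    rng: np.random.Generator | None = None,
    validation: tuple[Sequence, np.ndarray] | None = None,
    val_every: int = 200,
    log_path: str | Path | None = None,
) -> TrainedModel:
    """Train with AMSGrad on categorical cross-entropy.

    ``data`` is ``(stacks, labels)``: a sequence of (2w+1, S, S) binary
    stacks and their integer labels.  Class balance comes from the epoch
    plan alone (no loss weighting).  Fully reproducible for a fixed seed.
    """
    if isinstance(model, TrainedModel):
        trained = model
        net = model.net
    else:
        net = model
        trained = TrainedModel(net=net, config=config)
    stacks, pool_labels = data
    pool_labels = np.asarray(pool_labels)
    if len(stacks) == 0 or len(stacks) != pool_labels.size:
        raise ValueError("data must be a non-empty (stacks, labels) pair of equal length")
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    opt = AMSGrad(net.params(), lr=config.learning_rate)
    log_rows = []
    for epoch in range(epochs):
        idx = sample_epoch(pool_labels, plan, rng)
        losses = []
        for start in range(0, idx.size, plan.batch_size):
            batch = idx[start:start + plan.batch_size]
            x = np.stack([
                augment(np.asarray(stacks[i]), rng) for i in batch
            ]).astype(np.float32)[..., None]
            y = to_onehot(pool_labels[batch])
            logits = net.forward(x, training=True)
            loss, dlogits = softmax_cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // plan.batch_size}: {loss}"
                )
            net.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        trained.loss_history.append(epoch_loss)
        row = {"epoch": epoch, "loss": epoch_loss}
        if validation is not None and (epoch + 1) % val_every == 0:
            acc = _eval_accuracy(net, validation)
            trained.val_history.append((epoch, acc))
            row["val_accuracy"] = acc
        log_rows.append(row)
    if log_path is not None:
        _write_log(log_rows, log_path)
    return trained


def _eval_accuracy(net: Sequential, validation) -> float:
    stacks, labels = validation
    probs = predict_probs(net, stacks)
    pred = np.argmax(probs, axis=1)
    return float(np.mean(pred == np.asarray(labels)))


def _write_log(rows, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("epoch,loss,val_accuracy\n")
        for row in rows:
            va = row.get("val_accuracy")
            fh.write(f"{row['epoch']},{row['loss']:.6f},{'' if va is None else f'{va:.4f}'}\n")


def predict_probs(model: TrainedModel | Sequential, stacks, batch_size: int = 64) -> np.ndarray:
    """Per-stack class probabilities (softmax over the 3 logits), eval mode."""
    net = model.net if isinstance(model, TrainedModel) else model
    n = len(stacks)
    out = np.empty((n, 3), dtype=np.float64)
    for start in range(0, n, batch_size):
        idx = range(start, min(start + batch_size, n))
        x = _as_batch(stacks, idx)
        logits = net.forward(x, training=False)
        if logits.shape[-1] != 3:
            raise ValueError(f"model emitted {logits.shape[-1]} classes, expected 3")
        out[start:start + len(x)] = softmax(logits.astype(np.float64))
    return out


def argmax_labels(probs: np.ndarray, source_id: str = "") -> LabelTrack:
    """Most probable class per frame; ties go to the smallest class index."""
    probs = np.asarray(probs)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError("expected (n, 3) probability array")
    return LabelTrack(np.argmax(probs, axis=1), source_id=source_id)


def predict_stack(
    model: TrainedModel, stack: BinaryDiffStack, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Slide the model over a diff stack at stride 1.

    Returns ``(centers, probs)`` where centers are the valid diff-stack
    times ``t`` in ``[w, len(stack)-1-w]``.
    """
    w = model.config.w
    n = len(stack)
    centers = np.arange(w, n - w)
    if centers.size == 0:
        return centers, np.empty((0, 3))
    views = [stack.frames[t - w:t + w + 1] for t in centers]
    return centers, predict_probs(model, views, batch_size=batch_size)


# ---------------------------------------------------------------------------
# Checkpoints and prediction CSV.
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params())}
    np.savez_compressed(
        Path(path),
        config=model.config.to_json(),
        loss_history=np.asarray(model.loss_history, dtype=np.float64),
        **arrays,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as data:
        config = ModelConfig.from_json(str(data["config"]))
        net = build_model(config)
        for i, p in enumerate(net.params()):
            stored = data[f"p{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint mismatch for parameter {i}")
            p.value[...] = stored
        return TrainedModel(net=net, config=config,
                            loss_history=list(data["loss_history"]))


def write_prediction_csv(path: str | Path, frames: np.ndarray, probs: np.ndarray,
                         labels: LabelTrack | np.ndarray) -> None:
    values = labels.values if isinstance(labels, LabelTrack) else np.asarray(labels)
    with Path(path).open("w") as fh:
        fh.write("frame,p0,p1,p2,label_raw\n")
        for f, p, lab in zip(frames, probs, values):
            fh.write(f"{int(f)},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},{int(lab)}\n")


def read_prediction_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    needed = ["frame", "p0", "p1", "p2", "label_raw"]
    if list(df.columns[:5]) != needed:
        raise ValueError(f"{path}: expected columns {needed}")
    return (df["frame"].to_numpy(), df[["p0", "p1", "p2"]].to_numpy(),
            df["label_raw"].to_numpy())
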