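"""Two-phase training: pre-train on synthetic degradation, then fine-tune.

The workflow mirrors how the grader is meant to be deployed: clean
volumes (quality grades 1–2) are artificially smeared at five distortion
levels to pre-train the network on a large, perfectly labeled corpus;
transfer learning then refines those weights on the (smaller) target
dataset. Observer grades are reduced to a consensus label by the median;
train/test splitting is grouped by subject to prevent a patient's
follow-up scans leaking across the split.

Loss: the five sigmoid outputs are trained with per-unit binary
cross-entropy against a one-hot target, matching their independence (no
softmax coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.model_selection import GroupShuffleSplit, ShuffleSplit

from .nn.model import Model
from .nn.layers import Flatten, GlobalAvgPool3D, Sigmoid
from .nn.optim import Adam
from .phantom import GradedVolume, augment, degrade, sample_motion_kernel

__all__ = [
    "TrainingConfig",
    "Split",
    "TrainResult",
    "consensus_label",
    "split_dataset",
    "make_pretraining_set",
    "pretrain",
    "finetune",
    "bce_loss",
    "one_hot",
]


@dataclass(frozen=True)
class TrainingConfig:
    split_fraction: float = 0.8
    batch_size: int = 4
    epochs_pretrain: int = 4
    epochs_finetune: int = 6
    learning_rate: float = 2e-3
    lr_schedule: str = "cosine"  # or "constant"
    head_refine_epochs: int = 300
    augment_each_epoch: bool = True
    seed: int = 0
    group_split: bool = True
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class Split:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass
class TrainResult:
    weights: list[np.ndarray]
    loss_curve: list[float] = field(default_factory=list)
    head_curve: list[float] = field(default_factory=list)


def consensus_label(observer_grades: list[int]) -> int:
    """Median of an odd number of ordinal grades (default three observers).

    On an ordinal scale the median of an even count is ambiguous, so even
    counts are rejected rather than silently interpolated.
    """
    n = len(observer_grades)
    if n == 0 or n % 2 == 0:
        raise ValueError(
            f"need an odd number of observer grades (got {n}); "
            "the median of an even count is ambiguous on an ordinal scale"
        )
    for g in observer_grades:
        if not (1 <= int(g) <= 5) or int(g) != g:
            raise ValueError(f"grades must be integers in 1..5, got {g!r}")
    return int(sorted(int(g) for g in observer_grades)[n // 2])


def split_dataset(
    data: list[GradedVolume],
    config: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> Split:
    """80/20 (by default) train/test split, grouped by subject.

    With ``group_split`` no subject appears on both sides; the realized
    test fraction is then exact only up to group granularity.
    """
    if len(data) < 5:
        raise ValueError("need at least 5 items to split")
    rng = rng or np.random.default_rng(config.seed)
    state = int(rng.integers(0, 2**31 - 1))
    test_size = 1.0 - config.split_fraction
    ids = np.array([g.uid for g in data])
    if config.group_split:
        groups = [g.subject_id for g in data]
        if len(set(groups)) < 2:
            raise ValueError(
                "grouped split impossible: all items share one subject_id"
            )
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=state)
        train_idx, test_idx = next(splitter.split(ids, groups=groups))
    else:
        splitter = ShuffleSplit(n_splits=1, test_size=test_size, random_state=state)
        train_idx, test_idx = next(splitter.split(ids))
    return Split(
        train_ids=tuple(ids[sorted(train_idx)]),
        test_ids=tuple(ids[sorted(test_idx)]),
    )


def make_pretraining_set(
    clean: list[GradedVolume],
    n_per_level: int,
    rng: np.random.Generator,
) -> list[GradedVolume]:
    """Build a balanced synthetic pre-training corpus from clean volumes.

    Only grade-1/2 inputs are accepted (smearing an already-corrupted
    volume would mislabel the result). Each output samples a clean
    volume, applies a random mirror/rotation augmentation, then smears it
    with a kernel drawn for its level; the label is the level itself.
    """
    if not clean:
        raise ValueError("clean pool must be non-empty")
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    for g in clean:
        if g.grade > 2:
            raise ValueError(
                f"pre-training inputs must have grade <= 2; {g.uid!r} has grade {g.grade}"
            )
    out: list[GradedVolume] = []
    i = 0
    for level in range(1, 6):
        for _ in range(n_per_level):
            src = clean[int(rng.integers(len(clean)))]
            vol = augment(src.volume, rng)
            kernel = sample_motion_kernel(level, rng, max_support=min(vol.shape))
            vol = degrade(vol, kernel)
            out.append(
                GradedVolume(
                    volume=vol,
                    grade=level,
                    subject_id=src.subject_id,
                    origin="synthetic_level",
                    uid=f"pre{i:05d}-L{level}",
                )
            )
            i += 1
    return out


def one_hot(grades: np.ndarray, n_classes: int = 5) -> np.ndarray:
    t = np.zeros((len(grades), n_classes), dtype=np.float32)
    t[np.arange(len(grades)), np.asarray(grades) - 1] = 1.0
    return t


def bce_loss(scores: np.ndarray, targets: np.ndarray,
             weights: np.ndarray | None = None) -> float:
    """Mean-over-batch sum of per-unit binary cross-entropies."""
    s = np.clip(scores, 1e-7, 1.0 - 1e-7)
    per_unit = -(targets * np.log(s) + (1.0 - targets) * np.log(1.0 - s))
    if weights is not None:
        per_unit = per_unit * weights[:, None]
    return float(per_unit.sum(axis=1).mean())


def _as_batch(items: list[GradedVolume], idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([items[i].volume.data for i in idx])[:, None].astype(np.float32)
    y = one_hot(np.array([items[i].grade for i in idx]))
    return x, y


def _train_model(
    model: Model,
    dataset: list[GradedVolume],
    config: TrainingConfig,
    epochs: int,
    seed_offset: int = 0,
) -> TrainResult:
    rng = np.random.default_rng(config.seed + seed_offset)
    model.set_dropout_rng(np.random.default_rng(config.seed + seed_offset + 1))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = len(dataset)
    sample_w = None
    if config.class_weighting:
        grades = np.array([g.grade for g in dataset])
        counts = np.bincount(grades, minlength=6)[1:].astype(float)
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        inv = inv / inv[counts > 0].mean()
        sample_w = inv  # indexed by grade-1 below
    curve: list[float] = []
    assert isinstance(model.layers[-1], Sigmoid)
    hidden = model.layers[:-1]
    n_batches = max(1, -(-n // config.batch_size))
    total_steps = max(1, epochs * n_batches)
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            if config.lr_schedule == "cosine":
                # decay to 5% of the base rate over the run
                frac = step / total_steps
                opt.lr = config.learning_rate * (
                    0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * frac))
                )
            step += 1
            idx = order[start : start + config.batch_size]
            x, t = _as_batch(dataset, idx)
            if config.augment_each_epoch:
                # fresh mirror/rotation per sample per epoch: free data
                # diversity, and the quality grade is invariant under it
                from .phantom import sample_symmetry

                for j in range(len(idx)):
                    tr = sample_symmetry(x.shape[2:], rng)
                    x[j, 0] = tr.apply(x[j, 0])
            h = np.ascontiguousarray(np.moveaxis(x, 1, -1))  # channels-last
            for layer in hidden:
                h = layer.forward(h, train=True)
            scores = expit(h)
            bw = None
            if sample_w is not None:
                bw = sample_w[np.array([dataset[i].grade for i in idx]) - 1]
            loss = bce_loss(scores, t, bw)
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training loss is NaN/Inf; try a lower learning rate "
                    f"(current {config.learning_rate})"
                )
            losses.append(loss)
            # d(BCE)/d(logits) = (sigma - target), bypassing the sigmoid layer
            dlogits = (scores - t).astype(np.float32) / len(idx)
            if bw is not None:
                dlogits *= bw[:, None].astype(np.float32)
            model.zero_grad()
            g = dlogits
            for layer in reversed(hidden):
                g = layer.backward(g)
            opt.step(model.gradients())
        curve.append(float(np.mean(losses)))
    head_curve: list[float] = []
    if config.head_refine_epochs > 0:
        head_curve = _refine_head(model, dataset, config, rng)
    return TrainResult(
        weights=model.get_weights(), loss_curve=curve, head_curve=head_curve
    )


def _refine_head(
    model: Model,
    dataset: list[GradedVolume],
    config: TrainingConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Refit the fully connected head to convergence on frozen trunk features.

    Backprop through the convolutional trunk dominates the cost of a
    training step, so the main loop affords only a few hundred updates —
    enough to learn well-ranked features but not to calibrate the five
    output scores against each other. Caching the pooled trunk features
    once and training the ~8k-parameter head on them for a few hundred
    more epochs costs almost nothing and fixes that calibration.
    """
    pool_idx = next(
        i for i, l in enumerate(model.layers)
        if isinstance(l, (GlobalAvgPool3D, Flatten))
    )
    trunk = model.layers[: pool_idx + 1]
    head = model.layers[pool_idx + 1 : -1]  # exclude the sigmoid
    n = len(dataset)

    rows = []
    for start in range(0, n, 16):
        idx = np.arange(start, min(start + 16, n))
        x, _ = _as_batch(dataset, idx)
        h = np.ascontiguousarray(np.moveaxis(x, 1, -1))
        for layer in trunk:
            h = layer.forward(h, train=False)
        rows.append(h)
    feats = np.concatenate(rows).astype(np.float32)
    targets = one_hot(np.array([g.grade for g in dataset]))

    params = [p for layer in head for p in layer.params.values()]
    grads = [g for layer in head for g in layer.grads.values()]
    opt = Adam(params, lr=config.learning_rate)
    batch = 32
    total = max(1, config.head_refine_epochs * -(-n // batch))
    step = 0
    curve: list[float] = []
    for _epoch in range(config.head_refine_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            if config.lr_schedule == "cosine":
                opt.lr = config.learning_rate * (
                    0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * step / total))
                )
            step += 1
            idx = order[start : start + batch]
            h = feats[idx]
            for layer in head:
                h = layer.forward(h, train=True)
            scores = expit(h)
            t = targets[idx]
            losses.append(bce_loss(scores, t))
            for g in grads:
                g[...] = 0.0
            d = (scores - t).astype(np.float32) / len(idx)
            for layer in reversed(head):
                d = layer.backward(d)
            opt.step(grads)
        curve.append(float(np.mean(losses)))
    return curve


def pretrain(
    model: Model,
    pretraining_set: list[GradedVolume],
    config: TrainingConfig,
) -> TrainResult:
    """Phase 1: train on the synthetic degradation corpus."""
    if not pretraining_set:
        raise ValueError("pre-training set must be non-empty")
    return _train_model(model, pretraining_set, config, config.epochs_pretrain)


def finetune(
    model: Model,
    pretrained_weights: list[np.ndarray],
    labeled: list[GradedVolume],
    config: TrainingConfig,
) -> TrainResult:
    """Phase 2: transfer learning — refine pre-trained weights on labeled data.

    The model is initialized exactly from ``pretrained_weights``; with
    zero fine-tune epochs the returned weights are bit-identical to them.
    """
    if not labeled:
        raise ValueError("labeled set must be non-empty")
    model.set_weights(pretrained_weights)
    if config.epochs_finetune == 0:
        return TrainResult(weights=model.get_weights(), loss_curve=[])
    return _train_model(
        model, labeled, config, config.epochs_finetune, seed_offset=7919
    )
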