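"""Inference, stack/scan grading rules, and evaluation metrics.

A stack's grade is the most severe (maximum) grade observed within it; a
scan's grade is likewise the maximum over its stacks. Metrics follow the
one-vs-rest reduction: the confusion matrix is reported as counts and
row-normalized percentages, and ROC-AUC, specificity and precision are
macro-averaged over the five classes (classes with zero support are
excluded from the macro mean and flagged).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .nn.model import Model
from .volume import Volume

__all__ = [
    "GradePrediction",
    "EvaluationReport",
    "fit_to_shape",
    "predict_grade",
    "stack_grade",
    "evaluate",
    "grade_report",
]

N_CLASSES = 5


@dataclass(frozen=True)
class GradePrediction:
    """Five sigmoid scores and the argmax grade (ties break to the lower grade)."""

    scores: tuple[float, ...]
    grade: int
    id: str = ""

    @staticmethod
    def from_scores(scores: np.ndarray, id: str = "") -> "GradePrediction":
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} scores, got shape {scores.shape}")
        # np.argmax returns the first maximum: index 0 = grade 1, so ties
        # resolve toward the lower (better-quality) grade deterministically.
        grade = int(np.argmax(scores)) + 1
        return GradePrediction(scores=tuple(float(s) for s in scores), grade=grade, id=id)


@dataclass
class EvaluationReport:
    confusion: np.ndarray  # 5x5 counts, rows = truth
    confusion_pct: np.ndarray  # row-normalized to percent; NaN rows flagged
    accuracy: float
    roc_auc: float | None
    specificity: float
    precision: float
    n: int
    zero_support_classes: list[int] = field(default_factory=list)
    auc_definition: str = "macro one-vs-rest on sigmoid scores"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "roc_auc": self.roc_auc,
            "specificity": self.specificity,
            "precision": self.precision,
            "confusion": self.confusion.tolist(),
            "confusion_pct": [
                [None if np.isnan(v) else v for v in row] for row in self.confusion_pct
            ],
            "zero_support_classes": self.zero_support_classes,
            "auc_definition": self.auc_definition,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def fit_to_shape(data: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """Center-crop and/or zero-pad a volume to the network input shape."""
    out = data
    for ax, t in enumerate(target):
        cur = out.shape[ax]
        if cur > t:
            start = (cur - t) // 2
            out = np.take(out, np.arange(start, start + t), axis=ax)
        elif cur < t:
            before = (t - cur) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (before, t - cur - before)
            out = np.pad(out, pad)
    return out.astype(np.float32)


def predict_grade(model: Model, volume: Volume, id: str = "") -> GradePrediction:
    """Grade a single (normalized, [0, 1]) volume with the trained model."""
    data = fit_to_shape(volume.data, model.config.input_shape)
    scores = model.forward(data[None, None], train=False)[0]
    return GradePrediction.from_scores(scores, id=id or volume.meta.get("source", ""))


def predict_batch(
    model: Model,
    volumes: list[Volume],
    batch_size: int = 16,
    symmetry_views: int = 1,
) -> list[GradePrediction]:
    """Batched inference; optionally average scores over symmetry views.

    The quality grade is invariant under axis mirrors and 90-degree
    rotations (the degradation orientation is uniformly random), so with
    ``symmetry_views > 1`` the scores are averaged over that many
    shape-preserving group elements — a deterministic variance reduction.
    """
    transforms: list = [None]
    preds: list[GradePrediction] = []
    if symmetry_views > 1:
        from .phantom import SymmetryTransform, _admissible_perms

        shape = model.config.input_shape
        all_t = [
            SymmetryTransform(perm=p, flips=f)
            for p in _admissible_perms(shape)
            for f in [(bool(a), bool(b), bool(c))
                      for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        ]
        step = max(1, len(all_t) // symmetry_views)
        transforms = all_t[::step][:symmetry_views]
    for start in range(0, len(volumes), batch_size):
        chunk = volumes[start : start + batch_size]
        x = np.stack(
            [fit_to_shape(v.data, model.config.input_shape) for v in chunk]
        )[:, None]
        total = np.zeros((len(chunk), N_CLASSES))
        for t in transforms:
            if t is None:
                xt = x
            else:
                xt = np.stack([t.apply(x[j, 0]) for j in range(len(chunk))])[:, None]
            total += model.forward(xt, train=False)
        scores = total / len(transforms)
        for j, v in enumerate(chunk):
            preds.append(
                GradePrediction.from_scores(scores[j], id=v.meta.get("source", ""))
            )
    return preds


def stack_grade(grades: list[int]) -> int:
    """Most-severe rule: a stack's grade is the maximum grade within it."""
    if not grades:
        raise ValueError("stack_grade requires a non-empty list of grades")
    for g in grades:
        if not (1 <= g <= 5):
            raise ValueError(f"grades must be in 1..5, got {g}")
    return max(grades)


def evaluate(
    predictions: list[GradePrediction], truths: list[int]
) -> EvaluationReport:
    """Confusion matrix, accuracy, macro OvR ROC-AUC/specificity/precision."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    if not predictions:
        raise ValueError("cannot evaluate an empty prediction set")
    y_true = np.asarray(truths, dtype=int)
    if y_true.min() < 1 or y_true.max() > N_CLASSES:
        raise ValueError("truths must be in 1..5")
    y_pred = np.array([p.grade for p in predictions])
    labels = np.arange(1, N_CLASSES + 1)
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    n = len(y_true)
    accuracy = float(np.trace(conf)) / n

    row_sums = conf.sum(axis=1)
    conf_pct = np.full((N_CLASSES, N_CLASSES), np.nan)
    supported = row_sums > 0
    conf_pct[supported] = 100.0 * conf[supported] / row_sums[supported, None]
    zero_support = [int(l) for l, s in zip(labels, supported) if not s]

    spec_vals, prec_vals = [], []
    for i in range(N_CLASSES):
        if not supported[i]:
            continue
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        tn = n - tp - fp - fn
        spec_vals.append(tn / (tn + fp) if (tn + fp) > 0 else np.nan)
        prec_vals.append(tp / (tp + fp) if (tp + fp) > 0 else 0.0)
    specificity = float(np.nanmean(spec_vals))
    precision = float(np.nanmean(prec_vals))

    scores = np.array([p.scores for p in predictions])
    auc: float | None
    aucs = []
    for i in range(N_CLASSES):
        pos = y_true == i + 1
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos.astype(int), scores[:, i]))
    auc = float(np.mean(aucs)) if aucs else None

    return EvaluationReport(
        confusion=conf,
        confusion_pct=conf_pct,
        accuracy=accuracy,
        roc_auc=auc,
        specificity=specificity,
        precision=precision,
        n=n,
        zero_support_classes=zero_support,
    )


def render_confusion(report: EvaluationReport, path: str) -> None:
    """Render the row-normalized confusion matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    pct = np.nan_to_num(report.confusion_pct)
    im = ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
    labels = [str(g) for g in range(1, N_CLASSES + 1)]
    ax.set_xticks(range(N_CLASSES), labels)
    ax.set_yticks(range(N_CLASSES), labels)
    ax.set_xlabel("predicted grade")
    ax.set_ylabel("reference grade")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, f"{pct[i, j]:.0f}", ha="center", va="center",
                    color="white" if pct[i, j] > 50 else "black", fontsize=8)
    fig.colorbar(im, label="% of reference class")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def grade_report(
    model: Model,
    volumes: list[tuple[str, Volume]],
    out_path: str,
    stack_slices: int | None = None,
) -> int:
    """Write a per-input CSV grading report; returns the count of failed rows.

    If ``stack_slices`` is set, each input is split into axial stacks of
    that depth, every stack graded, and the scan grade is the maximum
    (most-severe) stack grade.
    """
    from .volume import StackSpec, split_into_stacks

    rows = []
    failures = 0
    for vid, vol in volumes:
        try:
            if stack_slices is not None:
                stacks = split_into_stacks(vol, StackSpec(slices_per_stack=stack_slices))
                preds = [predict_grade(model, s, id=f"{vid}/stack{i}")
                         for i, s in enumerate(stacks)]
                grade = stack_grade([p.grade for p in preds])
                scores = np.mean([p.scores for p in preds], axis=0)
                rule = f"max over {len(stacks)} stacks"
            else:
                p = predict_grade(model, vol, id=vid)
                grade, scores, rule = p.grade, np.array(p.scores), "direct"
            rows.append(
                [vid, grade, *[f"{s:.6f}" for s in scores], rule,
                 "yes" if grade >= 4 else "no"]
            )
        except Exception as exc:  # record row-level failure, keep going
            failures += 1
            rows.append([vid, "ERROR", "", "", "", "", "", str(exc), ""])
    with open(out_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "grade", "score1", "score2", "score3", "score4", "score5",
             "rule", "repeat_scan_suggested"]
        )
        w.writerows(rows)
    return failures
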