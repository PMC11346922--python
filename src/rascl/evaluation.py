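"""Confusion metrics, ROC/AUC, challenge evaluation and gradient saliency.

FTMH is the positive class throughout.  Per-class metrics treat each class as
positive in turn (the control row swaps tp<->tn and fp<->fn), mirroring the
"FTMH / Control" presentation of ensemble results; replicate aggregation
reports mean +/- sample SD.  Undefined ratios (0/0) are reported as 0 and
flagged degenerate rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .augmentation import resize_image
from .data_io import Cohort
from .exceptions import DomainError
from .models import Encoder, MLPHead
from .training import EnsembleModel, ensemble_predict
from . import nn

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "MetricsReport",
    "confusion_counts",
    "classification_metrics",
    "roc_curve_auc",
    "evaluate_predictions",
    "evaluate_holdout",
    "evaluate_challenge",
    "aggregate_replicates",
    "saliency_map",
    "saliency_from_modules",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the control class treated as positive."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass
class ClassMetrics:
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    degenerate: list[str] = field(default_factory=list)


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    counts: ConfusionCounts
    threshold: float
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)
    auc: float | None = None

    def to_jsonable(self) -> dict:
        out = {
            "threshold": self.threshold,
            "counts": vars(self.counts),
            "auc": self.auc,
            "per_class": {
                k: {
                    "precision": m.precision,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "f1": m.f1,
                    "degenerate": list(m.degenerate),
                }
                for k, m in self.per_class.items()
            },
        }
        if self.roc is not None:
            out["roc"] = {"fpr": self.roc[0].tolist(), "tpr": self.roc[1].tolist()}
        return out


def confusion_counts(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores at ``threshold`` (>= rule, FTMH-positive) and count."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise DomainError(f"labels {labels.shape} and scores {scores.shape} differ")
    pred = scores >= threshold
    pos = labels.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def classification_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Precision, sensitivity, specificity and F1 from integer counts.

    Values are exact rationals on the given counts; any 0/0 ratio is
    reported as 0 with its name in ``degenerate``.
    """
    if min(counts.tp, counts.fp, counts.fn, counts.tn) < 0:
        raise DomainError("confusion counts must be non-negative")
    deg: list[str] = []
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", deg)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", deg)
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity", deg)
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        deg.append("f1")
        f1 = 0.0
    return ClassMetrics(precision, sensitivity, specificity, f1, deg)


def roc_curve_auc(labels, scores):
    """ROC points by threshold sweep and trapezoidal AUC.

    Tied scores enter the curve simultaneously; equivalently the AUC equals
    the Mann-Whitney U statistic divided by n+ * n-.  Requires both classes.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.min(initial=1) == labels.max(initial=0):
        raise DomainError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full per-replicate report: both class rows, ROC and AUC."""
    counts = confusion_counts(labels, scores, threshold)
    roc, auc = roc_curve_auc(labels, scores)
    return MetricsReport(
        per_class={
            "FTMH": classification_metrics(counts),
            "Control": classification_metrics(counts.swapped()),
        },
        counts=counts,
        threshold=threshold,
        roc=roc,
        auc=auc,
    )


def _central_images(cohort: Cohort, input_hw) -> np.ndarray:
    imgs = [
        resize_image(v.slices[v.central_slice_index], input_hw)
        for _, v in sorted(cohort.volumes.items())
    ]
    return np.stack(imgs)


def evaluate_holdout(ensemble: EnsembleModel, holdout: Cohort) -> tuple[MetricsReport, pd.DataFrame]:
    """Score the central B-scan of every holdout eye through the ensemble."""
    input_hw = ensemble.encoder.spec.input_size[:2]
    eyes = sorted(holdout.volumes)
    images = _central_images(holdout, input_hw)
    scores, pred = ensemble_predict(ensemble, images)
    diag = dict(zip(holdout.manifest["eye_id"], holdout.manifest["diagnosis"]))
    labels = np.array([int(diag[e] == "FTMH") for e in eyes])
    report = evaluate_predictions(labels, scores, ensemble.threshold)
    table = pd.DataFrame(
        {"eye_id": eyes, "label": labels, "score": scores, "predicted": pred}
    )
    return report, table


def evaluate_challenge(ensemble: EnsembleModel, challenge: Cohort) -> tuple[float, pd.DataFrame]:
    """Fraction of challenge eyes classified FTMH-negative (central slices only).

    Challenge eyes are lamellar/pseudohole cases whose ground truth is
    FTMH-negative; accuracy 1.0 means no partial-thickness defect was
    mistaken for a full-thickness hole.
    """
    if len(challenge) == 0:
        raise DomainError("challenge set is empty")
    input_hw = ensemble.encoder.spec.input_size[:2]
    eyes = sorted(challenge.volumes)
    images = _central_images(challenge, input_hw)
    scores, pred = ensemble_predict(ensemble, images)
    table = pd.DataFrame(
        {"eye_id": eyes, "score": scores, "predicted_ftmh": pred.astype(bool)}
    )
    return float(np.mean(pred == 0)), table


def aggregate_replicates(reports: list[MetricsReport]) -> dict:
    """Mean +/- sample SD (ddof=1) of each metric across replicates.

    Formatted strings follow the `mean +/- sd` convention used when
    summarising triplicate holdouts (e.g. "1.000 +/- 0.000").
    """
    if not reports:
        raise DomainError("no reports to aggregate")
    out: dict = {}
    for cls in reports[0].per_class:
        out[cls] = {}
        for metric in ("precision", "sensitivity", "specificity", "f1"):
            vals = np.array([getattr(r.per_class[cls], metric) for r in reports])
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[cls][metric] = {
                "mean": float(vals.mean()),
                "sd": sd,
                "formatted": f"{vals.mean():.3f} ± {sd:.3f}",
            }
    aucs = np.array([r.auc for r in reports], dtype=float)
    sd = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
    out["auc"] = {"mean": float(aucs.mean()), "sd": sd,
                  "formatted": f"{aucs.mean():.3f} ± {sd:.3f}"}
    return out


# ---------------------------------------------------------------------------
# Gradient saliency


def saliency_from_modules(
    modules: list[nn.Module],
    image: np.ndarray,
    target_class: int,
    n_classes: int,
    method: str = "input_gradient",
) -> np.ndarray:
    """Saliency for an arbitrary module chain ending in class logits.

    ``input_gradient`` backpropagates the target logit to the input and
    returns ``|grad|`` max-normalised; ``gradcam`` weights the activations
    entering the last :class:`nn.GlobalAvgPool` by their pooled gradients
    (Grad-CAM), ReLU-rectifies and upsamples bilinearly to the input shape.
    """
    if not (0 <= target_class < n_classes):
        raise DomainError(f"invalid class {target_class} for {n_classes} classes")
    flat: list[nn.Module] = []
    for mod in modules:
        if isinstance(mod, nn.Sequential):
            flat.extend(mod.layers)
        else:
            flat.append(mod)
    modules = flat
    x = np.asarray(image, dtype=np.float64)
    spatial = x.shape[-2:]
    xb = x if x.ndim == 4 else x[None, None] if x.ndim == 2 else x[None]

    acts = [xb]
    for mod in modules:
        acts.append(mod.forward(acts[-1], train=True))
    logits = acts[-1]
    grad = np.zeros_like(logits)
    grad[..., target_class] = 1.0

    if method == "gradcam":
        gap_pos = max(
            (i for i, m in enumerate(modules)
             if isinstance(m, (nn.GlobalAvgPool, nn.GridAvgPool))),
            default=None,
        )
        if gap_pos is None:
            raise DomainError("gradcam needs a GlobalAvgPool stage in the model")
        for mod in reversed(modules[gap_pos:]):
            grad = mod.backward(grad)
        a = acts[gap_pos]  # (1, C, h, w) activations entering the pool
        alpha = grad.mean(axis=(2, 3), keepdims=True)
        cam = np.maximum((alpha * a).sum(axis=1)[0], 0.0)
        cam = resize_image(cam / cam.max() if cam.max() > 0 else cam, spatial)
        return cam / cam.max() if cam.max() > 0 else cam
    if method == "input_gradient":
        for mod in reversed(modules):
            grad = mod.backward(grad)
        sal = np.abs(grad).sum(axis=1)[0] if grad.ndim == 4 else np.abs(grad).reshape(spatial)
        return sal / sal.max() if sal.max() > 0 else sal
    raise DomainError(f"unknown saliency method {method!r}")


def saliency_map(
    encoder: Encoder,
    classifier_head: MLPHead,
    image: np.ndarray,
    target_class: int,
    method: str = "gradcam",
) -> np.ndarray:
    """Gradient saliency of one class for one B-scan.

    Returns a non-negative, max-normalised heatmap at the input resolution;
    deterministic for fixed weights.  Default is Grad-CAM on the final
    convolutional activations; ``input_gradient`` gives plain |d logit / d
    pixel| maps.
    """
    img = resize_image(np.asarray(image, dtype=float), encoder.spec.input_size[:2])
    xb = np.repeat(img[None, None], encoder.channels, axis=1)
    return saliency_from_modules(
        [encoder.net, classifier_head],
        xb,
        target_class,
        classifier_head.spec.n_classes,
        method=method,
    )
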