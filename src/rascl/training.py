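"""Pre-training, checkpoint selection, frozen-encoder fine-tuning and ensembling.

The protocol: contrastive pre-training of the encoder + projection head on
the training eyes (validated every ``val_interval`` epochs by NT-Xent loss
and top-1 positive-retrieval accuracy within validation batches), checkpoint
selection by ``min(val_loss / val_accuracy)``, then per-fold supervised
fine-tuning of a classifier head on up to three B-scans per eye centred on
the fovea — with the convolutional weights frozen — and equal-weight
ensembling of the fold heads' softmax outputs.

A contrastive model has no native notion of "accuracy"; the selection
criterion here uses top-1 positive retrieval: the fraction of validation
views whose positive partner is their nearest neighbour (cosine) within the
batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augmentation import AugmentationConfig, augment_view, resize_image
from .contrastive import (
    ContrastiveConfig,
    build_pair_batch,
    nt_xent_loss_and_grad,
)
from .data_io import BScanVolume, Cohort
from .exceptions import ConfigurationError, DomainError
from .models import Encoder, EncoderSpec, HeadSpec, MLPHead, build_encoder, build_head, classify

__all__ = [
    "PretrainConfig",
    "FinetuneConfig",
    "HistoryRecord",
    "TrainingHistory",
    "EnsembleModel",
    "training_slice_window",
    "pretrain",
    "select_checkpoint",
    "finetune_fold",
    "train_ensemble",
    "ensemble_predict",
]


@dataclass
class PretrainConfig:
    epochs: int = 800
    val_interval: int = 10
    learning_rate: float = 1e-3  # Adam, no schedule
    slices_per_eye: int = 3  # B-scans per eye centred on the fovea

    def validate(self) -> None:
        if self.epochs < 1 or self.val_interval < 1:
            raise ConfigurationError("epochs and val_interval must be >= 1")


@dataclass
class FinetuneConfig:
    epochs: int = 500
    val_interval: int = 10
    learning_rate: float = 1e-4
    encoder_mode: str = "frozen"  # frozen | trainable
    slices_per_eye: int = 3
    augment: bool = True  # augment training folds; evaluation is never augmented
    n_aug_variants: int = 3  # frozen mode: fixed augmented variants per slice
    threshold: float = 0.5
    class_weight: str = "none"  # none | balanced (inverse class frequency)

    def validate(self) -> None:
        if self.encoder_mode not in ("frozen", "trainable"):
            raise ConfigurationError(f"unknown encoder_mode {self.encoder_mode!r}")
        if self.class_weight not in ("none", "balanced"):
            raise ConfigurationError(f"unknown class_weight {self.class_weight!r}")
        if self.epochs < 1 or self.val_interval < 1:
            raise ConfigurationError("epochs and val_interval must be >= 1")


@dataclass
class HistoryRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float


@dataclass
class TrainingHistory:
    records: list[HistoryRecord] = field(default_factory=list)

    def add(self, epoch: int, train_loss: float, val_loss: float, val_accuracy: float):
        if self.records and epoch <= self.records[-1].epoch:
            raise DomainError("history epochs must be strictly increasing")
        self.records.append(HistoryRecord(epoch, float(train_loss), float(val_loss), float(val_accuracy)))

    def to_jsonable(self) -> list[dict]:
        return [vars(r) for r in self.records]


@dataclass
class EnsembleModel:
    """Shared frozen encoder plus one fine-tuned classifier head per fold.

    Members carry equal weight: the ensemble FTMH score is the arithmetic
    mean of the members' FTMH softmax scores.
    """

    encoder: Encoder
    heads: list[MLPHead]
    threshold: float = 0.5

    @property
    def n_members(self) -> int:
        return len(self.heads)


def training_slice_window(volume: BScanVolume, slices_per_eye: int = 3) -> list[int]:
    """Indices of up to ``slices_per_eye`` contiguous slices centred on the fovea."""
    n = volume.n_slices
    m = min(slices_per_eye, n)
    lo = int(np.clip(volume.central_slice_index - m // 2, 0, n - m))
    return list(range(lo, lo + m))


# ---------------------------------------------------------------------------
# Pre-training


def _retrieval_accuracy(z: np.ndarray) -> float:
    """Top-1 positive retrieval: is each view's nearest neighbour its partner?"""
    zhat = z / np.linalg.norm(z, axis=1, keepdims=True)
    sim = zhat @ zhat.T
    np.fill_diagonal(sim, -np.inf)
    partner = np.arange(len(z)) ^ 1
    return float(np.mean(sim.argmax(axis=1) == partner))


def pretrain(
    train_cohort: Cohort,
    val_cohort: Cohort,
    contrastive_config: ContrastiveConfig,
    augmentation_config: AugmentationConfig,
    pretrain_config: PretrainConfig,
    encoder_spec: EncoderSpec,
    head_spec: HeadSpec | None = None,
    seed: int = 0,
) -> tuple[Encoder, MLPHead, TrainingHistory]:
    """Contrastive pre-training; returns the selected-checkpoint encoder.

    One epoch is a pass over the training scans: ``round(n_training_slices /
    (2 * batch_pairs))`` batches (at least one).  Anchors and neighbours are
    restricted to the declared training slices of each eye.  Validation
    every ``val_interval`` epochs
    computes NT-Xent loss and retrieval accuracy on batches assembled
    deterministically from the held-out validation eyes; the returned
    encoder state is the ``min(val_loss/val_accuracy)`` checkpoint.
    """
    contrastive_config.validate()
    pretrain_config.validate()
    if head_spec is None:
        head_spec = HeadSpec(mode="projection")
    n_train_patients = train_cohort.manifest["patient_id"].nunique()
    if n_train_patients < contrastive_config.batch_pairs:
        raise ConfigurationError(
            f"pre-training needs >= {contrastive_config.batch_pairs} patients, "
            f"have {n_train_patients}"
        )
    n_val_patients = val_cohort.manifest["patient_id"].nunique()
    if n_val_patients < 2:
        raise ConfigurationError("pre-training validation needs >= 2 patients")

    ss = np.random.SeedSequence(seed)
    s_init, s_head, s_batch = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    encoder = build_encoder(encoder_spec, s_init)
    head = build_head(head_spec, encoder.feature_dim, s_head)
    opt = nn.Adam(encoder.parameters() + head.parameters(), lr=pretrain_config.learning_rate)

    windows = {
        e: training_slice_window(v, pretrain_config.slices_per_eye)
        for e, v in train_cohort.volumes.items()
    }
    val_windows = {
        e: training_slice_window(v, pretrain_config.slices_per_eye)
        for e, v in val_cohort.volumes.items()
    }
    val_pairs = min(contrastive_config.batch_pairs, n_val_patients)
    val_cc = ContrastiveConfig(
        contrastive_config.max_offset,
        contrastive_config.temperature,
        val_pairs,
        contrastive_config.embedding_dim,
        contrastive_config.boundary_mode,
    )

    batch_rng = np.random.default_rng(s_batch)
    n_train_scans = sum(len(w) for w in windows.values())
    n_batches = max(1, round(n_train_scans / (2 * contrastive_config.batch_pairs)))
    tau = contrastive_config.temperature

    history = TrainingHistory()
    snapshots: list[tuple[list, list]] = []
    for epoch in range(1, pretrain_config.epochs + 1):
        losses = []
        for _ in range(n_batches):
            batch = build_pair_batch(
                train_cohort.manifest,
                train_cohort.volumes,
                contrastive_config,
                augmentation_config,
                batch_rng,
                slice_windows=windows,
            )
            feats = encoder.features(batch.views, train=True)
            z = head.forward(feats, train=True)
            loss, dz = nt_xent_loss_and_grad(z, tau)
            opt.zero_grad()
            dfeat = head.backward(dz)
            encoder.net.backward(dfeat)
            opt.step()
            losses.append(loss)
        if epoch % pretrain_config.val_interval == 0:
            vloss, vacc = _validate_contrastive(
                encoder, head, val_cohort, val_cc, augmentation_config, val_windows,
                np.random.default_rng([s_batch, epoch]),
            )
            history.add(epoch, float(np.mean(losses)), vloss, vacc)
            snapshots.append((encoder.state_dict(), head.state_dict()))
    if history.records:
        best = select_checkpoint(history)
        encoder.load_state(snapshots[best][0])
        head.load_state(snapshots[best][1])
    return encoder, head, history


def _validate_contrastive(encoder, head, val_cohort, cc, aug_config, windows, rng):
    """Mean NT-Xent loss and retrieval accuracy over deterministic val batches."""
    losses, accs = [], []
    n_batches = max(1, val_cohort.manifest["patient_id"].nunique() // cc.batch_pairs)
    for _ in range(min(n_batches, 2)):
        batch = build_pair_batch(
            val_cohort.manifest, val_cohort.volumes, cc, aug_config, rng,
            slice_windows=windows,
        )
        feats = encoder.features(batch.views, train=False)
        z = head.forward(feats, train=False)
        loss, _ = nt_xent_loss_and_grad(z, cc.temperature)
        losses.append(loss)
        accs.append(_retrieval_accuracy(z))
    return float(np.mean(losses)), float(np.mean(accs))


def select_checkpoint(history: TrainingHistory) -> int:
    """Index (0-based) of the record minimising ``val_loss / val_accuracy``.

    Records with zero validation accuracy are treated as +inf (never
    selected) unless every record is, which is an error; ties resolve to the
    earliest epoch.
    """
    if not history.records:
        raise DomainError("empty history")
    crit = [
        (r.val_loss / r.val_accuracy) if r.val_accuracy > 0 else np.inf
        for r in history.records
    ]
    if not np.isfinite(crit).any():
        raise DomainError("all history records have zero validation accuracy")
    return int(np.argmin(crit))  # argmin takes the earliest of tied minima


# ---------------------------------------------------------------------------
# Supervised fine-tuning


def _fold_examples(cohort: Cohort, slices_per_eye: int) -> list[tuple[str, int, int]]:
    """(eye_id, slice_index, label) triples; label 1 = FTMH, 0 = control."""
    out = []
    labels = dict(zip(cohort.manifest["eye_id"], cohort.manifest["diagnosis"]))
    for eye_id, vol in cohort.volumes.items():
        y = int(labels[eye_id] == "FTMH")
        for idx in training_slice_window(vol, slices_per_eye):
            out.append((eye_id, idx, y))
    return sorted(out)


def _encode_batched(encoder: Encoder, images: list[np.ndarray], chunk: int = 64) -> np.ndarray:
    feats = []
    for i in range(0, len(images), chunk):
        feats.append(encoder.features(np.stack(images[i : i + chunk]), train=False))
    return np.concatenate(feats, axis=0)


def precompute_features(
    encoder: Encoder,
    cohort: Cohort,
    config: FinetuneConfig,
    augmentation_config: AugmentationConfig,
    seed: int,
) -> dict:
    """Frozen-encoder feature cache over the fine-tuning slices of a cohort.

    For every declared training slice this encodes the clean (resized) view
    plus ``n_aug_variants`` independently augmented views; fold training uses
    clean + augmented features, validation and evaluation use clean only.
    """
    input_hw = encoder.spec.input_size[:2]
    rng = np.random.default_rng(seed)
    examples = _fold_examples(cohort, config.slices_per_eye)
    clean_imgs, aug_imgs = [], []
    n_var = config.n_aug_variants if config.augment else 0
    for eye_id, idx, _y in examples:
        img = cohort.volumes[eye_id].slices[idx]
        clean_imgs.append(resize_image(img, input_hw, augmentation_config.interpolation))
        for _ in range(n_var):
            aug_imgs.append(augment_view(img, augmentation_config, rng))
    clean = _encode_batched(encoder, clean_imgs)
    aug = _encode_batched(encoder, aug_imgs) if aug_imgs else np.zeros((0, clean.shape[1]))
    return {
        "examples": examples,
        "clean": clean,
        "aug": aug.reshape(len(examples), n_var, -1) if n_var else None,
        "labels": np.array([y for _, _, y in examples]),
        "eyes": np.array([e for e, _, _ in examples]),
    }


def _fit_head(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    head_spec: HeadSpec,
    config: FinetuneConfig,
    seed: int,
) -> tuple[MLPHead, TrainingHistory]:
    """Full-batch Adam on binary cross-entropy with checkpoint selection.

    ``class_weight='balanced'`` weights samples by inverse class frequency so
    the minority (FTMH) class is not drowned by the control majority.
    """
    head = build_head(head_spec, train_x.shape[1], seed)
    opt = nn.Adam(head.parameters(), lr=config.learning_rate)
    weights = None
    if config.class_weight == "balanced":
        freq = np.bincount(train_y, minlength=2) / len(train_y)
        weights = (0.5 / freq[train_y]).astype(np.float64)
    history = TrainingHistory()
    snapshots = []
    for epoch in range(1, config.epochs + 1):
        logits = head.forward(train_x, train=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, train_y, weights)
        opt.zero_grad()
        head.backward(dlogits)
        opt.step()
        if epoch % config.val_interval == 0:
            vlogits = head.forward(val_x, train=False)
            vloss, _ = nn.softmax_cross_entropy(vlogits, val_y)
            scores = nn.softmax(vlogits)[:, 1]
            pred = (scores >= config.threshold).astype(int)
            vacc = float(np.mean(pred == val_y))
            history.add(epoch, loss, vloss, vacc)
            snapshots.append(head.state_dict())
    if history.records:
        head.load_state(snapshots[select_checkpoint(history)])
    return head, history


def finetune_fold(
    encoder: Encoder,
    fold_train: Cohort,
    fold_val: Cohort,
    finetune_config: FinetuneConfig,
    seed: int,
    head_spec: HeadSpec | None = None,
    augmentation_config: AugmentationConfig | None = None,
) -> tuple[MLPHead, TrainingHistory]:
    """Fine-tune one classifier head with the encoder frozen (default).

    In frozen mode the encoder state is bit-identical before and after; the
    best epoch is chosen by the same ``min(val_loss/val_accuracy)`` criterion
    as pre-training.  ``trainable`` mode backpropagates into the encoder
    (the externally initialised baseline configuration).
    """
    finetune_config.validate()
    if len(fold_train) == 0 or len(fold_val) == 0:
        raise ConfigurationError("fine-tuning folds must be non-empty")
    if set(fold_train.eye_ids) & set(fold_val.eye_ids):
        raise ConfigurationError("fold train/val sets must be disjoint")
    if head_spec is None:
        head_spec = HeadSpec(mode="classifier")
    else:
        head_spec = HeadSpec(head_spec.hidden_layers, head_spec.hidden_width,
                             "classifier", head_spec.n_classes)
    if augmentation_config is None:
        augmentation_config = AugmentationConfig(
            output_size=encoder.spec.input_size[:2]
        )
    ss = np.random.SeedSequence(seed)
    s_feat, s_head, s_aug = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))

    if finetune_config.encoder_mode == "frozen":
        tr = precompute_features(encoder, fold_train, finetune_config, augmentation_config, s_feat)
        va = precompute_features(
            encoder, fold_val,
            FinetuneConfig(**{**vars(finetune_config), "augment": False}),
            augmentation_config, s_feat + 1,
        )
        train_x, train_y = tr["clean"], tr["labels"]
        if tr["aug"] is not None:
            n, a, f = tr["aug"].shape
            train_x = np.concatenate([train_x, tr["aug"].reshape(n * a, f)])
            train_y = np.concatenate([train_y, np.repeat(tr["labels"], a)])
        return _fit_head(train_x, train_y, va["clean"], va["labels"],
                         head_spec, finetune_config, s_head)
    return _finetune_trainable(
        encoder, fold_train, fold_val, finetune_config, head_spec,
        augmentation_config, s_head, s_aug,
    )


def _finetune_trainable(encoder, fold_train, fold_val, config, head_spec,
                        aug_config, s_head, s_aug):
    """Baseline mode: encoder weights stay trainable during fine-tuning."""
    input_hw = encoder.spec.input_size[:2]
    head = build_head(head_spec, encoder.feature_dim, s_head)
    opt = nn.Adam(encoder.parameters() + head.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(s_aug)
    train_ex = _fold_examples(fold_train, config.slices_per_eye)
    val_ex = _fold_examples(fold_val, config.slices_per_eye)
    val_x = _encode_batched(
        encoder,
        [resize_image(fold_val.volumes[e].slices[i], input_hw) for e, i, _ in val_ex],
    )
    val_y = np.array([y for _, _, y in val_ex])
    history = TrainingHistory()
    snapshots = []
    for epoch in range(1, config.epochs + 1):
        imgs = []
        for eye, idx, _y in train_ex:
            img = fold_train.volumes[eye].slices[idx]
            imgs.append(
                augment_view(img, aug_config, rng) if config.augment
                else resize_image(img, input_hw)
            )
        y = np.array([yy for _, _, yy in train_ex])
        feats = encoder.features(np.stack(imgs), train=True)
        logits = head.forward(feats, train=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, y)
        opt.zero_grad()
        encoder.net.backward(head.backward(dlogits))
        opt.step()
        if epoch % config.val_interval == 0:
            val_x = _encode_batched(
                encoder,
                [resize_image(fold_val.volumes[e].slices[i], input_hw) for e, i, _ in val_ex],
            )
            vlogits = head.forward(val_x, train=False)
            vloss, _ = nn.softmax_cross_entropy(vlogits, val_y)
            pred = (nn.softmax(vlogits)[:, 1] >= config.threshold).astype(int)
            history.add(epoch, loss, vloss, float(np.mean(pred == val_y)))
            snapshots.append((encoder.state_dict(), head.state_dict()))
    if history.records:
        best = select_checkpoint(history)
        encoder.load_state(snapshots[best][0])
        head.load_state(snapshots[best][1])
    return head, history


def train_ensemble(
    encoder: Encoder,
    fold_assignment: dict[str, int],
    cohort: Cohort,
    finetune_config: FinetuneConfig,
    seed: int,
    head_spec: HeadSpec | None = None,
    augmentation_config: AugmentationConfig | None = None,
) -> tuple[EnsembleModel, list[TrainingHistory]]:
    """One fine-tuned classifier head per fold, fold ``i`` held out for member ``i``.

    In frozen mode the feature cache is computed once over the whole training
    cohort and shared by all members (the encoder is identical for every
    fold); member heads still differ because their train/validation fold
    compositions differ.
    """
    finetune_config.validate()
    if head_spec is None:
        head_spec = HeadSpec(mode="classifier")
    else:
        head_spec = HeadSpec(head_spec.hidden_layers, head_spec.hidden_width,
                             "classifier", head_spec.n_classes)
    if augmentation_config is None:
        augmentation_config = AugmentationConfig(output_size=encoder.spec.input_size[:2])
    folds = sorted(set(fold_assignment.values()))
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(len(folds) + 1)]

    heads, histories = [], []
    if finetune_config.encoder_mode == "frozen":
        cache = precompute_features(encoder, cohort, finetune_config,
                                    augmentation_config, seeds[-1])
        eye_fold = np.array([fold_assignment[e] for e in cache["eyes"]])
        for f, s in zip(folds, seeds):
            tr_mask, va_mask = eye_fold != f, eye_fold == f
            train_x, train_y = cache["clean"][tr_mask], cache["labels"][tr_mask]
            if cache["aug"] is not None:
                aug = cache["aug"][tr_mask]
                n, a, d = aug.shape
                train_x = np.concatenate([train_x, aug.reshape(n * a, d)])
                train_y = np.concatenate([train_y, np.repeat(train_y[: n], a)])
            head, hist = _fit_head(
                train_x, train_y, cache["clean"][va_mask], cache["labels"][va_mask],
                head_spec, finetune_config, s,
            )
            heads.append(head)
            histories.append(hist)
    else:
        for f, s in zip(folds, seeds):
            tr_ids = [e for e, ff in fold_assignment.items() if ff != f]
            va_ids = [e for e, ff in fold_assignment.items() if ff == f]
            head, hist = finetune_fold(
                encoder, cohort.subset(tr_ids), cohort.subset(va_ids),
                finetune_config, s, head_spec, augmentation_config,
            )
            heads.append(head)
            histories.append(hist)
    return EnsembleModel(encoder, heads, finetune_config.threshold), histories


def ensemble_predict(ensemble: EnsembleModel, images: np.ndarray):
    """Equal-weight mean of member FTMH softmax scores; label FTMH iff score >= 0.5.

    Returns ``(scores, labels)`` with labels 1 = FTMH.
    """
    scores = np.mean(
        [classify(ensemble.encoder, h, images)[:, 1] for h in ensemble.heads], axis=0
    )
    labels = (scores >= ensemble.threshold).astype(int)
    return scores, labels
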