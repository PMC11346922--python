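"""Training protocol: schedules, checkpoint criterion, freezing, ensembling."""

import numpy as np
import pytest

from rascl import nn
from rascl.augmentation import AugmentationConfig
from rascl.contrastive import ContrastiveConfig
from rascl.exceptions import ConfigurationError, DomainError
from rascl.models import EncoderSpec, HeadSpec, build_encoder
from rascl.training import (
    EnsembleModel,
    FinetuneConfig,
    PretrainConfig,
    TrainingHistory,
    ensemble_predict,
    finetune_fold,
    pretrain,
    select_checkpoint,
    train_ensemble,
    training_slice_window,
)

_AUG = AugmentationConfig(
    output_size=(64, 64),
    crop_area_range=(0.8, 1.0),
    noise_var_range=(0.0, 0.01),
    noise_mu_range=(-0.05, 0.05),
    brightness_delta_range=(-0.1, 0.1),
    contrast_factor_range=(0.9, 1.1),
)
_ENC = EncoderSpec("small_cnn", (64, 64, 1), 64)
_HEAD = HeadSpec(hidden_layers=3, hidden_width=64, mode="classifier")


def _history(rows):
    h = TrainingHistory()
    for i, (loss, acc) in enumerate(rows):
        h.add((i + 1) * 10, 0.0, loss, acc)
    return h


class TestSelectCheckpoint:
    def test_worked_example(self):
        """Criteria [1.2, 1/3, 0.421]: the second record wins."""
        h = _history([(0.6, 0.5), (0.3, 0.9), (0.4, 0.95)])
        assert select_checkpoint(h) == 1

    def test_ties_resolve_to_earliest(self):
        h = _history([(0.4, 0.8)] * 3)
        assert select_checkpoint(h) == 0

    def test_single_record(self):
        assert select_checkpoint(_history([(0.2, 0.5)])) == 0

    def test_zero_accuracy_never_selected(self):
        h = _history([(0.01, 0.0), (0.9, 0.1)])
        assert select_checkpoint(h) == 1
        with pytest.raises(DomainError):
            select_checkpoint(_history([(0.1, 0.0), (0.2, 0.0)]))

    def test_agrees_with_brute_force_on_random_histories(self):
        g = np.random.default_rng(0)
        for _ in range(1000):
            n = int(g.integers(1, 12))
            rows = [(float(g.uniform(0.01, 2)), float(g.choice([0.0, *g.uniform(0.05, 1, 3)])))
                    for _ in range(n)]
            if all(r[1] == 0 for r in rows):
                continue
            h = _history(rows)
            crit = [loss / acc if acc > 0 else np.inf for loss, acc in rows]
            assert select_checkpoint(h) == crit.index(min(crit))

    def test_history_epochs_strictly_increasing(self):
        h = TrainingHistory()
        h.add(10, 0.1, 0.1, 0.5)
        with pytest.raises(DomainError):
            h.add(10, 0.1, 0.1, 0.5)


class TestSliceWindow:
    def test_up_to_three_central_slices(self, small_cohort):
        """Fine-tuning uses min(3, n_slices) B-scans centred on the fovea."""
        for vol in small_cohort.volumes.values():
            win = training_slice_window(vol, 3)
            assert len(win) == min(3, vol.n_slices)
            assert vol.central_slice_index in win
            assert win == sorted(win) and win[-1] - win[0] == len(win) - 1

    def test_window_clips_at_edges(self, small_cohort):
        vol = next(iter(small_cohort.volumes.values()))
        vol2 = type(vol)(vol.eye_id, vol.slices, 0, vol.slice_spacing_um)
        assert training_slice_window(vol2, 3) == [0, 1, 2]


class TestPretrain:
    def test_schedule_and_learnability(self, small_cohort):
        """20 epochs at interval 5 -> 4 records; with photometric jitter only
        (positive pairs differ by slice offset alone) the contrastive train
        loss falls well below its starting value on coherent phantoms."""
        gentle = AugmentationConfig(
            output_size=(64, 64), crop_area_range=(1.0, 1.0),
            noise_var_range=(0.0, 0.002), noise_mu_range=(-0.02, 0.02),
            brightness_delta_range=(-0.05, 0.05),
            contrast_factor_range=(0.95, 1.05), hflip_prob=0.0,
        )
        ids = small_cohort.eye_ids
        enc, head, hist = pretrain(
            small_cohort.subset(ids[:18]),
            small_cohort.subset(ids[18:]),
            ContrastiveConfig(batch_pairs=8),
            gentle,
            PretrainConfig(epochs=20, val_interval=5, learning_rate=1e-3),
            _ENC,
            HeadSpec(hidden_width=64, mode="projection"),
            seed=0,
        )
        assert [r.epoch for r in hist.records] == [5, 10, 15, 20]
        assert hist.records[-1].train_loss < hist.records[0].train_loss

    def test_fixed_seed_reproducible(self, small_cohort):
        ids = small_cohort.eye_ids
        runs = [
            pretrain(
                small_cohort.subset(ids[:12]),
                small_cohort.subset(ids[12:16]),
                ContrastiveConfig(batch_pairs=4),
                _AUG,
                PretrainConfig(epochs=4, val_interval=2),
                _ENC,
                HeadSpec(hidden_width=32, mode="projection"),
                seed=5,
            )
            for _ in range(2)
        ]
        assert [vars(r) for r in runs[0][2].records] == [vars(r) for r in runs[1][2].records]
        assert nn.state_hash(runs[0][0].net) == nn.state_hash(runs[1][0].net)

    def test_insufficient_eyes_rejected(self, small_cohort):
        ids = small_cohort.eye_ids
        with pytest.raises(ConfigurationError):
            pretrain(
                small_cohort.subset(ids[:3]),
                small_cohort.subset(ids[3:6]),
                ContrastiveConfig(batch_pairs=8),
                _AUG,
                PretrainConfig(epochs=2, val_interval=1),
                _ENC,
                seed=0,
            )


class TestFinetune:
    def test_frozen_mode_leaves_encoder_bit_identical(self, small_cohort):
        encoder = build_encoder(_ENC, 0)
        before = nn.state_hash(encoder.net)
        ids = small_cohort.eye_ids
        finetune_fold(
            encoder,
            small_cohort.subset(ids[:16]),
            small_cohort.subset(ids[16:]),
            FinetuneConfig(epochs=20, val_interval=5, learning_rate=1e-3),
            seed=1,
            head_spec=_HEAD,
            augmentation_config=_AUG,
        )
        assert nn.state_hash(encoder.net) == before

    def test_trainable_mode_updates_encoder(self, small_cohort):
        encoder = build_encoder(_ENC, 0)
        before = nn.state_hash(encoder.net)
        ids = small_cohort.eye_ids  # 8 FTMH then 16 ERM
        finetune_fold(
            encoder,
            small_cohort.subset(ids[:4] + ids[8:12]),
            small_cohort.subset(ids[4:8] + ids[12:16]),  # mixed-class val fold
            FinetuneConfig(epochs=2, val_interval=1, encoder_mode="trainable",
                           slices_per_eye=1),
            seed=1,
            head_spec=_HEAD,
            augmentation_config=_AUG,
        )
        assert nn.state_hash(encoder.net) != before

    def test_overlapping_folds_rejected(self, small_cohort):
        encoder = build_encoder(_ENC, 0)
        ids = small_cohort.eye_ids
        with pytest.raises(ConfigurationError):
            finetune_fold(
                encoder,
                small_cohort.subset(ids[:8]),
                small_cohort.subset(ids[6:10]),
                FinetuneConfig(epochs=1, val_interval=1),
                seed=0,
            )

    def test_separable_features_reach_zero_loss_and_full_accuracy(self):
        """On linearly separable frozen features, BCE training drives the
        training loss toward 0 and fold accuracy to 1."""
        from rascl.training import _fit_head

        g = np.random.default_rng(0)
        x0 = g.normal(size=(40, 8)) + 4.0
        x1 = g.normal(size=(40, 8)) - 4.0
        x = np.concatenate([x0, x1])
        y = np.array([0] * 40 + [1] * 40)
        head, hist = _fit_head(
            x, y, x[::4], y[::4],
            HeadSpec(hidden_width=32, mode="classifier"),
            FinetuneConfig(epochs=200, val_interval=20, learning_rate=1e-3),
            seed=1,
        )
        assert hist.records[-1].train_loss < 1e-2
        assert hist.records[-1].val_accuracy == 1.0


class TestEnsemble:
    def _mini_ensemble(self, cohort, k=2, seed=0):
        encoder = build_encoder(_ENC, seed)
        ids = cohort.eye_ids
        folds = {e: i % k for i, e in enumerate(ids)}
        ensemble, hists = train_ensemble(
            encoder, folds, cohort,
            FinetuneConfig(epochs=10, val_interval=5, learning_rate=1e-3),
            seed=seed, head_spec=_HEAD, augmentation_config=_AUG,
        )
        return ensemble, hists

    def test_member_count_tracks_folds(self, small_cohort):
        ensemble, hists = self._mini_ensemble(small_cohort, k=2)
        assert ensemble.n_members == 2 and len(hists) == 2

    def test_member_heads_differ_across_folds(self, small_cohort):
        ensemble, _ = self._mini_ensemble(small_cohort, k=2)
        assert nn.state_hash(ensemble.heads[0]) != nn.state_hash(ensemble.heads[1])

    def test_score_is_member_mean_and_permutation_invariant(self, small_cohort, rng):
        from rascl.models import classify

        ensemble, _ = self._mini_ensemble(small_cohort, k=3)
        x = rng.random((4, 64, 64))
        scores, labels = ensemble_predict(ensemble, x)
        member = np.array([classify(ensemble.encoder, h, x)[:, 1] for h in ensemble.heads])
        assert np.allclose(scores, member.mean(axis=0))
        assert np.all(scores >= member.min(axis=0)) and np.all(scores <= member.max(axis=0))
        for perm_seed in range(5):
            order = np.random.default_rng(perm_seed).permutation(len(ensemble.heads))
            shuffled = EnsembleModel(ensemble.encoder, [ensemble.heads[i] for i in order])
            s2, _ = ensemble_predict(shuffled, x)
            assert np.allclose(s2, scores)

    def test_threshold_tie_labels_ftmh(self):
        """A score of exactly 0.5 classifies as FTMH under the >= rule."""
        enc = build_encoder(_ENC, 0)
        head = build_head_zero()
        ensemble = EnsembleModel(enc, [head])
        scores, labels = ensemble_predict(ensemble, np.zeros((2, 64, 64)))
        assert np.allclose(scores, 0.5) and np.all(labels == 1)

    def test_single_member_matches_that_member(self, small_cohort, rng):
        from rascl.models import classify

        ensemble, _ = self._mini_ensemble(small_cohort, k=2)
        solo = EnsembleModel(ensemble.encoder, [ensemble.heads[0]])
        x = rng.random((3, 64, 64))
        scores, _ = ensemble_predict(solo, x)
        assert np.allclose(scores, classify(solo.encoder, solo.heads[0], x)[:, 1])


def build_head_zero():
    from rascl.models import build_head

    head = build_head(_HEAD, 64, 0)
    head.load_state([np.zeros_like(a) for a in head.state_dict()])
    return head
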