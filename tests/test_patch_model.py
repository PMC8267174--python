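"""Patch classifier: architecture contracts, training protocol, inference."""

import numpy as np
import pytest

from pdacwsi import synthetic, tiling
from pdacwsi.patch_model import (PatchClassifier, TrainingConfig,
                                 build_classifier, load_checkpoint,
                                 predict_patches, prepare_images,
                                 save_checkpoint, train_patch_classifier)


def _small_cfg(**kw):
    kw.setdefault("backbone", "small_cnn")
    kw.setdefault("seed", 0)
    kw.setdefault("input_size", 64)
    kw.setdefault("epochs", 3)
    return TrainingConfig(**kw)


def _manifest(n_slides=6, seed=100):
    recs = []
    for i in range(n_slides):
        s = synthetic.generate_slide(1024, 1024, 2 if i % 2 else 0,
                                     seed=seed + i,
                                     region_radius_frac=(0.2, 0.3))
        recs += tiling.tile_slide(s, 256, 256)
    fractions = (0.7, 0.3, 0.0)
    n_min = min(sum(r.label == lab for r in recs)
                for lab in ("normal", "carcinoma"))
    n_tr, n_va, _ = tiling.split_sizes(n_min, fractions)
    targets = {"training": min(40, 6 * n_tr), "validation": min(12, 6 * n_va)}
    return tiling.build_balanced_manifest(recs, targets, seed=1,
                                          split_fractions=fractions)


class TestBuildClassifier:
    def test_forward_gives_simplex_after_softmax(self):
        from pdacwsi import nn

        clf = build_classifier(_small_cfg())
        x = np.random.default_rng(0).random((1, 64, 64, 3)).astype(np.float32)
        p = nn.softmax(clf.net.forward(x))
        assert p.shape == (1, 2)
        assert np.isclose(p.sum(), 1.0, atol=1e-6) and (p >= 0).all()

    def test_same_seed_identical_initial_weights(self):
        a = build_classifier(_small_cfg())
        b = build_classifier(_small_cfg())
        for sa, sb in zip(a.net.state_dict(), b.net.state_dict()):
            for k in sa:
                assert np.array_equal(sa[k], sb[k])

    def test_head_parameter_count_formula(self):
        """GAP -> FC(1024) -> 2-way softmax over F=64 backbone features:
        64*1024 + 1024 + 1024*2 + 2 = 68,610 parameters."""
        clf = build_classifier(_small_cfg())
        assert clf.head_parameter_count() == 64 * 1024 + 1024 + 1024 * 2 + 2

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            build_classifier(TrainingConfig(backbone="resnet"))

    def test_defaults_match_training_protocol(self):
        cfg = TrainingConfig()
        assert (cfg.learning_rate, cfg.epochs, cfg.batch_size) == (1e-3, 100, 8)
        assert cfg.checkpoint_metric == "val_accuracy"


class TestTraining:
    def test_separable_textures_reach_high_validation_accuracy(self):
        clf = build_classifier(_small_cfg(epochs=5))
        train_patch_classifier(clf, _manifest())
        assert clf.best_val_accuracy >= 0.95
        assert len(clf.log) == 5

    def test_zero_epochs_returns_initialization(self):
        cfg = _small_cfg(epochs=0)
        clf = build_classifier(cfg)
        init = clf.net.state_dict()
        train_patch_classifier(clf, _manifest())
        for sa, sb in zip(init, clf.net.state_dict()):
            for k in sa:
                assert np.array_equal(sa[k], sb[k])

    def test_single_class_training_rejected(self):
        man = _manifest()
        only_normal = ([r for r in man.subset("training") if r.label == "normal"],
                       man.subset("validation"))
        clf = build_classifier(_small_cfg())
        with pytest.raises(ValueError, match="both classes"):
            train_patch_classifier(clf, only_normal)

    def test_same_seed_reproduces_training_log(self):
        man = _manifest(n_slides=4)
        logs = []
        for _ in range(2):
            clf = build_classifier(_small_cfg(epochs=2))
            train_patch_classifier(clf, man)
            logs.append(clf.log)
        assert logs[0].equals(logs[1])

    def test_loss_decreases_on_separable_data(self):
        clf = build_classifier(_small_cfg(epochs=3))
        train_patch_classifier(clf, _manifest(n_slides=4))
        assert clf.log.train_loss.iloc[-1] < clf.log.train_loss.iloc[0]


class TestInference:
    def test_batched_equals_one_at_a_time(self):
        clf = build_classifier(_small_cfg())
        recs = _manifest(n_slides=2).subset("training")[:10]
        batched = predict_patches(clf, recs)
        single = [predict_patches(clf, [r])[0] for r in recs]
        for b, s in zip(batched, single):
            assert abs(b.p_tumor - s.p_tumor) < 1e-5

    def test_probabilities_sum_to_one(self):
        clf = build_classifier(_small_cfg())
        preds = predict_patches(clf, _manifest(n_slides=2).subset("training")[:8])
        for p in preds:
            assert abs(p.p_normal + p.p_tumor - 1.0) < 1e-6

    def test_background_patch_passes_through(self):
        clf = build_classifier(_small_cfg())
        white = tiling.PatchRecord("s", 0, 0, 64,
                                   np.full((64, 64, 3), 255, dtype=np.uint8),
                                   background_flag=True)
        (p,) = predict_patches(clf, [white])
        assert 0.0 <= p.p_tumor <= 1.0

    def test_generalizes_to_held_out_patches(self):
        """Held-out iid patches from the generator score within 2 points of
        validation accuracy."""
        clf = build_classifier(_small_cfg(epochs=5))
        train_patch_classifier(clf, _manifest())
        held = []
        for i in range(4):
            s = synthetic.generate_slide(1024, 1024, 2 if i % 2 else 0,
                                         seed=900 + i,
                                         region_radius_frac=(0.2, 0.3))
            held += [r for r in tiling.tile_slide(s, 256, 256)
                     if r.label in ("normal", "carcinoma")]
        preds = predict_patches(clf, held)
        y = np.array([r.label == "carcinoma" for r in held])
        yhat = np.array([p.p_tumor >= 0.5 for p in preds])
        acc = (y == yhat).mean()
        assert acc >= clf.best_val_accuracy - 0.02


def test_prepare_images_block_mean_and_range():
    img = np.full((128, 128, 3), 255, dtype=np.uint8)
    x = prepare_images([img], 64)
    assert x.shape == (1, 64, 64, 3)
    assert np.allclose(x, 1.0)
    assert np.allclose(prepare_images([np.zeros((64, 64, 3), np.uint8)], 64), -1.0)


def test_checkpoint_round_trip(tmp_path):
    cfg = _small_cfg()
    clf = build_classifier(cfg)
    clf.best_epoch, clf.best_val_accuracy = 3, 0.97
    save_checkpoint(clf, tmp_path / "ckpt")
    loaded = load_checkpoint(tmp_path / "ckpt", cfg)
    for sa, sb in zip(clf.net.state_dict(), loaded.net.state_dict()):
        for k in sa:
            assert np.array_equal(sa[k], sb[k])
    assert loaded.best_epoch == 3
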