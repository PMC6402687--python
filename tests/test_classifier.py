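import numpy as np
import pytest

from phasecell import nn
from phasecell.classifier import (DEFAULT_HP, AugmentationConfig, HyperParams,
                                  augment, build_cnn, build_triplet,
                                  confusion_and_stats, fuse, kfold_split,
                                  occlusion_probability_map, pairwise_distance,
                                  random_hp_search, ranked_marginal_loss,
                                  select_anchors, train_cnn, train_triplet)
from phasecell.image_io import CLASS_INDEX, CLASS_LABELS, to_network_range


# ---------------------------------------------------------------- CNN

def test_cnn_shape_chain_and_flatten_length():
    cnn = build_cnn(0)
    assert cnn.feature_length() == 2048
    x = np.zeros((3, 1, 64, 64), dtype=np.float32)
    shapes = []
    h = x
    for layer in cnn.net.layers:
        h = layer.forward(h, train=False)
        if h.ndim == 4:
            shapes.append((h.shape[1], h.shape[2]))
    assert shapes == [(64, 32), (64, 32), (64, 16), (128, 8), (128, 8), (128, 4)]
    assert cnn.forward(x, train=False).shape == (3, 6)


def test_cnn_rejects_wrong_input_size():
    cnn = build_cnn(0)
    with pytest.raises(ValueError):
        cnn.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))


def test_cnn_probabilities_sum_to_one(rng):
    cnn = build_cnn(rng)
    probs = cnn.predict_proba(rng.integers(0, 256, (4, 64, 64)).astype(float))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_cnn_memorizes_two_images(rng):
    images = np.stack([np.full((64, 64), 30.0), np.full((64, 64), 220.0)])
    labels = np.array([0, 5])
    model, hist = train_cnn((images, labels), (images, labels),
                            HyperParams(1e-2, 0.9, 0.0), rng,
                            max_epochs=30, patience=30, require_all_classes=False)
    assert hist["best_val_accuracy"] == 1.0


def test_train_cnn_requires_all_classes(small_crop_bank, rng):
    images, labels = small_crop_bank
    keep = labels != CLASS_INDEX["APO"]
    with pytest.raises(ValueError, match="missing classes"):
        train_cnn((images[keep], labels[keep]), (images, labels), rng=rng, max_epochs=1)


def test_train_cnn_loss_history_reproducible(small_crop_bank):
    images, labels = small_crop_bank
    runs = []
    for _ in range(2):
        _, hist = train_cnn((images, labels), (images[:12], labels[:12]),
                            rng=np.random.default_rng(7), max_epochs=2, patience=2)
        runs.append(hist["train_loss"])
    assert runs[0] == runs[1]


# ---------------------------------------------------------------- augmentation

def test_augment_identity_parameters_is_near_identity(rng):
    crop = rng.integers(0, 256, (64, 64)).astype(float)
    cfg = AugmentationConfig(rotation_deg=(0, 0), shear_deg=(0, 0), zoom=(1.0, 1.0))
    out = augment(crop, cfg, rng)
    assert np.abs(out - crop).max() < 1e-6


def test_augment_contract_and_determinism(rng):
    crop = rng.integers(0, 256, (64, 64)).astype(float)
    a = augment(crop, rng=np.random.default_rng(3))
    b = augment(crop, rng=np.random.default_rng(3))
    assert a.shape == (64, 64)
    assert a.min() >= 0 and a.max() <= 255
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------- triplet

@pytest.mark.parametrize("g1,g2,y,m,expected", [
    (2.0, 0.0, +1, 1.0, 0.0),
    (0.0, 0.0, +1, 1.0, 1.0),
    (0.2, 0.9, -1, 1.0, pytest.approx(0.3)),
])
def test_ranked_marginal_loss_closed_forms(g1, g2, y, m, expected):
    assert ranked_marginal_loss(g1, g2, y, m) == expected


def test_ranked_marginal_loss_nonnegative_and_zero_condition(rng):
    g1 = rng.random(50)
    g2 = rng.random(50)
    y = rng.choice([-1.0, 1.0], 50)
    loss = ranked_marginal_loss(g1, g2, y, 0.25)
    assert (loss >= 0).all()
    zero = loss == 0
    np.testing.assert_array_equal(zero, -y * (g1 - g2) <= -0.25)


def test_pairwise_distance_identities():
    e = np.zeros(4)
    e[0] = 1.0
    assert pairwise_distance(e, e) == 0.0
    assert pairwise_distance(e, -e) == pytest.approx(1.0)
    f = np.zeros(4)
    f[1] = 1.0
    assert pairwise_distance(e, f) == pytest.approx(np.sqrt(2) / 2)
    with pytest.raises(ValueError):
        pairwise_distance(2 * e, e)


def test_triplet_embeddings_unit_norm_and_shared_weights(rng):
    net = build_triplet(rng=rng)
    crops = rng.integers(0, 256, (3, 64, 64)).astype(float)
    emb = net.embed(crops)
    np.testing.assert_allclose(np.linalg.norm(emb, axis=1), 1.0, atol=1e-6)
    # identical inputs through the shared weights give identical embeddings
    same = net.embed(np.stack([crops[0], crops[0]]))
    np.testing.assert_allclose(same[0], same[1], atol=1e-7)


def test_train_triplet_beats_chance_and_is_reproducible(small_crop_bank):
    images, labels = small_crop_bank
    hists = []
    for _ in range(2):
        net, hist = train_triplet("A", (images, labels), rng=np.random.default_rng(5),
                                  n_train=512, n_val=256, batch_size=128)
        hists.append(hist)
    assert hists[0]["val_triplet_accuracy"] > 0.5
    assert hists[0]["loss"] == hists[1]["loss"]
    assert len(hists[0]["loss"]) == 4  # 512 triplets / 128 per batch


def test_train_triplet_missing_class_errors(small_crop_bank):
    images, labels = small_crop_bank
    keep = labels != CLASS_INDEX["DYN"]
    with pytest.raises(ValueError, match="DYN"):
        train_triplet("A", (images[keep], labels[keep]), rng=0, n_train=64, n_val=8)


# ---------------------------------------------------------------- fusion

class _FakeNet:
    """Embedding stub: maps mean intensity to a fixed unit vector."""

    def __init__(self, mapping):
        self.mapping = mapping  # intensity bucket -> embedding

    def embed(self, crops):
        out = []
        for c in np.atleast_3d(crops):
            key = int(c.mean() > 128)
            out.append(self.mapping[key])
        return np.stack(out)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def test_fuse_debris_decision_is_final():
    probs = np.array([0.02, 0.9, 0.02, 0.02, 0.02, 0.02])
    label, scores = fuse(probs, {}, {}, np.zeros((64, 64)))
    assert label == "DEB" and scores == {}


def test_fuse_product_rule_arithmetic():
    # CNN: CC=0.40, APO=0.35; distances d_CC=0.1, d_APO=0.8
    e_q = _unit([1, 0, 0])
    d_cc, d_apo = 0.1, 0.8

    def anchor_at_distance(d):
        # unit vector at ||e_q - a||/2 = d from e_q
        theta = 2 * np.arcsin(d)
        return _unit([np.cos(theta), np.sin(theta), 0])

    net = _FakeNet({0: e_q, 1: e_q})
    anchors = {"CC": anchor_at_distance(d_cc)[None], "APO": anchor_at_distance(d_apo)[None]}
    probs = np.array([0.40, 0.05, 0.05, 0.10, 0.05, 0.35])
    label, scores = fuse(probs, {"B": net}, anchors, np.zeros((64, 64)))
    assert label == "CC"
    assert scores["CC"] == pytest.approx(0.40 * (1 - d_cc), abs=1e-6)
    assert scores["APO"] == pytest.approx(0.35 * (1 - d_apo), abs=1e-6)


def test_fuse_tie_goes_to_cnn_argmax():
    e_q = _unit([1, 0, 0])
    net = _FakeNet({0: e_q, 1: e_q})
    anchors = {"AT": e_q[None], "DYN": e_q[None]}  # both distances 0
    probs = np.array([0.0, 0.0, 0.0, 0.5, 0.5, 0.0])
    probs = probs / probs.sum()
    label, scores = fuse(probs, {"A": net}, anchors, np.zeros((64, 64)))
    assert scores["AT"] == scores["DYN"]
    assert label == "AT"  # argmax of equal probs is the first (AT)


def test_fuse_empty_anchor_set_errors():
    probs = np.array([0.4, 0.05, 0.05, 0.1, 0.05, 0.35])
    net = _FakeNet({0: _unit([1, 0, 0]), 1: _unit([1, 0, 0])})
    with pytest.raises(ValueError, match="anchor"):
        fuse(probs, {"B": net}, {"CC": np.zeros((0, 3)), "APO": _unit([0, 1, 0])[None]},
             np.zeros((64, 64)))


# ---------------------------------------------------------------- protocol

def test_kfold_split_reproduces_study_fold_sizes(rng):
    counts = [122, 113, 135, 132, 104, 178]
    labels = np.concatenate([np.full(n, i) for i, n in enumerate(counts)])
    val_idx, folds = kfold_split(labels, k=5, held_out_val=10, rng=rng)
    assert len(val_idx) == 60
    sizes = sorted(len(f) for f in folds)
    assert sizes == [144, 145, 145, 145, 145]
    union = np.concatenate(folds)
    assert len(union) == 724
    assert len(np.unique(union)) == 724
    assert set(union).isdisjoint(set(val_idx))


def test_kfold_split_deterministic_and_validating():
    labels = np.repeat(np.arange(6), 20)
    a = kfold_split(labels, rng=np.random.default_rng(2))
    b = kfold_split(labels, rng=np.random.default_rng(2))
    np.testing.assert_array_equal(a[0], b[0])
    for fa, fb in zip(a[1], b[1]):
        np.testing.assert_array_equal(fa, fb)
    with pytest.raises(ValueError):
        kfold_split(np.repeat(np.arange(6), 12), k=5, held_out_val=10)


def test_random_hp_search_returns_max_candidate(small_crop_bank):
    images, labels = small_crop_bank
    train = (images[::2], labels[::2])
    val = (images[1::2], labels[1::2])
    space = {"lr": (1e-3, 1e-1), "momentum": (0.8, 0.9), "weight_decay": (1e-5, 1e-3)}
    best, results = random_hp_search(space, 2, train, val, rng=0, epochs=1)
    assert len(results) == 2
    assert best in [r["hp"] for r in results]
    best_acc = max(r["val_accuracy"] for r in results)
    assert next(r for r in results if r["hp"] is best)["val_accuracy"] == best_acc
    for r in results:
        assert 1e-3 <= r["hp"].lr <= 1e-1
        assert r["hp"].momentum in (0.8, 0.9)
        assert 1e-5 <= r["hp"].weight_decay <= 1e-3


# ---------------------------------------------------------------- occlusion

def test_occlusion_map_shape_and_stub_flatness():
    crop = np.random.default_rng(0).integers(0, 256, (64, 64)).astype(float)

    def constant_classifier(batch):
        return np.tile([0.1, 0.1, 0.1, 0.1, 0.1, 0.5], (len(batch), 1))

    heat = occlusion_probability_map(crop, constant_classifier, "APO")
    assert heat.shape == (60, 60)
    assert np.ptp(heat) == 0


def test_occlusion_masks_window_with_fill_value():
    crop = np.zeros((64, 64))
    seen = {}

    def spy(batch):
        seen.setdefault("first", batch[0].copy())
        return np.tile(np.ones(6) / 6, (len(batch), 1))

    occlusion_probability_map(crop, spy, "CC", window=5, fill=85.0)
    masked = seen["first"]
    assert (masked[0:5, 0:5] == 85.0).all()
    assert masked[10:, 10:].max() == 0.0
    with pytest.raises(ValueError):
        occlusion_probability_map(np.zeros((4, 4)), spy, "CC", window=5)


# ---------------------------------------------------------------- statistics

def test_confusion_identity_predictions():
    labels = list(CLASS_LABELS) * 3
    matrix, stats = confusion_and_stats(labels, labels)
    assert np.trace(matrix) == 18
    assert matrix.sum() == 18
    assert stats["overall_accuracy"] == 100.0
    assert all(v == 100.0 for v in stats["per_class_accuracy"].values())


def test_confusion_rejects_unknown_labels():
    with pytest.raises(ValueError):
        confusion_and_stats(["CC", "XX"], ["CC", "CC"])


def test_anchor_selection_nearest_centroid(small_crop_bank, rng):
    images, labels = small_crop_bank
    net = build_triplet(rng=rng)
    anchors = select_anchors(net, images, labels, "AT", n_anchors=5)
    assert anchors.shape == (5, 128)
    np.testing.assert_allclose(np.linalg.norm(anchors, axis=1), 1.0, atol=1e-5)
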