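"""Hierarchical six-class hESC classifier.

A small CNN produces six softmax scores; two triplet CNNs refine the two
visually confusable pairs (Attached vs Dynamically blebbing, and Cell clusters
vs Apoptotically blebbing).  The final decision is a product-rule fusion: the
CNN probability of a candidate class is multiplied by the complementary
embedding distance (1 - mean distance to that class's anchors), and the larger
product wins.  Debris and Unattached predictions are taken from the CNN alone.

The CNN layer stack is
``Conv(7,2,3)x64 -> MaxPool(3,2,1) -> Conv(5,2,2)x128 -> MaxPool(3,2,1) ->
FC(2048 -> 6)`` on 64x64 inputs scaled to [-1, 1].

The triplet CNNs share one convolutional stem whose feature maps feed two
branches — a spatially pooled *coarse* branch that keeps the early, large
receptive-field representation, and a *fine* branch of two further strided
convolutions — whose flattened features are concatenated and projected to a
unit-norm 128-d embedding.  They are trained with a ranked marginal loss

    L = max(0, -Y (G(X1) - G(X2)) + margin),   margin = 1

where G(X) is the query-anchor pairwise distance; labels are fed so that
minimizing L shrinks the same-class distance relative to the other-class one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, warp

from . import nn
from .image_io import CLASS_LABELS, CLASS_INDEX, DatasetManifest, load_crops, to_network_range

#: class pairs refined by the two triplet networks
TRIPLET_PAIRS: dict[str, tuple[str, str]] = {"A": ("AT", "DYN"), "B": ("CC", "APO")}
CNN_ONLY_CLASSES = ("DEB", "UN")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class HyperParams:
    lr: float
    momentum: float
    weight_decay: float


#: best hyper-parameters for the three networks
DEFAULT_HP: dict[str, HyperParams] = {
    "cnn": HyperParams(1.2e-2, 0.9, 1e-3),
    "triplet_A": HyperParams(1.2e-2, 0.8, 1e-3),
    "triplet_B": HyperParams(2e-2, 0.8, 1e-3),
}


@dataclass
class AugmentationConfig:
    rotation_deg: tuple[float, float] = (-180.0, 180.0)
    shear_deg: tuple[float, float] = (0.0, 30.0)
    zoom: tuple[float, float] = (0.70, 1.40)


@dataclass
class TripletLayout:
    """Config-exposed layer sizes of the triplet architecture."""

    stem_maps: int = 32
    fine_maps: tuple[int, int] = (64, 64)
    coarse_pool: int = 4
    embed_dim: int = 128


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

class CNNModel:
    """Six-class CNN on 64x64 grayscale crops."""

    INPUT = 64
    FLAT = 2048

    def __init__(self, rng: np.random.Generator | int | None = None, dtype=np.float32):
        rng = np.random.default_rng(rng)
        self.net = nn.Sequential(
            nn.Conv2d(1, 64, k=7, stride=2, pad=3, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.MaxPool2d(k=3, stride=2, pad=1),
            nn.Conv2d(64, 128, k=5, stride=2, pad=2, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.MaxPool2d(k=3, stride=2, pad=1),
            nn.Flatten(),
            nn.Linear(self.FLAT, len(CLASS_LABELS), rng=rng, dtype=dtype),
        )

    def _check(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1:] != (1, self.INPUT, self.INPUT):
            raise ValueError(f"expected (B,1,{self.INPUT},{self.INPUT}) input, got {x.shape}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check(x)
        return self.net.forward(x, train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.net.backward(gout)

    def params(self):
        return self.net.params()

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for [0, 255] crops (N,64,64)."""
        logits = self.forward(to_network_range(crops), train=False)
        return nn.softmax(logits)

    def feature_length(self) -> int:
        """Flattened feature length entering the fully connected layer."""
        x = np.zeros((1, 1, self.INPUT, self.INPUT), dtype=np.float32)
        for layer in self.net.layers[:-1]:
            x = layer.forward(x, train=False)
        return int(x.shape[1])


def build_cnn(rng: np.random.Generator | int | None = None) -> CNNModel:
    return CNNModel(rng)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(crop: np.ndarray, cfg: AugmentationConfig | None = None,
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Random rotation/shear/zoom of a crop; gaps filled with the median intensity."""
    cfg = cfg or AugmentationConfig()
    rng = np.random.default_rng(rng)
    crop = np.asarray(crop, dtype=float)
    rot = np.deg2rad(rng.uniform(*cfg.rotation_deg))
    shear = np.deg2rad(rng.uniform(*cfg.shear_deg))
    zoom = rng.uniform(*cfg.zoom)
    h, w = crop.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = (AffineTransform(translation=-center)
         + AffineTransform(rotation=rot, shear=shear, scale=(zoom, zoom))
         + AffineTransform(translation=center))
    out = warp(crop, t.inverse, order=1, cval=float(np.median(crop)),
               mode="constant", preserve_range=True)
    return np.clip(out, 0.0, 255.0)


# ---------------------------------------------------------------------------
# CNN training
# ---------------------------------------------------------------------------

def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, DatasetManifest):
        return load_crops(data)
    images, labels = data
    return np.asarray(images, dtype=float), np.asarray(labels, dtype=int)


def _accuracy(model: CNNModel, images: np.ndarray, labels: np.ndarray,
              batch: int = 256) -> float:
    correct = 0
    for i in range(0, len(images), batch):
        probs = model.predict_proba(images[i:i + batch])
        correct += int((probs.argmax(axis=1) == labels[i:i + batch]).sum())
    return correct / max(len(images), 1)


def train_cnn(train, val, hp: HyperParams | None = None,
              rng: np.random.Generator | int | None = None,
              *, batch_size: int = 64, max_epochs: int = 50, patience: int = 3,
              augment_cfg: AugmentationConfig | None = None,
              require_all_classes: bool = True) -> tuple[CNNModel, dict]:
    """SGD/cross-entropy training with early stopping on validation accuracy.

    The model is checkpointed only when validation accuracy improves; training
    stops once it has not improved for ``patience`` consecutive epochs.
    ``train``/``val`` are either manifests or ``(images, labels)`` pairs with
    intensities in [0, 255].
    """
    hp = hp or DEFAULT_HP["cnn"]
    rng = np.random.default_rng(rng)
    x_tr, y_tr = _as_arrays(train)
    x_va, y_va = _as_arrays(val)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("both training and validation splits must be non-empty")
    if require_all_classes and len(np.unique(y_tr)) < len(CLASS_LABELS):
        missing = sorted(set(range(len(CLASS_LABELS))) - set(np.unique(y_tr)))
        raise ValueError(f"training split is missing classes {missing}")

    model = CNNModel(rng)
    opt = nn.SGD(model.params(), lr=hp.lr, momentum=hp.momentum, weight_decay=hp.weight_decay)
    best_state = model.net.state_dict()
    best_acc = -1.0
    since_improved = 0
    history = {"train_loss": [], "val_accuracy": []}

    for epoch in range(max_epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            batch = x_tr[idx]
            if augment_cfg is not None:
                batch = np.stack([augment(im, augment_cfg, rng) for im in batch])
            xb = to_network_range(batch)
            logits = model.forward(xb, train=True)
            loss, g = nn.softmax_cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            model.backward(g.astype(logits.dtype))
            opt.step()
            losses.append(loss)
        val_acc = _accuracy(model, x_va, y_va)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.net.state_dict()
            since_improved = 0
        else:
            since_improved += 1
            if since_improved >= patience:
                break
    model.net.load_state_dict(best_state)
    history["best_val_accuracy"] = best_acc
    return model, history


# ---------------------------------------------------------------------------
# triplet network
# ---------------------------------------------------------------------------

def ranked_marginal_loss(g1, g2, y, margin: float = 1.0):
    """max(0, -Y (G(X1) - G(X2)) + margin), elementwise; always >= 0."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.maximum(0.0, -y * (g1 - g2) + margin)


def pairwise_distance(e1: np.ndarray, e2: np.ndarray, atol: float = 1e-3):
    """d = ||e1 - e2|| / 2 for unit embeddings; lies in [0, 1]."""
    e1 = np.atleast_2d(np.asarray(e1, dtype=float))
    e2 = np.atleast_2d(np.asarray(e2, dtype=float))
    for e in (e1, e2):
        norms = np.linalg.norm(e, axis=1)
        if not np.allclose(norms, 1.0, atol=atol):
            raise ValueError("embeddings must be unit-normalized")
    d = np.linalg.norm(e1 - e2, axis=1) / 2.0
    return d if d.size > 1 else float(d[0])


class TripletNet:
    """Shared-stem two-branch embedding network (coarse + fine, concatenated)."""

    INPUT = 64

    def __init__(self, layout: TripletLayout | None = None,
                 rng: np.random.Generator | int | None = None, dtype=np.float32):
        self.layout = layout or TripletLayout()
        rng = np.random.default_rng(rng)
        lo = self.layout
        self.stem = nn.Sequential(
            nn.Conv2d(1, lo.stem_maps, k=5, stride=2, pad=2, rng=rng, dtype=dtype),
            nn.ReLU(),
        )  # 64 -> 32
        self.coarse = nn.Sequential(
            nn.MaxPool2d(k=lo.coarse_pool, stride=lo.coarse_pool, pad=0),
            nn.Flatten(),
        )  # 32 -> 8 spatially
        f1, f2 = lo.fine_maps
        self.fine = nn.Sequential(
            nn.Conv2d(lo.stem_maps, f1, k=5, stride=2, pad=2, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(f1, f2, k=5, stride=2, pad=2, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Flatten(),
        )  # 32 -> 16 -> 8 spatially
        stem_hw = self.INPUT // 2
        coarse_len = lo.stem_maps * (stem_hw // lo.coarse_pool) ** 2
        fine_len = f2 * (stem_hw // 4) ** 2
        self.head = nn.Sequential(
            nn.Linear(coarse_len + fine_len, lo.embed_dim, rng=rng, dtype=dtype),
            nn.L2Normalize(),
        )
        self._coarse_len = coarse_len

    def params(self):
        return (self.stem.params() + self.coarse.params()
                + self.fine.params() + self.head.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1:] != (1, self.INPUT, self.INPUT):
            raise ValueError(f"expected (B,1,{self.INPUT},{self.INPUT}) input, got {x.shape}")
        h = self.stem.forward(x, train=train)
        c = self.coarse.forward(h, train=train)
        f = self.fine.forward(h, train=train)
        return self.head.forward(np.concatenate([c, f], axis=1), train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.head.backward(gout)
        gc, gf = g[:, :self._coarse_len], g[:, self._coarse_len:]
        gh = self.coarse.backward(gc) + self.fine.backward(gf)
        return self.stem.backward(gh)

    def embed(self, crops: np.ndarray) -> np.ndarray:
        """Unit embeddings for [0, 255] crops (N,64,64)."""
        return self.forward(to_network_range(crops), train=False)

    # checkpointing helpers
    def state_dict(self):
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]


def build_triplet(layout: TripletLayout | None = None,
                  rng: np.random.Generator | int | None = None) -> TripletNet:
    return TripletNet(layout, rng)


def _sample_triplets(idx_by_class: tuple[np.ndarray, np.ndarray], n: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of (query, same-class anchor, other-class anchor) triplets."""
    q_cls = rng.integers(0, 2, size=n)
    q = np.empty(n, dtype=int)
    a_same = np.empty(n, dtype=int)
    a_other = np.empty(n, dtype=int)
    for side in (0, 1):
        sel = np.flatnonzero(q_cls == side)
        own, other = idx_by_class[side], idx_by_class[1 - side]
        q[sel] = rng.choice(own, size=sel.size)
        a_same[sel] = rng.choice(own, size=sel.size)
        a_other[sel] = rng.choice(other, size=sel.size)
    return q, a_same, a_other


def _triplet_distances(net: TripletNet, crops_q, crops_s, crops_o, train: bool):
    """Stack the three crop batches through the shared net; return d_same, d_other
    and the embeddings (kept stacked so one backward pass trains all branches)."""
    B = len(crops_q)
    x = to_network_range(np.concatenate([crops_q, crops_s, crops_o]))
    e = net.forward(x, train=train)
    eq, es, eo = e[:B], e[B:2 * B], e[2 * B:]
    d_same = np.linalg.norm(eq - es, axis=1) / 2.0
    d_other = np.linalg.norm(eq - eo, axis=1) / 2.0
    return e, d_same, d_other


def train_triplet(variant: str, train, hp: HyperParams | None = None,
                  rng: np.random.Generator | int | None = None,
                  *, n_train: int = 100_000, n_val: int = 5_000,
                  batch_size: int = 256, margin: float = 1.0,
                  layout: TripletLayout | None = None,
                  val=None) -> tuple[TripletNet, dict]:
    """Train triplet network A (AT/DYN) or B (CC/APO).

    ``n_train`` triplets are sampled with replacement from the two classes of
    the variant and consumed once in mini-batches; ``n_val`` validation
    triplets measure the fraction with d_same < d_other.  The ranked marginal
    loss is evaluated with the label convention that makes minimization
    enforce d_same + margin <= d_other.
    """
    if variant not in TRIPLET_PAIRS:
        raise ValueError(f"variant must be one of {sorted(TRIPLET_PAIRS)}")
    hp = hp or DEFAULT_HP[f"triplet_{variant}"]
    rng = np.random.default_rng(rng)
    images, labels = _as_arrays(train)
    pair = TRIPLET_PAIRS[variant]
    idx_by_class = tuple(np.flatnonzero(labels == CLASS_INDEX[c]) for c in pair)
    for c, idx in zip(pair, idx_by_class):
        if idx.size == 0:
            raise ValueError(f"class {c} missing from training data")

    net = TripletNet(layout, rng)
    opt = nn.SGD(net.params(), lr=hp.lr, momentum=hp.momentum, weight_decay=hp.weight_decay)

    vq, vs, vo = _sample_triplets(idx_by_class, n_val, rng)
    tq, ts, to = _sample_triplets(idx_by_class, n_train, rng)
    eps = 1e-8
    history = {"loss": [], "val_triplet_accuracy": None}
    for start in range(0, n_train, batch_size):
        sl = slice(start, min(start + batch_size, n_train))
        cq, cs, co = images[tq[sl]], images[ts[sl]], images[to[sl]]
        B = len(cq)
        e, d_same, d_other = _triplet_distances(net, cq, cs, co, train=True)
        # Y = -1 with X1 = same-class anchor: loss = max(0, (d_same - d_other) + margin)
        per = ranked_marginal_loss(d_same, d_other, -np.ones(B), margin)
        active = per > 0
        eq, es, eo = e[:B], e[B:2 * B], e[2 * B:]
        gd_same = active.astype(e.dtype) / B
        gd_other = -gd_same
        u_same = (eq - es) / (2.0 * np.linalg.norm(eq - es, axis=1, keepdims=True) + eps)
        u_other = (eq - eo) / (2.0 * np.linalg.norm(eq - eo, axis=1, keepdims=True) + eps)
        g = np.zeros_like(e)
        g[:B] = gd_same[:, None] * u_same + gd_other[:, None] * u_other
        g[B:2 * B] = -gd_same[:, None] * u_same
        g[2 * B:] = -gd_other[:, None] * u_other
        opt.zero_grad()
        net.backward(g)
        opt.step()
        history["loss"].append(float(per.mean()))

    correct = 0
    for start in range(0, n_val, 1024):
        sl = slice(start, min(start + 1024, n_val))
        _, d_same, d_other = _triplet_distances(
            net, images[vq[sl]], images[vs[sl]], images[vo[sl]], train=False)
        correct += int((d_same < d_other).sum())
    history["val_triplet_accuracy"] = correct / max(n_val, 1)
    return net, history


def select_anchors(net: TripletNet, images: np.ndarray, labels: np.ndarray,
                   class_label: str, n_anchors: int = 5) -> np.ndarray:
    """Embeddings of the ``n_anchors`` training images nearest the class centroid."""
    idx = np.flatnonzero(labels == CLASS_INDEX[class_label])
    if idx.size == 0:
        raise ValueError(f"no images of class {class_label}")
    emb = net.embed(images[idx])
    centroid = emb.mean(axis=0)
    order = np.argsort(np.linalg.norm(emb - centroid, axis=1))
    return emb[order[:min(n_anchors, idx.size)]]


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def fuse(cnn_probs: np.ndarray, triplets: dict[str, TripletNet],
         anchors: dict[str, np.ndarray], query: np.ndarray) -> tuple[str, dict[str, float]]:
    """Product-rule decision fusion for one crop.

    DEB/UN CNN decisions are final.  Otherwise the relevant triplet network
    scores the two candidate classes as ``cnn_prob * (1 - mean anchor
    distance)``; the larger product wins, ties go to the CNN argmax.
    """
    cnn_probs = np.asarray(cnn_probs, dtype=float).ravel()
    if cnn_probs.shape != (len(CLASS_LABELS),) or not np.isclose(cnn_probs.sum(), 1.0, atol=1e-4):
        raise ValueError("cnn_probs must be a 6-vector summing to 1")
    top = CLASS_LABELS[int(cnn_probs.argmax())]
    if top in CNN_ONLY_CLASSES:
        return top, {}
    variant = "A" if top in TRIPLET_PAIRS["A"] else "B"
    pair = TRIPLET_PAIRS[variant]
    net = triplets[variant]
    e_q = net.embed(np.asarray(query, dtype=float)[None])
    scores: dict[str, float] = {}
    for c in pair:
        anc = anchors.get(c)
        if anc is None or len(anc) == 0:
            raise ValueError(f"empty anchor set for class {c}")
        d = float(np.mean(pairwise_distance(np.repeat(e_q, len(anc), axis=0), anc)))
        scores[c] = float(cnn_probs[CLASS_INDEX[c]] * (1.0 - d))
    c0, c1 = pair
    if scores[c0] == scores[c1]:
        return top, scores
    return (c0 if scores[c0] > scores[c1] else c1), scores


class HierarchicalClassifier:
    """CNN + triplet networks + anchors bundled behind one predict surface."""

    def __init__(self, cnn: CNNModel, triplets: dict[str, TripletNet],
                 anchors: dict[str, np.ndarray]):
        self.cnn = cnn
        self.triplets = triplets
        self.anchors = anchors

    def predict(self, crops: np.ndarray) -> list[str]:
        crops = np.asarray(crops, dtype=float)
        probs = self.cnn.predict_proba(crops)
        return [fuse(p, self.triplets, self.anchors, crop)[0]
                for p, crop in zip(probs, crops)]

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        """Class probabilities with the confusable pair re-weighted by fusion.

        For crops whose CNN argmax falls in a triplet pair, the two pair
        probabilities are redistributed proportionally to the fused scores
        (their sum is preserved), so the vector still sums to 1.
        """
        crops = np.asarray(crops, dtype=float)
        probs = self.cnn.predict_proba(crops).astype(float)
        for i, (p, crop) in enumerate(zip(probs, crops)):
            top = CLASS_LABELS[int(p.argmax())]
            if top in CNN_ONLY_CLASSES:
                continue
            _, scores = fuse(p, self.triplets, self.anchors, crop)
            (c0, s0), (c1, s1) = scores.items()
            total = p[CLASS_INDEX[c0]] + p[CLASS_INDEX[c1]]
            if s0 + s1 > 0:
                probs[i, CLASS_INDEX[c0]] = total * s0 / (s0 + s1)
                probs[i, CLASS_INDEX[c1]] = total * s1 / (s0 + s1)
        return probs


# ---------------------------------------------------------------------------
# protocol helpers
# ---------------------------------------------------------------------------

def kfold_split(labels: np.ndarray, k: int = 5, held_out_val: int = 10,
                rng: np.random.Generator | int | None = None
                ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Stratified k-fold split after removing a fixed per-class validation set.

    ``held_out_val`` images per class are removed first (the validation set);
    the remainder is stratified into ``k`` folds whose sizes are balanced to
    within one image.  Returns (validation indices, list of per-fold test
    indices); each remaining image appears in exactly one fold.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(rng)
    val_idx: list[int] = []
    remaining: dict[int, np.ndarray] = {}
    for ci in range(len(CLASS_LABELS)):
        idx = np.flatnonzero(labels == ci)
        if idx.size < k + held_out_val:
            raise ValueError(
                f"class {CLASS_LABELS[ci]} has {idx.size} images; "
                f"needs at least {k + held_out_val}")
        idx = rng.permutation(idx)
        val_idx.extend(idx[:held_out_val])
        remaining[ci] = idx[held_out_val:]

    folds: list[list[int]] = [[] for _ in range(k)]
    for ci in range(len(CLASS_LABELS)):
        idx = remaining[ci]
        base, extra = divmod(idx.size, k)
        pos = 0
        for f in range(k):
            folds[f].extend(idx[pos:pos + base])
            pos += base
        leftovers = idx[pos:]
        for item in leftovers:
            smallest = min(range(k), key=lambda f: (len(folds[f]), f))
            folds[smallest].append(item)
    return np.asarray(sorted(val_idx)), [np.asarray(sorted(f)) for f in folds]


def random_hp_search(space: dict, n_draws: int, train, val,
                     rng: np.random.Generator | int | None = None,
                     *, epochs: int = 3, batch_size: int = 64
                     ) -> tuple[HyperParams, list[dict]]:
    """Random hyper-parameter search: each candidate trains ``epochs`` epochs
    and the one with the highest validation accuracy wins.

    ``space`` keys: ``lr`` (log-uniform bounds), ``momentum`` (choices),
    ``weight_decay`` (log-uniform bounds).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng)
    lr_lo, lr_hi = space.get("lr", (1e-4, 1e-1))
    momenta = space.get("momentum", (0.8, 0.9, 0.95))
    wd_lo, wd_hi = space.get("weight_decay", (1e-5, 1e-2))
    results = []
    for _ in range(n_draws):
        hp = HyperParams(
            lr=float(np.exp(rng.uniform(np.log(lr_lo), np.log(lr_hi)))),
            momentum=float(momenta[rng.integers(len(momenta))]),
            weight_decay=float(np.exp(rng.uniform(np.log(wd_lo), np.log(wd_hi)))),
        )
        _, hist = train_cnn(train, val, hp, rng, batch_size=batch_size,
                            max_epochs=epochs, patience=epochs)
        results.append({"hp": hp, "val_accuracy": hist["best_val_accuracy"]})
    best = max(results, key=lambda r: r["val_accuracy"])
    return best["hp"], results


# ---------------------------------------------------------------------------
# interpretation and statistics
# ---------------------------------------------------------------------------

def occlusion_probability_map(crop: np.ndarray, classifier, target_class: str,
                              window: int = 5, fill: float = 85.0,
                              batch: int = 512) -> np.ndarray:
    """Occlusion-sensitivity heat map of a crop.

    A ``window`` x ``window`` patch of constant intensity ``fill`` slides over
    the crop with stride 1; at each valid center the classifier's probability
    of ``target_class`` is recorded.  ``classifier`` is any callable mapping
    (N, 64, 64) crops to (N, 6) class probabilities.  The map has dimensions
    (H - window + 1) x (W - window + 1).
    """
    crop = np.asarray(crop, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    H, W = crop.shape
    if window > H or window > W:
        raise ValueError("window larger than crop")
    fn = classifier.predict_proba if hasattr(classifier, "predict_proba") else classifier
    half = window // 2
    oh, ow = H - window + 1, W - window + 1
    centers = [(r + half, c + half) for r in range(oh) for c in range(ow)]
    target = CLASS_INDEX[target_class]
    out = np.empty(oh * ow)
    for start in range(0, len(centers), batch):
        chunk = centers[start:start + batch]
        stack = np.repeat(crop[None], len(chunk), axis=0)
        for i, (r, c) in enumerate(chunk):
            stack[i, r - half:r + half + 1, c - half:c + half + 1] = fill
        out[start:start + len(chunk)] = np.asarray(fn(stack))[:, target]
    return out.reshape(oh, ow)


def confusion_and_stats(true_labels, predicted_labels) -> tuple[np.ndarray, dict]:
    """6x6 confusion matrix (rows = true) plus the derived statistics.

    Statistics: overall accuracy = 100 * trace / total; per-class accuracy =
    100 * diagonal / row sum; pairwise misclassification between classes A, B =
    100 * (count(A->B) + count(B->A)) / (rowsum(A) + rowsum(B)).
    """
    def to_idx(seq):
        out = []
        for v in seq:
            if isinstance(v, str):
                if v not in CLASS_INDEX:
                    raise ValueError(f"unknown label {v!r}")
                out.append(CLASS_INDEX[v])
            else:
                iv = int(v)
                if not 0 <= iv < len(CLASS_LABELS):
                    raise ValueError(f"unknown label index {iv}")
                out.append(iv)
        return np.asarray(out, dtype=int)

    t = to_idx(true_labels)
    p = to_idx(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    n = len(CLASS_LABELS)
    matrix = np.zeros((n, n), dtype=int)
    np.add.at(matrix, (t, p), 1)
    return matrix, matrix_stats(matrix)


def matrix_stats(matrix: np.ndarray) -> dict:
    """Derived statistics of a 6x6 confusion matrix (axis order CC..APO)."""
    matrix = np.asarray(matrix, dtype=float)
    total = matrix.sum()
    row = matrix.sum(axis=1)
    per_class = {
        c: (100.0 * matrix[i, i] / row[i] if row[i] else float("nan"))
        for i, c in enumerate(CLASS_LABELS)
    }
    pairwise = {}
    for i, a in enumerate(CLASS_LABELS):
        for j, b in enumerate(CLASS_LABELS):
            if j <= i:
                continue
            denom = row[i] + row[j]
            pairwise[f"{a}/{b}"] = (
                100.0 * (matrix[i, j] + matrix[j, i]) / denom if denom else float("nan"))
    return {
        "overall_accuracy": 100.0 * np.trace(matrix) / total if total else float("nan"),
        "per_class_accuracy": per_class,
        "pairwise_misclassification": pairwise,
    }
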