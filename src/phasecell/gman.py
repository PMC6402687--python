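"""Generative Multi-Adversarial Network: one generator, three discriminators.

The generator maps a 100-d standard-normal noise vector through a fully
connected layer to 8,192 units, reshapes to 512 maps of 4x4, and upsamples
through four transposed convolutions (kernel 6, stride 2, pad 2) with
256/128/64/1 maps to a 64x64 tanh-bounded image.  The three discriminators are
strided-convolution stacks (kernel 5, stride 2, pad 2) of different capacity
ending in a single logistic unit.

The per-discriminator generator objectives V_i = E[log(1 - D_i(G(z)))] (always
negative) are aggregated by the lambda-weighted geometric mean

    GM(V, lambda) = -exp( sum_i w_i log(-V_i) ),  w_i = e^{lambda V_i} / sum_j e^{lambda V_j}

which the generator minimizes; lambda = 0 recovers the plain geometric mean,
and larger lambda focuses the generator on its best-performing adversary.
Discriminators minimize binary cross-entropy plus an intensity embedding
penalty alpha * mean ||X_i - X||^2 against a randomly drawn same-class real
image.  One independent model is trained per cell class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .image_io import from_network_range, to_network_range

NOISE_DIM = 100


@dataclass
class GMANConfig:
    lambda_: float = 1.0          # aggregation sharpness (>= 0)
    alpha: float = 5e-2           # embedding-loss weight
    lr_generator: float = 1e-4
    lr_discriminators: float = 1e-5
    batch_size: int = 32
    steps: int = 2000             # generator updates
    batchnorm: bool = True


class Generator:
    """100-d noise -> 64x64 image in [-1, 1]."""

    FC_OUT = 8192

    def __init__(self, rng: np.random.Generator | int | None = None,
                 batchnorm: bool = True, dtype=np.float32):
        rng = np.random.default_rng(rng)
        layers: list[nn.Module] = [
            nn.Linear(NOISE_DIM, self.FC_OUT, rng=rng, dtype=dtype),
            nn.Reshape(512, 4, 4),
        ]
        chans = [(512, 256), (256, 128), (128, 64)]
        for c_in, c_out in chans:
            layers.append(nn.ConvTranspose2d(c_in, c_out, k=6, stride=2, pad=2,
                                             rng=rng, dtype=dtype))
            if batchnorm:
                layers.append(nn.BatchNorm2d(c_out, dtype=dtype))
            layers.append(nn.ReLU())
        layers.append(nn.ConvTranspose2d(64, 1, k=6, stride=2, pad=2, rng=rng, dtype=dtype))
        layers.append(nn.Tanh())
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, z: np.ndarray, train: bool = True) -> np.ndarray:
        z = np.asarray(z, dtype=np.float32)
        if z.ndim != 2 or z.shape[1] != NOISE_DIM:
            raise ValueError(f"noise must be (B, {NOISE_DIM}), got {z.shape}")
        return self.net.forward(z, train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.net.backward(gout)

    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)


#: channel progressions of the three discriminator capacity variants
_DISC_CHANNELS: dict[int, list[int]] = {
    1: [32, 64, 128, 256],
    2: [16, 32, 64, 128],
    3: [32, 64, 128, 256, 512],
}


class Discriminator:
    """64x64 image -> probability of being real; logits exposed for training."""

    def __init__(self, variant: int, rng: np.random.Generator | int | None = None,
                 batchnorm: bool = True, dtype=np.float32):
        if variant not in _DISC_CHANNELS:
            raise ValueError("variant must be 1, 2 or 3")
        rng = np.random.default_rng(rng)
        chans = _DISC_CHANNELS[variant]
        self.variant = variant
        layers: list[nn.Module] = []
        c_in, hw = 1, 64
        for i, c_out in enumerate(chans):
            layers.append(nn.Conv2d(c_in, c_out, k=5, stride=2, pad=2, rng=rng, dtype=dtype))
            if batchnorm and i > 0:
                layers.append(nn.BatchNorm2d(c_out, dtype=dtype))
            layers.append(nn.LeakyReLU(0.2))
            c_in, hw = c_out, hw // 2
        self.flat_len = c_in * hw * hw
        layers.append(nn.Flatten())
        layers.append(nn.Linear(self.flat_len, 1, rng=rng, dtype=dtype))
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(x, train=train)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        z = self.logits(x, train=train)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.net.backward(gout)


def build_generator(rng=None, batchnorm: bool = True) -> Generator:
    return Generator(rng, batchnorm=batchnorm)


def build_discriminators(rng=None, batchnorm: bool = True) -> list[Discriminator]:
    rng = np.random.default_rng(rng)
    return [Discriminator(v, rng, batchnorm=batchnorm) for v in (1, 2, 3)]


def weighted_geometric_mean(V, lambda_: float = 1.0) -> float:
    """GM(V, lambda) of negative per-discriminator objectives.

    Lies between min(V) and max(V); reduces to the plain geometric mean of the
    magnitudes at lambda = 0 and to V_1 for a single discriminator.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V >= 0):
        raise ValueError("all objectives must be negative")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    w = np.exp(lambda_ * V - (lambda_ * V).max())
    w = w / w.sum()
    return float(-np.exp(np.sum(w * np.log(-V))))


def gman_loss(p: np.ndarray, y: np.ndarray, batch: np.ndarray | None = None,
              reference: np.ndarray | None = None, alpha: float = 5e-2) -> float:
    """Binary cross-entropy plus alpha times the mean squared intensity
    difference between each batch image and its same-class real reference."""
    loss = nn.binary_cross_entropy(p, y)
    if alpha and batch is not None and reference is not None:
        diff = np.asarray(batch, dtype=float) - np.asarray(reference, dtype=float)
        loss += alpha * float((diff ** 2).mean(axis=tuple(range(1, diff.ndim))).mean())
    return loss


@dataclass
class GMANHistory:
    generator_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[list[float]] = field(default_factory=list)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def train_gman(class_images: np.ndarray, cfg: GMANConfig | None = None,
               rng: np.random.Generator | int | None = None
               ) -> tuple[Generator, list[Discriminator], GMANHistory]:
    """Adversarial training on the images of one class.

    Each step updates every discriminator on a real batch (label 1) and a
    generated batch (label 0) under the BCE + embedding loss, then updates the
    generator on the geometric-mean aggregation of the three discriminators'
    objectives.  Images are [0, 255] crops; Adam is used throughout with the
    generator at ``lr_generator`` and discriminators at ``lr_discriminators``.
    """
    cfg = cfg or GMANConfig()
    rng = np.random.default_rng(rng)
    class_images = np.asarray(class_images, dtype=float)
    if len(class_images) < 2:
        raise ValueError("need at least 2 images of the class")
    real_all = to_network_range(class_images)

    gen = Generator(rng, batchnorm=cfg.batchnorm)
    discs = build_discriminators(rng, batchnorm=cfg.batchnorm)
    g_opt = nn.Adam(gen.params(), lr=cfg.lr_generator)
    d_opts = [nn.Adam(d.params(), lr=cfg.lr_discriminators) for d in discs]
    B = cfg.batch_size
    hist = GMANHistory()
    eps = 1e-7

    for _ in range(cfg.steps):
        # ---- discriminator updates -----------------------------------
        idx = rng.integers(0, len(real_all), size=B)
        real = real_all[idx]
        z = rng.standard_normal((B, NOISE_DIM)).astype(np.float32)
        fake = gen.forward(z, train=True)
        ref = real_all[rng.integers(0, len(real_all), size=2 * B)]
        x = np.concatenate([real, fake])
        y = np.concatenate([np.ones(B), np.zeros(B)]).astype(np.float32)
        step_d_losses = []
        for d, opt in zip(discs, d_opts):
            logits = d.logits(x, train=True)
            bce, g = nn.bce_with_logits(logits, y)
            opt.zero_grad()
            d.backward(g.astype(logits.dtype))
            opt.step()
            # embedding term is constant w.r.t. D parameters; reported in the loss
            p = np.clip(_sigmoid(logits.reshape(-1)), eps, 1 - eps)
            step_d_losses.append(gman_loss(p, y, x, ref, cfg.alpha))
        hist.discriminator_loss.append(step_d_losses)

        # ---- generator update ----------------------------------------
        z = rng.standard_normal((B, NOISE_DIM)).astype(np.float32)
        fake = gen.forward(z, train=True)
        V, probs, shapes = [], [], []
        for d in discs:
            logits = d.logits(fake, train=True)
            p = np.clip(_sigmoid(logits.reshape(-1)), eps, 1 - eps)
            V.append(float(np.log(1 - p).mean()))
            probs.append(p)
            shapes.append(logits.shape)
        gm = weighted_geometric_mean(V, cfg.lambda_)
        Va = np.asarray(V)
        w = np.exp(cfg.lambda_ * Va - (cfg.lambda_ * Va).max())
        w = w / w.sum()
        # d GM / d V_i with the aggregation weights treated as constants
        dgm_dV = gm * w / Va
        # propagate through each discriminator to the image (D grads discarded)
        dL_dimg = np.zeros_like(fake)
        for d, coef, p, shape in zip(discs, dgm_dV, probs, shapes):
            glog = (coef * (-p) / B).reshape(shape).astype(np.float32)
            dL_dimg += d.backward(glog)
            for dp in d.params():
                dp.zero_grad()
        g_opt.zero_grad()
        gen.backward(dL_dimg)
        g_opt.step()
        hist.generator_loss.append(gm)

    return gen, discs, hist


def generate(gen: Generator, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sample n images from a trained generator, rescaled to [0, 255]."""
    rng = np.random.default_rng(rng)
    if n == 0:
        return np.zeros((0, 64, 64))
    out = []
    for start in range(0, n, 64):
        b = min(64, n - start)
        z = rng.standard_normal((b, NOISE_DIM)).astype(np.float32)
        out.append(from_network_range(gen.forward(z, train=False)[:, 0]))
    return np.concatenate(out)
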