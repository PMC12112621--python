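"""Virtual staining: adversarial image-to-image objectives and a
desk-scale trainer.

The model family is a conditional GAN: a generator G maps a grayscale
patch x to a stained 3-channel patch G(x); a discriminator D scores
stained patches.  The combined objective is

    L(G, D) = E_y[log D(y)] + E_x[log(1 - D(G(x)))] + λ E_{x,y}[|G(x) - y|_1]

with λ = 10 balancing the adversarial and L1 terms, plus a pixel-wise
transform loss L_transform = mean |G(x) - y| used for evaluation.

The trainer here is deliberately tiny — per-pixel (1×1-convolution)
encoder/decoder generator and a pooled logistic patch discriminator,
trained with Adam on CPU — so the adversarial mechanics are exercised
end-to-end on synthetic paired patches in seconds.  Image resolution is
free; 32×32 patches are the default working size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12


@dataclass(frozen=True)
class PairedPatch:
    """A grayscale input patch and its stained 3-channel target."""

    x: np.ndarray   # H x W
    y: np.ndarray   # H x W x 3

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape[:2] or self.y.shape[-1] != 3:
            raise ValueError("paired patch dims mismatch")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite patch values")


@dataclass
class StainObjectiveConfig:
    lambda_l1: float = 10.0
    learning_rate: float = 0.0002
    batch_size: int = 32
    epochs: int = 100
    hidden: int = 16

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


def standardize(x: np.ndarray) -> np.ndarray:
    """(x - mean) / population std; output has mean 0 and std 1."""
    x = np.asarray(x, dtype=float)
    sigma = x.std()
    if sigma < EPS:
        raise ValueError("constant input: standardization undefined")
    return (x - x.mean()) / sigma


def gan_objective(
    d_real: np.ndarray,
    d_fake: np.ndarray,
    g_out: np.ndarray,
    y: np.ndarray,
    lambda_l1: float = 10.0,
) -> float:
    """Combined adversarial + L1 objective (natural log, batch means).

    Discriminator outputs are clipped to (eps, 1-eps) before the logs,
    since the expression is undefined at exactly 0 or 1.
    """
    if np.shape(g_out) != np.shape(y):
        raise ValueError("generator output and target shapes differ")
    d_real = np.clip(np.asarray(d_real, dtype=float), EPS, 1 - EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=float), EPS, 1 - EPS)
    adv = float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))
    return adv + lambda_l1 * transform_loss(g_out, y)


def transform_loss(g_out: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute per-pixel difference: (1/(H·W)) Σ |G(x) - y|."""
    g_out, y = np.asarray(g_out, dtype=float), np.asarray(y, dtype=float)
    if g_out.shape != y.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(g_out - y)))


# ---------------------------------------------------------------------------
# Tiny per-pixel GAN
# ---------------------------------------------------------------------------


class PixelGenerator:
    """Per-pixel two-layer map 1 → hidden → 3 (a 1×1-conv encoder/decoder)."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.w1 = rng.normal(0, 0.2, (1, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0, 0.2, (hidden, 3))
        self.b2 = np.zeros(3)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # x: (..., 1)
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        return h @ self.w2 + self.b2, h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """x: H x W grayscale -> H x W x 3 stained."""
        out, _ = self.forward(np.asarray(x, dtype=float)[..., None])
        return out

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]


class PatchDiscriminator:
    """Per-pixel features, global average pooling, logistic output."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.w1 = rng.normal(0, 0.2, (3, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0, 0.2, (hidden, 1))
        self.b2 = np.zeros(1)

    def forward(self, y: np.ndarray):
        # y: (N, H, W, 3) -> probabilities (N,)
        h = np.maximum(y @ self.w1 + self.b1, 0.0)
        pooled = h.mean(axis=(1, 2))
        logit = (pooled @ self.w2 + self.b2)[:, 0]
        return 1.0 / (1.0 + np.exp(-logit)), h, pooled

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = 0.9, 0.999
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


@dataclass
class StainerModel:
    generator: PixelGenerator
    discriminator: PatchDiscriminator
    config: StainObjectiveConfig
    loss_trace: list[dict] = field(default_factory=list)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.generator(x)


def train_virtual_stainer(
    pairs: list[PairedPatch],
    config: StainObjectiveConfig | None = None,
    seed: int = 0,
    holdout: list[PairedPatch] | None = None,
) -> StainerModel:
    """Adversarially train the tiny stainer on paired patches.

    Alternates one discriminator ascent step and one generator descent
    step per minibatch; data order and initialization are seeded, so loss
    traces are reproducible.  The recorded trace holds, per epoch, the
    combined objective and the held-out transform loss (when a holdout
    set is given).
    """
    config = config or StainObjectiveConfig()
    if not pairs:
        raise ValueError("need at least one paired patch")
    shapes = {p.x.shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError("paired patches must share spatial dims")
    rng = np.random.default_rng(seed)
    G = PixelGenerator(config.hidden, rng)
    D = PatchDiscriminator(config.hidden, rng)
    model = StainerModel(G, D, config)

    X = np.stack([p.x for p in pairs])[..., None]     # (N, H, W, 1)
    Y = np.stack([p.y for p in pairs])                # (N, H, W, 3)
    n = len(pairs)
    model.loss_trace.append(_epoch_record(model, X, Y, holdout, config))
    opt_g = _Adam(G.params(), config.learning_rate)
    opt_d = _Adam(D.params(), config.learning_rate)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            fake, h_g = G.forward(xb)

            # --- discriminator ascent on log D(y) + log(1 - D(G(x)))
            _d_step(D, opt_d, yb, fake)

            # --- generator descent on log(1 - D(G(x))) + λ L1
            _g_step(G, D, opt_g, xb, yb, config.lambda_l1)
        model.loss_trace.append(_epoch_record(model, X, Y, holdout, config))
    return model


def _epoch_record(model, X, Y, holdout, config) -> dict:
    fake, _ = model.generator.forward(X)
    d_real, _, _ = model.discriminator.forward(Y)
    d_fake, _, _ = model.discriminator.forward(fake)
    rec = {
        "objective": gan_objective(d_real, d_fake, fake, Y, config.lambda_l1),
        "l1": transform_loss(fake, Y),
    }
    if holdout:
        Xh = np.stack([p.x for p in holdout])[..., None]
        Yh = np.stack([p.y for p in holdout])
        fh, _ = model.generator.forward(Xh)
        rec["holdout_l1"] = transform_loss(fh, Yh)
    return rec


def _d_step(D, opt, y_real, y_fake) -> None:
    n = len(y_real)
    grads = [np.zeros_like(p) for p in D.params()]
    for ybatch, sign in ((y_real, 1.0), (y_fake, -1.0)):
        p, h, pooled = D.forward(ybatch)
        p = np.clip(p, EPS, 1 - EPS)
        # ascend log p for real, log(1-p) for fake: dL/dlogit = (1-p) or (-p)
        dlogit = (1.0 - p) if sign > 0 else (-p)
        dlogit = -dlogit / n   # negate: optimizer minimizes
        g_w2 = pooled.T @ dlogit[:, None]
        g_b2 = dlogit.sum(keepdims=True)
        dpooled = dlogit[:, None] @ D.w2.T
        H, W = ybatch.shape[1:3]
        dh = (dpooled[:, None, None, :] / (H * W)) * (h > 0)
        g_w1 = np.einsum("nhwc,nhwk->ck", ybatch, dh)
        g_b1 = dh.sum(axis=(0, 1, 2))
        for gacc, g in zip(grads, (g_w1, g_b1, g_w2, g_b2)):
            gacc += g
    opt.step(grads)


def _g_step(G, D, opt, xb, yb, lambda_l1: float) -> None:
    n = len(xb)
    fake, h_g = G.forward(xb)
    p, h_d, pooled = D.forward(fake)
    p = np.clip(p, EPS, 1 - EPS)
    # generator minimizes log(1 - D(G(x))) + λ mean|G(x) - y|
    dlogit = -p / n                       # d/dlogit of mean log(1-p)
    dpooled = dlogit[:, None] @ D.w2.T
    H, W = xb.shape[1:3]
    dh_d = (dpooled[:, None, None, :] / (H * W)) * (h_d > 0)
    dfake_adv = dh_d @ D.w1.T
    dfake_l1 = lambda_l1 * np.sign(fake - yb) / fake.size
    dfake = dfake_adv + dfake_l1
    g_w2 = np.einsum("nhwk,nhwc->kc", h_g, dfake)
    g_b2 = dfake.sum(axis=(0, 1, 2))
    dh_g = (dfake @ G.w2.T) * (h_g > 0)
    g_w1 = np.einsum("nhwc,nhwk->ck", xb, dh_g)
    g_b1 = dh_g.sum(axis=(0, 1, 2))
    opt.step([g_w1, g_b1, g_w2, g_b2])


def make_affine_stain_pairs(
    n: int,
    seed: int,
    shape: tuple[int, int] = (32, 32),
    coeffs: tuple[float, float, float] = (0.9, 0.55, 0.65),
    offsets: tuple[float, float, float] = (0.05, 0.1, 0.2),
) -> list[PairedPatch]:
    """Deterministic synthetic colormap task: stain = channel-wise affine map.

    The ideal generator is exactly representable by the per-pixel model,
    so the task isolates optimizer behavior from model capacity.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        x = rng.uniform(0, 1, shape)
        y = np.stack([c * x + o for c, o in zip(coeffs, offsets)], axis=-1)
        pairs.append(PairedPatch(x, y))
    return pairs
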