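"""Attribute-based zero-shot classification of cell subclasses.

A linear compatibility model scores how well a cell's 50-descriptor
morphometric vector x matches a class y described by an attribute vector
a_y in the same 50-dimensional registry space:

    f(x, y) = θ(x)ᵀ φ(y),   θ(x) = W x,   φ(y) = a_y

W is fitted by softmax cross-entropy over the seen classes with an L2
penalty (λ = 0.01), input dropout, and early stopping; classes never seen
in training are scored through their attribute vectors alone, which is
what makes zero-shot prediction of novel subclasses possible.  The L2
penalty is centered on the identity map, so attribute directions never
exercised by the seen classes fall back to direct descriptor–attribute
matching instead of collapsing to a zero score — without this, classes
whose attributes are orthogonal to everything seen in training would be
unrankable.

The attribute space is the morphometric registry itself, so φ(y) is a
class's prototypical morphometric profile; an optional dense projection
to a lower-dimensional embedding is supported but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometry import REGISTRY

DIM = len(REGISTRY.names)


@dataclass
class AttributeKB:
    """Semantic knowledge base: class name → attribute vector (registry order)."""

    attributes: dict[str, np.ndarray]
    seen: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, vec in self.attributes.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (DIM,):
                raise ValueError(f"attribute vector for {name!r} must have length {DIM}")
            if not np.isfinite(vec).all():
                raise ValueError(f"non-finite attributes for {name!r}")
            self.attributes[name] = vec
        unknown = set(self.seen) - set(self.attributes)
        if unknown:
            raise ValueError(f"seen classes missing from KB: {sorted(unknown)}")

    @property
    def class_order(self) -> list[str]:
        return list(self.attributes)

    def matrix(self, names: list[str]) -> np.ndarray:
        return np.stack([self.attributes[n] for n in names])


@dataclass
class CompatibilityModel:
    """Bilinear compatibility scorer f(x, y) = (W x)ᵀ a_y."""

    W: np.ndarray
    l2_lambda: float = 0.01
    fitted: bool = False
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (DIM, DIM):
            raise ValueError(f"W must be {DIM}x{DIM}")


def compatibility(x: np.ndarray, model: CompatibilityModel, a_y: np.ndarray) -> float:
    """Score (W x)ᵀ a_y; linear in both the features and the attributes."""
    x = np.asarray(x, dtype=float)
    a_y = np.asarray(a_y, dtype=float)
    if x.shape != (DIM,) or a_y.shape != (DIM,):
        raise ValueError("dimension mismatch with the descriptor registry")
    return float((model.W @ x) @ a_y)


@dataclass
class ZslFitConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 100
    dropout: float = 0.3
    l2_lambda: float = 0.01
    patience: int = 5
    val_fraction: float = 0.2
    init: str = "identity"   # "identity" | "zero"


def fit_compatibility(
    features: np.ndarray,
    labels: list[str],
    kb: AttributeKB,
    config: ZslFitConfig | None = None,
    seed: int = 0,
) -> CompatibilityModel:
    """Fit W by seen-class softmax cross-entropy + L2, with early stopping.

    Dropout is applied to input features during fitting only.  Training
    is fully seeded (init, batch order, dropout masks, validation split),
    so repeated fits are identical.
    """
    config = config or ZslFitConfig()
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != DIM:
        raise ValueError(f"features must be (n, {DIM})")
    missing = sorted(set(labels) - set(kb.attributes))
    if missing:
        raise ValueError(f"labels absent from KB: {missing}")
    seen = sorted(set(labels))
    if len(seen) < 2:
        raise ValueError("need at least two seen classes")
    not_seen_flagged = set(labels) - set(kb.seen)
    if kb.seen and not_seen_flagged:
        raise ValueError(f"training labels not marked seen: {sorted(not_seen_flagged)}")

    rng = np.random.default_rng(seed)
    A = kb.matrix(seen)                     # (K, DIM)
    y_idx = np.array([seen.index(l) for l in labels])
    n = len(labels)
    n_val = max(1, int(round(config.val_fraction * n)))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = order
    Xtr, ytr = features[train_idx], y_idx[train_idx]
    Xva, yva = features[val_idx], y_idx[val_idx]

    if config.init == "identity":
        W = np.eye(DIM)
    elif config.init == "zero":
        W = np.zeros((DIM, DIM))
    else:
        raise ValueError(f"unknown init {config.init!r}")
    center = np.eye(DIM)   # ridge center: identity compatibility
    opt_m = np.zeros_like(W)
    opt_v = np.zeros_like(W)
    t = 0
    best_val = np.inf
    best_W = W.copy()
    stale = 0
    trace: list[float] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            if config.dropout > 0:
                keep = rng.random(xb.shape) >= config.dropout
                xb = xb * keep / (1.0 - config.dropout)
            scores = xb @ W.T @ A.T            # (B, K)
            scores -= scores.max(axis=1, keepdims=True)
            p = np.exp(scores)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(len(yb)), yb] -= 1.0
            grad = A.T @ p.T @ xb / len(yb) + 2 * config.l2_lambda * (W - center)
            t += 1
            opt_m = 0.9 * opt_m + 0.1 * grad
            opt_v = 0.999 * opt_v + 0.001 * grad**2
            mhat = opt_m / (1 - 0.9**t)
            vhat = opt_v / (1 - 0.999**t)
            W -= config.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
        trace.append(_ce_loss(Xtr, ytr, W, A, 0.0))
        val_loss = _ce_loss(Xva, yva, W, A, config.l2_lambda)
        if val_loss < best_val - 1e-9:
            best_val, best_W, stale = val_loss, W.copy(), 0
        else:
            stale += 1
            if stale > config.patience:
                break
    return CompatibilityModel(best_W, config.l2_lambda, fitted=True, loss_trace=trace)


def _ce_loss(X, y, W, A, l2) -> float:
    scores = X @ W.T @ A.T
    scores -= scores.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(scores).sum(axis=1))
    penalty = l2 * ((W - np.eye(W.shape[0])) ** 2).sum()
    return float(-(scores[np.arange(len(y)), y] - logZ).mean() + penalty)


def cross_entropy_at_init(n_classes: int) -> float:
    """Uniform softmax cross-entropy: ln K (the W = 0 starting loss)."""
    return float(np.log(n_classes))


def predict(
    x: np.ndarray,
    model: CompatibilityModel,
    kb: AttributeKB,
    candidates: list[str],
) -> list[tuple[str, float]]:
    """Candidates ranked by descending compatibility.

    Candidates may include classes unseen at fit time; deterministic
    tie-break follows KB insertion order.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    missing = sorted(set(candidates) - set(kb.attributes))
    if missing:
        raise ValueError(f"candidates absent from KB: {missing}")
    kb_order = {name: i for i, name in enumerate(kb.class_order)}
    scored = [(name, compatibility(x, model, kb.attributes[name])) for name in candidates]
    scored.sort(key=lambda s: (-s[1], kb_order[s[0]]))
    return scored


def top1_accuracy(predictions: list[str], truths: list[str]) -> float:
    """Fraction of rank-1 predictions matching the truth."""
    if len(predictions) != len(truths):
        raise ValueError("length mismatch")
    if not truths:
        raise ValueError("empty inputs")
    return sum(p == t for p, t in zip(predictions, truths)) / len(truths)


def make_subclass_kb(seed: int = 0) -> AttributeKB:
    """Synthetic prototype KB with example leukocyte subclasses.

    Prototype attribute vectors are documented stand-ins expressed in
    registry units (not measured population means): subclasses share the
    parent class profile and differ along a few discriminative axes
    (nuclear shape factor, chromatin density, granularity).
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 1.0, DIM)
    kb: dict[str, np.ndarray] = {}
    parents = ["lymphocyte", "monocyte", "neutrophil", "myelocyte"]
    for i, parent in enumerate(parents):
        proto = base + rng.normal(0, 0.25, DIM)
        kb[parent] = proto
    kb["Lymphocyte T"] = kb["lymphocyte"] + _axis("nuclear_shape_factor", 0.8)
    kb["Lymphocyte B"] = kb["lymphocyte"] + _axis("chromatin_density", 0.8)
    kb["Promyelocyte-N"] = kb["myelocyte"] + _axis("granularity_index", 0.8)
    return AttributeKB(kb, seen=frozenset(parents))


def _axis(name: str, value: float) -> np.ndarray:
    v = np.zeros(DIM)
    v[REGISTRY.index(name)] = value
    return v
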