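"""Supervised classification stages over cell patches and feature tables.

Covers: the binary cross-entropy objective and the mononuclear vs
polynuclear leukocyte classifier; a 2048-dimensional deep-feature
contract backed by a seeded residual CNN; unsupervised outlier filtering
(Isolation Forest / Elliptic Envelope); monotone k-means discretization;
the eight-family classifier comparison harness with its top-3 selection
rule (precision, then F1); and the report-stage ensemble (random forest,
decision tree, gradient boosting; 100 estimators each) with its empirical
misclassification rate.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPS = 1e-12

EIGHT_FAMILIES: tuple[str, ...] = (
    "KNeighborsClassifier",
    "DecisionTreeClassifier",
    "RandomForestClassifier",
    "SVC",
    "GaussianNB",
    "GradientBoostingClassifier",
    "AdaBoostClassifier",
    "MLPClassifier",
)


def binary_cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """-(1/N) Σ [y log ŷ + (1-y) log(1-ŷ)], with ε-clipped probabilities."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    y_hat = np.clip(y_hat, EPS, 1 - EPS)
    return float(-np.mean(y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat)))


# ---------------------------------------------------------------------------
# Mononuclear / polynuclear classifier
# ---------------------------------------------------------------------------

@dataclass
class MonoPolyConfig:
    """Training protocol defaults for the nuclear-lobation classifier."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 50
    dropout: float = 0.5
    patience: int = 5
    val_fraction: float = 0.2


@dataclass
class MonoPolyModel:
    estimator: object
    feature_names: list[str]
    classes: tuple[str, str] = ("mononuclear", "polynuclear")
    val_curve: list[float] = field(default_factory=list)
    prior: float = 0.5
    trained: bool = False

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if not self.trained:
            label = self.classes[int(self.prior >= 0.5)]
            return np.array([label] * len(features))
        pred = self.estimator.predict(features[self.feature_names].to_numpy())
        return np.array([self.classes[int(p)] for p in pred])


def train_mono_poly(
    features: pd.DataFrame,
    labels: list[str],
    config: MonoPolyConfig | None = None,
    seed: int = 0,
) -> MonoPolyModel:
    """Train the mononuclear/polynuclear classifier on morphometric features.

    Feature mode: a logistic model (SGD, log loss, early stopping) over
    lobe-count-bearing descriptor tables.  Labels are "mononuclear" /
    "polynuclear".  Zero epochs returns an untrained model that predicts
    the majority prior.
    """
    config = config or MonoPolyConfig()
    y = np.array([{"mononuclear": 0, "polynuclear": 1}[l] for l in labels])
    names = list(features.columns)
    prior = float(y.mean())
    if config.epochs == 0:
        return MonoPolyModel(None, names, prior=prior, trained=False)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present for training")

    from sklearn.linear_model import SGDClassifier
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X = features.to_numpy(dtype=float)
    Xtr, Xva, ytr, yva = train_test_split(
        X, y, test_size=config.val_fraction, random_state=seed, stratify=y
    )
    scaler = StandardScaler().fit(Xtr)
    clf = SGDClassifier(
        loss="log_loss",
        learning_rate="constant",
        eta0=config.learning_rate,
        alpha=1e-4,
        random_state=seed,
        max_iter=1,
        warm_start=True,
        tol=None,
    )
    rng = np.random.default_rng(seed)
    best_loss, stale, best_coef = np.inf, 0, None
    curve: list[float] = []
    Xtr_s, Xva_s = scaler.transform(Xtr), scaler.transform(Xva)
    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr_s))
        clf.partial_fit(Xtr_s[order], ytr[order], classes=[0, 1])
        p = np.clip(clf.predict_proba(Xva_s)[:, 1], EPS, 1 - EPS)
        loss = binary_cross_entropy(yva, p)
        curve.append(loss)
        if loss < best_loss - 1e-9:
            best_loss, stale = loss, 0
            best_coef = (clf.coef_.copy(), clf.intercept_.copy())
        else:
            stale += 1
            if stale > config.patience:
                break
    if best_coef is not None:
        clf.coef_, clf.intercept_ = best_coef
    model = MonoPolyModel(
        make_pipeline(scaler, clf), names, val_curve=curve, prior=prior, trained=True
    )
    # re-wire the pipeline to reuse the fitted pieces
    model.estimator.steps[0] = ("standardscaler", scaler)
    model.estimator.steps[1] = ("sgdclassifier", clf)
    return model


# ---------------------------------------------------------------------------
# Deep-feature contract
# ---------------------------------------------------------------------------

class ResidualBackbone:
    """Seeded random-weight residual CNN emitting 2048-d pooled embeddings.

    A bottleneck residual architecture (stem convolution, four stages of
    1x1-3x3-1x1 bottleneck blocks with stride-2 stage transitions,
    global average pooling into a 2048-channel head).  ``blocks_per_stage
    = (3, 4, 6, 3)`` gives the classical 50-layer layout; the default
    (1, 1, 1, 1) keeps single-CPU forward passes fast while preserving
    the embedding contract.  Weights are He-initialized from the seed and
    never trained here: the embedding is a fixed random projection with
    convolutional structure, deterministic given the seed.
    """

    def __init__(
        self,
        seed: int = 42,
        input_size: int = 64,
        blocks_per_stage: tuple[int, ...] = (1, 1, 1, 1),
    ):
        self.input_size = input_size
        self.blocks_per_stage = blocks_per_stage
        rng = np.random.default_rng(seed)
        self.layers: list[dict] = []
        widths = (256, 512, 1024, 2048)
        c_in = 16
        self.stem = self._conv_init(rng, 3, c_in, 3)
        for stage, (width, n_blocks) in enumerate(zip(widths, blocks_per_stage)):
            mid = width // 16
            for b in range(n_blocks):
                stride = 2 if b == 0 else 1
                self.layers.append(
                    {
                        "conv1": self._conv_init(rng, c_in, mid, 1),
                        "conv2": self._conv_init(rng, mid, mid, 3),
                        "conv3": self._conv_init(rng, mid, width, 1),
                        "proj": (
                            self._conv_init(rng, c_in, width, 1)
                            if (stride != 1 or c_in != width)
                            else None
                        ),
                        "stride": stride,
                    }
                )
                c_in = width
        self.out_dim = c_in

    @staticmethod
    def _conv_init(rng, c_in, c_out, k):
        fan_in = c_in * k * k
        w = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
        return w

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
        # x: (H, W, C_in); w: (C_out, C_in, k, k); 'same' padding
        k = w.shape[-1]
        pad = k // 2
        xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(0, 1))
        windows = windows[::stride, ::stride]
        return np.einsum("hwckl,ockl->hwo", windows, w, optimize=True)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self.features(patch)

    def features(self, patch: np.ndarray) -> np.ndarray:
        """Embed an RGB patch; resized to the backbone input size first."""
        patch = np.asarray(patch, dtype=float)
        if patch.ndim != 3 or patch.shape[-1] != 3:
            raise ValueError("patch must be H x W x 3")
        if patch.shape[0] < 8 or patch.shape[1] < 8:
            raise ValueError("patch too small to embed")
        from skimage.transform import resize

        x = resize(
            patch, (self.input_size, self.input_size, 3), anti_aliasing=True
        )
        x = np.maximum(self._conv(x, self.stem, stride=2), 0.0)
        for layer in self.layers:
            identity = x
            h = np.maximum(self._conv(x, layer["conv1"], stride=layer["stride"]), 0.0)
            h = np.maximum(self._conv(h, layer["conv2"]), 0.0)
            h = self._conv(h, layer["conv3"])
            if layer["proj"] is not None:
                identity = self._conv(identity, layer["proj"], stride=layer["stride"])
            x = np.maximum(h + identity, 0.0)
        pooled = x.mean(axis=(0, 1))
        assert pooled.shape == (self.out_dim,)
        return pooled


def deep_features(patch: np.ndarray, backbone: ResidualBackbone) -> np.ndarray:
    """The deep-feature contract: f(x) ∈ R^2048, deterministic per backbone."""
    vec = backbone.features(patch)
    if vec.shape != (2048,):
        raise AssertionError("backbone violated the 2048-d contract")
    return vec


# ---------------------------------------------------------------------------
# Preprocessing: outlier filtering and discretization
# ---------------------------------------------------------------------------

def outlier_filter(
    table: pd.DataFrame,
    method: str = "isolation_forest",
    contamination: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Boolean keep-mask over rows; ~``contamination`` flagged as outliers."""
    if len(table) < 10:
        raise ValueError("need at least 10 rows for outlier detection")
    X = table.to_numpy(dtype=float)
    if contamination == 0:
        return np.ones(len(table), dtype=bool)
    if method == "isolation_forest":
        from sklearn.ensemble import IsolationForest

        est = IsolationForest(contamination=contamination, random_state=seed)
    elif method == "elliptic_envelope":
        from sklearn.covariance import EllipticEnvelope

        if np.any(X.std(axis=0) < 1e-12):
            raise ValueError("constant feature: covariance is degenerate")
        est = EllipticEnvelope(contamination=contamination, random_state=seed)
    else:
        raise ValueError(f"unknown outlier method {method!r}")
    return est.fit_predict(X) == 1


def discretize(table: pd.DataFrame, n_bins: int, seed: int = 0) -> pd.DataFrame:
    """K-means binning of every numeric column into ids 0..n_bins-1.

    Bin ids are re-ordered by centroid value, so the mapping is monotone
    in the underlying feature.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    from sklearn.preprocessing import KBinsDiscretizer

    out = {}
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float).reshape(-1, 1)
        if len(np.unique(vals)) < n_bins:
            raise ValueError(f"column {col!r} has fewer than {n_bins} distinct values")
        disc = KBinsDiscretizer(
            n_bins=n_bins,
            encode="ordinal",
            strategy="kmeans",
            random_state=seed,
        )
        out[col] = disc.fit_transform(vals)[:, 0].astype(int)
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# Eight-family comparison harness
# ---------------------------------------------------------------------------

@dataclass
class HarnessResult:
    metrics: pd.DataFrame          # Model, Model Precision, F1 Score, Decision Time
    ranking: list[str]             # all families, by precision then F1
    top3: list[str]


def _make_families(seed: int) -> dict[str, object]:
    from sklearn.ensemble import (
        AdaBoostClassifier,
        GradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "KNeighborsClassifier": KNeighborsClassifier(),
        "DecisionTreeClassifier": DecisionTreeClassifier(random_state=seed),
        "RandomForestClassifier": RandomForestClassifier(random_state=seed),
        "SVC": SVC(random_state=seed),
        "GaussianNB": GaussianNB(),
        "GradientBoostingClassifier": GradientBoostingClassifier(random_state=seed),
        "AdaBoostClassifier": AdaBoostClassifier(random_state=seed),
        "MLPClassifier": MLPClassifier(
            random_state=seed, max_iter=800, hidden_layer_sizes=(32,)
        ),
    }


def compare_classifiers(
    table: pd.DataFrame,
    labels: list[str] | np.ndarray,
    preprocessing: str = "none",
    seed: int = 0,
    n_bins: int = 5,
    contamination: float = 0.05,
) -> HarnessResult:
    """Train the eight families on an 80:20 split; rank by precision then F1.

    ``preprocessing`` is ``none``, ``outlier:isolation_forest``,
    ``outlier:elliptic_envelope`` or ``discretize``.  Decision time (mean
    per-split prediction wall time) is recorded but plays no role in the
    ranking and carries no determinism guarantee.
    """
    from sklearn.metrics import f1_score, precision_score
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two classes")
    X = table.copy()
    y = labels
    if preprocessing == "none":
        pass
    elif preprocessing.startswith("outlier:"):
        keep = outlier_filter(
            X, preprocessing.split(":", 1)[1], contamination=contamination, seed=seed
        )
        X, y = X[keep], y[keep]
    elif preprocessing == "discretize":
        X = discretize(X, n_bins=n_bins, seed=seed)
    else:
        raise ValueError(f"unknown preprocessing {preprocessing!r}")

    Xtr, Xte, ytr, yte = train_test_split(
        X.to_numpy(dtype=float), y, test_size=0.2, random_state=seed, stratify=y
    )
    rows = []
    for name, est in _make_families(seed).items():
        est.fit(Xtr, ytr)
        t0 = time.perf_counter()
        pred = est.predict(Xte)
        dt = time.perf_counter() - t0
        rows.append(
            {
                "Model": name,
                "Model Precision": precision_score(
                    yte, pred, average="macro", zero_division=0
                ),
                "F1 Score": f1_score(yte, pred, average="macro", zero_division=0),
                "Decision Time": dt,
            }
        )
    metrics = pd.DataFrame(rows)
    ranked = metrics.sort_values(
        ["Model Precision", "F1 Score", "Model"], ascending=[False, False, True]
    )["Model"].tolist()
    return HarnessResult(metrics=metrics, ranking=ranked, top3=ranked[:3])


# ---------------------------------------------------------------------------
# Report-stage ensemble
# ---------------------------------------------------------------------------

REPORT_MODELS = (
    "RandomForestClassifier",
    "DecisionTreeClassifier",
    "GradientBoostingClassifier",
)


def generate_report(
    cell_results: list[dict],
    table: pd.DataFrame,
    labels: list[str] | np.ndarray,
    seed: int = 0,
) -> dict:
    """Fit the three report ensembles and summarize pipeline outputs.

    Returns a JSON-ready structure with per-model held-out precision/F1,
    the empirical misclassification rate of the forest ensemble (the mean
    0/1 error of its trees' committee on held-out data), anomaly counts
    over all 15 shape labels (zero-filled), and leukocyte activity flags.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.metrics import f1_score, precision_score
    from sklearn.model_selection import train_test_split
    from sklearn.tree import DecisionTreeClassifier

    from .anomaly_rules import RBC_SHAPE_LABELS

    if table is None or len(table) == 0:
        raise ValueError("empty feature table")
    labels = np.asarray(labels)
    Xtr, Xte, ytr, yte = train_test_split(
        table.to_numpy(dtype=float),
        labels,
        test_size=0.2,
        random_state=seed,
        stratify=labels if len(set(labels.tolist())) > 1 else None,
    )
    models = {
        "RandomForestClassifier": RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "DecisionTreeClassifier": DecisionTreeClassifier(random_state=seed),
        "GradientBoostingClassifier": GradientBoostingClassifier(
            n_estimators=100, random_state=seed
        ),
    }
    model_metrics = {}
    l_rf = None
    for name, est in models.items():
        est.fit(Xtr, ytr)
        pred = est.predict(Xte)
        model_metrics[name] = {
            "precision": float(
                precision_score(yte, pred, average="macro", zero_division=0)
            ),
            "f1": float(f1_score(yte, pred, average="macro", zero_division=0)),
        }
        if name == "RandomForestClassifier":
            l_rf = float(np.mean(pred != yte))
    anomaly_counts = {label: 0 for label in RBC_SHAPE_LABELS}
    wbc_flags = 0
    for cell in cell_results:
        call = cell.get("anomaly")
        if call:
            anomaly_counts[call["label"]] = anomaly_counts.get(call["label"], 0) + 1
        if cell.get("wbc_flagged"):
            wbc_flags += 1
    return {
        "models": model_metrics,
        "rf_misclassification_rate": l_rf,
        "anomaly_counts": anomaly_counts,
        "wbc_activity_flags": wbc_flags,
        "n_cells": len(cell_results),
        "seed": seed,
    }
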