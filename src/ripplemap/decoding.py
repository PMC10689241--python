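"""Decoding laminar information from waveform-space position.

A per-layer regressor predicts current-source-density values from an event's
coordinates in the original waveform space, the reduced embedding, or the
feature space, under tenfold cross-validation; in the reduced space the
embedding is refit on each training fold and the test fold is projected into
it, so no test event shapes the space it is decoded from. Performance is the
explained variance 1 - var(y - y') / var(y), with a chance band from
decoding shuffled targets through the same folds. A support-vector
classifier (C = 1, RBF kernel) separates event origins in the reduced space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, SVR

logger = logging.getLogger(__name__)


def explained_variance(y: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - var(y - y') / var(y); at most 1, negative when worse than the
    mean predictor."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size < 2:
        raise ValueError("y and y_pred must share length >= 2")
    vy = np.var(y)
    if vy == 0:
        raise ValueError("explained variance undefined for constant y")
    return float(1.0 - np.var(y - y_pred) / vy)


class _WienerCascade:
    """Linear stage followed by a cubic polynomial output nonlinearity."""

    def __init__(self) -> None:
        self.linear = Ridge()
        self.poly: np.ndarray | None = None

    def fit(self, X, y):
        self.linear.fit(X, y)
        z = self.linear.predict(X)
        self.poly = np.polyfit(z, y, 3) if np.ptp(z) > 0 else np.array([0, 0, 1, 0])
        return self

    def predict(self, X):
        return np.polyval(self.poly, self.linear.predict(X))


def _make_model(model: str, seed: int | None):
    m = model.lower()
    if m == "svr":
        return SVR()
    if m == "wiener":
        return Ridge()
    if m == "wienercascade":
        return _WienerCascade()
    if m == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed)
    raise ValueError(f"unknown decoder model {model!r}")


@dataclass
class DecoderBundle:
    """Per-layer, per-fold decoders with their cross-validated scores."""

    space: str
    model: str
    layers: list[str]
    fold_models: dict  # layer -> list of fitted models (one per fold)
    fold_embeddings: list  # per-fold fitted reducers (reduced space only)
    scores: pd.DataFrame  # layer x fold explained variance
    chance: pd.DataFrame  # same, with shuffled targets
    scale: dict  # layer -> s.d. divisor
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def layer_score(self, layer: str) -> float:
        s = self.scores
        return float(s.loc[s["layer"] == layer, "ev"].mean())

    def chance_band(self, layer: str, q: float = 0.95) -> tuple[float, float]:
        c = self.chance.loc[self.chance["layer"] == layer, "ev"]
        return float(c.quantile(1 - q)), float(c.quantile(q))


def _fold_indices(n: int, folds: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return [order[f::folds] for f in range(folds)]


def train_csd_decoder(
    X: np.ndarray,
    csd: pd.DataFrame,
    space: str = "original",
    model: str = "svr",
    folds: int = 10,
    reduce_d: int = 4,
    reduce_method: str = "pca",
    seed: int | None = 0,
) -> DecoderBundle:
    """Tenfold cross-validated per-layer CSD decoders.

    ``X`` is the event coordinate matrix of the chosen input space:
    ``original`` (waveform cloud) and ``feature`` use it as given;
    ``reduced`` refits a ``reduce_method`` embedding of dimension
    ``reduce_d`` on each training fold and projects the test fold into it.
    CSD targets are scaled per layer by their s.d. only (no mean
    subtraction, preserving sink/source polarity). A shuffled-target control
    through the same folds defines the chance band.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    layers = [c.replace("csd_", "") for c in csd.columns if c.startswith("csd_")]
    if not layers:
        raise ValueError("csd table has no csd_<layer> columns")
    n = X.shape[0]
    if n < 100:
        raise ValueError("need at least 100 events with CSD")
    if space not in ("original", "reduced", "feature"):
        raise ValueError(f"unknown space {space!r}")
    rng = np.random.default_rng(seed)
    fold_idx = _fold_indices(n, folds, rng)
    small = [f for f in fold_idx if f.size < 5]
    if small:
        logger.warning("refolding: %d folds below 5 test events", len(small))
        folds = max(2, n // 5)
        fold_idx = _fold_indices(n, folds, rng)

    scale = {}
    targets = {}
    for l in layers:
        y = csd[f"csd_{l}"].to_numpy(dtype=float)
        sd = y.std()
        scale[l] = sd if sd > 0 else 1.0
        targets[l] = y / scale[l]

    shuffled = {l: rng.permutation(v) for l, v in targets.items()}

    fold_models: dict[str, list] = {l: [] for l in layers}
    fold_embeddings = []
    rows, chance_rows = [], []
    for f, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n), test)
        if space == "reduced":
            from .geometry import reduce_embedding

            emb = reduce_embedding(X[train], method=reduce_method, d=reduce_d, seed=seed)
            Xtr, Xte = emb.coords, emb.transform(X[test])
            fold_embeddings.append(emb)
        else:
            Xtr, Xte = X[train], X[test]
        for l in layers:
            reg = _make_model(model, seed).fit(Xtr, targets[l][train])
            fold_models[l].append(reg)
            rows.append(
                {"layer": l, "fold": f, "ev": explained_variance(targets[l][test], reg.predict(Xte))}
            )
            ctrl = _make_model(model, seed).fit(Xtr, shuffled[l][train])
            chance_rows.append(
                {"layer": l, "fold": f, "ev": explained_variance(shuffled[l][test], ctrl.predict(Xte))}
            )
    return DecoderBundle(
        space=space,
        model=model,
        layers=layers,
        fold_models=fold_models,
        fold_embeddings=fold_embeddings,
        scores=pd.DataFrame(rows),
        chance=pd.DataFrame(chance_rows),
        scale=scale,
        seed=seed,
        meta={"folds": folds, "reduce_d": reduce_d, "reduce_method": reduce_method},
    )


def predict_csd(
    bundle: DecoderBundle, X: np.ndarray, scaled: bool = True
) -> pd.DataFrame:
    """Average prediction of the fold decoders for new coordinates.

    ``X`` must live in the bundle's input space: for a reduced-space bundle
    pass original-space coordinates — each fold's own embedding projects
    them. Set ``scaled=False`` to undo the per-layer s.d. scaling.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = {}
    for l in bundle.layers:
        preds = []
        for f, reg in enumerate(bundle.fold_models[l]):
            if bundle.space == "reduced":
                if X.shape[1] == bundle.meta["reduce_d"]:
                    raise ValueError(
                        "reduced-space bundle expects original-space coordinates"
                    )
                Xf = bundle.fold_embeddings[f].transform(X)
            else:
                Xf = X
            preds.append(reg.predict(Xf))
        p = np.mean(preds, axis=0)
        out[f"csd_{l}"] = p if scaled else p * bundle.scale[l]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# origin classification


def equalize_by_feature(
    labels: np.ndarray,
    feature: np.ndarray,
    n_bins: int = 10,
    seed: int | None = 0,
) -> np.ndarray:
    """Indices subsampling both classes to matched feature distributions.

    Histogram-bin matching: within each of ``n_bins`` equal-width feature
    bins, both classes are subsampled to the smaller class count in that bin.
    """
    labels = np.asarray(labels)
    feature = np.asarray(feature, dtype=float)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("equalization expects exactly 2 classes")
    rng = np.random.default_rng(seed)
    edges = np.linspace(feature.min(), feature.max(), n_bins + 1)
    binned = np.clip(np.digitize(feature, edges[1:-1]), 0, n_bins - 1)
    keep = []
    for b in range(n_bins):
        per_class = [np.flatnonzero((binned == b) & (labels == c)) for c in classes]
        m = min(len(ix) for ix in per_class)
        for ix in per_class:
            keep.append(rng.choice(ix, m, replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class OriginClassifierResult:
    accuracy: float
    fold_accuracies: np.ndarray
    shuffle_accuracies: np.ndarray
    p_value: float
    n_used: int
    meta: dict = field(default_factory=dict)


def train_origin_classifier(
    coords: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    kernel: str = "rbf",
    folds: int = 10,
    equalize: np.ndarray | None = None,
    n_shuffles: int = 100,
    seed: int | None = 0,
) -> OriginClassifierResult:
    """Tenfold SV classification of event origin in the reduced space.

    ``equalize`` optionally names a feature vector whose distribution is
    matched across classes before training. The accuracy fraction is tested
    against label shuffles re-run through the same pipeline.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need 2 classes")
    if equalize is not None:
        keep = equalize_by_feature(labels, equalize, seed=seed)
        coords, labels = coords[keep], labels[keep]
    counts = [np.sum(labels == c) for c in classes]
    if min(counts) < 50:
        logger.warning("origin classifier with a class below 50 events")

    def cv_accuracy(y, rng_seed):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        accs = []
        for tr, te in skf.split(coords, y):
            clf = SVC(C=C, kernel=kernel).fit(coords[tr], y[tr])
            accs.append(float(np.mean(clf.predict(coords[te]) == y[te])))
        return np.asarray(accs)

    fold_acc = cv_accuracy(labels, seed)
    rng = np.random.default_rng(seed)
    sh = np.empty(n_shuffles)
    for s in range(n_shuffles):
        sh[s] = cv_accuracy(rng.permutation(labels), seed).mean()
    acc = float(fold_acc.mean())
    p = float((np.sum(sh >= acc) + 1) / (n_shuffles + 1))
    return OriginClassifierResult(
        accuracy=acc,
        fold_accuracies=fold_acc,
        shuffle_accuracies=sh,
        p_value=p,
        n_used=len(labels),
        meta={"C": C, "kernel": kernel, "folds": folds, "equalized": equalize is not None},
    )
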