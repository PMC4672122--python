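"""Regularized morphological shared-weight neural network (RMSNN).

Architecture: two gray-scale Hit-Miss feature-extraction layers (shared
structuring elements, disk domain of radius 4 by default, feature maps
keep the input size via replicate padding at stride 1) feeding a fully
connected sigmoid classifier with one hidden layer and three output
nodes, one per spine morphology.  The Hit-Miss node

    a_y = min_{x in D}(a(x) - t_h(x)) - max_{x in D}(a(x) - t_m(x))

is invariant to additive intensity shifts, which the whole forward pass
inherits.

Training is per-sample (sequential) gradient descent on the squared
error E = 1/2 sum_o (t_o - O_o)^2 with weight-elimination
regularization

    R(w) = E_s(w) + lambda * sum (w/w0)^2 / (1 + (w/w0)^2),

which drives near-zero classifier weights to zero.  Structuring
elements receive subgradient updates concentrated on the recorded
arg-extremum of each min/max window (first raster-order index on ties),
accumulated over all window positions of a sample before application.

The numerics live twice: a pure-numpy reference in this module (used by
the gradient tests) and numba kernels in :mod:`spinewave._kernels` used
for training and scanning; a unit test keeps them identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import _kernels
from .morphology import disk_domain, square_domain
from .synthetic import CLASS_NAMES


@dataclass
class TrainingConfig:
    """Hyperparameters of sequential gradient-descent training.

    ``eta`` — learning rate (default 0.0015); ``lam``/``w0`` — weight
    elimination strength and scale; ``mse_target`` — mean per-sample
    squared error at which training stops; ``init_range`` — classifier
    weights start uniform in [-init_range, init_range] scaled by
    1/sqrt(fan-in); ``se_init`` — structuring elements start uniform in
    [-se_init, se_init].
    """

    eta: float = 0.0015
    max_epochs: int = 15000
    mse_target: float = 1e-3
    lam: float = 1e-4
    w0: float = 1.0
    init_range: float = 1.0
    se_init: float = 0.05
    seed: int = 0
    shuffle: bool = True
    regularize_ses: bool = False

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate eta must be > 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.w0 <= 0:
            raise ValueError("w0 must be > 0")


@dataclass
class RMSNNModel:
    """Two Hit-Miss feature layers (one SE pair per map, one-to-one map
    connectivity) plus a fully connected sigmoid classifier."""

    domain: np.ndarray  # (k, k) bool SE domain
    hit1: np.ndarray  # (M, nd) flat SE values over the domain
    miss1: np.ndarray
    hit2: np.ndarray
    miss2: np.ndarray
    W1: np.ndarray  # (hidden, M * input_size^2)
    b1: np.ndarray
    W2: np.ndarray  # (3, hidden)
    b2: np.ndarray
    input_size: int = 20
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        nd = int(self.domain.sum())
        for name in ("hit1", "miss1", "hit2", "miss2"):
            arr = getattr(self, name)
            if arr.shape[1] != nd:
                raise ValueError(f"{name} has {arr.shape[1]} values for a domain of {nd}")
        nf = self.hit1.shape[0] * self.input_size**2
        if self.W1.shape[1] != nf:
            raise ValueError("classifier input size must equal the flattened last feature layer")
        if self.W2.shape[0] != len(self.class_names):
            raise ValueError("output layer must have one node per class")

    @property
    def n_maps(self) -> int:
        return self.hit1.shape[0]

    @property
    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.domain.shape[0]
        c = (k - 1) // 2
        idx = np.argwhere(self.domain)
        return (idx[:, 0] - c).astype(np.int64), (idx[:, 1] - c).astype(np.int64)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "input_size": self.input_size,
            "class_names": list(self.class_names),
            "domain": self.domain.astype(int).tolist(),
        }
        for name in ("hit1", "miss1", "hit2", "miss2", "W1", "b1", "W2", "b2"):
            payload[name] = getattr(self, name).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "RMSNNModel":
        payload = json.loads(Path(path).read_text())
        kwargs = {
            name: np.asarray(payload[name], float)
            for name in ("hit1", "miss1", "hit2", "miss2", "W1", "b1", "W2", "b2")
        }
        return cls(
            domain=np.asarray(payload["domain"], bool),
            input_size=int(payload["input_size"]),
            class_names=tuple(payload["class_names"]),
            **kwargs,
        )


def one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Class-index labels to one-hot target rows ([1,0,0] = mushroom...)."""
    labels = np.asarray(labels, int)
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def init_model(
    n_maps: int = 2,
    hidden: int = 10,
    input_size: int = 20,
    se_shape: str = "disk:4",
    seed: int = 0,
    init_range: float = 1.0,
    se_init: float = 0.05,
) -> RMSNNModel:
    """Fresh model with small random structuring elements and uniform
    classifier weights scaled by 1/sqrt(fan-in)."""
    kind, _, size = se_shape.partition(":")
    size = int(size or 4)
    if kind == "disk":
        domain = disk_domain(size)
    elif kind == "square":
        domain = square_domain(size)
    else:
        raise ValueError(f"unknown SE shape {se_shape!r}")
    nd = int(domain.sum())
    rng = np.random.default_rng(seed)
    nf = n_maps * input_size**2
    return RMSNNModel(
        domain=domain,
        hit1=rng.uniform(-se_init, se_init, (n_maps, nd)),
        miss1=rng.uniform(-se_init, se_init, (n_maps, nd)),
        hit2=rng.uniform(-se_init, se_init, (n_maps, nd)),
        miss2=rng.uniform(-se_init, se_init, (n_maps, nd)),
        W1=rng.uniform(-init_range, init_range, (hidden, nf)) / np.sqrt(nf),
        b1=rng.uniform(-init_range, init_range, hidden) / np.sqrt(nf),
        W2=rng.uniform(-init_range, init_range, (3, hidden)) / np.sqrt(hidden),
        b2=rng.uniform(-init_range, init_range, 3) / np.sqrt(hidden),
        input_size=input_size,
    )


# ---------------------------------------------------------------------------
# pure-numpy reference path


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _hm_map_numpy(inp: np.ndarray, hitv: np.ndarray, missv: np.ndarray, dy: np.ndarray, dx: np.ndarray):
    h, w = inp.shape
    nd = hitv.shape[0]
    rr, cc = np.mgrid[0:h, 0:w]
    vals = np.empty((nd, h, w))
    for d in range(nd):
        ii = np.clip(rr + dy[d], 0, h - 1)
        jj = np.clip(cc + dx[d], 0, w - 1)
        vals[d] = inp[ii, jj]
    vh = vals - hitv[:, None, None]
    vm = vals - missv[:, None, None]
    amin = vh.argmin(axis=0).astype(np.int32)
    amax = vm.argmax(axis=0).astype(np.int32)
    out = vh.min(axis=0) - vm.max(axis=0)
    return out, amin, amax


def forward(model: RMSNNModel, subimage: np.ndarray):
    """Reference forward pass: returns (class scores, cache of
    intermediates for backprop)."""
    img = np.asarray(subimage, float)
    if img.shape != (model.input_size, model.input_size):
        raise ValueError(f"subimage must be {model.input_size}x{model.input_size}")
    dy, dx = model.offsets
    a1, amin1, amax1, a2, amin2, amax2 = [], [], [], [], [], []
    for m in range(model.n_maps):
        o, mn, mx = _hm_map_numpy(img, model.hit1[m], model.miss1[m], dy, dx)
        a1.append(o)
        amin1.append(mn)
        amax1.append(mx)
    for m in range(model.n_maps):
        o, mn, mx = _hm_map_numpy(a1[m], model.hit2[m], model.miss2[m], dy, dx)
        a2.append(o)
        amin2.append(mn)
        amax2.append(mx)
    feat = np.stack(a2).reshape(-1)
    net1 = model.W1 @ feat + model.b1
    hid = _sigmoid(net1)
    net2 = model.W2 @ hid + model.b2
    out = _sigmoid(net2)
    cache = dict(
        img=img, a1=np.stack(a1), amin1=np.stack(amin1), amax1=np.stack(amax1),
        a2=np.stack(a2), amin2=np.stack(amin2), amax2=np.stack(amax2),
        feat=feat, hid=hid, out=out,
    )
    return out, cache


def regularized_cost(sample_error: float, model: RMSNNModel, lam: float, w0: float, include_ses: bool = False) -> float:
    """R = E_s + lambda * E_c with the weight-elimination penalty
    E_c = sum (w/w0)^2 / (1 + (w/w0)^2) over the classifier weights
    (optionally also the SE values)."""
    if lam < 0 or w0 <= 0:
        raise ValueError("need lambda >= 0 and w0 > 0")
    ws = [model.W1, model.W2]
    if include_ses:
        ws += [model.hit1, model.miss1, model.hit2, model.miss2]
    ec = 0.0
    for w in ws:
        u = (w / w0) ** 2
        ec += float((u / (1.0 + u)).sum())
    return float(sample_error) + lam * ec


def loss_and_grads(model: RMSNNModel, subimage: np.ndarray, target: np.ndarray, lam: float = 0.0, w0: float = 1.0,
                   regularize_ses: bool = False):
    """Reference E and analytic gradients of R = E + lam*E_c w.r.t. every
    parameter (min/max routed through the recorded arg-extrema)."""
    out, cache = forward(model, subimage)
    t = np.asarray(target, float)
    e = 0.5 * float(((t - out) ** 2).sum())

    dy, dx = model.offsets
    h = w = model.input_size
    delta_o = (t - out) * out * (1 - out)
    delta_h = cache["hid"] * (1 - cache["hid"]) * (model.W2.T @ delta_o)
    delta_feat = model.W1.T @ delta_h

    def pen(wv):
        return lam * 2.0 * wv * w0**2 / (w0**2 + wv**2) ** 2

    grads = {
        "W2": -np.outer(delta_o, cache["hid"]) + pen(model.W2),
        "b2": -delta_o,
        "W1": -np.outer(delta_h, cache["feat"]) + pen(model.W1),
        "b1": -delta_h,
    }
    M = model.n_maps
    ghit1 = np.zeros_like(model.hit1)
    gmiss1 = np.zeros_like(model.miss1)
    ghit2 = np.zeros_like(model.hit2)
    gmiss2 = np.zeros_like(model.miss2)
    for m in range(M):
        g = delta_feat.reshape(M, h, w)[m]
        delta_a1 = np.zeros((h, w))
        for i in range(h):
            for j in range(w):
                gv = g[i, j]
                if gv == 0:
                    continue
                dmin = cache["amin2"][m, i, j]
                dmax = cache["amax2"][m, i, j]
                ghit2[m, dmin] += gv  # dE/dt_h = +delta_y at the argmin
                gmiss2[m, dmax] -= gv
                ii, jj = np.clip(i + dy[dmin], 0, h - 1), np.clip(j + dx[dmin], 0, w - 1)
                delta_a1[ii, jj] += gv
                ii, jj = np.clip(i + dy[dmax], 0, h - 1), np.clip(j + dx[dmax], 0, w - 1)
                delta_a1[ii, jj] -= gv
        for i in range(h):
            for j in range(w):
                gv = delta_a1[i, j]
                if gv == 0:
                    continue
                ghit1[m, cache["amin1"][m, i, j]] += gv
                gmiss1[m, cache["amax1"][m, i, j]] -= gv
    grads["hit1"], grads["miss1"] = ghit1, gmiss1
    grads["hit2"], grads["miss2"] = ghit2, gmiss2
    if regularize_ses:
        for name in ("hit1", "miss1", "hit2", "miss2"):
            grads[name] = grads[name] + pen(getattr(model, name))
    return e, grads, cache


def backward_update(model: RMSNNModel, subimage: np.ndarray, target: np.ndarray, config: TrainingConfig) -> float:
    """One reference gradient-descent step on a single sample (in place);
    returns the sample's squared error."""
    e, grads, _ = loss_and_grads(
        model, subimage, target, lam=config.lam, w0=config.w0, regularize_ses=config.regularize_ses
    )
    for name, g in grads.items():
        arr = getattr(model, name)
        arr -= config.eta * g
    return e


# ---------------------------------------------------------------------------
# fast path


def predict_scores(model: RMSNNModel, images: np.ndarray) -> np.ndarray:
    """Class scores for a batch of subimages, shape (N, 3)."""
    images = np.ascontiguousarray(np.asarray(images, float))
    if images.ndim == 2:
        images = images[None]
    dy, dx = model.offsets
    return _kernels.forward_batch(
        images, model.hit1, model.miss1, model.hit2, model.miss2, dy, dx,
        model.W1, model.b1, model.W2, model.b2,
    )


def predict(model: RMSNNModel, images: np.ndarray) -> np.ndarray:
    return predict_scores(model, images).argmax(axis=1)


def train(
    model: RMSNNModel,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig | None = None,
) -> dict:
    """Sequential gradient-descent training with weight elimination.

    Samples are presented one at a time (shuffled each epoch when
    ``config.shuffle``); training stops when the mean per-sample squared
    error reaches ``mse_target`` or at ``max_epochs``.  Returns a
    history dict with the mean and median squared-error curves (the
    median-squared error is the monitoring statistic; the mean drives
    the stop rule).  Divergence to NaN aborts with an error.
    """
    config = config or TrainingConfig()
    images = np.ascontiguousarray(np.asarray(images, float))
    labels = np.asarray(labels)
    targets = one_hot(labels, len(model.class_names)) if labels.ndim == 1 else np.asarray(labels, float)
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training library")
    rng = np.random.default_rng(config.seed)
    dy, dx = model.offsets
    mean_curve, median_curve = [], []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        errors = _kernels.train_epoch(
            images, targets, order,
            model.hit1, model.miss1, model.hit2, model.miss2, dy, dx,
            model.W1, model.b1, model.W2, model.b2,
            config.eta, config.lam, config.w0, config.regularize_ses,
        )
        if not np.isfinite(errors).all():
            raise FloatingPointError(f"training diverged (non-finite error) at epoch {epoch}")
        mean_curve.append(float(errors.mean()))
        median_curve.append(float(np.median(errors)))
        if mean_curve[-1] <= config.mse_target:
            break
    return {
        "epochs": len(mean_curve),
        "mean_squared_error": np.array(mean_curve),
        "median_squared_error": np.array(median_curve),
    }


def confusion_matrix_counts(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


def cross_validate(
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig | None = None,
    folds: int = 10,
    repeats: int = 1,
    n_maps: int = 2,
    hidden: int = 10,
    se_shape: str = "disk:4",
) -> dict:
    """Repeated stratified k-fold cross-validation.

    A fresh model is trained per fold; the count confusion matrices are
    accumulated over all folds and repeats and reported both as counts
    and as row-normalized percentages (rows = actual class, columns =
    predicted).  Every class needs at least ``folds`` samples.
    """
    config = config or TrainingConfig()
    images = np.asarray(images, float)
    labels = np.asarray(labels, int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"every class needs >= {folds} samples for {folds}-fold CV")
    input_size = images.shape[1]
    total = np.zeros((len(classes), len(classes)), dtype=int)
    fold_histories = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed + rep)
        for fi, (tr, te) in enumerate(skf.split(images, labels)):
            model = init_model(
                n_maps=n_maps, hidden=hidden, input_size=input_size, se_shape=se_shape,
                seed=config.seed + 1000 * rep + fi,
                init_range=config.init_range, se_init=config.se_init,
            )
            fold_cfg = TrainingConfig(**{**asdict(config), "seed": config.seed + 1000 * rep + fi})
            hist = train(model, images[tr], labels[tr], fold_cfg)
            pred = predict(model, images[te])
            total += confusion_matrix_counts(labels[te], pred, len(classes))
            fold_histories.append(hist["epochs"])
    percent = 100.0 * total / total.sum(axis=1, keepdims=True)
    return {
        "confusion_counts": total,
        "confusion_percent": percent,
        "per_class_accuracy": np.diag(percent),
        "fold_epochs": fold_histories,
        "class_names": CLASS_NAMES,
    }
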