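"""The two model families behind the dual-path architecture.

Tabular path: a feed-forward network (batch-norm + dropout, ReLU) on the
standardized 12-descriptor panel.  Graph path: a graph convolutional
network with symmetric-normalized propagation
H' = ReLU(D^{-1/2}(A+I)D^{-1/2} H W + b) and mean-pool readout over atom
embeddings, followed by a dense logistic head.  Both train with Adam on
either plain cross-entropy or the focal loss, early-stopping on
validation F1.

Everything is implemented directly on NumPy arrays (graphs batch into a
single block-diagonal sparse propagation matrix), which keeps training
bit-reproducible under a fixed seed on a single thread and makes the
forward pass easy to verify against hand arithmetic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from sklearn.model_selection import StratifiedKFold

from .balance import (
    EPS,
    FocalParams,
    LabeledMatrix,
    adasyn,
    downsample_majority,
    focal_loss,
    smote,
)
from .evalmetrics import MetricsReport, classification_metrics
from .molgraph import ATOM_FEATURE_WIDTH, MolecularGraph

MODEL_MAGIC = "dualscreen-model-v1"
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class TabularNetConfig:
    hidden_sizes: tuple[int, ...] = (200, 100)
    dropout: float = 0.0
    use_batchnorm: bool = True
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 64
    loss: str = "cross_entropy"          # or "focal"
    focal: FocalParams = field(default_factory=FocalParams)
    standardize_inputs: bool = True
    val_frac: float = 0.2
    sampler: str = "none"                # none | smote | adasyn
    sampler_k: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(h > 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.sampler not in ("none", "smote", "adasyn"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass(frozen=True)
class GraphNetConfig:
    conv_layers: int = 2
    hidden_dim: int = 64
    readout: str = "mean"                # fixed
    learning_rate: float = 1e-2
    max_epochs: int = 300
    patience: int = 30
    loss: str = "cross_entropy"
    focal: FocalParams = field(default_factory=FocalParams)
    val_frac: float = 0.2
    sampler: str = "none"                # none | downsample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_layers < 1:
            raise ValueError("need at least one conv layer")
        if self.readout != "mean":
            raise ValueError("only mean readout is supported")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.sampler not in ("none", "downsample"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class TrainedAttributeModel:
    attribute_id: str
    path: str                                  # "tabular" | "graph"
    config: TabularNetConfig | GraphNetConfig
    parameters: dict[str, np.ndarray]
    input_standardization: tuple[np.ndarray, np.ndarray] | None  # (mean, sd)
    decision_threshold: float = 0.5
    training_fingerprint: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")


@dataclass
class CVReport:
    per_fold: list[MetricsReport]
    selected_fold: int                         # highest F1; ties -> lowest index
    mean: dict[str, float]
    sd: dict[str, float]


# ---------------------------------------------------------------------------
# shared numerics


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _loss_grad_logit(
    z: np.ndarray, y: np.ndarray, loss: str, focal: FocalParams
) -> tuple[float, np.ndarray]:
    """Mean loss over the batch and its gradient with respect to logits."""
    p = _sigmoid(z)
    if loss == "cross_entropy":
        pc = np.clip(p, EPS, 1 - EPS)
        value = float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))
        grad = (p - y) / len(y)
    else:
        per, dldp = focal_loss(p, y, focal)
        value = float(per.mean())
        grad = dldp * p * (1 - p) / len(y)
    return value, grad


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _fingerprint(seed: int, config, parameters: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    h.update(repr(config).encode())
    h.update(str(seed).encode())
    for k in sorted(parameters):
        h.update(k.encode())
        h.update(np.ascontiguousarray(parameters[k]).tobytes())
    return h.hexdigest()


def _stratified_holdout(y: np.ndarray, frac: float, rng: np.random.Generator):
    """Index split (fit, holdout) keeping class proportions."""
    fit_idx, hold_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_hold = max(1, int(round(len(idx) * frac)))
        hold_idx.extend(idx[:n_hold])
        fit_idx.extend(idx[n_hold:])
    return np.sort(np.array(fit_idx)), np.sort(np.array(hold_idx))


def _f1_at_half(y: np.ndarray, p: np.ndarray) -> float:
    return classification_metrics(y, p, 0.5).f1


# ---------------------------------------------------------------------------
# tabular network


class _MLP:
    """Feed-forward binary classifier: [Linear -> (BatchNorm) -> ReLU ->
    (Dropout)] * L -> Linear logit."""

    def __init__(self, d_in: int, cfg: TabularNetConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        sizes = [d_in, *cfg.hidden_sizes]
        for i in range(len(cfg.hidden_sizes)):
            fan_in = sizes[i]
            self.params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (sizes[i], sizes[i + 1]))
            self.params[f"b{i}"] = np.zeros(sizes[i + 1])
            if cfg.use_batchnorm:
                self.params[f"g{i}"] = np.ones(sizes[i + 1])
                self.params[f"beta{i}"] = np.zeros(sizes[i + 1])
                self.running[f"mu{i}"] = np.zeros(sizes[i + 1])
                self.running[f"var{i}"] = np.ones(sizes[i + 1])
        self.params["W_out"] = rng.normal(0, np.sqrt(1.0 / sizes[-1]), (sizes[-1], 1))
        self.params["b_out"] = np.zeros(1)

    @property
    def n_hidden(self) -> int:
        return len(self.cfg.hidden_sizes)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        cfg = self.cfg
        cache = []
        h = x
        for i in range(self.n_hidden):
            a = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            layer: dict = {"h_in": h}
            if cfg.use_batchnorm:
                if train:
                    mu = a.mean(axis=0)
                    var = a.var(axis=0)
                    self.running[f"mu{i}"] = (
                        _BN_MOMENTUM * self.running[f"mu{i}"] + (1 - _BN_MOMENTUM) * mu
                    )
                    self.running[f"var{i}"] = (
                        _BN_MOMENTUM * self.running[f"var{i}"] + (1 - _BN_MOMENTUM) * var
                    )
                else:
                    mu = self.running[f"mu{i}"]
                    var = self.running[f"var{i}"]
                invstd = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (a - mu) * invstd
                a = self.params[f"g{i}"] * xhat + self.params[f"beta{i}"]
                layer.update(xhat=xhat, invstd=invstd)
            z = np.maximum(a, 0.0)
            layer["relu_mask"] = a > 0
            if train and cfg.dropout > 0:
                mask = (rng.uniform(size=z.shape) >= cfg.dropout) / (1 - cfg.dropout)
                z = z * mask
                layer["drop_mask"] = mask
            cache.append(layer)
            h = z
        logits = (h @ self.params["W_out"] + self.params["b_out"]).ravel()
        return logits, (cache, h)

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        layers, h_last = cache
        grads: dict[str, np.ndarray] = {}
        d = dlogits[:, None]
        grads["W_out"] = h_last.T @ d
        grads["b_out"] = d.sum(axis=0)
        dh = d @ self.params["W_out"].T
        for i in range(self.n_hidden - 1, -1, -1):
            layer = layers[i]
            if "drop_mask" in layer:
                dh = dh * layer["drop_mask"]
            da = dh * layer["relu_mask"]
            if self.cfg.use_batchnorm:
                xhat, invstd = layer["xhat"], layer["invstd"]
                grads[f"g{i}"] = (da * xhat).sum(axis=0)
                grads[f"beta{i}"] = da.sum(axis=0)
                dxhat = da * self.params[f"g{i}"]
                m = len(dxhat)
                da = (
                    invstd
                    / m
                    * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
                )
            grads[f"W{i}"] = layer["h_in"].T @ da
            grads[f"b{i}"] = da.sum(axis=0)
            dh = da @ self.params[f"W{i}"].T
        return grads

    def state(self) -> dict[str, np.ndarray]:
        out = {k: v.copy() for k, v in self.params.items()}
        out.update({f"running_{k}": v.copy() for k, v in self.running.items()})
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k.startswith("running_"):
                self.running[k[len("running_") :]] = v.copy()
            else:
                self.params[k] = v.copy()


def train_tabular(data: LabeledMatrix, cfg: TabularNetConfig) -> TrainedAttributeModel:
    """Fit the tabular classifier with an internal stratified validation
    holdout, optional oversampling of the training part (in standardized
    space), and early stopping on validation F1."""
    if not np.isfinite(data.x).all():
        raise ValueError("non-finite values in input matrix")
    if len(np.unique(data.y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    fit_idx, val_idx = _stratified_holdout(data.y, cfg.val_frac, rng)
    x_fit, y_fit = data.x[fit_idx], data.y[fit_idx]
    x_val, y_val = data.x[val_idx], data.y[val_idx]

    if cfg.standardize_inputs:
        mean = x_fit.mean(axis=0)
        sd = x_fit.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mean = np.zeros(data.x.shape[1])
        sd = np.ones(data.x.shape[1])
    x_fit = (x_fit - mean) / sd
    x_val = (x_val - mean) / sd

    if cfg.sampler != "none":
        lm = LabeledMatrix(x_fit, y_fit, [str(i) for i in range(len(y_fit))])
        sampler_seed = int(rng.integers(2**31))
        if cfg.sampler == "smote":
            classes, counts = np.unique(y_fit, return_counts=True)
            minority_class = classes[np.argmin(counts)]
            need = int(round(cfg.target_ratio * counts.max())) - counts.min()
            if need > 0:
                k = min(cfg.sampler_k, counts.min() - 1)
                synth = smote(x_fit[y_fit == minority_class], k, need, sampler_seed)
                x_fit = np.vstack([x_fit, synth])
                y_fit = np.concatenate([y_fit, np.full(need, minority_class, dtype=int)])
        else:
            aug = adasyn(lm, cfg.sampler_k, cfg.target_ratio, sampler_seed)
            x_fit, y_fit = aug.x, aug.y

    net = _MLP(data.x.shape[1], cfg, rng)
    opt = _Adam(net.params, cfg.learning_rate)
    n = len(y_fit)
    best_f1, best_state, since_best = -1.0, net.state(), 0
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            if cfg.use_batchnorm and len(batch) < 2:
                continue  # batch statistics undefined on a single sample
            logits, cache = net.forward(x_fit[batch], train=True, rng=rng)
            _, dlogits = _loss_grad_logit(logits, y_fit[batch], cfg.loss, cfg.focal)
            grads = net.backward(dlogits, cache)
            opt.step(net.params, grads)
        val_logits, _ = net.forward(x_val, train=False)
        f1 = _f1_at_half(y_val, _sigmoid(val_logits))
        if f1 > best_f1 + 1e-12:
            best_f1, best_state, since_best = f1, net.state(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    net.load_state(best_state)
    return TrainedAttributeModel(
        attribute_id="",
        path="tabular",
        config=cfg,
        parameters=net.state(),
        input_standardization=(mean, sd),
        training_fingerprint=_fingerprint(cfg.seed, cfg, net.state()),
    )


# ---------------------------------------------------------------------------
# graph network


@dataclass
class GraphBatch:
    """A set of molecular graphs packed into one block-diagonal system."""

    features: np.ndarray        # (N_total, d)
    adj_norm: sparse.csr_matrix  # (N_total, N_total) symmetric-normalized A+I
    pooling: sparse.csr_matrix   # (n_graphs, N_total) mean-pool operator

    @classmethod
    def from_arrays(
        cls, feature_list: Sequence[np.ndarray], edge_list: Sequence[np.ndarray]
    ) -> "GraphBatch":
        feats, rows, cols, prow, pcol, pval = [], [], [], [], [], []
        offset = 0
        for g, (x, edges) in enumerate(zip(feature_list, edge_list)):
            n = len(x)
            feats.append(np.asarray(x, dtype=float))
            # bidirected edges + self loops
            for i, j in np.asarray(edges, dtype=int).reshape(-1, 2):
                rows.extend([offset + i, offset + j])
                cols.extend([offset + j, offset + i])
            rows.extend(range(offset, offset + n))
            cols.extend(range(offset, offset + n))
            prow.extend([g] * n)
            pcol.extend(range(offset, offset + n))
            pval.extend([1.0 / n] * n)
            offset += n
        a = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(offset, offset)
        )
        deg = np.asarray(a.sum(axis=1)).ravel()
        dinv = sparse.diags(1.0 / np.sqrt(deg))
        adj_norm = (dinv @ a @ dinv).tocsr()
        pooling = sparse.csr_matrix((pval, (prow, pcol)), shape=(len(feature_list), offset))
        return cls(np.vstack(feats), adj_norm, pooling)

    @classmethod
    def from_graphs(cls, graphs: Sequence[MolecularGraph]) -> "GraphBatch":
        return cls.from_arrays([g.atom_features for g in graphs], [g.edges for g in graphs])

    @property
    def n_graphs(self) -> int:
        return self.pooling.shape[0]


class _GCN:
    def __init__(self, d_in: int, cfg: GraphNetConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        sizes = [d_in] + [cfg.hidden_dim] * cfg.conv_layers
        for i in range(cfg.conv_layers):
            self.params[f"W{i}"] = rng.normal(
                0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1])
            )
            self.params[f"b{i}"] = np.zeros(sizes[i + 1])
        self.params["W_out"] = rng.normal(0, np.sqrt(1.0 / cfg.hidden_dim), (cfg.hidden_dim, 1))
        self.params["b_out"] = np.zeros(1)

    def forward(self, batch: GraphBatch):
        h = batch.features
        cache = []
        for i in range(self.cfg.conv_layers):
            m = batch.adj_norm @ h
            a = m @ self.params[f"W{i}"] + self.params[f"b{i}"]
            cache.append({"m": m, "mask": a > 0})
            h = np.maximum(a, 0.0)
        pooled = batch.pooling @ h
        logits = (pooled @ self.params["W_out"] + self.params["b_out"]).ravel()
        return logits, (cache, pooled)

    def backward(self, batch: GraphBatch, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        layers, pooled = cache
        grads: dict[str, np.ndarray] = {}
        d = dlogits[:, None]
        grads["W_out"] = pooled.T @ d
        grads["b_out"] = d.sum(axis=0)
        dh = batch.pooling.T @ (d @ self.params["W_out"].T)
        for i in range(self.cfg.conv_layers - 1, -1, -1):
            da = dh * layers[i]["mask"]
            grads[f"W{i}"] = layers[i]["m"].T @ da
            grads[f"b{i}"] = da.sum(axis=0)
            # adj_norm is symmetric
            dh = batch.adj_norm @ (da @ self.params[f"W{i}"].T)
        return grads

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


def train_graph(
    graphs: Sequence[MolecularGraph], y: np.ndarray, cfg: GraphNetConfig
) -> TrainedAttributeModel:
    """Fit the graph classifier (full-batch Adam, internal stratified
    validation holdout, early stopping on validation F1).  With
    ``sampler="downsample"`` the training part's majority class is
    randomly downsampled to balance."""
    if len(graphs) == 0:
        raise ValueError("empty graph list")
    y = np.asarray(y, dtype=int)
    if len(graphs) != len(y):
        raise ValueError("|graphs| must equal |y|")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    fit_idx, val_idx = _stratified_holdout(y, cfg.val_frac, rng)
    if cfg.sampler == "downsample":
        keep = downsample_majority(y[fit_idx], int(rng.integers(2**31)))
        fit_idx = fit_idx[keep]
    train_batch = GraphBatch.from_graphs([graphs[i] for i in fit_idx])
    val_batch = GraphBatch.from_graphs([graphs[i] for i in val_idx])
    y_fit, y_val = y[fit_idx], y[val_idx]

    net = _GCN(train_batch.features.shape[1], cfg, rng)
    opt = _Adam(net.params, cfg.learning_rate)
    best_f1, best_state, since_best = -1.0, net.state(), 0
    for _ in range(cfg.max_epochs):
        logits, cache = net.forward(train_batch)
        _, dlogits = _loss_grad_logit(logits, y_fit, cfg.loss, cfg.focal)
        grads = net.backward(train_batch, dlogits, cache)
        opt.step(net.params, grads)
        val_logits, _ = net.forward(val_batch)
        f1 = _f1_at_half(y_val, _sigmoid(val_logits))
        if f1 > best_f1 + 1e-12:
            best_f1, best_state, since_best = f1, net.state(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    net.load_state(best_state)
    return TrainedAttributeModel(
        attribute_id="",
        path="graph",
        config=cfg,
        parameters=net.state(),
        input_standardization=None,
        training_fingerprint=_fingerprint(cfg.seed, cfg, net.state()),
    )


# ---------------------------------------------------------------------------
# prediction


def predict(model: TrainedAttributeModel, inputs) -> np.ndarray:
    """Probabilities in (0, 1) aligned to input order; a pure function of
    (model, inputs).  ``inputs`` is a descriptor matrix for tabular models
    and a sequence of :class:`MolecularGraph` (or a :class:`GraphBatch`)
    for graph models."""
    if model.path == "tabular":
        x = np.asarray(inputs, dtype=float)
        if x.ndim != 2:
            raise ValueError("tabular inputs must be a 2-D matrix")
        mean, sd = model.input_standardization
        if x.shape[1] != len(mean):
            raise ValueError(f"expected {len(mean)} features, got {x.shape[1]}")
        net = _MLP(x.shape[1], model.config, np.random.default_rng(0))
        net.load_state(model.parameters)
        logits, _ = net.forward((x - mean) / sd, train=False)
    elif model.path == "graph":
        batch = inputs if isinstance(inputs, GraphBatch) else GraphBatch.from_graphs(inputs)
        if batch.features.shape[1] != model.parameters["W0"].shape[0]:
            raise ValueError(
                f"expected atom feature width {model.parameters['W0'].shape[0]}, "
                f"got {batch.features.shape[1]}"
            )
        net = _GCN(batch.features.shape[1], model.config, np.random.default_rng(0))
        net.load_state(model.parameters)
        logits, _ = net.forward(batch)
    else:
        raise ValueError(f"unknown model path {model.path!r}")
    return np.clip(_sigmoid(logits), EPS, 1 - EPS)


# ---------------------------------------------------------------------------
# cross-validation and hyperparameter search


def cross_validate(data, cfg, k: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation.

    ``data`` is a :class:`LabeledMatrix` for a tabular config or a tuple
    ``(graphs, y)`` for a graph config.  The reported fold is the one with
    the highest held-out F1 (ties break toward the lowest index).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(cfg, TabularNetConfig):
        y = data.y
    else:
        graphs, y = data
        y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        if isinstance(cfg, TabularNetConfig):
            model = train_tabular(data.subset(tr), fold_cfg)
            probs = predict(model, data.x[te])
        else:
            model = train_graph([graphs[i] for i in tr], y[tr], fold_cfg)
            probs = predict(model, [graphs[i] for i in te])
        per_fold.append(classification_metrics(y[te], probs, 0.5))
    f1s = np.array([m.f1 for m in per_fold])
    selected = int(np.argmax(f1s))
    names = ("accuracy", "precision", "recall", "f1", "auc")
    mean = {nm: float(np.mean([getattr(m, nm) for m in per_fold])) for nm in names}
    sd = {nm: float(np.std([getattr(m, nm) for m in per_fold])) for nm in names}
    return CVReport(per_fold=per_fold, selected_fold=selected, mean=mean, sd=sd)


@dataclass
class Trial:
    config: dict
    value: float | None
    error: str | None = None


class SearchError(RuntimeError):
    def __init__(self, message: str, trials: list[Trial]):
        super().__init__(message)
        self.trials = trials


def hyperparameter_search(
    space: dict[str, Sequence | tuple[float, float]],
    objective: Callable[[dict], float],
    budget: int,
    seed: int,
) -> tuple[dict, list[Trial]]:
    """Seeded random search: lists are sampled by choice, (low, high)
    float pairs uniformly.  Returns the best (argmax) evaluated config and
    the full trial log; raises :class:`SearchError` carrying the log when
    every trial fails."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("search space is empty")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for _ in range(budget):
        config = {}
        for name, spec in space.items():
            if isinstance(spec, tuple) and len(spec) == 2 and all(
                isinstance(v, (int, float)) and not isinstance(v, bool) for v in spec
            ):
                config[name] = float(rng.uniform(spec[0], spec[1]))
            else:
                config[name] = spec[int(rng.integers(len(spec)))]
        try:
            value = float(objective(config))
            trials.append(Trial(config, value))
        except Exception as exc:  # logged, not fatal unless all fail
            trials.append(Trial(config, None, error=str(exc)))
    scored = [t for t in trials if t.value is not None]
    if not scored:
        raise SearchError("objective failed on every trial", trials)
    best = max(scored, key=lambda t: t.value)
    return best.config, trials


# ---------------------------------------------------------------------------
# model archive


def save_model(model: TrainedAttributeModel, path: str | Path) -> None:
    """Single-file .npz archive with a versioned magic header."""
    cfg = model.config
    meta = {
        "magic": MODEL_MAGIC,
        "attribute_id": model.attribute_id,
        "path": model.path,
        "decision_threshold": model.decision_threshold,
        "training_fingerprint": model.training_fingerprint,
        "config_kind": type(cfg).__name__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()
            if not isinstance(v, FocalParams)
        },
        "focal": {"gamma": cfg.focal.gamma, "alpha": cfg.focal.alpha},
    }
    arrays = {f"param_{k}": v for k, v in model.parameters.items()}
    if model.input_standardization is not None:
        arrays["std_mean"], arrays["std_sd"] = model.input_standardization
    with open(path, "wb") as fh:  # exact path, no implicit .npz suffix
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> TrainedAttributeModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("magic") != MODEL_MAGIC:
            raise ValueError(f"{path} is not a {MODEL_MAGIC} archive")
        cfg_cls = {"TabularNetConfig": TabularNetConfig, "GraphNetConfig": GraphNetConfig}[
            meta["config_kind"]
        ]
        cfg_kwargs = dict(meta["config"])
        if "hidden_sizes" in cfg_kwargs:
            cfg_kwargs["hidden_sizes"] = tuple(cfg_kwargs["hidden_sizes"])
        cfg = cfg_cls(focal=FocalParams(**meta["focal"]), **cfg_kwargs)
        params = {
            k[len("param_") :]: archive[k] for k in archive.files if k.startswith("param_")
        }
        std = None
        if "std_mean" in archive.files:
            std = (archive["std_mean"], archive["std_sd"])
    return TrainedAttributeModel(
        attribute_id=meta["attribute_id"],
        path=meta["path"],
        config=cfg,
        parameters=params,
        input_standardization=std,
        decision_threshold=meta["decision_threshold"],
        training_fingerprint=meta["training_fingerprint"],
    )
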