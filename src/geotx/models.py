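"""Model architectures and training harness for geographic m6A prediction.

Five model kinds share the same convolutional building blocks:

* ``geo_cnn``   — two-layer CNN (64 then 32 filters, kernels 5 and 3, one
  max-pool, one dropout) on a geographic matrix (gridTX / chunkTX /
  one-hot region), geography only.
* ``seq_cnn``   — a stack of convolutional blocks on the one-hot sequence
  window, sequence only (a simplified reference branch in the spirit of
  existing sequence-based predictors; bit-faithful reproduction of their
  published architectures is a non-goal).
* ``gepse``     — the fused model: sequence branch + geographic branch,
  concatenated and fed to dense layers.
* ``i_gepse``   — isoform-aware attention MIL: the geographic branch is
  shared across all isoforms of a bag, the sequence feature is broadcast
  and concatenated to each isoform feature, and gated attention pools the
  bag; the attention weights indicate which isoform carries the signal.
* ``ti_gepse``  — nested MIL for peak-level (low-resolution) labels: the
  peak sequence is cut into 50-nt instances with stride 10, pooled by a
  first attention layer into a region-level sequence feature, then the
  isoform-level MIL proceeds as in ``i_gepse``.
* ``read_gepse`` — read-level bags of read-truncated chunk encodings; a
  shared branch scores each read and the Noisy-OR function lifts the read
  probabilities to a site-level probability (zero-pad reads are masked out).

Fixed-shape kinds train with mini-batches of 128 for 20 epochs; bag kinds
train one bag at a time for a single epoch (bags are ragged).  Adam
minimizes binary cross-entropy throughout, and a single config seed drives
initialization, shuffling and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag
from .evaluate import MetricReport, evaluate

__all__ = [
    "ModelConfig",
    "build_model",
    "train",
    "cross_validate",
    "attention_pool",
    "noisy_or",
    "make_instances",
    "permutation_importance",
    "TrainResult",
]


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    The convolutional geographic branch uses 64 then 32 filters with kernels
    5 and 3, one max-pool and one dropout layer; training defaults are Adam,
    binary cross-entropy, mini-batch 128, 20 epochs for fixed-shape inputs
    and 1 epoch for ragged (bag) inputs.  ``attention_hidden`` and
    ``hidden_dense`` default to 128/64 and are overridable.
    """

    kind: str = "geo_cnn"
    geo_shape: tuple[int, int] = (35, 7)
    seq_window: int = 101
    instance_length: int = 50
    instance_stride: int = 10
    geo_filters: tuple[int, int] = (64, 32)
    geo_kernels: tuple[int, int] = (5, 3)
    seq_filters: tuple[int, ...] = (32, 64, 32)
    seq_kernels: tuple[int, ...] = (5, 5, 3)
    pool: int = 2
    dropout: float = 0.2
    feature_dim: int = 64
    attention_hidden: int = 128
    hidden_dense: int = 64
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 20
    epochs_variable: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pool", "feature_dim", "attention_hidden", "hidden_dense",
                     "batch_size", "epochs", "epochs_variable"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# standalone operations


def attention_pool(
    features: np.ndarray,
    params: dict,
    mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gated attention pooling of a bag, as a plain NumPy computation.

    ``params`` holds the matrices ``V`` (d x H), ``U`` (d x H) and ``w``
    (H x 1).  Returns the pooled vector (d,) and the weights (k,), which are
    a softmax over bag members and sum to 1.
    """
    h = np.asarray(features, dtype=np.float64)
    if h.ndim != 2 or h.shape[1] == 0:
        raise ValueError("features must be a (bag, d) matrix with d >= 1")
    V, U, w = params["V"], params["U"], params["w"]
    query = np.tanh(h @ V) * (0.5 * (1.0 + np.tanh(0.5 * (h @ U))))
    scores = (query @ w).reshape(-1)
    if mask is not None:
        scores = np.where(np.asarray(mask, bool), scores, -np.inf)
    scores = scores - scores.max()
    e = np.exp(scores)
    weights = e / e.sum()
    pooled = weights @ h
    return pooled, weights


def noisy_or(read_probs: Sequence[float],
             mask: Optional[Sequence[bool]] = None) -> float:
    """Site-level probability 1 - prod(1 - p_i) over read-level probabilities.

    Masked-out (zero-pad) members are excluded from the product.  Monotone
    non-decreasing in every argument and permutation-invariant.
    """
    p = np.asarray(read_probs, dtype=np.float64).reshape(-1)
    if mask is not None:
        p = p[np.asarray(mask, bool).reshape(-1)]
    if p.size == 0:
        raise ValueError("noisy_or needs at least one (unmasked) probability")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def make_instances(sequence, length: int = 50, stride: int = 10) -> list:
    """Sliding windows at offsets 0, stride, 2*stride, ...; tail dropped.

    Works on strings or on arrays indexed along axis 0; the number of
    instances is floor((L - length) / stride) + 1.
    """
    L = len(sequence)
    if L < length:
        raise ValueError(
            f"sequence length {L} < instance length {length}; pad the input"
        )
    return [sequence[off : off + length]
            for off in range(0, L - length + 1, stride)]


# ---------------------------------------------------------------------------
# branches


class _GeoBranch(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        L, C = cfg.geo_shape
        f1, f2 = cfg.geo_filters
        k1, k2 = cfg.geo_kernels
        self.conv1 = nn.Conv1d(C, f1, k1, rng)
        self.pool = nn.MaxPool1d(cfg.pool)
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.conv2 = nn.Conv1d(f1, f2, k2, rng)
        flat = (L // cfg.pool) * f2
        self.dense = nn.Dense(flat, cfg.feature_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.relu(self.conv1(x))
        x = self.pool(x)
        x = self.drop(x)
        x = ag.relu(self.conv2(x))
        x = x.reshape(x.shape[0], -1)
        return ag.relu(self.dense(x))


class _SeqBranch(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        W = cfg.seq_window
        f = cfg.seq_filters
        k = cfg.seq_kernels
        self.conv1 = nn.Conv1d(4, f[0], k[0], rng)
        self.conv2 = nn.Conv1d(f[0], f[1], k[1], rng)
        self.conv3 = nn.Conv1d(f[1], f[2], k[2], rng)
        self.pool = nn.MaxPool1d(cfg.pool)
        self.drop = nn.Dropout(cfg.dropout, rng)
        flat = (W // cfg.pool // cfg.pool) * f[2]
        self.dense = nn.Dense(flat, cfg.feature_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.relu(self.conv1(x))
        x = self.pool(x)
        x = ag.relu(self.conv2(x))
        x = self.pool(x)
        x = self.drop(x)
        x = ag.relu(self.conv3(x))
        x = x.reshape(x.shape[0], -1)
        return ag.relu(self.dense(x))


class _InstanceBranch(nn.Module):
    """Shared feature extractor for 50-nt sequence instances."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        Li = cfg.instance_length
        self.conv1 = nn.Conv1d(4, 32, 5, rng)
        self.pool = nn.MaxPool1d(cfg.pool)
        self.conv2 = nn.Conv1d(32, 64, 3, rng)
        flat = (Li // cfg.pool) * 64
        self.dense = nn.Dense(flat, cfg.feature_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.relu(self.conv1(x))
        x = self.pool(x)
        x = ag.relu(self.conv2(x))
        x = x.reshape(x.shape[0], -1)
        return ag.relu(self.dense(x))


# ---------------------------------------------------------------------------
# models


class _BaseModel(nn.Module):
    kind: str
    config: ModelConfig

    def predict(self, data) -> np.ndarray:
        raise NotImplementedError


class GeoCNN(_BaseModel):
    kind = "geo_cnn"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.config = cfg
        self.branch = _GeoBranch(cfg, rng)
        self.head = nn.Dense(cfg.feature_dim, 1, rng)

    def forward(self, geo: Tensor) -> Tensor:
        return self.head(self.branch(geo))

    def loss(self, batch: dict) -> Tensor:
        return ag.bce_with_logits(self.forward(Tensor(batch["geo"])), batch["y"])

    def predict(self, data: dict) -> np.ndarray:
        self.eval()
        z = self.forward(Tensor(np.asarray(data["geo"]))).data.reshape(-1)
        return 1.0 / (1.0 + np.exp(-z))


class SeqCNN(_BaseModel):
    kind = "seq_cnn"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.config = cfg
        self.branch = _SeqBranch(cfg, rng)
        self.head = nn.Dense(cfg.feature_dim, 1, rng)

    def forward(self, seq: Tensor) -> Tensor:
        return self.head(self.branch(seq))

    def loss(self, batch: dict) -> Tensor:
        return ag.bce_with_logits(self.forward(Tensor(batch["seq"])), batch["y"])

    def predict(self, data: dict) -> np.ndarray:
        self.eval()
        z = self.forward(Tensor(np.asarray(data["seq"]))).data.reshape(-1)
        return 1.0 / (1.0 + np.exp(-z))


class GepSe(_BaseModel):
    kind = "gepse"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.config = cfg
        self.geo = _GeoBranch(cfg, rng)
        self.seq = _SeqBranch(cfg, rng)
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.dense = nn.Dense(2 * cfg.feature_dim, cfg.hidden_dense, rng)
        self.head = nn.Dense(cfg.hidden_dense, 1, rng)

    def forward(self, geo: Tensor, seq: Tensor) -> Tensor:
        h = ag.concat([self.geo(geo), self.seq(seq)], axis=1)
        h = self.drop(h)
        h = ag.relu(self.dense(h))
        return self.head(h)

    def loss(self, batch: dict) -> Tensor:
        return ag.bce_with_logits(
            self.forward(Tensor(batch["geo"]), Tensor(batch["seq"])), batch["y"]
        )

    def predict(self, data: dict) -> np.ndarray:
        self.eval()
        z = self.forward(
            Tensor(np.asarray(data["geo"])), Tensor(np.asarray(data["seq"]))
        ).data.reshape(-1)
        return 1.0 / (1.0 + np.exp(-z))


class IGepSe(_BaseModel):
    """Isoform-aware attention MIL over bags of geographic encodings."""

    kind = "i_gepse"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.config = cfg
        self.geo = _GeoBranch(cfg, rng)
        self.seq = _SeqBranch(cfg, rng)
        self.mix = nn.Dense(2 * cfg.feature_dim, cfg.hidden_dense, rng)
        self.attention = nn.GatedAttention(cfg.hidden_dense, cfg.attention_hidden, rng)
        self.head = nn.Dense(cfg.hidden_dense, 1, rng)

    def _member_features(self, bag: dict) -> Tensor:
        geo = Tensor(np.asarray(bag["geo"]))  # (k, L, C)
        feats = self.geo(geo)  # (k, F)
        if bag.get("seq") is not None:
            seq_feat = self.seq(Tensor(np.asarray(bag["seq"])[None]))  # (1, F)
            k = geo.shape[0]
            seq_tile = ag.concat([seq_feat] * k, axis=0) if k > 1 else seq_feat
            feats = ag.concat([feats, seq_tile], axis=1)
        else:
            feats = ag.concat([feats, feats * 0.0], axis=1)
        return ag.relu(self.mix(feats))

    def forward_bag(self, bag: dict) -> tuple[Tensor, np.ndarray]:
        h = self._member_features(bag)
        pooled, weights = self.attention(h, mask=bag.get("mask"))
        return self.head(pooled), weights.data.reshape(-1)

    def loss(self, bag: dict) -> Tensor:
        logit, _ = self.forward_bag(bag)
        return ag.bce_with_logits(logit, np.array([[bag["y"]]]))

    def predict(self, data: dict, return_attention: bool = False):
        self.eval()
        probs, attn = [], []
        for bag in data["bags"]:
            logit, w = self.forward_bag(bag)
            probs.append(1.0 / (1.0 + np.exp(-logit.data.item())))
            attn.append(w)
        probs = np.asarray(probs)
        return (probs, attn) if return_attention else probs


class TiGepSe(IGepSe):
    """Nested MIL: attention over 50-nt sequence instances, then isoforms."""

    kind = "ti_gepse"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.config = cfg
        self.geo = _GeoBranch(cfg, rng)
        self.instance = _InstanceBranch(cfg, rng)
        self.inst_attention = nn.GatedAttention(
            cfg.feature_dim, cfg.attention_hidden, rng
        )
        self.mix = nn.Dense(2 * cfg.feature_dim, cfg.hidden_dense, rng)
        self.attention = nn.GatedAttention(cfg.hidden_dense, cfg.attention_hidden, rng)
        self.head = nn.Dense(cfg.hidden_dense, 1, rng)

    def _member_features(self, bag: dict) -> Tensor:
        geo = Tensor(np.asarray(bag["geo"]))
        feats = self.geo(geo)
        inst = Tensor(np.asarray(bag["instances"]))  # (n_i, 50, 4)
        inst_feats = self.instance(inst)  # (n_i, F)
        seq_feat, _ = self.inst_attention(inst_feats)  # (1, F)
        k = geo.shape[0]
        seq_tile = ag.concat([seq_feat] * k, axis=0) if k > 1 else seq_feat
        feats = ag.concat([feats, seq_tile], axis=1)
        return ag.relu(self.mix(feats))


class ReadGepSe(_BaseModel):
    """Per-read scoring of truncated encodings, Noisy-OR to site level."""

    kind = "read_gepse"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.config = cfg
        self.geo = _GeoBranch(cfg, rng)
        self.head = nn.Dense(cfg.feature_dim, 1, rng)

    def read_logits(self, bag: dict) -> Tensor:
        geo = Tensor(np.asarray(bag["geo"]))  # (k, L, C)
        return self.head(self.geo(geo))  # (k, 1)

    def forward_bag(self, bag: dict) -> tuple[Tensor, np.ndarray]:
        """Site probability via Noisy-OR; pad reads are masked out."""
        logits = self.read_logits(bag)
        mask = np.asarray(
            bag.get("mask", np.ones(logits.shape[0], bool)), bool
        ).reshape(-1, 1)
        # log(1 - p_i) = -softplus(logit_i); pads contribute log(1) = 0
        log1mp = -ag.softplus(logits) * mask
        log_none = log1mp.sum(axis=0, keepdims=True)  # log prod(1 - p_i)
        p_site = 1.0 - ag.exp(log_none)
        read_probs = 1.0 / (1.0 + np.exp(-logits.data.reshape(-1)))
        return p_site, read_probs

    def loss(self, bag: dict) -> Tensor:
        p_site, _ = self.forward_bag(bag)
        y = float(bag["y"])
        eps = 1e-12
        return -(y * ag.log(p_site + eps) + (1.0 - y) * ag.log(1.0 - p_site + eps)).mean()

    def predict(self, data: dict, return_read_probs: bool = False):
        self.eval()
        probs, reads = [], []
        for bag in data["bags"]:
            p, rp = self.forward_bag(bag)
            probs.append(p.data.item())
            reads.append(rp)
        probs = np.asarray(probs)
        return (probs, reads) if return_read_probs else probs


_KINDS = {
    "geo_cnn": GeoCNN,
    "seq_cnn": SeqCNN,
    "gepse": GepSe,
    "i_gepse": IGepSe,
    "ti_gepse": TiGepSe,
    "read_gepse": ReadGepSe,
}

_BAG_KINDS = {"i_gepse", "ti_gepse", "read_gepse"}


def build_model(kind: str, config: Optional[ModelConfig] = None) -> _BaseModel:
    """Instantiate a model; the config seed fixes the initialization."""
    if kind not in _KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(_KINDS)}")
    cfg = replace(config, kind=kind) if config is not None else ModelConfig(kind=kind)
    rng = np.random.default_rng(cfg.seed)
    return _KINDS[kind](cfg, rng)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    model: _BaseModel
    loss_history: list[float]


def _is_bag_model(model: "_BaseModel") -> bool:
    return model.kind in _BAG_KINDS


def train(model: _BaseModel, data: dict,
          config: Optional[ModelConfig] = None) -> TrainResult:
    """Seeded Adam / binary cross-entropy training.

    ``data`` is either ``{"geo": ..., "seq": ..., "y": ...}`` arrays for the
    fixed-shape kinds or ``{"bags": [...], "y": ...}`` for the MIL kinds
    (bags are processed one at a time).  Returns the per-epoch mean loss.
    """
    cfg = config or model.config
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[float] = []
    model.train()
    if _is_bag_model(model):
        bags = data["bags"]
        y = np.asarray(data["y"], dtype=np.float64)
        for _ in range(cfg.epochs_variable):
            order = rng.permutation(len(bags))
            losses = []
            for i in order:
                bag = dict(bags[i])
                bag["y"] = y[i]
                opt.zero_grad()
                loss = model.loss(bag)
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
    else:
        y = np.asarray(data["y"], dtype=np.float64)
        n = len(y)
        arrays = {k: np.asarray(v) for k, v in data.items()
                  if k in ("geo", "seq")}
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = {k: v[idx] for k, v in arrays.items()}
                batch["y"] = y[idx].reshape(-1, 1)
                opt.zero_grad()
                loss = model.loss(batch)
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
    model.eval()
    return TrainResult(model=model, loss_history=history)


def cross_validate(
    builder: Callable[[], _BaseModel],
    data: dict,
    folds: int = 10,
    independent: Optional[dict] = None,
) -> dict:
    """Stratified k-fold cross-validation.

    Returns per-fold :class:`MetricReport` objects, their mean/sd summary,
    and — when an independent dataset is supplied — predictions for it
    obtained by averaging the outputs of all fold models.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(data["y"], dtype=np.float64)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=0)
    reports: list[MetricReport] = []
    indep_preds = []
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[te_idx])) < 2:
            raise ValueError("a fold contains a single class; use fewer folds")
        model = builder()
        train(model, _subset(data, tr_idx), model.config)
        scores = model.predict(_subset(data, te_idx))
        reports.append(evaluate(scores, y[te_idx]))
        if independent is not None:
            indep_preds.append(model.predict(independent))
    summary = MetricReport.aggregate(reports)
    out = {"folds": reports, "summary": summary}
    if independent is not None:
        avg = np.mean(indep_preds, axis=0)
        out["independent_scores"] = avg
        out["independent_report"] = evaluate(avg, independent["y"])
    return out


def _subset(data: dict, idx: np.ndarray) -> dict:
    out = {}
    for k, v in data.items():
        if k == "bags":
            out[k] = [v[i] for i in idx]
        else:
            out[k] = np.asarray(v)[idx]
    return out


def permutation_importance(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """AUC drop when one feature column is permuted across samples.

    ``X`` is (n, ...) with features along the last axis; the returned array
    gives the mean AUC decrease per feature.
    """
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    base = roc_auc_score(y, predict_fn(X))
    n_feat = X.shape[-1]
    drops = np.zeros(n_feat)
    for j in range(n_feat):
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(X.shape[0])
            Xp[..., j] = Xp[perm, ..., j]
            vals.append(base - roc_auc_score(y, predict_fn(Xp)))
        drops[j] = np.mean(vals)
    return drops
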