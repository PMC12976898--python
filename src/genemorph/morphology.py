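"""Gene-aligned multiple-instance morphology classifier.

A slide is a bag of patch embeddings. Each patch embedding is compressed by
a shared two-layer GELU encoder into a hidden representation, projected by
``G`` linear *gene heads* — one latent axis per gene of the fixed
co-expression network — mean-pooled into a slide-level gene-latent vector
``Ghat``, and classified by a sigmoid head.

Training minimizes

    total = cls + lambda_graph * graph + lambda_dis * dis

where ``cls`` is binary cross-entropy on the slide label, ``graph`` is the
Laplacian smoothness penalty Ghat' L Ghat that forces latents of co-expressed
genes to co-vary, and ``dis`` is a decorrelation penalty
``|| Gtilde' Gtilde - I ||_F`` on the column-normalized patch-level gene
latent matrix, preventing gene heads from collapsing onto one direction.
(The decorrelation term must act on the N x G patch-level matrix: for the
pooled G-vector the Gram matrix would be a scalar and the Frobenius
distance to the identity would be ill-formed.)

Gradients are derived analytically and optimized with Adam; all randomness
(init, dropout, shuffling, splits) flows from the config seed, so training
histories are bit-reproducible.

An optional auxiliary alignment term (mean-squared error between ``Ghat``
and the slide's z-scored true expression over the network genes, weight
``align_weight``, default 0 = off) lets paired expression supervise the
latents directly when it is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .evaluation import roc_auc, sens_spec
from .network import CoexpressionNetwork
from .nnet import Adam, gelu, gelu_grad

__all__ = [
    "SlideBag",
    "ModelParams",
    "TrainConfig",
    "LossBreakdown",
    "encode_patches",
    "gene_project",
    "pool_slide",
    "predict",
    "graph_loss",
    "dis_loss",
    "total_loss",
    "train",
    "MorphologyGeneModel",
    "MorphologyResults",
]

_EPS = 1e-7


@dataclass
class SlideBag:
    """One slide: an N x P patch-embedding matrix and a binary label
    (Basal = 0, Classical = 1; ``None`` for unlabeled inference bags)."""

    slide_id: str
    embeddings: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError(f"bag {self.slide_id}: embeddings must be N x P with N >= 1")
        if np.isnan(self.embeddings).any():
            raise ValueError(f"bag {self.slide_id}: missing values in embeddings")

    @property
    def n_patches(self) -> int:
        return self.embeddings.shape[0]


@dataclass
class TrainConfig:
    """Training knobs (reference defaults: 30 epochs, Adam lr 1e-4,
    slide-level batch 1, 80/20 split, lambda_graph 1.0, lambda_dis 0.1,
    hidden dim 256)."""

    epochs: int = 30
    lr: float = 1e-4
    batch: int = 1
    split: float = 0.8
    seed: int = 0
    classifier_threshold: float = 0.5
    lambda_graph: float = 1.0
    lambda_dis: float = 0.1
    hidden: int = 256
    width: int = 512
    dropout: float = 0.1
    dtype: str = "float32"
    head_noise: float = 0.05
    align_weight: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.split < 1.0):
            raise ValueError("split must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ModelParams:
    """All learnable arrays: encoder (W1, b1, W2, b2), gene heads (Wg, bg)
    and the sigmoid classifier (wc, bc)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    Wg: np.ndarray  # G x H
    bg: np.ndarray  # G
    wc: np.ndarray  # G
    bc: float

    @classmethod
    def init(cls, rng: np.random.Generator, patch_dim: int, hidden: int,
             n_genes: int, width: int = 512, dtype: str = "float32",
             head_noise: float = 0.05) -> "ModelParams":
        """Seeded initialization.

        Encoder layers use Glorot scaling. Gene heads start near a shared
        direction (``head_noise`` controls the per-head perturbation): a
        constant head vector lies in the Laplacian's null space, so training
        begins inside the graph-smoothness feasible set and the quadratic
        penalty cannot dominate early feature learning; the decorrelation
        pressure then differentiates heads along low-penalty directions.
        """
        dt = np.dtype(dtype)

        def glorot(fan_in, fan_out):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return (rng.standard_normal((fan_in, fan_out)) * s).astype(dt)

        s_head = np.sqrt(2.0 / (hidden + 1))
        shared = rng.standard_normal(hidden) * s_head
        Wg = shared[None, :] + head_noise * s_head * rng.standard_normal((n_genes, hidden))
        return cls(
            W1=glorot(patch_dim, width),
            b1=np.zeros(width, dtype=dt),
            W2=glorot(width, hidden),
            b2=np.zeros(hidden, dtype=dt),
            Wg=Wg.astype(dt),
            bg=np.zeros(n_genes, dtype=dt),
            wc=np.zeros(n_genes, dtype=dt),
            bc=0.0,
        )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in ("W1", "b1", "W2", "b2", "Wg", "bg", "wc")}

    def to_npz(self, path: str | Path) -> None:
        np.savez(path, bc=np.array([self.bc]), **self.as_dict())

    @classmethod
    def from_npz(cls, path: str | Path) -> "ModelParams":
        d = np.load(path)
        return cls(
            W1=d["W1"], b1=d["b1"], W2=d["W2"], b2=d["b2"],
            Wg=d["Wg"], bg=d["bg"], wc=d["wc"], bc=float(d["bc"][0]),
        )


@dataclass
class LossBreakdown:
    """Loss components and their weighted total."""

    cls: float
    graph: float
    dis: float
    lambda_graph: float = 1.0
    lambda_dis: float = 0.1
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.cls + self.lambda_graph * self.graph + self.lambda_dis * self.dis


# ---------------------------------------------------------------------------
# forward operations


def encode_patches(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """Deterministic (eval-mode) row-wise encoding of patch embeddings."""
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(f"patch dim {X.shape[1]} != encoder input {params.W1.shape[0]}")
    H1 = gelu(X @ params.W1 + params.b1)
    return H1 @ params.W2 + params.b2


def gene_project(Z: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Apply the G gene heads: row i of the result is W @ z_i + b."""
    if Z.shape[1] != W.shape[1]:
        raise ValueError(f"hidden dim {Z.shape[1]} != gene-head width {W.shape[1]}")
    return Z @ W.T + b


def pool_slide(Gmat: np.ndarray) -> np.ndarray:
    """Mean-pool patch-level gene latents into the slide vector Ghat."""
    if Gmat.shape[0] < 1:
        raise ValueError("empty bag")
    return Gmat.mean(axis=0)


def predict(Ghat: np.ndarray, w_c: np.ndarray, b_c: float) -> float:
    """Sigmoid slide-level subtype probability."""
    if Ghat.shape != w_c.shape:
        raise ValueError("classifier weight shape mismatch")
    logit = float(np.dot(w_c, Ghat) + b_c)
    return float(1.0 / (1.0 + np.exp(-logit)))


def graph_loss(Ghat: np.ndarray, L: np.ndarray) -> float:
    """Smoothness penalty Ghat' L Ghat over the gene network."""
    if L.shape != (Ghat.size, Ghat.size):
        raise ValueError("Laplacian shape does not match gene vector")
    val = float(Ghat @ L @ Ghat)
    return max(val, 0.0)  # PSD up to round-off


def dis_loss(Gmat: np.ndarray) -> float:
    """Gene-head decorrelation: ||Gtilde' Gtilde - I||_F with columns of the
    patch-level latent matrix normalized to unit length (zero columns kept)."""
    if Gmat.shape[0] < 2:
        raise ValueError("decorrelation needs >= 2 patches (degenerate Gram otherwise)")
    norms = np.linalg.norm(Gmat, axis=0)
    Gt = np.where(norms > 0, Gmat / np.where(norms > 0, norms, 1.0), 0.0)
    C = Gt.T @ Gt - np.eye(Gmat.shape[1])
    return float(np.linalg.norm(C))


def total_loss(
    yhat: float,
    y: int,
    Ghat: np.ndarray,
    Gmat: np.ndarray,
    L: np.ndarray,
    lambda_graph: float = 1.0,
    lambda_dis: float = 0.1,
) -> LossBreakdown:
    """Composite loss breakdown; yhat is clamped to [eps, 1 - eps]."""
    p = min(max(yhat, _EPS), 1.0 - _EPS)
    cls = -(y * np.log(p) + (1 - y) * np.log(1.0 - p))
    return LossBreakdown(
        float(cls), graph_loss(Ghat, L), dis_loss(Gmat), lambda_graph, lambda_dis
    )


# ---------------------------------------------------------------------------
# training


def _forward(X, params, dropout_mask=None):
    A1 = X @ params.W1 + params.b1
    H1 = gelu(A1)
    H1d = H1 * dropout_mask if dropout_mask is not None else H1
    Z = H1d @ params.W2 + params.b2
    Gmat = Z @ params.Wg.T + params.bg
    Ghat = Gmat.mean(axis=0)
    logit = float(params.wc @ Ghat + params.bc)
    yhat = 1.0 / (1.0 + np.exp(-logit))
    return {"A1": A1, "H1d": H1d, "Z": Z, "Gmat": Gmat, "Ghat": Ghat,
            "logit": logit, "yhat": yhat}


def _backward(X, y, cache, params, L, cfg, align_target=None, dropout_mask=None):
    N, G = cache["Gmat"].shape
    Gmat, Ghat, Z = cache["Gmat"], cache["Ghat"], cache["Z"]
    dlogit = cache["yhat"] - y
    dwc = dlogit * Ghat
    dbc = dlogit
    dGhat = dlogit * params.wc.astype(float) + cfg.lambda_graph * 2.0 * (L @ Ghat)
    if align_target is not None and cfg.align_weight > 0:
        dGhat = dGhat + cfg.align_weight * 2.0 * (Ghat - align_target) / G
    dGmat = np.broadcast_to(dGhat / N, (N, G)).copy()
    if cfg.lambda_dis > 0 and N >= 2:
        norms = np.linalg.norm(Gmat, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        Gt = np.where(norms > 0, Gmat / safe, 0.0)
        C = Gt.T @ Gt - np.eye(G)
        f = np.linalg.norm(C)
        if f > 1e-12:
            dGt = 2.0 * (Gt @ C) / f
            proj = (Gt * dGt).sum(axis=0)
            dGmat += cfg.lambda_dis * np.where(norms > 0, (dGt - Gt * proj) / safe, 0.0)
    dWg = dGmat.T @ Z
    dbg = dGmat.sum(axis=0)
    dZ = dGmat @ params.Wg
    dW2 = cache["H1d"].T @ dZ
    db2 = dZ.sum(axis=0)
    dH1d = dZ @ params.W2.T
    dH1 = dH1d * dropout_mask if dropout_mask is not None else dH1d
    dA1 = dH1 * gelu_grad(cache["A1"])
    dW1 = X.T @ dA1
    db1 = dA1.sum(axis=0)
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2,
            "Wg": dWg, "bg": dbg, "wc": dwc, "bc": dbc}


def _predict_bags(bags, params):
    out = np.empty(len(bags))
    for i, b in enumerate(bags):
        Z = encode_patches(b.embeddings.astype(params.W1.dtype), params)
        out[i] = predict(pool_slide(gene_project(Z, params.Wg, params.bg)),
                         params.wc, params.bc)
    return out


def train(
    bags: Sequence[SlideBag],
    network: CoexpressionNetwork,
    cfg: TrainConfig,
    labels: Mapping[str, int] | None = None,
    expression_targets: Mapping[str, np.ndarray] | None = None,
) -> tuple[ModelParams, pd.DataFrame, list[str], list[str]]:
    """Train the gene-aligned classifier with a stratified 80/20 split.

    Returns (params, per-epoch history, train slide IDs, validation slide
    IDs). The history carries train/validation loss breakdowns and AUCs per
    epoch. Two self-checks run during training: pooling/projection
    commutativity (pool(project(Z)) == project(mean(Z)) by linearity) and
    the loss-composition identity total == cls + lg*graph + ld*dis.
    """
    y_of = {b.slide_id: (labels[b.slide_id] if labels else b.label) for b in bags}
    if any(v is None for v in y_of.values()):
        raise ValueError("every training bag needs a label")
    ids = [b.slide_id for b in bags]
    yv = np.array([int(y_of[i]) for i in ids])
    if np.bincount(yv, minlength=2).min() < 2:
        raise ValueError("need at least 2 bags per class")
    tr_ids, va_ids = train_test_split(
        ids, train_size=cfg.split, stratify=yv, random_state=cfg.seed % (2**31)
    )
    by_id = {b.slide_id: b for b in bags}
    tr_y = np.array([int(y_of[i]) for i in tr_ids])
    if tr_y.min() == tr_y.max():
        raise ValueError("single-class training set")

    dt = np.dtype(cfg.dtype)
    G = network.n_genes
    P = bags[0].embeddings.shape[1]
    L = network.laplacian.astype(float)
    rng = np.random.default_rng(cfg.seed)
    params = ModelParams.init(rng, P, cfg.hidden, G, width=cfg.width, dtype=cfg.dtype,
                              head_noise=cfg.head_noise)
    opt = Adam(lr=cfg.lr)
    Xtr = {i: by_id[i].embeddings.astype(dt) for i in tr_ids}
    param_view = params.as_dict()
    param_view["bc"] = bc_arr = np.array([params.bc], dtype=float)

    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(tr_ids))
        sums = np.zeros(4)  # cls, graph, dis, total
        train_scores = np.empty(len(tr_ids))
        grads_acc, n_acc = None, 0
        for step, oi in enumerate(order):
            sid = tr_ids[oi]
            X = Xtr[sid]
            y = int(y_of[sid])
            mask = None
            if cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = (rng.random((X.shape[0], cfg.width)) < keep).astype(dt) / keep
            cache = _forward(X, params, dropout_mask=mask)
            if step == 0:
                # linearity self-check: pooling and projection commute
                direct = params.Wg @ cache["Z"].mean(axis=0) + params.bg
                if not np.allclose(cache["Ghat"], direct, atol=1e-3):
                    raise AssertionError("pooling/projection commutativity violated")
            lb = total_loss(cache["yhat"], y, cache["Ghat"].astype(float),
                            cache["Gmat"].astype(float), L,
                            cfg.lambda_graph, cfg.lambda_dis)
            expected = lb.cls + cfg.lambda_graph * lb.graph + cfg.lambda_dis * lb.dis
            if abs(lb.total - expected) > 1e-6 * max(1.0, abs(expected)):
                raise AssertionError("loss composition identity violated")
            sums += (lb.cls, lb.graph, lb.dis, lb.total)
            train_scores[oi] = cache["yhat"]
            target = None
            if expression_targets is not None:
                target = np.asarray(expression_targets[sid], dtype=float)
            g = _backward(X, y, cache, params, L, cfg,
                          align_target=target, dropout_mask=mask)
            g["bc"] = np.array([g["bc"]], dtype=float)
            if cfg.batch <= 1:
                opt.step(param_view, g)
                params.bc = float(bc_arr[0])
            else:
                if grads_acc is None:
                    grads_acc = g
                else:
                    for k in g:
                        grads_acc[k] = grads_acc[k] + g[k]
                n_acc += 1
                if n_acc == cfg.batch or step == len(order) - 1:
                    for k in grads_acc:
                        grads_acc[k] = grads_acc[k] / n_acc
                    opt.step(param_view, grads_acc)
                    params.bc = float(bc_arr[0])
                    grads_acc, n_acc = None, 0
        n_tr = len(tr_ids)
        va_scores = _predict_bags([by_id[i] for i in va_ids], params)
        va_y = np.array([int(y_of[i]) for i in va_ids])
        val_lb = _eval_losses([by_id[i] for i in va_ids], va_y, params, L, cfg)
        row = {
            "epoch": epoch,
            "train_cls": sums[0] / n_tr, "train_graph": sums[1] / n_tr,
            "train_dis": sums[2] / n_tr, "train_total": sums[3] / n_tr,
            "val_cls": val_lb[0], "val_graph": val_lb[1],
            "val_dis": val_lb[2], "val_total": val_lb[3],
            "train_auc": roc_auc(train_scores, tr_y) if tr_y.min() != tr_y.max() else np.nan,
            "val_auc": roc_auc(va_scores, va_y) if va_y.min() != va_y.max() else np.nan,
        }
        history.append(row)
    return params, pd.DataFrame(history), list(tr_ids), list(va_ids)


def _eval_losses(bags, y, params, L, cfg):
    sums = np.zeros(4)
    for b, yi in zip(bags, y):
        X = b.embeddings.astype(params.W1.dtype)
        cache = _forward(X, params)
        lb = total_loss(cache["yhat"], int(yi), cache["Ghat"].astype(float),
                        cache["Gmat"].astype(float), L,
                        cfg.lambda_graph, cfg.lambda_dis)
        sums += (lb.cls, lb.graph, lb.dis, lb.total)
    return sums / max(len(bags), 1)


# ---------------------------------------------------------------------------
# statsmodels-style wrapper


class MorphologyGeneModel:
    """Morphology-only subtype model constrained by a gene network.

    Parameters
    ----------
    bags : sequence of SlideBag
    network : CoexpressionNetwork
        Fixed co-expression network whose Laplacian regularizes training;
        its gene count sets the latent dimensionality.
    config : TrainConfig, optional
    labels : mapping slide_id -> {0, 1}, optional
        Overrides bag labels (1 = Classical).
    expression : mapping slide_id -> ndarray, optional
        Z-scored true expression of the network genes per slide, enabling
        the optional alignment term (``config.align_weight``).
    """

    def __init__(self, bags, network, config=None, labels=None, expression=None):
        self.bags = list(bags)
        self.network = network
        self.config = config or TrainConfig()
        self.labels = labels
        self.expression = expression

    def fit(self) -> "MorphologyResults":
        params, history, tr, va = train(
            self.bags, self.network, self.config,
            labels=self.labels, expression_targets=self.expression,
        )
        return MorphologyResults(self, params, history, tr, va)


class MorphologyResults:
    """Fitted parameters, training history and prediction interface."""

    def __init__(self, model, params, history, train_ids, val_ids):
        self.model = model
        self.params = params
        self.history = history
        self.train_ids = train_ids
        self.val_ids = val_ids

    def predict(self, bags: Sequence[SlideBag]) -> np.ndarray:
        """Slide-level Classical probabilities."""
        return _predict_bags(list(bags), self.params)

    def gene_latents(self, bags: Sequence[SlideBag]) -> np.ndarray:
        """Slide-level pooled gene-latent vectors (n_slides x G)."""
        out = np.empty((len(bags), self.model.network.n_genes))
        for i, b in enumerate(bags):
            Z = encode_patches(b.embeddings.astype(self.params.W1.dtype), self.params)
            out[i] = pool_slide(gene_project(Z, self.params.Wg, self.params.bg))
        return out

    def evaluate(self, bags: Sequence[SlideBag], labels: Mapping[str, int]) -> dict:
        scores = self.predict(bags)
        y = [int(labels[b.slide_id]) for b in bags]
        auc = roc_auc(scores, y)
        se, sp = sens_spec(scores, y, self.model.config.classifier_threshold)
        return {"auc": auc, "sensitivity": se, "specificity": sp, "n": len(y)}

    @property
    def validation_auc(self) -> float:
        return float(self.history["val_auc"].iloc[-1])

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            "Morphology gene-latent model",
            "=" * 58,
            f"slides (train / validation)  {len(self.train_ids):>6} / {len(self.val_ids)}",
            f"gene heads / hidden / width  {self.model.network.n_genes:>6} / {cfg.hidden} / {cfg.width}",
            f"epochs x lr                  {cfg.epochs:>6} x {cfg.lr:g}",
            f"lambda_graph / lambda_dis    {cfg.lambda_graph:>6g} / {cfg.lambda_dis:g}",
            f"final train loss (total)     {h['train_total'].iloc[-1]:>9.4f}",
            f"final val loss (total)       {h['val_total'].iloc[-1]:>9.4f}",
            f"final train AUC              {h['train_auc'].iloc[-1]:>9.3f}",
            f"final validation AUC         {h['val_auc'].iloc[-1]:>9.3f}",
            "=" * 58,
        ]
        return "\n".join(lines)
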