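"""Attention-based classifier producing per-sample, per-feature importance.

The network classifies a sample x_j = [x_j1, ..., x_jd] into one of two
classes while emitting an importance vector beta_j over the d input features:

1. each feature i owns a fixed random embedding vector e_i (row i of the
   d x m matrix E); the embedded value of feature i for sample j is the
   multiplicative interaction  xhat_j^(i) = x_ji * e_i;
2. a shared scoring network f_alpha (one hidden tanh layer, m -> 1) maps
   each embedded vector independently to a raw attention score alpha_ji —
   self-attention: a feature's score depends only on that feature;
3. beta_j = softmax(alpha_j), so importances are positive and sum to one;
4. a shared representation network f_x (single tanh layer, m -> p) maps each
   embedded vector to R^p, and the sample representation is the
   attention-weighted mixture  xbar_j = sum_i beta_ji f_x(xhat_j^(i));
5. a classifier head f_y (one hidden layer with batch normalisation and
   ReLU, then a sigmoid output) maps xbar_j to Pr(y_j = 1).

Because m << d and the three sub-networks share weights across features, the
parameter count is independent of d, which keeps the attention mechanism
tractable when features vastly outnumber samples.

Training minimises the binary log-loss with Adam; dropout (default rate 0.5)
is applied to the hidden activations of f_x, f_alpha and f_y during training
only. All forward/backward passes are plain NumPy; gradients are derived
analytically (and verified against finite differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import ExpressionMatrix

__all__ = [
    "ModelConfig",
    "EmbeddingMatrix",
    "TriageModel",
    "SampleAttention",
    "ImportanceMatrix",
    "build_embedding",
    "embed_sample",
    "attention_scores",
    "represent_sample",
    "predict_proba",
    "forward",
    "fit",
    "predict",
    "score_importance",
    "save_model",
    "load_model",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    m is the embedding dimension (m << d), p the dimension of the final
    sample representation (p <= m recommended). With random embeddings the
    scorer can only tell features apart through their embedding directions,
    so m must be large enough for d random directions to stay nearly
    orthogonal; m = 256 is comfortable for feature spaces of hundreds to
    tens of thousands of features while keeping the parameter count
    independent of d.
    """

    m: int = 256
    p: int = 16
    alpha_hidden: int = 32
    y_hidden: int = 8
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 16
    seed: int = 0
    # input transform before embedding: "log_center" = log1p then subtract the
    # per-feature training mean (keeps the magnitude signal attention needs
    # while removing the shared baseline), "log_zscore" additionally divides
    # by the training sd, "log" = log1p only, "none" = raw values
    input_scaling: str = "log_center"
    validation_fraction: float = 0.1
    early_stopping: bool = False
    patience: int = 10
    class_weight: str | None = None  # None | "balanced"

    def __post_init__(self) -> None:
        if self.m < 1 or self.p < 1 or self.alpha_hidden < 1 or self.y_hidden < 1:
            raise ValueError("layer sizes must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_scaling not in ("log_center", "log_zscore", "log", "none"):
            raise ValueError(f"unknown input_scaling {self.input_scaling!r}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch normalisation)")


@dataclass
class EmbeddingMatrix:
    """Fixed (untrained) random feature embeddings: row i is e_i."""

    E: np.ndarray
    seed: int
    distribution: str

    @property
    def d(self) -> int:
        return self.E.shape[0]

    @property
    def m(self) -> int:
        return self.E.shape[1]


@dataclass
class SampleAttention:
    """Raw attention scores alpha and softmax-normalised importances beta."""

    alpha: np.ndarray
    beta: np.ndarray


@dataclass
class ImportanceMatrix:
    """Stack of per-sample importance vectors beta_j (rows sum to 1)."""

    sample_ids: list[str]
    feature_ids: list[str]
    B: np.ndarray
    class_labels: np.ndarray | None = None

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.B, index=self.sample_ids, columns=self.feature_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ImportanceMatrix":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in frame.index], [str(c) for c in frame.columns], frame.to_numpy(float))


@dataclass
class TriageModel:
    """Trained model: fixed embedding + parameters of f_x, f_alpha, f_y."""

    embedding: EmbeddingMatrix
    params: dict[str, np.ndarray]
    bn_mean: np.ndarray
    bn_var: np.ndarray
    config: ModelConfig
    feature_ids: list[str] | None = None
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    training_log: list[float] = field(default_factory=list)
    validation_log: list[float] = field(default_factory=list)

    @property
    def theta_x(self) -> dict[str, np.ndarray]:
        return {k: self.params[k] for k in ("Wx", "bx")}

    @property
    def theta_alpha(self) -> dict[str, np.ndarray]:
        return {k: self.params[k] for k in ("Wa1", "ba1", "wa2", "ba2")}

    @property
    def theta_y(self) -> dict[str, np.ndarray]:
        return {k: self.params[k] for k in ("Wy1", "by1", "gamma", "delta", "wy2", "by2")}


# ---------------------------------------------------------------------------
# construction


def build_embedding(d: int, m: int, seed: int) -> EmbeddingMatrix:
    """Draw a fixed d x m embedding with i.i.d. N(0, 1/m) entries.

    The 1/sqrt(m) scale keeps ||xhat|| comparable across embedding sizes.
    Deterministic given the seed.
    """
    if d < 1 or m < 1:
        raise ValueError("embedding dimensions must be positive")
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((d, m)) / np.sqrt(m)
    return EmbeddingMatrix(E=E, seed=seed, distribution=f"normal(0, 1/{m})")


def _init_params(d: int, cfg: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    m, p, ha, hy = cfg.m, cfg.p, cfg.alpha_hidden, cfg.y_hidden

    def lin(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        return rng.standard_normal(shape) / np.sqrt(fan_in)

    return {
        "Wx": lin(m, (m, p)),
        "bx": np.zeros(p),
        "Wa1": lin(m, (m, ha)),
        "ba1": np.zeros(ha),
        "wa2": lin(ha, (ha,)),
        "ba2": np.zeros(1),
        "Wy1": lin(p, (p, hy)),
        "by1": np.zeros(hy),
        "gamma": np.ones(hy),
        "delta": np.zeros(hy),
        "wy2": lin(hy, (hy,)),
        "by2": np.zeros(1),
    }


# ---------------------------------------------------------------------------
# forward pieces (evaluation mode, exposed per operation)


def embed_sample(x: np.ndarray, E: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Multiplicative interaction: row i of the output is x_i * e_i."""
    Em = E.E if isinstance(E, EmbeddingMatrix) else np.asarray(E)
    x = np.asarray(x, dtype=float)
    if x.shape != (Em.shape[0],):
        raise ValueError(f"sample has {x.shape} values but embedding has {Em.shape[0]} rows")
    return x[:, None] * Em


def _softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    a = a - a.max(axis=axis, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=axis, keepdims=True)


def attention_scores(embedded: np.ndarray, model: TriageModel) -> SampleAttention:
    """Per-feature self-attention scores and softmax importances (eval mode)."""
    if not np.all(np.isfinite(embedded)):
        raise ValueError("embedded values contain non-finite entries")
    P = model.params
    A = np.tanh(embedded @ P["Wa1"] + P["ba1"])
    alpha = A @ P["wa2"] + P["ba2"][0]
    return SampleAttention(alpha=alpha, beta=_softmax(alpha))


def represent_sample(embedded: np.ndarray, beta: np.ndarray, model: TriageModel) -> np.ndarray:
    """Attention-weighted mixture of per-feature representations f_x."""
    if embedded.shape[0] != beta.shape[0]:
        raise ValueError("beta length does not match number of embedded features")
    P = model.params
    H = np.tanh(embedded @ P["Wx"] + P["bx"])
    return beta @ H


def predict_proba(x_bar: np.ndarray, model: TriageModel) -> float:
    """Classifier head probability in (0, 1) (eval mode: frozen BN stats)."""
    x_bar = np.asarray(x_bar, dtype=float)
    if not np.all(np.isfinite(x_bar)):
        raise ValueError("representation contains non-finite entries")
    P = model.params
    z = x_bar @ P["Wy1"] + P["by1"]
    zn = (z - model.bn_mean) / np.sqrt(model.bn_var + _BN_EPS)
    h = np.maximum(P["gamma"] * zn + P["delta"], 0.0)
    logit = h @ P["wy2"] + P["by2"][0]
    return float(1.0 / (1.0 + np.exp(-logit)))


def forward(x: np.ndarray, model: TriageModel, scale: bool = True) -> tuple[float, SampleAttention]:
    """Full per-sample evaluation pass: probability and attention.

    ``scale`` applies the model's stored input transform (set False when the
    input is already in model space).
    """
    x = np.asarray(x, dtype=float)
    if scale:
        x = _apply_scaler(x[None, :], model)[0]
    embedded = embed_sample(x, model.embedding)
    att = attention_scores(embedded, model)
    x_bar = represent_sample(embedded, att.beta, model)
    return predict_proba(x_bar, model), att


# ---------------------------------------------------------------------------
# batched forward/backward for training


def _forward_batch(
    X: np.ndarray,
    params: dict[str, np.ndarray],
    E: np.ndarray,
    training: bool,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    bn_mean: np.ndarray | None = None,
    bn_var: np.ndarray | None = None,
) -> dict:
    """Vectorised forward pass. Returns a cache for backprop.

    Training mode uses batch statistics for batch-norm and (optionally)
    inverted dropout; evaluation mode uses the running statistics and no
    dropout.
    """
    n, d = X.shape
    m = E.shape[1]
    P = params
    Xh = (X[:, :, None] * E).reshape(n * d, m)

    keep = 1.0 - dropout_rate

    def mask(shape: tuple[int, ...]) -> np.ndarray | None:
        if not training or dropout_rate == 0.0:
            return None
        assert rng is not None
        return (rng.random(shape) < keep).astype(float) / keep

    # attention branch
    Za = Xh @ P["Wa1"] + P["ba1"]
    Aa = np.tanh(Za)
    Ma = mask(Aa.shape)
    Aad = Aa if Ma is None else Aa * Ma
    alpha = (Aad @ P["wa2"] + P["ba2"][0]).reshape(n, d)
    beta = _softmax(alpha, axis=1)

    # representation branch
    Zx = Xh @ P["Wx"] + P["bx"]
    Ax = np.tanh(Zx)
    Mx = mask(Ax.shape)
    Axd = Ax if Mx is None else Ax * Mx
    Ax3 = Axd.reshape(n, d, -1)
    xbar = np.einsum("nd,ndp->np", beta, Ax3)

    # classifier head
    Zy = xbar @ P["Wy1"] + P["by1"]
    if training:
        mu = Zy.mean(axis=0)
        var = Zy.var(axis=0)
    else:
        mu = bn_mean
        var = bn_var
    zn = (Zy - mu) / np.sqrt(var + _BN_EPS)
    bn = P["gamma"] * zn + P["delta"]
    H = np.maximum(bn, 0.0)
    Mh = mask(H.shape)
    Hd = H if Mh is None else H * Mh
    logit = Hd @ P["wy2"] + P["by2"][0]
    prob = 1.0 / (1.0 + np.exp(-logit))

    return dict(
        X=X, Xh=Xh, Aa=Aa, Ma=Ma, Aad=Aad, beta=beta, Ax=Ax, Mx=Mx, Ax3=Ax3,
        xbar=xbar, mu=mu, var=var, zn=zn, bn=bn, H=H, Mh=Mh, Hd=Hd,
        logit=logit, prob=prob, n=n, d=d,
    )


def _bce_loss(prob: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> float:
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    ll = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    if weights is not None:
        ll = ll * weights
    return float(ll.mean())


def _backward_batch(
    cache: dict, params: dict[str, np.ndarray], y: np.ndarray,
    weights: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Analytic gradients of the mean log-loss w.r.t. every parameter."""
    P = params
    n, d = cache["n"], cache["d"]
    prob, Hd, H, Mh, bn, zn = (
        cache["prob"], cache["Hd"], cache["H"], cache["Mh"], cache["bn"], cache["zn"],
    )
    dlogit = (prob - y) / n
    if weights is not None:
        dlogit = dlogit * weights

    g: dict[str, np.ndarray] = {}
    g["wy2"] = Hd.T @ dlogit
    g["by2"] = np.array([dlogit.sum()])
    dHd = np.outer(dlogit, P["wy2"])
    dH = dHd if Mh is None else dHd * Mh
    dbn = dH * (bn > 0)
    g["gamma"] = (dbn * zn).sum(axis=0)
    g["delta"] = dbn.sum(axis=0)
    dzn = dbn * P["gamma"]
    inv = 1.0 / np.sqrt(cache["var"] + _BN_EPS)
    # batch-norm backprop through batch mean/variance
    dZy = (inv / n) * (n * dzn - dzn.sum(axis=0) - zn * (dzn * zn).sum(axis=0))
    g["Wy1"] = cache["xbar"].T @ dZy
    g["by1"] = dZy.sum(axis=0)
    dxbar = dZy @ P["Wy1"].T

    beta, Ax3 = cache["beta"], cache["Ax3"]
    dbeta = np.einsum("np,ndp->nd", dxbar, Ax3)
    dAx3 = beta[:, :, None] * dxbar[:, None, :]
    dAxd = dAx3.reshape(n * d, -1)
    dAx = dAxd if cache["Mx"] is None else dAxd * cache["Mx"]
    dZx = dAx * (1.0 - cache["Ax"] ** 2)
    g["Wx"] = cache["Xh"].T @ dZx
    g["bx"] = dZx.sum(axis=0)

    # softmax jacobian, rowwise
    dalpha = beta * (dbeta - (dbeta * beta).sum(axis=1, keepdims=True))
    dal = dalpha.reshape(n * d)
    g["wa2"] = cache["Aad"].T @ dal
    g["ba2"] = np.array([dal.sum()])
    dAad = np.outer(dal, P["wa2"])
    dAa = dAad if cache["Ma"] is None else dAad * cache["Ma"]
    dZa = dAa * (1.0 - cache["Aa"] ** 2)
    g["Wa1"] = cache["Xh"].T @ dZa
    g["ba1"] = dZa.sum(axis=0)
    return g


def loss_and_grads(
    params: dict[str, np.ndarray], E: np.ndarray, X: np.ndarray, y: np.ndarray,
    dropout_rate: float = 0.0, rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Training-mode loss and analytic gradients for one batch."""
    cache = _forward_batch(X, params, E, training=True, dropout_rate=dropout_rate, rng=rng)
    loss = _bce_loss(cache["prob"], y, weights)
    grads = _backward_batch(cache, params, y, weights)
    return loss, grads


# ---------------------------------------------------------------------------
# input scaling


def _fit_scaler(X: np.ndarray, cfg: ModelConfig) -> tuple[np.ndarray | None, np.ndarray | None]:
    d = X.shape[1]
    if cfg.input_scaling == "none":
        return None, None
    if cfg.input_scaling == "log":
        return np.zeros(d), np.ones(d)
    L = np.log1p(X)
    mean = L.mean(axis=0)
    if cfg.input_scaling == "log_center":
        return mean, np.ones(d)
    std = L.std(axis=0)
    std[std < 1e-8] = 1.0
    return mean, std


def _apply_scaler(X: np.ndarray, model: TriageModel) -> np.ndarray:
    if model.scaler_mean is None:
        return X
    return (np.log1p(X) - model.scaler_mean) / model.scaler_std


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.mom = {k: np.zeros_like(v) for k, v in params.items()}
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, gval in grads.items():
            self.mom[k] = self.b1 * self.mom[k] + (1 - self.b1) * gval
            self.vel[k] = self.b2 * self.vel[k] + (1 - self.b2) * gval ** 2
            params[k] -= self.lr * (self.mom[k] / bc1) / (np.sqrt(self.vel[k] / bc2) + self.eps)


def fit(
    train: ExpressionMatrix | np.ndarray,
    labels: np.ndarray,
    config: ModelConfig | None = None,
    embedding: EmbeddingMatrix | None = None,
) -> TriageModel:
    """Train the attention classifier end to end.

    Labels are binary (1 = class "A", 0 = class "B"); both classes must be
    present with at least two samples each. Reproducible given
    ``config.seed``: embedding draw, parameter init, validation split,
    shuffling and dropout all derive from it.
    """
    cfg = config or ModelConfig()
    if isinstance(train, ExpressionMatrix):
        X_raw = train.values
        feature_ids: list[str] | None = list(train.feature_ids)
    else:
        X_raw = np.asarray(train, dtype=float)
        feature_ids = None
    y = np.asarray(labels, dtype=float).ravel()
    if X_raw.shape[0] != y.shape[0]:
        raise ValueError("labels do not align with samples")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples in each of the two classes")

    n, d = X_raw.shape
    ss = np.random.SeedSequence(cfg.seed)
    s_embed, s_init, s_split, s_train = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))

    if embedding is None:
        embedding = build_embedding(d, cfg.m, s_embed)
    elif embedding.d != d:
        raise ValueError(f"embedding has {embedding.d} rows but data has {d} features")

    scaler_mean, scaler_std = _fit_scaler(X_raw, cfg)
    model = TriageModel(
        embedding=embedding,
        params=_init_params(d, cfg, np.random.default_rng(s_init)),
        bn_mean=np.zeros(cfg.y_hidden),
        bn_var=np.ones(cfg.y_hidden),
        config=cfg,
        feature_ids=feature_ids,
        scaler_mean=scaler_mean,
        scaler_std=scaler_std,
    )
    X = _apply_scaler(X_raw, model)

    # optional held-out fraction for monitoring / early stopping (stratified)
    val_idx = np.array([], dtype=int)
    tr_idx = np.arange(n)
    if cfg.validation_fraction > 0 and (cfg.early_stopping or cfg.validation_fraction > 0):
        rng_split = np.random.default_rng(s_split)
        val_parts = []
        for c in (0.0, 1.0):
            idx_c = np.flatnonzero(y == c)
            rng_split.shuffle(idx_c)
            n_val = int(round(cfg.validation_fraction * len(idx_c)))
            n_val = min(n_val, len(idx_c) - 2)  # keep >=2 per class for training
            if n_val > 0:
                val_parts.append(idx_c[:n_val])
        if val_parts:
            val_idx = np.concatenate(val_parts)
            tr_idx = np.setdiff1d(np.arange(n), val_idx)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    weights_tr = None
    if cfg.class_weight == "balanced":
        w = ytr.shape[0] / (2.0 * np.bincount(ytr.astype(int), minlength=2))
        weights_tr = w[ytr.astype(int)]

    rng = np.random.default_rng(s_train)
    opt = _Adam(model.params, cfg.learning_rate)
    best_val = np.inf
    best_state: tuple | None = None
    stale = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(ytr))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:  # batch-norm needs >=2 samples
                continue
            Xb, yb = Xtr[idx], ytr[idx]
            wb = weights_tr[idx] if weights_tr is not None else None
            cache = _forward_batch(
                Xb, model.params, embedding.E, training=True,
                dropout_rate=cfg.dropout_rate, rng=rng,
            )
            loss = _bce_loss(cache["prob"], yb, wb)
            if not np.isfinite(loss):
                raise RuntimeError(f"training loss became non-finite at epoch {epoch}")
            grads = _backward_batch(cache, model.params, yb, wb)
            opt.step(model.params, grads)
            # running batch-norm statistics (unbiased variance)
            nb = len(idx)
            model.bn_mean = (1 - _BN_MOMENTUM) * model.bn_mean + _BN_MOMENTUM * cache["mu"]
            model.bn_var = (1 - _BN_MOMENTUM) * model.bn_var + _BN_MOMENTUM * cache["var"] * nb / (nb - 1)
            epoch_losses.append(loss)
        model.training_log.append(float(np.mean(epoch_losses)))

        if len(val_idx) > 0:
            pv = _forward_batch(
                Xval, model.params, embedding.E, training=False,
                bn_mean=model.bn_mean, bn_var=model.bn_var,
            )["prob"]
            vloss = _bce_loss(pv, yval)
            model.validation_log.append(vloss)
            if cfg.early_stopping:
                if vloss < best_val - 1e-6:
                    best_val = vloss
                    best_state = (
                        {k: v.copy() for k, v in model.params.items()},
                        model.bn_mean.copy(), model.bn_var.copy(),
                    )
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
    if best_state is not None:
        model.params, model.bn_mean, model.bn_var = best_state
    return model


def predict(model: TriageModel, data: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Evaluation-mode class-1 probabilities for a batch of samples."""
    X_raw = data.values if isinstance(data, ExpressionMatrix) else np.asarray(data, dtype=float)
    if isinstance(data, ExpressionMatrix) and model.feature_ids is not None:
        _check_features(model.feature_ids, data.feature_ids)
    X = _apply_scaler(X_raw, model)
    out = _forward_batch(
        X, model.params, model.embedding.E, training=False,
        bn_mean=model.bn_mean, bn_var=model.bn_var,
    )
    return out["prob"]


def _check_features(expected: list[str], got: list[str]) -> None:
    if list(expected) != list(got):
        missing = sorted(set(expected) - set(got))[:5]
        extra = sorted(set(got) - set(expected))[:5]
        raise ValueError(
            f"feature mismatch with the trained model: missing={missing}, unexpected={extra}"
            if missing or extra
            else "feature order differs from the trained model"
        )


def score_importance(model: TriageModel, test: ExpressionMatrix) -> ImportanceMatrix:
    """Per-sample importance vectors beta_j for the given (test) samples.

    Evaluation mode: no dropout, frozen batch-norm statistics. Every row of
    the returned matrix sums to 1.
    """
    if model.feature_ids is not None:
        _check_features(model.feature_ids, test.feature_ids)
    X = _apply_scaler(test.values, model)
    out = _forward_batch(
        X, model.params, model.embedding.E, training=False,
        bn_mean=model.bn_mean, bn_var=model.bn_var,
    )
    return ImportanceMatrix(
        sample_ids=list(test.sample_ids),
        feature_ids=list(test.feature_ids),
        B=out["beta"],
    )


# ---------------------------------------------------------------------------
# serialisation


def save_model(model: TriageModel, path: str | Path) -> None:
    """Write a single self-describing archive (config + embedding + weights)."""
    meta = {
        "config": asdict(model.config),
        "embedding_seed": model.embedding.seed,
        "embedding_distribution": model.embedding.distribution,
        "feature_ids": model.feature_ids,
        "training_log": model.training_log,
        "validation_log": model.validation_log,
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays["E"] = model.embedding.E
    arrays["bn_mean"] = model.bn_mean
    arrays["bn_var"] = model.bn_var
    if model.scaler_mean is not None:
        arrays["scaler_mean"] = model.scaler_mean
        arrays["scaler_std"] = model.scaler_std
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> TriageModel:
    with np.load(path, allow_pickle=False) as arc:
        meta = json.loads(str(arc["meta"]))
        params = {k[len("param_"):]: arc[k] for k in arc.files if k.startswith("param_")}
        emb = EmbeddingMatrix(
            E=arc["E"], seed=meta["embedding_seed"], distribution=meta["embedding_distribution"]
        )
        return TriageModel(
            embedding=emb,
            params=params,
            bn_mean=arc["bn_mean"],
            bn_var=arc["bn_var"],
            config=ModelConfig(**meta["config"]),
            feature_ids=meta["feature_ids"],
            scaler_mean=arc["scaler_mean"] if "scaler_mean" in arc.files else None,
            scaler_std=arc["scaler_std"] if "scaler_std" in arc.files else None,
            training_log=list(meta["training_log"]),
            validation_log=list(meta["validation_log"]),
        )
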