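"""Outcome predictors built on TME marker genes.

Two models mirror each other: a risk score (mean of Cox-coefficient-weighted,
standardized marker expression) and a five-layer neural classifier (input,
three batch-normalized ReLU hidden layers, sigmoid output) trained by
full-batch Adam on binary cross-entropy. Both are evaluated by rank-based AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .containers import ExpressionMatrix
from .survival import fit_cox_univariate


# ---------------------------------------------------------------------------
# risk score
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """Per-gene Cox coefficients plus the training standardization constants."""

    genes: List[str]
    betas: Dict[str, float]
    mu: Dict[str, float]
    sd: Dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_risk_score(
    expr: ExpressionMatrix, genes: Sequence[str], surv: pd.DataFrame
) -> RiskModel:
    """Fit per-gene univariate Cox coefficients on standardized expression.

    Genes absent from the matrix or with zero variance are dropped with a
    warning; the model keeps each gene's training mean/SD so the score can be
    applied to external cohorts on the training scale.
    """
    vals = expr.values.loc[:, surv.index]
    kept, betas, mus, sds = [], {}, {}, {}
    dropped = []
    for g in genes:
        if g not in vals.index:
            dropped.append(g)
            continue
        x = vals.loc[g].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            dropped.append(g)
            continue
        z = (x - x.mean()) / sd
        fit = fit_cox_univariate(z, surv)
        kept.append(g)
        betas[g] = fit.beta
        mus[g] = float(x.mean())
        sds[g] = float(sd)
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) dropped from the risk model "
                      f"(absent or constant): {dropped[:5]}")
    if not kept:
        raise ValueError("no usable genes for the risk model")
    return RiskModel(genes=kept, betas=betas, mu=mus, sd=sds)


def apply_risk_score(model: RiskModel, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample risk score: mean over genes of beta_g * z_g (training scale)."""
    present = [g for g in model.genes if g in expr.genes]
    if len(present) < 0.5 * len(model.genes):
        raise ValueError(
            f"only {len(present)}/{len(model.genes)} model genes present in the matrix"
        )
    vals = expr.values.loc[present].to_numpy(dtype=float)
    mu = np.array([model.mu[g] for g in present])[:, None]
    sd = np.array([model.sd[g] for g in present])[:, None]
    beta = np.array([model.betas[g] for g in present])[:, None]
    z = (vals - mu) / sd
    score = (beta * z).sum(axis=0) / len(present)
    return pd.Series(score, index=expr.columns, name="risk_score")


# ---------------------------------------------------------------------------
# five-layer neural classifier
# ---------------------------------------------------------------------------


@dataclass
class MLPConfig:
    hidden_sizes: Tuple[int, int, int] = (64, 32, 16)
    iterations: int = 400
    learning_rate: float = 0.01
    train_fraction: float = 2.0 / 3.0
    bn_eps: float = 1e-5
    seed: int = 0


@dataclass
class MLPModel:
    """Weights, batch-normalization statistics and split of the trained net."""

    feature_names: List[str]
    layer_sizes: List[int]
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    bn_gamma: List[np.ndarray]
    bn_beta: List[np.ndarray]
    bn_mean: List[np.ndarray]
    bn_var: List[np.ndarray]
    feat_mu: np.ndarray
    feat_sd: np.ndarray
    config: MLPConfig
    train_index: List[str] = field(default_factory=list)
    test_index: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "bn_gamma": [g.tolist() for g in self.bn_gamma],
            "bn_beta": [b.tolist() for b in self.bn_beta],
            "bn_mean": [m.tolist() for m in self.bn_mean],
            "bn_var": [v.tolist() for v in self.bn_var],
            "feat_mu": self.feat_mu.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "config": asdict(self.config),
            "train_index": self.train_index,
            "test_index": self.test_index,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        with open(path) as fh:
            d = json.load(fh)
        cfg = d.pop("config")
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            feature_names=d["feature_names"],
            layer_sizes=d["layer_sizes"],
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            bn_gamma=[np.asarray(g) for g in d["bn_gamma"]],
            bn_beta=[np.asarray(b) for b in d["bn_beta"]],
            bn_mean=[np.asarray(m) for m in d["bn_mean"]],
            bn_var=[np.asarray(v) for v in d["bn_var"]],
            feat_mu=np.asarray(d["feat_mu"]),
            feat_sd=np.asarray(d["feat_sd"]),
            config=MLPConfig(**cfg),
            train_index=d["train_index"],
            test_index=d["test_index"],
        )


def _forward(model_params, X, bn_eps, training, bn_stats=None):
    """Forward pass; returns activations cache for backprop when training."""
    Ws, bs, gammas, betas = model_params
    cache = {"h": [X], "xhat": [], "mean": [], "var": [], "pre": []}
    h = X
    n_hidden = len(Ws) - 1
    for l in range(n_hidden):
        z = h @ Ws[l] + bs[l]
        if training:
            mean = z.mean(axis=0)
            var = z.var(axis=0)
        else:
            mean, var = bn_stats[0][l], bn_stats[1][l]
        xhat = (z - mean) / np.sqrt(var + bn_eps)
        a = np.maximum(gammas[l] * xhat + betas[l], 0.0)  # BN then ReLU
        cache["pre"].append(z)
        cache["xhat"].append(xhat)
        cache["mean"].append(mean)
        cache["var"].append(var)
        cache["h"].append(a)
        h = a
    logit = (h @ Ws[-1] + bs[-1]).ravel()
    prob = expit(logit)
    return prob, cache


def train_mlp(
    features: pd.DataFrame,
    labels: pd.Series,
    config: Optional[MLPConfig] = None,
) -> MLPModel:
    """Train the five-layer classifier on a random 2/3 split of the samples.

    ``features`` is samples x features; ``labels`` binary. Hidden layers use
    batch normalization (batch statistics while training, final-epoch running
    statistics at inference) followed by ReLU; the output layer is a sigmoid
    unit initialized at zero, trained by full-batch Adam on binary
    cross-entropy for ``config.iterations`` steps. Fully deterministic under
    ``config.seed``.
    """
    config = config or MLPConfig()
    labels = labels.loc[features.index]
    y_all = labels.to_numpy(dtype=float)
    if len(np.unique(y_all)) < 2:
        raise ValueError("labels contain a single class")
    if len(y_all) < 20:
        raise ValueError("need at least 20 labeled samples")

    rng = np.random.default_rng(config.seed)
    n = len(y_all)
    perm = rng.permutation(n)
    n_train = int(round(config.train_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    if len(np.unique(y_all[train_idx])) < 2:
        raise ValueError("training split contains a single class; reseed or add samples")

    X_all = features.to_numpy(dtype=float)
    mu = X_all[train_idx].mean(axis=0)
    sd = X_all[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    X = (X_all - mu) / sd
    Xtr, ytr = X[train_idx], y_all[train_idx]

    sizes = [X.shape[1], *config.hidden_sizes, 1]
    Ws, bs, gammas, betas = [], [], [], []
    for l in range(len(sizes) - 1):
        fan_in = sizes[l]
        if l == len(sizes) - 2:
            W = np.zeros((fan_in, sizes[l + 1]))  # zero output layer -> p = 0.5 untrained
        else:
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, sizes[l + 1]))
        Ws.append(W)
        bs.append(np.zeros(sizes[l + 1]))
    for h in config.hidden_sizes:
        gammas.append(np.ones(h))
        betas.append(np.zeros(h))

    params = [*Ws, *bs, *gammas, *betas]
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    n_hidden = len(config.hidden_sizes)
    last_mean = [np.zeros(h) for h in config.hidden_sizes]
    last_var = [np.ones(h) for h in config.hidden_sizes]

    for it in range(config.iterations):
        prob, cache = _forward((Ws, bs, gammas, betas), Xtr, config.bn_eps, training=True)
        last_mean = [m.copy() for m in cache["mean"]]
        last_var = [v.copy() for v in cache["var"]]
        B = len(ytr)
        dlogit = (prob - ytr)[:, None] / B  # d(BCE)/dlogit for sigmoid output

        gW = [None] * len(Ws)
        gb = [None] * len(bs)
        gg = [None] * n_hidden
        gbeta = [None] * n_hidden

        h_last = cache["h"][-1]
        gW[-1] = h_last.T @ dlogit
        gb[-1] = dlogit.sum(axis=0)
        da = dlogit @ Ws[-1].T
        for l in range(n_hidden - 1, -1, -1):
            a = cache["h"][l + 1]
            da = da * (a > 0)  # ReLU gate
            xhat = cache["xhat"][l]
            gg[l] = (da * xhat).sum(axis=0)
            gbeta[l] = da.sum(axis=0)
            dxhat = da * gammas[l]
            var = cache["var"][l]
            inv_std = 1.0 / np.sqrt(var + config.bn_eps)
            # batch-norm backward (batch statistics are functions of the batch)
            dz = (inv_std / B) * (
                B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
            h_in = cache["h"][l]
            gW[l] = h_in.T @ dz
            gb[l] = dz.sum(axis=0)
            da = dz @ Ws[l].T

        grads = [*gW, *gb, *gg, *gbeta]
        t = it + 1
        for p, g, m_, v_ in zip(params, grads, m_adam, v_adam):
            m_ *= b1
            m_ += (1 - b1) * g
            v_ *= b2
            v_ += (1 - b2) * g * g
            mhat = m_ / (1 - b1**t)
            vhat = v_ / (1 - b2**t)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)

    return MLPModel(
        feature_names=list(features.columns),
        layer_sizes=sizes,
        weights=Ws, biases=bs, bn_gamma=gammas, bn_beta=betas,
        bn_mean=last_mean, bn_var=last_var,
        feat_mu=mu, feat_sd=sd, config=config,
        train_index=list(features.index[train_idx]),
        test_index=list(features.index[test_idx]),
    )


def predict_mlp(model: MLPModel, features: pd.DataFrame) -> pd.Series:
    """Probability scores for new samples (features on the training scale)."""
    X = features.loc[:, model.feature_names].to_numpy(dtype=float)
    X = (X - model.feat_mu) / model.feat_sd
    prob, _ = _forward(
        (model.weights, model.biases, model.bn_gamma, model.bn_beta),
        X, model.config.bn_eps, training=False,
        bn_stats=(model.bn_mean, model.bn_var),
    )
    return pd.Series(prob, index=features.index, name="dnn_score")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with tied scores averaged."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> Dict[str, float]:
    """2x2 confusion counts (predicted positive when score >= threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "accuracy": (tp + tn) / len(y)}


def label_one_year_survival(surv: pd.DataFrame, horizon: float = 365.0) -> pd.Series:
    """Binary death-within-horizon labels.

    1 when the event occurred at or before the horizon, 0 when follow-up
    passed the horizon; samples censored before the horizon are indeterminate
    and excluded.
    """
    dead = (surv["event"] == 1) & (surv["time"] <= horizon)
    alive = surv["time"] > horizon
    keep = dead | alive
    if not keep.any():
        raise ValueError("every sample is censored before the horizon")
    return dead[keep].astype(int).rename("dead_by_horizon")
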