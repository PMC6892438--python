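"""Stacked variational autoencoder producing non-negative latent factors.

The generative model explains the stacked multi-omics vector x through a small
set of latent factors z with prior N(0, I). The encoder maps x through one
hidden layer (linear -> batch-norm -> ReLU) to a diagonal Gaussian posterior
q(z|x) = N(mu, diag sigma^2); the decoder maps z through a mirror hidden layer
to sigmoid outputs x_hat. Training minimizes the negative evidence lower bound

    l = BCE(x, x_hat) + beta * KL( N(mu, sigma^2) || N(0, I) ),

with the reparametrization z = mu + sigma * eps, eps ~ N(0, I), and a KL
warm-up schedule beta = min(1, kappa * epoch) that lets the network find a
good reconstruction before regularizing. Latent factors reported at inference
are ReLU(mu) — deterministic and non-negative, which encourages disentangled,
parts-based representations.

The network is implemented directly on numpy (dense layers, batch
normalization, manual backpropagation, Adam), keeping training bit-reproducible
from a single integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import OmicsStack, ScalingModel

_BN_EPS = 1e-5
_CLAMP = 1e-7  # sigmoid outputs clipped into [eps, 1-eps] before the log


@dataclass
class VAEConfig:
    """Hyper-parameters of the stacked VAE.

    Defaults follow the published configuration: 1,100 hidden units, 100
    latent factors, 600 epochs of Adam on minibatches of 100 samples, and a
    KL warm-up increment kappa = 0.01 per epoch (beta reaches 1 at epoch 100).
    """

    n_hidden: int = 1100
    n_latent: int = 100
    epochs: int = 600
    batch_size: int = 100
    kappa: float = 0.01
    learning_rate: float = 1e-3
    seed: int = 0
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        for name in ("n_hidden", "n_latent", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must lie in (0, 1]")
        if self.kappa * self.epochs < 1:
            warnings.warn(
                "kappa * epochs < 1: the KL weight never reaches 1 during training"
            )


@dataclass
class LatentSpace:
    """Non-negative sample x factor matrix z with factor ids LF1..LFk."""

    values: np.ndarray
    sample_ids: list[str]
    factor_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.factor_ids is None:
            self.factor_ids = [f"LF{i + 1}" for i in range(self.values.shape[1])]
        if self.values.shape != (len(self.sample_ids), len(self.factor_ids)):
            raise ValueError("latent matrix shape does not match ids")
        if (self.values < 0).any():
            raise ValueError("latent factors must be non-negative")

    @property
    def n_factors(self) -> int:
        return len(self.factor_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.factor_ids)

    def subset_factors(self, keep: list[str]) -> "LatentSpace":
        idx = [self.factor_ids.index(f) for f in keep]
        return LatentSpace(self.values[:, idx], list(self.sample_ids), list(keep))


def warmup_beta(epoch: int, kappa: float) -> float:
    """KL weight at a 0-based epoch: beta = min(1, epoch * kappa)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return min(1.0, epoch * kappa)


def kl_term(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)) per sample (summed over dims)."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if (sigma <= 0).any():
        raise ValueError("sigma must be strictly positive")
    return 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=-1)


def reconstruction_term(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    """Binary cross-entropy per sample, summed over features; targets are soft
    [0,1]-scaled values."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.clip(np.atleast_2d(np.asarray(x_hat, dtype=float)), _CLAMP, 1 - _CLAMP)
    return -np.sum(x * np.log(x_hat) + (1 - x) * np.log(1 - x_hat), axis=-1)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class MultiOmicsVAE(BaseEstimator, TransformerMixin):
    """Stacked VAE for multi-omics integration, as a sklearn transformer.

    ``fit`` expects a samples x features array scaled to [0,1] (see
    :func:`movae.io.scale_stack`); ``transform`` returns the deterministic
    non-negative latent representation ReLU(mu).

    Attributes set by ``fit`` (trailing underscore): ``params_`` (weights),
    ``history_`` (per-epoch loss table), ``n_features_in_``.
    """

    def __init__(
        self,
        n_hidden: int = 1100,
        n_latent: int = 100,
        epochs: int = 600,
        batch_size: int = 100,
        kappa: float = 0.01,
        learning_rate: float = 1e-3,
        seed: int = 0,
        bn_momentum: float = 0.9,
    ):
        self.n_hidden = n_hidden
        self.n_latent = n_latent
        self.epochs = epochs
        self.batch_size = batch_size
        self.kappa = kappa
        self.learning_rate = learning_rate
        self.seed = seed
        self.bn_momentum = bn_momentum

    # ------------------------------------------------------------------ setup
    def _config(self) -> VAEConfig:
        return VAEConfig(
            n_hidden=self.n_hidden,
            n_latent=self.n_latent,
            epochs=self.epochs,
            batch_size=self.batch_size,
            kappa=self.kappa,
            learning_rate=self.learning_rate,
            seed=self.seed,
            bn_momentum=self.bn_momentum,
        )

    def build(self, n_features: int) -> "MultiOmicsVAE":
        """Initialize weights for ``n_features`` inputs from the seeded RNG."""
        cfg = self._config()
        if n_features < cfg.n_latent:
            warnings.warn(
                f"n_features ({n_features}) < n_latent ({cfg.n_latent}): "
                "the latent space is wider than the data"
            )
        rng = np.random.default_rng(cfg.seed)
        h, k = cfg.n_hidden, cfg.n_latent
        p = {
            # encoder: x -> hidden -> (mu, logvar)
            "W_eh": _glorot(rng, n_features, h),
            "b_eh": np.zeros(h),
            "g_e": np.ones(h),
            "be_e": np.zeros(h),
            "W_mu": _glorot(rng, h, k),
            "b_mu": np.zeros(k),
            "W_lv": _glorot(rng, h, k),
            "b_lv": np.zeros(k),
            # decoder: z -> hidden -> sigmoid(x_hat)
            "W_dh": _glorot(rng, k, h),
            "b_dh": np.zeros(h),
            "g_d": np.ones(h),
            "be_d": np.zeros(h),
            "W_out": _glorot(rng, h, n_features),
            "b_out": np.zeros(n_features),
        }
        self.params_ = p
        self.bn_stats_ = {
            "mean_e": np.zeros(h),
            "var_e": np.ones(h),
            "mean_d": np.zeros(h),
            "var_d": np.ones(h),
        }
        self.n_features_in_ = n_features
        self._rng = rng
        return self

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params_.values()))

    # ---------------------------------------------------------------- forward
    @staticmethod
    def _bn_forward(x, gamma, beta, training, running_mean, running_var, momentum):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            running_mean *= momentum
            running_mean += (1 - momentum) * mean
            running_var *= momentum
            running_var += (1 - momentum) * var
        else:
            mean, var = running_mean, running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (x - mean) * inv_std
        return gamma * x_hat + beta, (x_hat, inv_std)

    @staticmethod
    def _bn_backward(dy, gamma, cache):
        x_hat, inv_std = cache
        n = dy.shape[0]
        dgamma = (dy * x_hat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dxhat = dy * gamma
        dx = (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - x_hat * (dxhat * x_hat).sum(axis=0)
        )
        return dx, dgamma, dbeta

    def _encode(self, X, training: bool):
        p, s = self.params_, self.bn_stats_
        a = X @ p["W_eh"] + p["b_eh"]
        bn, bn_cache = self._bn_forward(
            a, p["g_e"], p["be_e"], training, s["mean_e"], s["var_e"], self.bn_momentum
        )
        h = np.maximum(bn, 0.0)
        mu = h @ p["W_mu"] + p["b_mu"]
        logvar = np.clip(h @ p["W_lv"] + p["b_lv"], -15.0, 15.0)
        return mu, logvar, {"a": a, "bn": bn, "bn_cache": bn_cache, "h": h, "X": X}

    def _decode(self, Z, training: bool):
        p, s = self.params_, self.bn_stats_
        a = Z @ p["W_dh"] + p["b_dh"]
        bn, bn_cache = self._bn_forward(
            a, p["g_d"], p["be_d"], training, s["mean_d"], s["var_d"], self.bn_momentum
        )
        h = np.maximum(bn, 0.0)
        logits = h @ p["W_out"] + p["b_out"]
        x_hat = 1.0 / (1.0 + np.exp(-logits))
        return x_hat, {"a": a, "bn": bn, "bn_cache": bn_cache, "h": h, "Z": Z}

    # --------------------------------------------------------------- gradient
    def _loss_and_grads(self, X, beta: float, eps: np.ndarray):
        """One minibatch: loss terms and gradients w.r.t. every parameter.

        Reconstruction is summed over features and averaged over the batch; KL
        summed over latent dims and averaged over the batch; total = recon +
        beta * KL.
        """
        p = self.params_
        B = X.shape[0]
        mu, logvar, enc = self._encode(X, training=True)
        sigma = np.exp(0.5 * logvar)
        Z_raw = mu + sigma * eps
        Z = np.maximum(Z_raw, 0.0)  # latent representation is rectified before decoding
        x_hat, dec = self._decode(Z, training=True)

        recon = float(np.mean(reconstruction_term(X, x_hat)))
        kl = float(np.mean(kl_term(mu, sigma)))
        loss = recon + beta * kl

        g = {}
        # decoder backward: d recon / d logits = (x_hat - x) / B
        dlogits = (x_hat - X) / B
        g["W_out"] = dec["h"].T @ dlogits
        g["b_out"] = dlogits.sum(axis=0)
        dh = dlogits @ p["W_out"].T
        dbn = dh * (dec["bn"] > 0)
        da, g["g_d"], g["be_d"] = self._bn_backward(dbn, p["g_d"], dec["bn_cache"])
        g["W_dh"] = Z.T @ da
        g["b_dh"] = da.sum(axis=0)
        dZ = (da @ p["W_dh"].T) * (Z_raw > 0)

        # through the reparametrization plus the KL term
        dmu = dZ + beta * mu / B
        dlogvar = dZ * eps * 0.5 * sigma + beta * 0.5 * (sigma**2 - 1.0) / B

        g["W_mu"] = enc["h"].T @ dmu
        g["b_mu"] = dmu.sum(axis=0)
        g["W_lv"] = enc["h"].T @ dlogvar
        g["b_lv"] = dlogvar.sum(axis=0)
        dh_e = dmu @ p["W_mu"].T + dlogvar @ p["W_lv"].T
        dbn_e = dh_e * (enc["bn"] > 0)
        da_e, g["g_e"], g["be_e"] = self._bn_backward(dbn_e, p["g_e"], enc["bn_cache"])
        g["W_eh"] = X.T @ da_e
        g["b_eh"] = da_e.sum(axis=0)
        return loss, recon, kl, g

    # --------------------------------------------------------------- training
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x features")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("inputs must be scaled to [0,1]; see movae.io.scale_stack")
        n_samples, n_features = X.shape
        self.build(n_features)
        cfg = self._config()
        batch = cfg.batch_size
        if batch > n_samples:
            warnings.warn(
                f"batch_size {batch} > n_samples {n_samples}; shrinking to {n_samples}"
            )
            batch = n_samples

        adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        b1, b2, eps_adam, t = 0.9, 0.999, 1e-8, 0

        history = []
        rng = self._rng
        for epoch in range(cfg.epochs):
            beta = warmup_beta(epoch, cfg.kappa)
            order = rng.permutation(n_samples)
            ep_loss = ep_recon = ep_kl = 0.0
            n_batches = 0
            for start in range(0, n_samples, batch):
                idx = order[start : start + batch]
                xb = X[idx]
                eps = rng.standard_normal((len(idx), cfg.n_latent))
                loss, recon, kl, grads = self._loss_and_grads(xb, beta, eps)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; try a lower learning "
                        f"rate than {cfg.learning_rate}"
                    )
                t += 1
                corr = np.sqrt(1 - b2**t) / (1 - b1**t)
                for k_, gk in grads.items():
                    adam_m[k_] = b1 * adam_m[k_] + (1 - b1) * gk
                    adam_v[k_] = b2 * adam_v[k_] + (1 - b2) * gk**2
                    self.params_[k_] -= (
                        cfg.learning_rate * corr * adam_m[k_] / (np.sqrt(adam_v[k_]) + eps_adam)
                    )
                ep_loss += loss
                ep_recon += recon
                ep_kl += kl
                n_batches += 1
            history.append(
                {
                    "epoch": epoch,
                    "loss": ep_loss / n_batches,
                    "reconstruction": ep_recon / n_batches,
                    "kl": ep_kl / n_batches,
                    "beta": beta,
                }
            )
        self.history_ = pd.DataFrame(history)
        return self

    def transform(self, X) -> np.ndarray:
        """Deterministic inference: ReLU(mu(x)) with batch-norm in eval mode."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was trained on {self.n_features_in_}"
            )
        mu, _, _ = self._encode(X, training=False)
        return np.maximum(mu, 0.0)

    def reconstruct(self, X) -> np.ndarray:
        """Decoder output for the deterministic latent code (eval mode)."""
        Z = self.transform(X)
        x_hat, _ = self._decode(Z, training=False)
        return x_hat


# ------------------------------------------------------------- module facade


def build_model(n_features: int, config: VAEConfig | None = None) -> MultiOmicsVAE:
    config = config or VAEConfig()
    return MultiOmicsVAE(**asdict(config)).build(n_features)


def train(stack: OmicsStack, config: VAEConfig | None = None):
    """Train on a [0,1]-scaled stack; returns (model, history DataFrame).

    The model keeps the training feature ordering so later ``transform`` calls
    can verify feature compatibility.
    """
    config = config or VAEConfig()
    model = MultiOmicsVAE(**asdict(config))
    model.fit(stack.values.T)
    model.feature_ids_ = stack.feature_ids
    model.modality_of_row_ = stack.modality_of_row
    return model, model.history_


def transform(
    model: MultiOmicsVAE,
    X_new: OmicsStack,
    scaling: list[ScalingModel] | None = None,
) -> LatentSpace:
    """Map (optionally unscaled) new samples into the latent space.

    If ``scaling`` is given (one frozen ScalingModel per stacked matrix, as
    returned by :func:`movae.io.scale_stack` on the training data), it is
    applied first so new samples are normalized exactly like the training set.
    """
    if hasattr(model, "feature_ids_") and X_new.feature_ids != model.feature_ids_:
        extra = sorted(set(X_new.feature_ids) - set(model.feature_ids_))[:5]
        missing = sorted(set(model.feature_ids_) - set(X_new.feature_ids))[:5]
        raise ValueError(
            f"feature mismatch with training data (unseen: {extra}, missing: {missing})"
        )
    if scaling is not None:
        mats = [m.apply(x) for m, x in zip(scaling, X_new.matrices)]
        X_new = OmicsStack(mats)
    Z = model.transform(X_new.values.T)
    return LatentSpace(Z, list(X_new.sample_ids))


# ----------------------------------------------------------------- persistence


def save_model(model: MultiOmicsVAE, directory) -> None:
    """Checkpoint weights, batch-norm statistics, config and feature order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"p__{k}": v for k, v in model.params_.items()}
    arrays.update({f"s__{k}": v for k, v in model.bn_stats_.items()})
    np.savez(directory / "weights.npz", **arrays)
    meta = {
        "schema": 1,
        "config": model.get_params(),
        "n_features": int(model.n_features_in_),
        "feature_ids": getattr(model, "feature_ids_", None),
        "modality_of_row": getattr(model, "modality_of_row_", None),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> MultiOmicsVAE:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    model = MultiOmicsVAE(**meta["config"])
    model.build(meta["n_features"])
    with np.load(directory / "weights.npz") as data:
        model.params_ = {k[3:]: data[k] for k in data.files if k.startswith("p__")}
        model.bn_stats_ = {k[3:]: data[k] for k in data.files if k.startswith("s__")}
    if meta.get("feature_ids"):
        model.feature_ids_ = meta["feature_ids"]
        model.modality_of_row_ = meta.get("modality_of_row")
    return model
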