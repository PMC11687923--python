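"""Feature extractors for volumetric scans and their PCA reduction.

Two extractors are provided, mirroring the two arms of the study design:

* a multi-task conditional variational autoencoder (:func:`train_cvae`)
  whose latent mean is the per-sample representation. The loss is
  ``1 * reconstruction-MSE + 1e-4 * KLD + 1e-2 * prediction-MSE`` with the
  decoder and the dementia-score prediction head conditioned on
  standardized age and sex, so the encoder is pushed to produce latents
  invariant to those covariates;
* a slice-averaging wrapper (:func:`slice_average_encode`) that applies any
  user-supplied 2D feature function to every axial slice and averages the
  resulting vectors — the hook through which a pretrained 2D encoder can be
  plugged in. A seeded random linear projection is the shipped default.

The network is a fully-connected encoder/decoder/head trained with Adam and
explicit backpropagation on NumPy arrays; with a fixed seed training is
bit-reproducible on one machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .types import CovariateTable, LatentMatrix, ValidationError, VolumeStack

__all__ = [
    "CVAEConfig",
    "CVAE",
    "PCModel",
    "train_cvae",
    "encode_volumes",
    "slice_average_encode",
    "random_projection_features",
    "fit_pca",
]


@dataclass
class CVAEConfig:
    """Hyperparameters of the conditional multi-task VAE.

    Loss weights follow the reference configuration (reconstruction 1,
    KLD 1e-4, prediction 1e-2). The latent dimension and epoch budget are
    desk-scale defaults; the KLD is summed over latent dimensions and the
    reconstruction error averaged over voxels, both averaged over the batch.
    """

    latent_dim: int = 16
    lambda_recon: float = 1.0
    lambda_kld: float = 1e-4
    lambda_pred: float = 1e-2
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0
    conditioning: tuple[str, ...] = ("age", "sex")
    hidden: int = 64
    head_hidden: int = 16

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be >= 1")
        for name in ("lambda_recon", "lambda_kld", "lambda_pred"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        self.conditioning = tuple(self.conditioning)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
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
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)


class CVAE:
    """Trained conditional multi-task VAE (encoder / decoder / head)."""

    def __init__(self, config: CVAEConfig, n_voxels: int, volume_shape, n_cond: int):
        self.config = config
        self.n_voxels = int(n_voxels)
        self.volume_shape = tuple(volume_shape)
        self.n_cond = int(n_cond)
        H, L, Hp = config.hidden, config.latent_dim, config.head_hidden
        rng = np.random.default_rng(config.seed)

        def glorot(fan_in, fan_out):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(0.0, s, size=(fan_in, fan_out))

        V, C = self.n_voxels, self.n_cond
        self.params: dict[str, np.ndarray] = {
            "W1": glorot(V, H), "b1": np.zeros(H),
            "W2m": glorot(H, L), "b2m": np.zeros(L),
            "W2v": glorot(H, L) * 0.1, "b2v": np.zeros(L),
            "W3": glorot(L + C, H), "b3": np.zeros(H),
            "W4": glorot(H, V), "b4": np.zeros(V),
            "W5": glorot(L + C, Hp), "b5": np.zeros(Hp),
            "W6": glorot(Hp, 1), "b6": np.zeros(1),
        }
        # input / conditioning / target scalers, set by train_cvae
        self.x_center = 0.0
        self.x_scale = 1.0
        self.cond_center = np.zeros(C)
        self.cond_scale = np.ones(C)
        self.y_center = 0.0
        self.y_scale = 1.0
        self.history: list[dict] = []

    # -- forward pieces ----------------------------------------------------
    def _encode_std(self, xs: np.ndarray):
        p = self.params
        pre1 = xs @ p["W1"] + p["b1"]
        h1 = np.maximum(pre1, 0.0)
        mu = h1 @ p["W2m"] + p["b2m"]
        logvar = np.clip(h1 @ p["W2v"] + p["b2v"], -10.0, 10.0)
        return pre1, h1, mu, logvar

    def _decode_std(self, z: np.ndarray, cond: np.ndarray):
        p = self.params
        din = np.concatenate([z, cond], axis=1)
        pre3 = din @ p["W3"] + p["b3"]
        h3 = np.maximum(pre3, 0.0)
        xhat = h3 @ p["W4"] + p["b4"]
        return din, pre3, h3, xhat

    def _head_std(self, z: np.ndarray, cond: np.ndarray):
        p = self.params
        pin = np.concatenate([z, cond], axis=1)
        pre5 = pin @ p["W5"] + p["b5"]
        h5 = np.maximum(pre5, 0.0)
        yhat = (h5 @ p["W6"] + p["b6"]).ravel()
        return pin, pre5, h5, yhat

    # -- public inference --------------------------------------------------
    def _standardize_x(self, volumes: VolumeStack) -> np.ndarray:
        if volumes.shape != self.volume_shape:
            raise ValidationError(
                f"volume shape {volumes.shape} differs from training shape {self.volume_shape}"
            )
        x = volumes.volumes.reshape(volumes.n_samples, -1).astype(float)
        if not np.isfinite(x).all():
            raise ValidationError("volumes contain non-finite intensities")
        return (x - self.x_center) / self.x_scale

    def _standardize_cond(self, cond_raw: np.ndarray) -> np.ndarray:
        return (cond_raw - self.cond_center) / self.cond_scale

    def encode_mu(self, volumes: VolumeStack) -> np.ndarray:
        """Deterministic latent means (no sampling)."""
        return self._encode_std(self._standardize_x(volumes))[2]

    def predict(self, volumes: VolumeStack, cond_raw: np.ndarray) -> np.ndarray:
        mu = self.encode_mu(volumes)
        yhat = self._head_std(mu, self._standardize_cond(cond_raw))[3]
        return yhat * self.y_scale + self.y_center

    def eval_losses(self, xs: np.ndarray, cond: np.ndarray, ys: np.ndarray) -> dict:
        """Deterministic (z = mu) loss components on standardized data."""
        _, h1, mu, logvar = self._encode_std(xs)
        _, _, _, xhat = self._decode_std(mu, cond)
        _, _, _, yhat = self._head_std(mu, cond)
        recon = float(np.mean((xhat - xs) ** 2))
        kld = float(np.mean(-0.5 * np.sum(1 + logvar - mu**2 - np.exp(logvar), axis=1)))
        pred = float(np.mean((yhat - ys) ** 2))
        cfg = self.config
        total = cfg.lambda_recon * recon + cfg.lambda_kld * kld + cfg.lambda_pred * pred
        return {"loss": total, "recon": recon, "kld": kld, "pred": pred}

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": {**self.config.__dict__, "conditioning": list(self.config.conditioning)},
            "volume_shape": list(self.volume_shape),
            "n_cond": self.n_cond,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            x_center=self.x_center, x_scale=self.x_scale,
            cond_center=self.cond_center, cond_scale=self.cond_scale,
            y_center=self.y_center, y_scale=self.y_scale,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "CVAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["conditioning"] = tuple(cfg_d["conditioning"])
            config = CVAEConfig(**cfg_d)
            shape = tuple(meta["volume_shape"])
            model = cls(config, int(np.prod(shape)), shape, int(meta["n_cond"]))
            for k in model.params:
                model.params[k] = data[k]
            model.x_center = float(data["x_center"])
            model.x_scale = float(data["x_scale"])
            model.cond_center = data["cond_center"]
            model.cond_scale = data["cond_scale"]
            model.y_center = float(data["y_center"])
            model.y_scale = float(data["y_scale"])
        return model


def _conditioning_matrix(covariates: CovariateTable, names: Sequence[str]) -> np.ndarray:
    cols = []
    for name in names:
        if name not in covariates.table.columns:
            raise ValidationError(f"conditioning covariate {name!r} not in covariate table")
        cols.append(covariates.table[name].to_numpy(float))
    if not cols:
        return np.empty((len(covariates.table), 0))
    return np.column_stack(cols)


def train_cvae(
    volumes: VolumeStack,
    covariates: CovariateTable,
    dementia_score: np.ndarray,
    config: CVAEConfig | None = None,
) -> CVAE:
    """Train the conditional multi-task VAE.

    Minimizes ``l_recon * MSE(xhat, x) + l_kld * KLD(q(z|x) || N(0, I)) +
    l_pred * MSE(yhat, y)`` where the decoder and prediction head receive
    the sampled latent concatenated with the standardized conditioning
    covariates. Training uses reparameterized sampling; inference uses the
    latent mean. ``model.history`` records deterministic loss components
    before training (epoch 0) and after each epoch.
    """
    config = config or CVAEConfig()
    n = volumes.n_samples
    if n < 2:
        raise ValidationError("need at least 2 samples to train")
    y = np.asarray(dementia_score, float)
    if len(y) != n:
        raise ValidationError("dementia score length differs from volume count")
    if not np.isfinite(volumes.volumes).all() or not np.isfinite(y).all():
        raise ValidationError("non-finite training inputs")

    cond_raw = _conditioning_matrix(covariates, config.conditioning)
    model = CVAE(config, int(np.prod(volumes.shape)), volumes.shape, cond_raw.shape[1])

    x = volumes.volumes.reshape(n, -1).astype(float)
    model.x_center = float(x.mean())
    model.x_scale = float(x.std()) or 1.0
    xs = (x - model.x_center) / model.x_scale
    if cond_raw.size:
        model.cond_center = cond_raw.mean(axis=0)
        model.cond_scale = np.where(cond_raw.std(axis=0) == 0, 1.0, cond_raw.std(axis=0))
    cond = model._standardize_cond(cond_raw) if cond_raw.size else cond_raw
    model.y_center = float(y.mean())
    model.y_scale = float(y.std()) or 1.0
    ys = (y - model.y_center) / model.y_scale

    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.params, config.lr)
    p = model.params
    L = config.latent_dim
    cfg = config
    model.history.append({"epoch": 0, **model.eval_losses(xs, cond, ys)})

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, cb, yb = xs[idx], cond[idx], ys[idx]
            B, V = xb.shape

            pre1 = xb @ p["W1"] + p["b1"]
            h1 = np.maximum(pre1, 0.0)
            mu = h1 @ p["W2m"] + p["b2m"]
            logvar = np.clip(h1 @ p["W2v"] + p["b2v"], -10.0, 10.0)
            eps = rng.standard_normal(mu.shape)
            sig = np.exp(0.5 * logvar)
            z = mu + eps * sig

            din = np.concatenate([z, cb], axis=1)
            pre3 = din @ p["W3"] + p["b3"]
            h3 = np.maximum(pre3, 0.0)
            xhat = h3 @ p["W4"] + p["b4"]

            pin = np.concatenate([z, cb], axis=1)
            pre5 = pin @ p["W5"] + p["b5"]
            h5 = np.maximum(pre5, 0.0)
            yhat = (h5 @ p["W6"] + p["b6"]).ravel()

            # gradients
            g_xhat = 2.0 * cfg.lambda_recon * (xhat - xb) / (B * V)
            g_W4 = h3.T @ g_xhat
            g_b4 = g_xhat.sum(axis=0)
            g_h3 = g_xhat @ p["W4"].T
            g_pre3 = g_h3 * (pre3 > 0)
            g_W3 = din.T @ g_pre3
            g_b3 = g_pre3.sum(axis=0)
            g_din = g_pre3 @ p["W3"].T

            g_yhat = (2.0 * cfg.lambda_pred * (yhat - yb) / B)[:, None]
            g_W6 = h5.T @ g_yhat
            g_b6 = g_yhat.sum(axis=0)
            g_h5 = g_yhat @ p["W6"].T
            g_pre5 = g_h5 * (pre5 > 0)
            g_W5 = pin.T @ g_pre5
            g_b5 = g_pre5.sum(axis=0)
            g_pin = g_pre5 @ p["W5"].T

            g_z = g_din[:, :L] + g_pin[:, :L]
            g_mu = g_z + cfg.lambda_kld * mu / B
            g_logvar = g_z * eps * 0.5 * sig + cfg.lambda_kld * 0.5 * (np.exp(logvar) - 1.0) / B

            g_W2m = h1.T @ g_mu
            g_b2m = g_mu.sum(axis=0)
            g_W2v = h1.T @ g_logvar
            g_b2v = g_logvar.sum(axis=0)
            g_h1 = g_mu @ p["W2m"].T + g_logvar @ p["W2v"].T
            g_pre1 = g_h1 * (pre1 > 0)
            g_W1 = xb.T @ g_pre1
            g_b1 = g_pre1.sum(axis=0)

            opt.step(
                p,
                {
                    "W1": g_W1, "b1": g_b1, "W2m": g_W2m, "b2m": g_b2m,
                    "W2v": g_W2v, "b2v": g_b2v, "W3": g_W3, "b3": g_b3,
                    "W4": g_W4, "b4": g_b4, "W5": g_W5, "b5": g_b5,
                    "W6": g_W6, "b6": g_b6,
                },
            )
        model.history.append({"epoch": epoch, **model.eval_losses(xs, cond, ys)})
    return model


def encode_volumes(model: CVAE, volumes: VolumeStack) -> LatentMatrix:
    """Latent means for every sample (deterministic, order-equivariant)."""
    mu = model.encode_mu(volumes)
    ids = volumes.sample_ids or [f"S{i + 1:05d}" for i in range(volumes.n_samples)]
    return LatentMatrix(sample_ids=list(ids), features=mu, extractor="cvae")


def slice_average_encode(
    volumes: VolumeStack,
    feature_fn: Callable[[np.ndarray], np.ndarray],
    axis: int = 0,
) -> LatentMatrix:
    """Apply a 2D feature function slice-wise and average along one axis.

    Row i of the output is the arithmetic mean over slices (along ``axis``,
    axial by default) of ``feature_fn(slice)``. The feature function must
    return a fixed-length 1D vector for every slice.
    """
    feats = []
    d = None
    for i in range(volumes.n_samples):
        vol = np.moveaxis(volumes.volumes[i], axis, 0)
        acc = None
        for s in range(vol.shape[0]):
            f = np.asarray(feature_fn(vol[s]), float).ravel()
            if d is None:
                d = f.size
            elif f.size != d:
                raise ValidationError(
                    f"feature_fn returned length {f.size}, expected {d}"
                )
            acc = f if acc is None else acc + f
        feats.append(acc / vol.shape[0])
    ids = volumes.sample_ids or [f"S{i + 1:05d}" for i in range(volumes.n_samples)]
    return LatentMatrix(sample_ids=list(ids), features=np.vstack(feats), extractor="slice2d")


def random_projection_features(out_dim: int, seed: int = 0) -> Callable[[np.ndarray], np.ndarray]:
    """Seeded random linear projection as a stand-in 2D feature function.

    The projection matrix is drawn once (lazily, from the slice shape of
    the first call) and reused, so the function is deterministic across
    slices and volumes. Serves as the default test double for a pretrained
    2D encoder supplied by the user.
    """
    state: dict = {}

    def fn(slice2d: np.ndarray) -> np.ndarray:
        flat = np.asarray(slice2d, float).ravel()
        if "W" not in state:
            rng = np.random.default_rng(seed)
            state["W"] = rng.standard_normal((out_dim, flat.size)) / np.sqrt(flat.size)
        elif state["W"].shape[1] != flat.size:
            raise ValidationError("slice shape changed between calls")
        return state["W"] @ flat

    return fn


@dataclass
class PCModel:
    """PCA reduction of a latent matrix: centering only, no rescaling."""

    loadings: np.ndarray                 # (d, k), orthonormal columns
    center: np.ndarray                   # (d,)
    explained_variance_ratio: np.ndarray # (k,), non-increasing

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, float) - self.center) @ self.loadings

    def save(self, path) -> None:
        np.savez(path, loadings=self.loadings, center=self.center,
                 explained_variance_ratio=self.explained_variance_ratio)

    @classmethod
    def load(cls, path) -> "PCModel":
        with np.load(path) as d:
            return cls(d["loadings"], d["center"], d["explained_variance_ratio"])


def fit_pca(latents: LatentMatrix | np.ndarray, k: int) -> tuple[PCModel, np.ndarray]:
    """Principal components of the feature matrix (centering only).

    Features are centered by the stored mean but not variance-scaled, so
    the explained-variance ratios refer to the raw feature variances.
    Component signs are fixed deterministically (the largest-magnitude
    loading of each component is positive). Returns the model and the
    n x k score matrix.
    """
    X = latents.features if isinstance(latents, LatentMatrix) else np.asarray(latents, float)
    n, d = X.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k must lie in [1, min(n-1, d)] = [1, {min(n - 1, d)}]")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    # deterministic sign convention
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    model = PCModel(
        loadings=loadings,
        center=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )
    return model, scores
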