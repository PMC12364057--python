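"""Variational autoencoders for stimuli (sVAE) and neural activity (nVAE).

Both embed high-dimensional observations into a 2-D latent space with a
Gaussian encoder (mu, log sigma^2) and a deterministic decoder whose output
is squashed through a logistic so reconstructions stay in [0, 1]. The loss
is squared-error reconstruction plus ``alpha`` times the closed-form KL
divergence of the encoder posterior from a standard normal; the KL term
encourages nearby latent points to decode to similar observations, which is
what makes the latent space usable as a control-input space.

This module also turns latent embeddings into control-ready input
sequences: k-means cluster centers of the embedded data, connected by a
step function (each center held 500 steps) or by fast (200-step) / slow
(1000-step) linear interpolation between consecutive centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.cluster import KMeans

from . import _autodiff as ad
from ._autodiff import MLP, Tensor

__all__ = [
    "VaeModel", "VaeConfig", "LatentInputPlan", "vae_loss", "fit_vae",
    "extract_centers", "build_latent_input_sequence", "decode_stimulus",
    "save_vae", "load_vae",
]

SEGMENT_DURATIONS = {"step": 500, "fast": 200, "slow": 1000}


class VaeModel:
    """Gaussian-encoder VAE with logistic-output decoder.

    The encoder maps an input vector to (mu, log sigma^2), each of dimension
    ``k`` (default 2); the decoder maps a k-vector back to input space.
    """

    def __init__(self, input_dim: int, k: int = 2, hidden: tuple[int, ...] = (128,),
                 alpha: float = 1.0, seed: int = 0):
        self.input_dim = input_dim
        self.k = k
        self.hidden = tuple(hidden)
        self.alpha = alpha
        rng = np.random.default_rng(seed)
        self.encoder = MLP([input_dim, *hidden, 2 * k], rng)
        self.decoder = MLP([k, *reversed(hidden), input_dim], rng,
                           out_activation="sigmoid")

    # -- numpy inference paths ----------------------------------------
    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = self.encoder.forward_np(np.atleast_2d(np.asarray(x, dtype=np.float64)))
        mu, logvar = out[:, :self.k], out[:, self.k:]
        if np.asarray(x).ndim == 1:
            return mu[0], logvar[0]
        return mu, logvar

    def encode_mean(self, x: np.ndarray) -> np.ndarray:
        return self.encode(x)[0]

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Deterministic decode (no sampling; used at control time)."""
        out = self.decoder.forward_np(np.atleast_2d(np.asarray(z, dtype=np.float64)))
        return out[0] if np.asarray(z).ndim == 1 else out

    # -- training utilities -------------------------------------------
    @property
    def params(self) -> list[Tensor]:
        return self.encoder.params + self.decoder.params

    def get_weights(self) -> list[np.ndarray]:
        return self.encoder.get_weights() + self.decoder.get_weights()

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n_enc = len(self.encoder.params)
        self.encoder.set_weights(weights[:n_enc])
        self.decoder.set_weights(weights[n_enc:])


def _vae_loss_t(batch: np.ndarray, model: VaeModel,
                eps: np.ndarray | None) -> tuple[Tensor, Tensor, Tensor]:
    """(total, reconstruction, KL) as autodiff Tensors."""
    x = Tensor(batch)
    enc = model.encoder(x)
    k = model.k
    mu = enc @ np.vstack([np.eye(k), np.zeros((k, k))])
    logvar = enc @ np.vstack([np.zeros((k, k)), np.eye(k)])
    if eps is None:
        z = mu
    else:
        z = mu + ad.exp(logvar * 0.5) * eps
    recon = ((x - model.decoder(z)) ** 2.0).sum()
    kl = (1.0 + logvar - mu ** 2.0 - ad.exp(logvar)).sum() * -0.5
    total = recon + model.alpha * kl
    return total, recon, kl


def vae_loss(batch: np.ndarray, model: VaeModel,
             eps: np.ndarray | None = None) -> tuple[float, float, float]:
    """Evaluate (total, reconstruction, KL) on a batch.

    ``eps`` supplies standard-normal latent draws for the reparameterized
    sample used in decoding; with ``eps=None`` the encoder mean is decoded.
    Reconstruction is the summed squared error over the batch; KL is the
    closed-form Gaussian divergence -1/2 sum(1 + log s^2 - mu^2 - s^2);
    total = reconstruction + alpha * KL.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    total, recon, kl = _vae_loss_t(batch, model, eps)
    return float(total.data), float(recon.data), float(kl.data)


@dataclass
class VaeConfig:
    k: int = 2
    hidden: tuple[int, ...] = (128,)
    alpha: float = 1.0
    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 5              # early stopping on validation loss
    lr_decay: float | None = None  # per-epoch multiplicative decay (0.99 for the nVAE path)
    seed: int = 0


def fit_vae(train: np.ndarray, val: np.ndarray, config: VaeConfig,
            model: VaeModel | None = None) -> VaeModel:
    """Fit a VAE by minibatch adaptive-moment descent on the VAE loss.

    Stops early when validation total loss has not improved for
    ``config.patience`` consecutive epochs; with ``lr_decay`` set, the
    learning rate at epoch e is lr * decay**e. Passing ``model`` continues
    training from existing weights (used for nVAE pretraining handoff).
    """
    train = np.atleast_2d(np.asarray(train, dtype=np.float64))
    val = np.atleast_2d(np.asarray(val, dtype=np.float64))
    if train.shape[0] == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = VaeModel(train.shape[1], k=config.k, hidden=config.hidden,
                         alpha=config.alpha, seed=config.seed)
    opt = ad.Adam(model.params, lr=config.lr)
    best_loss, best_w, stale = np.inf, model.get_weights(), 0
    for epoch in range(config.epochs):
        if config.lr_decay is not None:
            opt.lr = config.lr * config.lr_decay ** epoch
        order = rng.permutation(train.shape[0])
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            eps = rng.standard_normal((len(idx), model.k))
            total, _, _ = _vae_loss_t(train[idx], model, eps)
            opt.zero_grad()
            (total * (1.0 / len(idx))).backward()
            opt.step()
        val_loss = vae_loss(val, model)[0] if val.shape[0] else np.inf
        if val_loss < best_loss:
            best_loss, best_w, stale = val_loss, model.get_weights(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.set_weights(best_w)
    return model


def extract_centers(points: np.ndarray, n_clusters: int, seed: int = 0,
                    split: bool = True):
    """k-means centers of latent points, optionally split into equal thirds.

    With ``split=True`` (the identification protocol: 120 centers split
    40/40/40) the centers are shuffled deterministically and partitioned
    into train/validation/test sets of equal size.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] < n_clusters:
        raise ValueError("need at least n_clusters points")
    if split and n_clusters % 3 != 0:
        raise ValueError("n_clusters must be divisible by 3 when splitting")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    km.fit(points)
    centers = km.cluster_centers_
    if not split:
        return centers
    rng = np.random.default_rng(seed)
    centers = centers[rng.permutation(n_clusters)]
    third = n_clusters // 3
    return centers[:third], centers[third:2 * third], centers[2 * third:]


@dataclass
class LatentInputPlan:
    """Ordered latent centers plus the scheme converting them to a sequence."""

    centers: np.ndarray
    method: str = "step"   # step | fast | slow
    durations: dict = field(default_factory=lambda: dict(SEGMENT_DURATIONS))

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        if self.method not in SEGMENT_DURATIONS:
            raise ValueError(f"method must be one of {sorted(SEGMENT_DURATIONS)}")
        if any(d <= 0 for d in self.durations.values()):
            raise ValueError("durations must be positive")


def build_latent_input_sequence(plan: LatentInputPlan) -> np.ndarray:
    """Discrete 1-ms latent input sequence from a center plan.

    step: each center held for its duration (default 500 steps).
    fast/slow: consecutive centers joined by linear interpolation over the
    per-segment duration (defaults 200/1000 steps); sample j of a segment
    equals c_i + (j/dur) * (c_{i+1} - c_i), so the next center is reached at
    the first sample of the following segment.
    """
    centers = plan.centers
    dur = int(plan.durations[plan.method])
    if plan.method == "step":
        if len(centers) < 1:
            raise ValueError("need at least one center")
        return np.repeat(centers, dur, axis=0)
    if len(centers) < 2:
        raise ValueError("interpolation methods need at least two centers")
    frac = (np.arange(dur) / dur)[:, None]
    segments = [c0 + frac * (c1 - c0) for c0, c1 in zip(centers[:-1], centers[1:])]
    return np.concatenate(segments, axis=0)


def decode_stimulus(v: np.ndarray, svae: VaeModel) -> np.ndarray:
    """Deterministically decode a latent input point to a stimulus image
    vector (pixels in [0, 1]; no sampling at control time)."""
    return svae.decode(np.asarray(v, dtype=np.float64))


def save_vae(model: VaeModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["input_dim"] = model.input_dim
        f.attrs["k"] = model.k
        f.attrs["alpha"] = model.alpha
        f.attrs["hidden"] = list(model.hidden)
        for name, net in (("encoder", model.encoder), ("decoder", model.decoder)):
            g = f.create_group(name)
            for i, w in enumerate(net.get_weights()):
                g.create_dataset(f"p{i:03d}", data=w)


def load_vae(path) -> VaeModel:
    with h5py.File(path, "r") as f:
        model = VaeModel(int(f.attrs["input_dim"]), k=int(f.attrs["k"]),
                         hidden=tuple(int(h) for h in f.attrs["hidden"]),
                         alpha=float(f.attrs["alpha"]))
        for name, net in (("encoder", model.encoder), ("decoder", model.decoder)):
            g = f[name]
            net.set_weights([g[key][...] for key in sorted(g)])
    return model
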