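"""Surrogate-gradient training of the rLIF circuit on image classification.

The spike nonlinearity is a Heaviside step in the forward pass and the
derivative of a scaled logistic in the backward pass, which makes the
network trainable with backpropagation through time (BPTT). Each stimulus
is presented for ``T`` consecutive 1-ms steps; the per-step softmax
cross-entropy over the ten output-neuron membrane voltages is summed over
the presentation window, which pushes the output neuron of the correct
class toward the highest firing rate. Prediction is the argmax of the
summed output voltages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from .snn_circuit import LAYER_NAMES, CircuitParams

__all__ = ["TrainConfig", "surrogate_spike", "classification_loss",
           "train_circuit", "predict_labels", "evaluate_accuracy"]


@dataclass
class TrainConfig:
    T: int = 25                   # presentation length, steps per stimulus
    batch_size: int = 32
    lr: float = 1e-3
    max_epochs: int = 30
    patience: int = 5             # early stopping on validation accuracy
    surrogate_slope: float = 10.0
    eval_repeats: int = 5         # noise repeats when assessing accuracy
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def surrogate_spike(v_minus_theta, slope: float = 10.0) -> Tensor:
    """Heaviside spike with a logistic-derivative surrogate gradient.

    Forward: 1 where v - theta >= 0 else 0. Backward: slope * s * (1 - s)
    with s = sigma(slope * (v - theta)); equals slope/4 at threshold.
    """
    if not isinstance(v_minus_theta, Tensor):
        v_minus_theta = Tensor(v_minus_theta)
    if not np.isfinite(v_minus_theta.data).all():
        raise ValueError("non-finite input to surrogate spike")
    return ad.spike_surrogate(v_minus_theta, slope=slope)


def classification_loss(output_voltages: np.ndarray, label: int) -> float:
    """Summed per-step softmax cross-entropy of output voltages vs label.

    ``output_voltages`` has shape (T, 10); per step the softmax over the ten
    output-neuron voltages is compared against the one-hot label and the
    losses are summed over all T steps.
    """
    V = np.atleast_2d(np.asarray(output_voltages, dtype=np.float64))
    if not np.isfinite(V).all():
        raise FloatingPointError("non-finite output voltages")
    if not 0 <= int(label) < V.shape[1]:
        raise ValueError("label out of range")
    Vs = V - V.max(axis=1, keepdims=True)
    log_p = Vs - np.log(np.exp(Vs).sum(axis=1, keepdims=True))
    return float(-log_p[:, int(label)].sum())


# ---------------------------------------------------------------------
# numpy (inference) and autodiff (training) forward passes
# ---------------------------------------------------------------------

def _forward_np(images: np.ndarray, params: CircuitParams, T: int,
                rng: np.random.Generator | None) -> np.ndarray:
    """Summed output voltages (B, n_out) for a batch of flattened images."""
    B = images.shape[0]
    V = {n: np.zeros((B, lp.size)) for n, lp in params.layers.items()}
    S = {n: np.zeros((B, lp.size)) for n, lp in params.layers.items()}
    out_sum = np.zeros((B, params.layers["output"].size))
    for _ in range(T):
        upstream = images
        for name in LAYER_NAMES:
            lp = params.layers[name]
            x = upstream
            if rng is not None and lp.eta > 0:
                x = x + rng.normal(0.0, lp.eta, size=x.shape)
            v = lp.beta * V[name] + x @ lp.w + S[name] @ lp.r
            s = (v >= lp.theta).astype(np.float64)
            V[name] = np.maximum(np.where(s > 0, 0.0, v), params.v_floor)
            S[name] = s
            upstream = s
        # voltage *before* reset carries the class evidence summed below
        out_sum += v
    return out_sum


def predict_labels(images: np.ndarray, params: CircuitParams, T: int = 25,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Highest-summed-voltage (equivalently highest-rate) output neuron."""
    flat = images.reshape(images.shape[0], -1)
    return np.argmax(_forward_np(flat, params, T, rng), axis=1)


def evaluate_accuracy(images: np.ndarray, labels: np.ndarray,
                      params: CircuitParams, T: int = 25, repeats: int = 5,
                      seed: int = 0) -> float:
    """Mean accuracy over ``repeats`` independent noise draws."""
    rng = np.random.default_rng(seed)
    accs = [np.mean(predict_labels(images, params, T, rng) == labels)
            for _ in range(repeats)]
    return float(np.mean(accs))


class _TrainableCircuit:
    """Tensor-typed view of the circuit weights for BPTT."""

    def __init__(self, params: CircuitParams):
        self.template = params
        self.w = {n: Tensor(lp.w.copy(), requires_grad=True)
                  for n, lp in params.layers.items()}
        self.r = {n: Tensor(lp.r.copy(), requires_grad=True)
                  for n, lp in params.layers.items()}

    @property
    def trainables(self) -> list[Tensor]:
        return [*self.w.values(), *self.r.values()]

    def forward(self, images: np.ndarray, T: int, slope: float,
                rng: np.random.Generator) -> list[Tensor]:
        """Per-step output voltages (pre-reset), each (B, n_out)."""
        p = self.template
        B = images.shape[0]
        V = {n: Tensor(np.zeros((B, lp.size))) for n, lp in p.layers.items()}
        S = {n: Tensor(np.zeros((B, lp.size))) for n, lp in p.layers.items()}
        out_voltages = []
        for _ in range(T):
            upstream: Tensor | np.ndarray = images
            for name in LAYER_NAMES:
                lp = p.layers[name]
                x = upstream if isinstance(upstream, Tensor) else Tensor(upstream)
                if lp.eta > 0:
                    x = x + rng.normal(0.0, lp.eta, size=x.shape)
                v = lp.beta * V[name] + x @ self.w[name] + S[name] @ self.r[name]
                s = ad.spike_surrogate(v - lp.theta, slope=slope)
                V[name] = (v * (1.0 - s)).clamp_min(p.v_floor)
                S[name] = s
                upstream = s
            out_voltages.append(v)   # output-layer pre-reset voltage
        return out_voltages

    def export(self) -> CircuitParams:
        import copy
        params = copy.deepcopy(self.template)
        for n in LAYER_NAMES:
            params.layers[n].w = self.w[n].data.copy()
            params.layers[n].r = self.r[n].data.copy()
        return params

    def snapshot(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.trainables]

    def restore(self, snap: list[np.ndarray]) -> None:
        for t, s in zip(self.trainables, snap):
            t.data = s.copy()


def _batch_ce_loss(out_voltages: list[Tensor], labels: np.ndarray) -> Tensor:
    """Summed-over-steps, mean-over-batch softmax cross-entropy."""
    B = len(labels)
    n_out = out_voltages[0].data.shape[1]
    onehot = np.zeros((B, n_out))
    onehot[np.arange(B), labels] = 1.0
    total = None
    for v in out_voltages:
        shift = v.data.max(axis=1, keepdims=True)      # constant, for stability
        vs = v - shift
        lse = ad.log(ad.exp(vs).sum(axis=1, keepdims=True))
        ce = ((vs - lse) * onehot).sum(axis=1, keepdims=True) * -1.0
        total = ce if total is None else total + ce
    return total.mean()


def train_circuit(dataset: tuple[np.ndarray, np.ndarray], params: CircuitParams,
                  config: TrainConfig) -> tuple[CircuitParams, pd.DataFrame]:
    """Train feedforward and recurrent weights by BPTT on classification.

    ``dataset`` is (images, labels); it is partitioned into train/validation/
    test splits (default 60/20/20). Training minimizes the summed per-step
    cross-entropy with surrogate gradients and adaptive-moment updates, and
    halts early when validation accuracy has not improved for ``patience``
    consecutive epochs. Returns the best-validation weights and a per-epoch
    history (epoch, train_acc, val_acc, loss).
    """
    images, labels = dataset
    if len(images) == 0:
        raise ValueError("empty dataset")
    flat = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(flat))
    n_train = int(config.split[0] * len(flat))
    n_val = int(config.split[1] * len(flat))
    tr, va = perm[:n_train], perm[n_train:n_train + n_val]
    Xtr, ytr, Xva, yva = flat[tr], labels[tr], flat[va], labels[va]

    net = _TrainableCircuit(params)
    opt = ad.Adam(net.trainables, lr=config.lr)
    best_val, best_snap, stale = -np.inf, net.snapshot(), 0
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            out_v = net.forward(Xtr[idx], config.T, config.surrogate_slope, rng)
            loss = _batch_ce_loss(out_v, ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        current = net.export()
        eval_seed = config.seed + 1000 + epoch
        train_acc = evaluate_accuracy(Xtr, ytr, current, config.T,
                                      config.eval_repeats, eval_seed)
        val_acc = evaluate_accuracy(Xva, yva, current, config.T,
                                    config.eval_repeats, eval_seed + 1)
        rows.append({"epoch": epoch, "train_acc": train_acc,
                     "val_acc": val_acc, "loss": float(np.mean(losses))})
        if val_acc > best_val:
            best_val, best_snap, stale = val_acc, net.snapshot(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    net.restore(best_snap)
    return net.export(), pd.DataFrame(rows)
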