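"""Synthetic stimuli and ground-truth latent fixtures.

Two generators make every downstream stage testable without downloads:

* a glyph generator producing 28x28 grayscale images in ten parameterized
  shape classes (bars, rings, crosses, ...) with within-class jitter -- a
  stand-in for a handwritten-digit set that retains clustered,
  low-dimensionally embeddable class structure;
* a linear-Gaussian latent system with Bernoulli spiking emissions, used as
  ground truth when testing latent-dynamics identification and control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "IMAGE_SIZE",
    "N_GLYPH_CLASSES",
    "generate_glyph_dataset",
    "save_glyph_dataset",
    "load_glyph_dataset",
    "LinearSpikingFixture",
    "generate_linear_spiking_sequence",
]

IMAGE_SIZE = 28
N_GLYPH_CLASSES = 10


# ---------------------------------------------------------------------
# Glyph stimuli
# ---------------------------------------------------------------------

def _soft_band(d: np.ndarray, half_width: float, softness: float = 0.7) -> np.ndarray:
    """Smooth indicator of |d| <= half_width (anti-aliased stroke edge)."""
    return 1.0 / (1.0 + np.exp(-(half_width - np.abs(d)) / softness))


def _render_glyph(class_id: int, rotation: float, shift: np.ndarray,
                  stroke: float, intensity: float) -> np.ndarray:
    """Render one glyph. Classes are deterministic geometric primitives:

    0 bar, 1 orthogonal bar, 2/3 diagonal bars, 4 ring, 5 filled disk,
    6 upright cross, 7 diagonal cross, 8 square outline, 9 double bar.
    Rotation/translation/stroke/intensity provide within-class jitter.
    """
    c = (IMAGE_SIZE - 1) / 2.0
    yy, xx = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE].astype(np.float64)
    x = xx - c - shift[0]
    y = yy - c - shift[1]
    ca, sa = np.cos(rotation), np.sin(rotation)
    xr = ca * x + sa * y
    yr = -sa * x + ca * y
    r = np.hypot(xr, yr)
    hw = stroke / 2.0

    if class_id == 0:        # horizontal bar
        img = _soft_band(yr, hw) * _soft_band(xr, 9.0, 1.5)
    elif class_id == 1:      # vertical bar
        img = _soft_band(xr, hw) * _soft_band(yr, 9.0, 1.5)
    elif class_id == 2:      # 45-degree bar
        img = _soft_band((xr - yr) / np.sqrt(2), hw) * _soft_band(r, 10.0, 1.5)
    elif class_id == 3:      # 135-degree bar
        img = _soft_band((xr + yr) / np.sqrt(2), hw) * _soft_band(r, 10.0, 1.5)
    elif class_id == 4:      # ring
        img = _soft_band(r - 7.0, hw)
    elif class_id == 5:      # filled disk
        img = _soft_band(r, 5.5, 1.0)
    elif class_id == 6:      # upright cross
        img = np.maximum(_soft_band(yr, hw) * _soft_band(xr, 8.0, 1.5),
                         _soft_band(xr, hw) * _soft_band(yr, 8.0, 1.5))
    elif class_id == 7:      # diagonal cross
        img = np.maximum(
            _soft_band((xr - yr) / np.sqrt(2), hw) * _soft_band(r, 9.0, 1.5),
            _soft_band((xr + yr) / np.sqrt(2), hw) * _soft_band(r, 9.0, 1.5))
    elif class_id == 8:      # square outline
        d = np.maximum(np.abs(xr), np.abs(yr)) - 7.0
        img = _soft_band(d, hw)
    elif class_id == 9:      # two parallel bars
        img = np.maximum(_soft_band(yr - 5.0, hw), _soft_band(yr + 5.0, hw))
        img = img * _soft_band(xr, 8.0, 1.5)
    else:
        raise ValueError(f"unknown glyph class {class_id}")
    return np.clip(img * intensity, 0.0, 1.0)


def generate_glyph_dataset(n_per_class: int, n_classes: int = N_GLYPH_CLASSES,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Generate a labeled glyph image set.

    Parameters
    ----------
    n_per_class : images per class (>= 1)
    n_classes : number of shape classes to use (<= 10)
    seed : reproducibility seed; identical seeds give bitwise-identical data

    Returns
    -------
    images : (n_per_class * n_classes, 28, 28) float array in [0, 1]
    labels : matching int array of class ids
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 1 <= n_classes <= N_GLYPH_CLASSES:
        raise ValueError(f"n_classes must be in [1, {N_GLYPH_CLASSES}]")
    rng = np.random.default_rng(seed)
    images = np.empty((n_per_class * n_classes, IMAGE_SIZE, IMAGE_SIZE))
    labels = np.empty(n_per_class * n_classes, dtype=np.int64)
    i = 0
    for cls in range(n_classes):
        for _ in range(n_per_class):
            rotation = rng.normal(0.0, 0.12)
            shift = rng.normal(0.0, 1.5, size=2)
            stroke = max(1.0, 3.0 + rng.normal(0.0, 0.4))
            intensity = np.clip(1.0 + rng.normal(0.0, 0.12), 0.3, 1.0)
            images[i] = _render_glyph(cls, rotation, shift, stroke, intensity)
            labels[i] = cls
            i += 1
    return images, labels


def save_glyph_dataset(path, images: np.ndarray, labels: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images.astype(np.float64))
        f.create_dataset("labels", data=labels.astype(np.int64))


def load_glyph_dataset(path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["images"][...], f["labels"][...]


# ---------------------------------------------------------------------
# Linear latent system with spiking emissions
# ---------------------------------------------------------------------

@dataclass
class LinearSpikingFixture:
    """Ground-truth linear latent system with Bernoulli spiking readout.

    Latents evolve as ``z' = A_true z + B_true v + noise``; each of ``n``
    neurons spikes with probability ``sigma(W z + b)`` (logistic squashing of
    a linear readout, keeping spikes binary and rates bounded).

    The default dynamics are slow (eigenvalues 0.95 and 0.92) relative to
    the 0.1 exponential smoothing filter used downstream, and the input gain
    is small (~0.05) so that latent inputs of order one produce latent
    displacements of order one at steady state.
    """

    A_true: np.ndarray
    B_true: np.ndarray
    emission_weights: np.ndarray   # (n_neurons, k)
    emission_bias: np.ndarray      # (n_neurons,)
    noise_scale: float = 0.02

    def __post_init__(self):
        self.A_true = np.atleast_2d(np.asarray(self.A_true, dtype=np.float64))
        self.B_true = np.atleast_2d(np.asarray(self.B_true, dtype=np.float64))
        self.emission_weights = np.asarray(self.emission_weights, dtype=np.float64)
        self.emission_bias = np.asarray(self.emission_bias, dtype=np.float64)
        if self.A_true.shape[0] != self.A_true.shape[1]:
            raise ValueError("A_true must be square")
        if self.B_true.shape[0] != self.k:
            raise ValueError("B_true row count must match latent dimension")
        if self.emission_weights.shape[1] != self.k:
            raise ValueError("emission weights must have k columns")

    @property
    def k(self) -> int:
        return self.A_true.shape[0]

    @property
    def m(self) -> int:
        return self.B_true.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.emission_weights.shape[0]

    def spike_rate(self, z: np.ndarray) -> np.ndarray:
        """Per-neuron Bernoulli rate at latent state(s) z."""
        pre = np.asarray(z) @ self.emission_weights.T + self.emission_bias
        return 1.0 / (1.0 + np.exp(-pre))

    @classmethod
    def default(cls, n_neurons: int = 60, seed: int = 0,
                noise_scale: float = 0.02) -> "LinearSpikingFixture":
        """Default 2-latent, 2-input fixture with ``n_neurons`` neurons."""
        rng = np.random.default_rng(seed)
        A = np.array([[0.95, 0.03], [0.00, 0.92]])
        B = np.array([[0.05, 0.01], [0.00, 0.05]])
        W = rng.normal(0.0, 1.2, size=(n_neurons, 2))
        b = np.full(n_neurons, -1.0)
        return cls(A, B, W, b, noise_scale=noise_scale)

    def to_json(self, path) -> None:
        blob = {
            "A_true": self.A_true.tolist(),
            "B_true": self.B_true.tolist(),
            "emission_weights": self.emission_weights.tolist(),
            "emission_bias": self.emission_bias.tolist(),
            "noise_scale": self.noise_scale,
        }
        with open(path, "w") as f:
            json.dump(blob, f)

    @classmethod
    def from_json(cls, path) -> "LinearSpikingFixture":
        with open(path) as f:
            blob = json.load(f)
        return cls(np.array(blob["A_true"]), np.array(blob["B_true"]),
                   np.array(blob["emission_weights"]),
                   np.array(blob["emission_bias"]), blob["noise_scale"])


def make_excitation_inputs(T: int, m: int = 2, seed: int = 0,
                           scale: float = 1.0) -> np.ndarray:
    """Identification-friendly latent input sequence of length T.

    Mirrors the step / fast-interpolation / slow-interpolation structure of
    the latent input protocol: random centers in [-scale, scale]^m held for
    500 steps, then linearly interpolated center-to-center over 200 and
    1000 steps, concatenated and trimmed to T. The mix perturbs the latent
    system at several timescales, which is what makes A and B identifiable.
    """
    rng = np.random.default_rng(seed)
    chunks = []
    total = 0
    durations = (500, 200, 1000)
    i = 0
    while total < T:
        dur = durations[i % 3]
        c0 = rng.uniform(-scale, scale, size=m)
        c1 = rng.uniform(-scale, scale, size=m)
        if dur == 500:
            seg = np.repeat(c0[None, :], dur, axis=0)
        else:
            frac = (np.arange(dur) / dur)[:, None]
            seg = c0 + frac * (c1 - c0)
        chunks.append(seg)
        total += dur
        i += 1
    return np.concatenate(chunks, axis=0)[:T]


def generate_linear_spiking_sequence(
    fixture: LinearSpikingFixture,
    inputs: np.ndarray,
    T: int,
    seed: int = 0,
    z0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the fixture for T steps under a known input sequence.

    Returns the latent trajectory ``Z`` of shape (T, k) with
    ``z[n+1] = A z[n] + B v[n] + noise`` and a binary spike raster of shape
    (T, n_neurons) with spikes drawn per neuron per step from the logistic
    emission at ``z[n]``.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    if inputs.shape[0] < T:
        raise ValueError(f"need at least T={T} inputs, got {inputs.shape[0]}")
    if inputs.shape[1] != fixture.m:
        raise ValueError("input dimension does not match fixture B_true")
    if np.max(np.abs(np.linalg.eigvals(fixture.A_true))) >= 1.0:
        warnings.warn("fixture A_true is unstable (spectral radius >= 1)")
    rng = np.random.default_rng(seed)
    k, n = fixture.k, fixture.n_neurons
    Z = np.zeros((T, k))
    S = np.zeros((T, n), dtype=np.uint8)
    z = np.zeros(k) if z0 is None else np.asarray(z0, dtype=np.float64).copy()
    for t in range(T):
        Z[t] = z
        S[t] = (rng.random(n) < fixture.spike_rate(z)).astype(np.uint8)
        noise = (fixture.noise_scale * rng.standard_normal(k)
                 if fixture.noise_scale > 0 else 0.0)
        z = fixture.A_true @ z + fixture.B_true @ inputs[t] + noise
    return Z, S
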