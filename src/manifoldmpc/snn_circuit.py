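"""Recurrent leaky integrate-and-fire (rLIF) circuit simulation.

The artificial circuit has three layers -- sensory, reservoir, output --
of discrete-time rLIF neurons. Per layer, the subthreshold update is

    V' = beta * V + w^T (x + eps) + r^T S_prev

where ``x`` is the feedforward drive (the stimulus image for the sensory
layer, the upstream layer's *current-step* spikes otherwise), ``eps`` is
independent Gaussian noise added to every feedforward input element each
step, and ``S_prev`` is the layer's own previous-step spike vector. Any
neuron with V' >= theta emits a spike and its voltage resets to 0 (which
implicitly imposes a 1-ms refractory period at the 1-ms step used here);
voltages are clamped from below at a floor (default -2) after the reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "LayerParams",
    "CircuitParams",
    "CircuitState",
    "SpikeRaster",
    "rlif_step",
    "simulate_circuit",
    "sample_ensemble",
]

LAYER_NAMES = ("sensory", "reservoir", "output")
INPUT_DIM = 784
V_FLOOR_DEFAULT = -2.0


@dataclass
class LayerParams:
    """Weights and neuron constants for one rLIF layer."""

    w: np.ndarray          # feedforward weights, (input_dim, layer_size)
    r: np.ndarray          # recurrent weights, (layer_size, layer_size)
    beta: float = 0.9      # voltage decay per 1-ms step, 0 <= beta < 1
    theta: float = 1.0     # spike threshold
    eta: float = 0.05      # feedforward noise standard deviation

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        self.r = np.asarray(self.r, dtype=np.float64)
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must satisfy 0 <= beta < 1")
        if self.r.shape[0] != self.r.shape[1] or self.r.shape[0] != self.w.shape[1]:
            raise ValueError("recurrent weight shape inconsistent with layer size")

    @property
    def size(self) -> int:
        return self.w.shape[1]


@dataclass
class CircuitParams:
    """Full three-layer circuit parameterization."""

    layers: dict[str, LayerParams]
    v_floor: float = V_FLOOR_DEFAULT

    def __post_init__(self):
        if tuple(self.layers) != LAYER_NAMES:
            raise ValueError(f"layers must be exactly {LAYER_NAMES} in order")
        sizes = self.layer_sizes
        if self.layers["reservoir"].w.shape[0] != sizes[0]:
            raise ValueError("reservoir feedforward weights must map from sensory layer")
        if self.layers["output"].w.shape[0] != sizes[1]:
            raise ValueError("output feedforward weights must map from reservoir layer")
        for lp in self.layers.values():
            if lp.theta <= self.v_floor:
                raise ValueError("threshold must exceed the voltage floor")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(self.layers[name].size for name in LAYER_NAMES)

    @property
    def total_neurons(self) -> int:
        return sum(self.layer_sizes)

    @classmethod
    def random(cls, layer_sizes: tuple[int, int, int] = (400, 200, 10),
               input_dim: int = INPUT_DIM, seed: int = 0, beta: float = 0.9,
               theta: float = 1.0, eta: float = 0.05,
               w_scale: float = 1.0, r_scale: float = 0.3) -> "CircuitParams":
        """Random initial weights, scaled by fan-in for comparable drive."""
        rng = np.random.default_rng(seed)
        fan_ins = (input_dim, layer_sizes[0], layer_sizes[1])
        layers = {}
        for name, fan_in, size in zip(LAYER_NAMES, fan_ins, layer_sizes):
            w = rng.normal(0.0, w_scale / np.sqrt(fan_in), size=(fan_in, size))
            r = rng.normal(0.0, r_scale / np.sqrt(size), size=(size, size))
            layers[name] = LayerParams(w=w, r=r, beta=beta, theta=theta, eta=eta)
        return cls(layers=layers)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["v_floor"] = self.v_floor
            for name, lp in self.layers.items():
                g = f.create_group(name)
                g.create_dataset("w", data=lp.w)
                g.create_dataset("r", data=lp.r)
                g.attrs["beta"] = lp.beta
                g.attrs["theta"] = lp.theta
                g.attrs["eta"] = lp.eta

    @classmethod
    def load(cls, path) -> "CircuitParams":
        with h5py.File(path, "r") as f:
            layers = {
                name: LayerParams(
                    w=f[name]["w"][...], r=f[name]["r"][...],
                    beta=float(f[name].attrs["beta"]),
                    theta=float(f[name].attrs["theta"]),
                    eta=float(f[name].attrs["eta"]))
                for name in LAYER_NAMES
            }
            return cls(layers=layers, v_floor=float(f.attrs["v_floor"]))


@dataclass
class CircuitState:
    """Membrane voltages and last spike vectors, one entry per layer."""

    V: dict[str, np.ndarray]
    S: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, params: CircuitParams) -> "CircuitState":
        return cls(
            V={n: np.zeros(lp.size) for n, lp in params.layers.items()},
            S={n: np.zeros(lp.size) for n, lp in params.layers.items()},
        )


@dataclass
class SpikeRaster:
    """Binary time x neuron spike matrix at 1-ms resolution."""

    spikes: np.ndarray                     # (T, n) uint8
    neuron_ids: np.ndarray                 # (n,) global circuit indices
    dt_ms: float = 1.0

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if len(np.unique(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("spikes must be binary")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("spikes", data=self.spikes.astype(np.uint8))
            f.create_dataset("neuron_ids", data=self.neuron_ids)
            f.attrs["dt_ms"] = self.dt_ms

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with h5py.File(path, "r") as f:
            return cls(spikes=f["spikes"][...], neuron_ids=f["neuron_ids"][...],
                       dt_ms=float(f.attrs["dt_ms"]))


def rlif_step(V: np.ndarray, S_prev: np.ndarray, feedforward_input: np.ndarray,
              layer: LayerParams, noise_draw: np.ndarray | None = None,
              v_floor: float = V_FLOOR_DEFAULT) -> tuple[np.ndarray, np.ndarray]:
    """Advance one rLIF layer a single time step.

    ``noise_draw`` is added elementwise to the feedforward input before
    weighting; pass an explicit draw for reproducibility or None for no
    noise.  Returns (new voltages, spike vector).  Neurons whose updated
    voltage reaches the threshold spike and reset to 0; voltages are then
    clamped at ``v_floor`` (clamp applied after the reset).
    """
    V = np.asarray(V, dtype=np.float64)
    x = np.asarray(feedforward_input, dtype=np.float64)
    if x.shape[-1] != layer.w.shape[0]:
        raise ValueError(
            f"feedforward input length {x.shape[-1]} != weight rows {layer.w.shape[0]}")
    if V.shape[-1] != layer.size:
        raise ValueError("voltage vector length does not match layer size")
    if noise_draw is not None:
        x = x + noise_draw
    V_new = layer.beta * V + x @ layer.w + np.asarray(S_prev, dtype=np.float64) @ layer.r
    spikes = (V_new >= layer.theta).astype(np.float64)
    V_new = np.where(spikes > 0, 0.0, V_new)
    V_new = np.maximum(V_new, v_floor)
    return V_new, spikes


def simulate_circuit(stimulus_sequence: np.ndarray, params: CircuitParams,
                     seed: int = 0, state: CircuitState | None = None,
                     ) -> tuple[SpikeRaster, CircuitState]:
    """Simulate the full circuit driven by a stimulus sequence.

    ``stimulus_sequence`` has shape (T, input_dim), each row a flattened
    image presented for one 1-ms step. Layers update in order
    sensory -> reservoir -> output, each receiving the upstream layer's
    current-step spikes (plus noise) feedforward and its own previous-step
    spikes recurrently. Returns the spike record of all three layers
    (columns ordered sensory, reservoir, output) and the final state.
    """
    stim = np.atleast_2d(np.asarray(stimulus_sequence, dtype=np.float64))
    if not np.isfinite(stim).all():
        raise ValueError("stimulus sequence contains non-finite values")
    if stim.shape[1] != params.layers["sensory"].w.shape[0]:
        raise ValueError("stimulus dimension does not match sensory weights")
    T = stim.shape[0]
    rng = np.random.default_rng(seed)
    if state is None:
        state = CircuitState.zeros(params)
    spikes_out = np.zeros((T, params.total_neurons), dtype=np.uint8)
    for t in range(T):
        upstream = stim[t]
        col = 0
        for name in LAYER_NAMES:
            lp = params.layers[name]
            noise = (rng.normal(0.0, lp.eta, size=upstream.shape)
                     if lp.eta > 0 else None)
            state.V[name], state.S[name] = rlif_step(
                state.V[name], state.S[name], upstream, lp,
                noise_draw=noise, v_floor=params.v_floor)
            spikes_out[t, col:col + lp.size] = state.S[name].astype(np.uint8)
            col += lp.size
            upstream = state.S[name]
    raster = SpikeRaster(spikes=spikes_out,
                         neuron_ids=np.arange(params.total_neurons))
    return raster, state


def sample_ensemble(layer_sizes: tuple[int, ...], fraction: float,
                    seed: int = 0) -> np.ndarray:
    """Sample a recordable ensemble: round(fraction * N) neuron ids drawn
    uniformly without replacement across all layers, returned in canonical
    (ascending) order. Emulates partial extracellular observability."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    total = int(sum(layer_sizes))
    n = int(round(fraction * total))
    rng = np.random.default_rng(seed)
    ids = rng.choice(total, size=n, replace=False)
    return np.sort(ids)
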