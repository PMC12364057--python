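"""Closed-loop control of latent dynamics: the full measurement-to-stimulus
loop, reference construction, metrics, and the experiment protocols.

At each 1-ms step the loop measures spikes from the observed ensemble,
updates the exponential filter, encodes the smoothed state to the latent
z, compares it with the reference z*, computes the latent input v (PID or
MPC), decodes v to a pixel stimulus through the frozen stimulus decoder,
and advances the circuit by one step. Plants abstract the controlled
system so the same loop runs against the spiking circuit or directly
against a ground-truth linear latent system.

Metrics follow the tracking experiments: per-dimension nMSE (mean squared
tracking error normalized by the reference range max - min per dimension)
and the per-dimension RMS of the control input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .controllers import MpcController, PidController
from .latent_dynamics import (LdmConfig, LdmModel, exp_filter, fit_ldm,
                              forecast_correlation, open_loop_forecast)
from .snn_circuit import CircuitParams, CircuitState, sample_ensemble
from .snn_circuit import simulate_circuit as _simulate_circuit
from .vae_latent import VaeConfig, VaeModel, fit_vae

__all__ = [
    "ReferenceTrajectory", "TrialRecord", "LinearFixturePlant", "CircuitPlant",
    "run_control_trial", "make_setpoint_reference", "make_arc_references",
    "nmse", "input_rms", "run_observability_sweep",
]


# ---------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------

def nmse(z: np.ndarray, z_ref: np.ndarray) -> np.ndarray:
    """Per-dimension mean squared tracking error normalized by the
    reference range (max - min). A dimension with a constant reference
    falls back to unnormalized MSE (divide by 1)."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    z_ref = np.atleast_2d(np.asarray(z_ref, dtype=np.float64))
    if z.shape != z_ref.shape:
        raise ValueError("trajectory and reference lengths differ")
    mse = np.mean((z - z_ref) ** 2, axis=0)
    rng = z_ref.max(axis=0) - z_ref.min(axis=0)
    rng = np.where(rng > 0, rng, 1.0)
    return mse / rng


def input_rms(V: np.ndarray) -> np.ndarray:
    """Per-dimension root mean square of the control input over a trial."""
    V = np.atleast_2d(np.asarray(V, dtype=np.float64))
    if V.size == 0:
        raise ValueError("empty input sequence")
    return np.sqrt(np.mean(V ** 2, axis=0))


# ---------------------------------------------------------------------
# References
# ---------------------------------------------------------------------

@dataclass
class ReferenceTrajectory:
    z_star: np.ndarray                  # (T, 2)
    kind: str = "setpoint-step"         # setpoint-step | arc-1 | arc-2
    switch_times: tuple[int, ...] = ()

    def __post_init__(self):
        self.z_star = np.atleast_2d(np.asarray(self.z_star, dtype=np.float64))

    def __len__(self) -> int:
        return len(self.z_star)

    def window(self, start: int, length: int) -> np.ndarray:
        """Reference rows start..start+length, padded with the final value."""
        end = min(start + length, len(self.z_star))
        chunk = self.z_star[start:end]
        if len(chunk) < length:
            pad = np.repeat(self.z_star[-1][None, :], length - len(chunk), axis=0)
            chunk = np.vstack([chunk, pad])
        return chunk


def make_setpoint_reference(latent_states: np.ndarray,
                            duration_per_point: int = 500,
                            seed: int = 0) -> ReferenceTrajectory:
    """Step reference from 2-means centroids of the latent states.

    The two centroids become consecutive set points, each held
    ``duration_per_point`` steps (default 500, switching at 500 ms). The
    set points are ordered by their first latent coordinate for
    reproducibility.
    """
    pts = np.atleast_2d(np.asarray(latent_states, dtype=np.float64))
    if np.allclose(pts, pts[0]):
        raise ValueError("latent states are degenerate (all identical)")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pts)
    centers = km.cluster_centers_[np.argsort(km.cluster_centers_[:, 0])]
    z_star = np.vstack([np.repeat(centers[0][None, :], duration_per_point, axis=0),
                        np.repeat(centers[1][None, :], duration_per_point, axis=0)])
    return ReferenceTrajectory(z_star=z_star, kind="setpoint-step",
                               switch_times=(duration_per_point,))


def make_arc_references(z0_star: np.ndarray, zf_star: np.ndarray,
                        duration: int = 1000
                        ) -> tuple[ReferenceTrajectory, ReferenceTrajectory]:
    """Two equal-length semicircular arc references sharing endpoints.

    The circle takes the chord z0* -> zf* as its diameter -- the unique
    circle through both points whose two opposite arcs have equal length.
    Each arc is sampled uniformly in angle over ``duration`` steps; the
    first and last samples are set to the endpoints exactly.
    """
    z0 = np.asarray(z0_star, dtype=np.float64)
    zf = np.asarray(zf_star, dtype=np.float64)
    if np.allclose(z0, zf):
        raise ValueError("arc endpoints must be distinct")
    center = (z0 + zf) / 2.0
    radius = np.linalg.norm(zf - z0) / 2.0
    theta0 = np.arctan2(z0[1] - center[1], z0[0] - center[0])
    arcs = []
    for sign, kind in ((+1.0, "arc-1"), (-1.0, "arc-2")):
        theta = theta0 + sign * np.linspace(0.0, np.pi, duration)
        pts = center[None, :] + radius * np.column_stack([np.cos(theta),
                                                          np.sin(theta)])
        pts[0], pts[-1] = z0, zf
        arcs.append(ReferenceTrajectory(z_star=pts, kind=kind))
    return arcs[0], arcs[1]


# ---------------------------------------------------------------------
# Plants
# ---------------------------------------------------------------------

class LinearFixturePlant:
    """Ground-truth linear latent plant z' = A z + B v (+ noise).

    Used to exercise the controllers against exact dynamics, bypassing the
    circuit and the observation models.
    """

    def __init__(self, A: np.ndarray, B: np.ndarray, noise_scale: float = 0.0,
                 z0: np.ndarray | None = None):
        self.A = np.atleast_2d(np.asarray(A, dtype=np.float64))
        self.B = np.atleast_2d(np.asarray(B, dtype=np.float64))
        self.noise_scale = noise_scale
        self.z0 = np.zeros(self.A.shape[0]) if z0 is None else np.asarray(z0)

    def reset(self, seed: int = 0) -> np.ndarray:
        self._rng = np.random.default_rng(seed)
        self.z = self.z0.copy()
        return self.z.copy()

    def step(self, v: np.ndarray) -> np.ndarray:
        noise = (self.noise_scale * self._rng.standard_normal(len(self.z))
                 if self.noise_scale > 0 else 0.0)
        self.z = self.A @ self.z + self.B @ np.asarray(v) + noise
        return self.z.copy()


class CircuitPlant:
    """The full loop plant: decode v -> stimulate circuit -> filter spikes
    -> encode to z. Records stimuli and observed spikes as it runs."""

    def __init__(self, params: CircuitParams, ensemble_ids: np.ndarray,
                 ldm: LdmModel, svae: VaeModel):
        if ldm.svae is not None and ldm.svae is not svae:
            raise ValueError("stimulus decoder must match the LDM's sVAE")
        self.params = params
        self.ensemble_ids = np.asarray(ensemble_ids, dtype=np.int64)
        self.ldm = ldm
        self.svae = svae
        self.record_stimuli: list[np.ndarray] = []
        self.record_spikes: list[np.ndarray] = []

    def reset(self, seed: int = 0) -> np.ndarray:
        self._rng = np.random.default_rng(seed)
        self._seed = seed
        self.state = CircuitState.zeros(self.params)
        self._step_count = 0
        # x0 = s0 with no spikes yet observed
        self.x = np.zeros(len(self.ensemble_ids))
        self.record_stimuli = []
        self.record_spikes = []
        return self.ldm.encode_neural(self.x)

    def step(self, v: np.ndarray) -> np.ndarray:
        u = self.svae.decode(np.asarray(v, dtype=np.float64))
        raster, self.state = _simulate_circuit(
            u[None, :], self.params,
            seed=self._seed + 7919 * (self._step_count + 1), state=self.state)
        s = raster.spikes[0, self.ensemble_ids].astype(np.float64)
        self.x = self.ldm.omega * s + (1.0 - self.ldm.omega) * self.x
        self.record_stimuli.append(u)
        self.record_spikes.append(s.astype(np.uint8))
        self._step_count += 1
        return self.ldm.encode_neural(self.x)


# ---------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------

@dataclass
class TrialRecord:
    z: np.ndarray                    # controlled latent trajectory (T, 2)
    v: np.ndarray                    # applied latent inputs (T, 2)
    reference: ReferenceTrajectory
    nmse: np.ndarray                 # per-dimension
    rms: np.ndarray                  # per-dimension
    seed: int
    stimuli: np.ndarray | None = None
    spikes: np.ndarray | None = None


def run_control_trial(plant, controller, reference: ReferenceTrajectory,
                      seed: int = 0) -> TrialRecord:
    """Run one closed-loop trial over the full reference duration.

    At step n the measured latent z_n is compared with z*_n, the controller
    produces v_n (PID from the error; MPC from z_n and the upcoming
    reference window), and the plant is advanced with v_n -- the stimulus
    presented at step n is exactly the decode of the input computed at
    step n. The whole trial is reproducible from (configuration, seed).
    """
    T = len(reference)
    horizon = getattr(getattr(controller, "spec", None), "horizon", 1)
    z = plant.reset(seed)
    controller.reset()
    Z = np.zeros((T, len(z)))
    Vs = np.zeros((T, 2))
    for n in range(T):
        Z[n] = z
        window = reference.window(n + 1, horizon)
        v = controller(z, window if horizon > 1 else reference.z_star[n][None, :])
        Vs[n] = v
        z = plant.step(v)
    rec = TrialRecord(
        z=Z, v=Vs, reference=reference,
        nmse=nmse(Z, reference.z_star), rms=input_rms(Vs), seed=seed,
        stimuli=(np.asarray(plant.record_stimuli)
                 if getattr(plant, "record_stimuli", None) else None),
        spikes=(np.asarray(plant.record_spikes)
                if getattr(plant, "record_spikes", None) else None),
    )
    return rec


# ---------------------------------------------------------------------
# Observability sweep (Experiment II analogue)
# ---------------------------------------------------------------------

def run_observability_sweep(params: CircuitParams, spikes_full: np.ndarray,
                            stimuli_latent: np.ndarray, svae: VaeModel,
                            fractions: list[float], n_ensembles: int,
                            trials: int, controllers: tuple[str, ...] = ("pid", "mpc"),
                            seed: int = 0, omega: float = 0.1,
                            nvae_epochs: int = 20, ldm_config: LdmConfig | None = None,
                            trial_length: int = 1000,
                            nvae_hidden: tuple[int, ...] = (64,),
                            input_bound_margin: float | None = 0.5) -> pd.DataFrame:
    """Refit the observation models per random ensemble and compare
    controllers across observability levels.

    ``spikes_full`` is a (T, N) recording of the whole circuit under the
    latent stimulus sequence ``stimuli_latent`` (already encoded through
    the frozen sVAE). For each observed fraction, ``n_ensembles`` random
    ensembles are drawn; an nVAE + LDM is fit per ensemble with constant
    architecture (only the input width changes), and ``trials`` set-point
    control trials are run per controller. Returns one row per
    (fraction, ensemble, controller, trial, dimension) with nMSE, input
    RMS, and the ensemble's held-out forecast correlation.
    """
    from .controllers import MpcSpec

    rng = np.random.default_rng(seed)
    ldm_config = ldm_config if ldm_config is not None else LdmConfig()
    v_bounds = None
    if input_bound_margin is not None:
        vmin, vmax = stimuli_latent.min(axis=0), stimuli_latent.max(axis=0)
        margin = input_bound_margin * (vmax - vmin)
        v_bounds = (vmin - margin, vmax + margin)
    rows = []
    layer_sizes = params.layer_sizes
    n_total = params.total_neurons
    split = int(0.8 * len(spikes_full))
    for fraction in fractions:
        if int(round(fraction * n_total)) < 2:
            warnings.warn(f"fraction {fraction} yields <2 neurons; skipped")
            continue
        for ens in range(n_ensembles):
            ens_seed = int(rng.integers(2 ** 31 - 1))
            ids = sample_ensemble(layer_sizes, fraction, seed=ens_seed)
            x = exp_filter(spikes_full[:, ids], omega)
            nvae = fit_vae(x[:split], x[split:],
                           VaeConfig(hidden=nvae_hidden, epochs=nvae_epochs,
                                     patience=nvae_epochs, seed=ens_seed))
            ldm = fit_ldm(x[:split], stimuli_latent[:split], nvae, None,
                          ldm_config)
            ldm = LdmModel(A=ldm.A, B=ldm.B, nvae=ldm.nvae, svae=svae,
                           omega=omega, horizon=ldm.horizon)
            z_test = ldm.nvae.encode_mean(x[split:])
            z_hat = open_loop_forecast(z_test[0], stimuli_latent[split:],
                                       ldm, len(z_test))
            corr = forecast_correlation(z_test, z_hat)
            reference = make_setpoint_reference(
                z_test, duration_per_point=trial_length // 2, seed=ens_seed)
            for name in controllers:
                for trial in range(trials):
                    trial_seed = int(rng.integers(2 ** 31 - 1))
                    plant = CircuitPlant(params, ids, ldm, svae)
                    ctrl = (MpcController(ldm.A, ldm.B,
                                          MpcSpec(v_bounds=v_bounds))
                            if name == "mpc" else PidController())
                    rec = run_control_trial(plant, ctrl, reference, trial_seed)
                    for dim in range(2):
                        rows.append({
                            "fraction": fraction, "ensemble": ens,
                            "controller": name, "trial": trial, "dim": dim,
                            "nmse": rec.nmse[dim], "rms": rec.rms[dim],
                            "forecast_corr": corr[dim],
                        })
    return pd.DataFrame(rows)
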