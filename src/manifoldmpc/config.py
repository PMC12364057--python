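"""Experiment configuration, stage seeding, and the pipeline driver.

Configuration is a nested, strictly validated schema (unknown keys are
rejected with the offending key path). Every random operation consumes a
seed derived deterministically from the global seed and a stage label, so
stages can be rerun independently. The pipeline driver executes the stages

    stimuli -> train-circuit -> train-svae -> build-inputs -> record
            -> train-ldm -> control / sweep

writing artifacts under ``<output_root>/<stage>/`` with a manifest that
records a content hash of the stage configuration and of every input
artifact consumed; a rerun with unchanged configuration skips stages whose
manifests still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

logger = logging.getLogger("manifoldmpc")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "save_config",
           "stage_seed", "run_pipeline", "PIPELINE_STAGES"]

PIPELINE_STAGES = ("stimuli", "train-circuit", "train-svae", "build-inputs",
                   "record", "train-ldm", "control", "sweep")


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CircuitSection(_Strict):
    layer_sizes: tuple[int, int, int] = (400, 200, 10)
    beta: float = 0.9
    theta: float = 1.0
    eta: float = 0.05
    v_floor: float = -2.0
    w_scale: float = 1.0
    r_scale: float = 0.3


class CircuitTrainingSection(_Strict):
    T: int = 25
    batch_size: int = 32
    lr: float = 1e-3
    max_epochs: int = 30
    patience: int = 5
    surrogate_slope: float = 10.0
    eval_repeats: int = 5


class VaeSection(_Strict):
    k: int = 2
    hidden: tuple[int, ...] = (128,)
    alpha: float = 1.0
    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 5
    lr_decay: float | None = None


class LdmSection(_Strict):
    horizon: int = 40
    epochs: int = 50
    batch_windows: int = 64
    lr: float = 1e-3
    patience: int = 5
    lr_decay: float = 0.99
    val_fraction: float = 0.2
    nvae_pretrain_epochs: int = 20
    omega: float = 0.1


class GlyphSection(_Strict):
    n_per_class: int = 200
    n_classes: int = 10


class InputsSection(_Strict):
    n_centers: int = 120           # k-means centers, split into equal thirds
    step_duration: int = 500
    fast_duration: int = 200
    slow_duration: int = 1000
    methods: tuple[str, ...] = ("step", "fast", "slow")


class PidSection(_Strict):
    K_P: list[list[float]] = [[20.0, 20.0], [5.0, 20.0]]
    K_I: list[list[float]] = [[0.9, 0.9], [0.1, 0.1]]
    K_D: list[list[float]] = [[0.01, 0.01], [0.01, 0.01]]


class MpcSection(_Strict):
    horizon: int = 10
    Q: list[list[float]] = [[1.0, 0.0], [0.0, 1.0]]
    R: list[list[float]] = [[0.001, 0.0], [0.0, 0.001]]
    S: list[list[float]] = [[1.0, 0.0], [0.0, 1.0]]


class ControllersSection(_Strict):
    pid: PidSection = PidSection()
    mpc: MpcSection = MpcSection()


class ReferencesSection(_Strict):
    duration_per_point: int = 500
    arc_duration: int = 1000


class ControlSection(_Strict):
    trials: int = 10               # desk-scale default (full protocol: 50)
    observed_fraction: float = 0.2
    controllers: tuple[str, ...] = ("pid", "mpc")
    reference: str = "setpoints"   # setpoints | arc1 | arc2
    # MPC searches latent inputs only inside the training-input bounding box
    # expanded by this fraction of its range per side (None = unbounded):
    # the stimulus decoder is meaningless outside its training support.
    input_bound_margin: float | None = 0.5


class SweepSection(_Strict):
    fractions: tuple[float, ...] = (0.05, 0.2)
    n_ensembles: int = 2           # desk-scale default (full protocol: 10)
    trials: int = 5
    trial_length: int = 1000


class ExperimentConfig(_Strict):
    seed: int = 0
    output_root: str = "outputs"
    circuit: CircuitSection = CircuitSection()
    circuit_training: CircuitTrainingSection = CircuitTrainingSection()
    svae: VaeSection = VaeSection()
    nvae: VaeSection = VaeSection(hidden=(64,), lr_decay=0.99, alpha=0.01)
    ldm: LdmSection = LdmSection()
    glyphs: GlyphSection = GlyphSection()
    inputs: InputsSection = InputsSection()
    controllers: ControllersSection = ControllersSection()
    references: ReferencesSection = ReferencesSection()
    control: ControlSection = ControlSection()
    sweep: SweepSection = SweepSection()


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML/JSON configuration file.

    An empty file yields the full default configuration; unknown keys raise
    a ConfigError naming the offending key path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration file: {exc}") from exc
    if data is None:
        data = {}
    try:
        return ExperimentConfig(**data)
    except ValidationError as exc:
        locs = [".".join(str(p) for p in err["loc"]) for err in exc.errors()]
        raise ConfigError(f"invalid configuration key(s): {', '.join(locs)}") from exc


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def stage_seed(global_seed: int, label: str) -> int:
    """Deterministic per-stage substream seed (below 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


# ---------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: ExperimentConfig, sections: tuple[str, ...]) -> str:
    blob = {s: config.model_dump()[s] for s in sections}
    blob["seed"] = config.seed
    return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()


class _Stage:
    """One pipeline stage: config sections consumed, upstream stages, and
    the function producing the artifacts."""

    def __init__(self, name, sections, deps, func, outputs):
        self.name, self.sections, self.deps = name, sections, deps
        self.func, self.outputs = func, outputs


def _stage_dir(root: Path, name: str) -> Path:
    d = root / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: ExperimentConfig, stages: list[str] | None = None,
                 output_root: str | Path | None = None) -> dict[str, Path]:
    """Execute pipeline stages in order, skipping up-to-date ones.

    Returns a mapping stage name -> stage artifact directory. Raises a
    ``ConfigError`` naming the stage whose upstream artifact is missing.
    """
    from . import closed_loop, latent_dynamics, snn_circuit, snn_training, \
        synthetic_data, vae_latent

    root = Path(output_root if output_root is not None else config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(PIPELINE_STAGES)
    for s in stages:
        if s not in PIPELINE_STAGES:
            raise ConfigError(f"unknown stage '{s}'")

    # ----- stage bodies ---------------------------------------------
    def do_stimuli(d: Path):
        g = config.glyphs
        images, labels = synthetic_data.generate_glyph_dataset(
            g.n_per_class, g.n_classes, seed=stage_seed(config.seed, "stimuli"))
        synthetic_data.save_glyph_dataset(d / "glyphs.h5", images, labels)

    def do_train_circuit(d: Path):
        images, labels = synthetic_data.load_glyph_dataset(
            root / "stimuli" / "glyphs.h5")
        c = config.circuit
        params = snn_circuit.CircuitParams.random(
            layer_sizes=c.layer_sizes, seed=stage_seed(config.seed, "circuit-init"),
            beta=c.beta, theta=c.theta, eta=c.eta,
            w_scale=c.w_scale, r_scale=c.r_scale)
        params.v_floor = c.v_floor
        t = config.circuit_training
        tc = snn_training.TrainConfig(
            T=t.T, batch_size=t.batch_size, lr=t.lr, max_epochs=t.max_epochs,
            patience=t.patience, surrogate_slope=t.surrogate_slope,
            eval_repeats=t.eval_repeats,
            seed=stage_seed(config.seed, "train-circuit"))
        trained, history = snn_training.train_circuit((images, labels), params, tc)
        trained.save(d / "circuit.h5")
        history.to_csv(d / "history.csv", index=False, float_format="%.9g")

    def do_train_svae(d: Path):
        images, _ = synthetic_data.load_glyph_dataset(root / "stimuli" / "glyphs.h5")
        flat = images.reshape(len(images), -1)
        rng = np.random.default_rng(stage_seed(config.seed, "svae-split"))
        perm = rng.permutation(len(flat))
        n_train = int(0.7 * len(flat))
        n_val = int(0.15 * len(flat))
        s = config.svae
        model = vae_latent.fit_vae(
            flat[perm[:n_train]], flat[perm[n_train:n_train + n_val]],
            vae_latent.VaeConfig(k=s.k, hidden=s.hidden, alpha=s.alpha,
                                 epochs=s.epochs, batch_size=s.batch_size,
                                 lr=s.lr, patience=s.patience,
                                 lr_decay=s.lr_decay,
                                 seed=stage_seed(config.seed, "train-svae")))
        vae_latent.save_vae(model, d / "svae.h5")
        np.save(d / "val_indices.npy", perm[n_train:n_train + n_val])

    def do_build_inputs(d: Path):
        images, _ = synthetic_data.load_glyph_dataset(root / "stimuli" / "glyphs.h5")
        svae = vae_latent.load_vae(root / "train-svae" / "svae.h5")
        val_idx = np.load(root / "train-svae" / "val_indices.npy")
        embedded = svae.encode_mean(images[val_idx].reshape(len(val_idx), -1))
        ic = config.inputs
        thirds = vae_latent.extract_centers(
            embedded, ic.n_centers, seed=stage_seed(config.seed, "centers"))
        durations = {"step": ic.step_duration, "fast": ic.fast_duration,
                     "slow": ic.slow_duration}
        for part, centers in zip(("train", "val", "test"), thirds):
            seqs = [vae_latent.build_latent_input_sequence(
                        vae_latent.LatentInputPlan(centers, method=m,
                                                   durations=durations))
                    for m in ic.methods]
            seq = np.concatenate(seqs, axis=0)
            pd.DataFrame({"step": np.arange(len(seq)),
                          "v1": seq[:, 0], "v2": seq[:, 1]}).to_csv(
                d / f"inputs_{part}.csv", index=False, float_format="%.9g")
            np.save(d / f"centers_{part}.npy", centers)

    def do_record(d: Path):
        params = snn_circuit.CircuitParams.load(root / "train-circuit" / "circuit.h5")
        svae = vae_latent.load_vae(root / "train-svae" / "svae.h5")
        for part in ("train", "val", "test"):
            df = pd.read_csv(root / "build-inputs" / f"inputs_{part}.csv")
            V = df[["v1", "v2"]].to_numpy()
            stim = svae.decode(V)
            raster, _ = snn_circuit.simulate_circuit(
                stim, params, seed=stage_seed(config.seed, f"record-{part}"))
            raster.save(d / f"raster_{part}.h5")

    def do_train_ldm(d: Path):
        svae = vae_latent.load_vae(root / "train-svae" / "svae.h5")
        lc = config.ldm
        data = {}
        for part in ("train", "val", "test"):
            raster = snn_circuit.SpikeRaster.load(root / "record" / f"raster_{part}.h5")
            df = pd.read_csv(root / "build-inputs" / f"inputs_{part}.csv")
            data[part] = (raster.spikes, df[["v1", "v2"]].to_numpy())
        frac = config.control.observed_fraction
        params = snn_circuit.CircuitParams.load(root / "train-circuit" / "circuit.h5")
        ids = snn_circuit.sample_ensemble(
            params.layer_sizes, frac, seed=stage_seed(config.seed, "ensemble"))
        np.save(d / "ensemble_ids.npy", ids)
        x = {p: latent_dynamics.exp_filter(s[:, ids], lc.omega)
             for p, (s, _) in data.items()}
        nv = config.nvae
        nvae = vae_latent.fit_vae(
            x["train"], x["val"],
            vae_latent.VaeConfig(k=nv.k, hidden=nv.hidden, alpha=nv.alpha,
                                 epochs=lc.nvae_pretrain_epochs,
                                 batch_size=nv.batch_size, lr=nv.lr,
                                 patience=lc.nvae_pretrain_epochs,
                                 lr_decay=nv.lr_decay,
                                 seed=stage_seed(config.seed, "nvae")))
        ldm = latent_dynamics.fit_ldm(
            x["train"], data["train"][1], nvae, None,
            latent_dynamics.LdmConfig(
                horizon=lc.horizon, epochs=lc.epochs,
                batch_windows=lc.batch_windows, lr=lc.lr, patience=lc.patience,
                lr_decay=lc.lr_decay, val_fraction=lc.val_fraction,
                seed=stage_seed(config.seed, "ldm")))
        ldm = latent_dynamics.LdmModel(A=ldm.A, B=ldm.B, nvae=ldm.nvae,
                                       svae=svae, omega=lc.omega,
                                       horizon=lc.horizon)
        latent_dynamics.save_ldm(ldm, d / "ldm.h5")
        z_test = ldm.nvae.encode_mean(x["test"])
        z_hat = latent_dynamics.open_loop_forecast(
            z_test[0], data["test"][1], (ldm.A, ldm.B), len(z_test))
        corr = latent_dynamics.forecast_correlation(z_test, z_hat)
        out = pd.DataFrame({"step": np.arange(len(z_test)),
                            "z1_true": z_test[:, 0], "z2_true": z_test[:, 1],
                            "z1_hat": z_hat[:, 0], "z2_hat": z_hat[:, 1]})
        out.to_csv(d / "forecast_test.csv", index=False, float_format="%.9g")
        (d / "forecast_metrics.json").write_text(json.dumps(
            {"corr_z1": float(corr[0]), "corr_z2": float(corr[1])}, indent=2))

    def do_control(d: Path):
        from .controllers import MpcController, MpcSpec, PidController, PidGains
        params = snn_circuit.CircuitParams.load(root / "train-circuit" / "circuit.h5")
        ldm = latent_dynamics.load_ldm(root / "train-ldm" / "ldm.h5")
        ids = np.load(root / "train-ldm" / "ensemble_ids.npy")
        raster = snn_circuit.SpikeRaster.load(root / "record" / "raster_test.h5")
        x_test = latent_dynamics.exp_filter(raster.spikes[:, ids], ldm.omega)
        z_test = ldm.nvae.encode_mean(x_test)
        cc = config.control
        v_bounds = None
        if cc.input_bound_margin is not None:
            vtr = pd.read_csv(root / "build-inputs" / "inputs_train.csv")
            vmin = vtr[["v1", "v2"]].min().to_numpy()
            vmax = vtr[["v1", "v2"]].max().to_numpy()
            margin = cc.input_bound_margin * (vmax - vmin)
            v_bounds = (vmin - margin, vmax + margin)
        if cc.reference == "setpoints":
            refs = [closed_loop.make_setpoint_reference(
                z_test, config.references.duration_per_point,
                seed=stage_seed(config.seed, "reference"))]
        else:
            sp = closed_loop.make_setpoint_reference(
                z_test, config.references.duration_per_point,
                seed=stage_seed(config.seed, "reference"))
            arc1, arc2 = closed_loop.make_arc_references(
                sp.z_star[0], sp.z_star[-1], config.references.arc_duration)
            refs = [arc1 if cc.reference == "arc1" else arc2]
        rows = []
        for ref in refs:
            for name in cc.controllers:
                mc = config.controllers.mpc
                pc = config.controllers.pid
                for trial in range(cc.trials):
                    t_seed = stage_seed(config.seed, f"control-{name}-{trial}")
                    plant = closed_loop.CircuitPlant(params, ids, ldm, ldm.svae)
                    ctrl = (MpcController(ldm.A, ldm.B,
                                          MpcSpec(horizon=mc.horizon,
                                                  Q=np.array(mc.Q),
                                                  R=np.array(mc.R),
                                                  S=np.array(mc.S),
                                                  v_bounds=v_bounds))
                            if name == "mpc" else
                            PidController(PidGains(np.array(pc.K_P),
                                                   np.array(pc.K_I),
                                                   np.array(pc.K_D))))
                    rec = closed_loop.run_control_trial(plant, ctrl, ref, t_seed)
                    for dim in range(2):
                        rows.append({"reference": ref.kind, "controller": name,
                                     "trial": trial, "dim": dim,
                                     "nmse": rec.nmse[dim], "rms": rec.rms[dim]})
        pd.DataFrame(rows).to_csv(d / "trials.csv", index=False,
                                  float_format="%.9g")

    def do_sweep(d: Path):
        params = snn_circuit.CircuitParams.load(root / "train-circuit" / "circuit.h5")
        svae = vae_latent.load_vae(root / "train-svae" / "svae.h5")
        raster = snn_circuit.SpikeRaster.load(root / "record" / "raster_train.h5")
        df = pd.read_csv(root / "build-inputs" / "inputs_train.csv")
        sw = config.sweep
        table = closed_loop.run_observability_sweep(
            params, raster.spikes, df[["v1", "v2"]].to_numpy(), svae,
            list(sw.fractions), sw.n_ensembles, sw.trials,
            seed=stage_seed(config.seed, "sweep"),
            omega=config.ldm.omega, trial_length=sw.trial_length,
            nvae_hidden=config.nvae.hidden)
        table.to_csv(d / "sweep.csv", index=False, float_format="%.9g")

    catalog = {
        "stimuli": _Stage("stimuli", ("glyphs",), (), do_stimuli,
                          ("glyphs.h5",)),
        "train-circuit": _Stage("train-circuit",
                                ("circuit", "circuit_training"), ("stimuli",),
                                do_train_circuit, ("circuit.h5", "history.csv")),
        "train-svae": _Stage("train-svae", ("svae",), ("stimuli",),
                             do_train_svae, ("svae.h5",)),
        "build-inputs": _Stage("build-inputs", ("inputs",),
                               ("stimuli", "train-svae"), do_build_inputs,
                               ("inputs_train.csv", "inputs_val.csv",
                                "inputs_test.csv")),
        "record": _Stage("record", ("circuit",),
                         ("train-circuit", "train-svae", "build-inputs"),
                         do_record, ("raster_train.h5", "raster_val.h5",
                                     "raster_test.h5")),
        "train-ldm": _Stage("train-ldm", ("ldm", "nvae", "control"),
                            ("record", "build-inputs", "train-svae",
                             "train-circuit"),
                            do_train_ldm, ("ldm.h5", "forecast_metrics.json")),
        "control": _Stage("control",
                          ("control", "controllers", "references"),
                          ("train-ldm", "train-circuit", "record"),
                          do_control, ("trials.csv",)),
        "sweep": _Stage("sweep", ("sweep", "nvae", "ldm"),
                        ("train-circuit", "train-svae", "build-inputs",
                         "record"), do_sweep, ("sweep.csv",)),
    }

    results: dict[str, Path] = {}
    for name in stages:
        stage = catalog[name]
        d = _stage_dir(root, name)
        input_hashes = {}
        for dep in stage.deps:
            dep_dir = root / dep
            dep_manifest = dep_dir / "manifest.json"
            if not dep_manifest.exists():
                raise ConfigError(
                    f"stage '{name}' requires artifacts from '{dep}'; "
                    f"run that stage first")
            for out in catalog[dep].outputs:
                p = dep_dir / out
                if p.exists():
                    input_hashes[f"{dep}/{out}"] = _sha256_file(p)
        chash = _config_hash(config, stage.sections)
        manifest_path = d / "manifest.json"
        manifest = {"stage": name, "config_hash": chash, "inputs": input_hashes}
        if manifest_path.exists():
            old = json.loads(manifest_path.read_text())
            outputs_ok = all((d / o).exists() for o in stage.outputs)
            if (old.get("config_hash") == chash
                    and old.get("inputs") == input_hashes and outputs_ok):
                logger.info("[%s] up to date, skipped", name)
                results[name] = d
                continue
        logger.info("[%s] running", name)
        stage.func(d)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        results[name] = d
    return results
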