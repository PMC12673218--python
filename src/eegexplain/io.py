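"""File formats and run configuration.

Epochs travel as HDF5 containers with integer-coded labels plus a string
table; montages alone round-trip as CSV (label,x,y,z).  Trained decoders
serialise to a directory holding the architecture/training configuration as
JSON, the weights as an ``.npz`` checkpoint, and the training history as
CSV.  Run configurations are YAML with strict unknown-key rejection.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .decoding import ArchitectureSpec, TrainConfig, TrainedDecoder, build_decoder
from .interpretability import LaplacianParams
from .simulate import (EpochsSet, Montage, SimConfig, default_prepost_config,
                       default_visual_config)

# --------------------------------------------------------------------------
# epochs container
# --------------------------------------------------------------------------


def write_epochs(epochs: EpochsSet, path) -> None:
    """Write the HDF5 epochs container (float32 data, coded labels)."""
    classes = sorted(np.unique(epochs.labels).tolist())
    codes = np.array([classes.index(l) for l in epochs.labels], dtype=np.int32)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=codes)
        f.create_dataset("label_names", data=np.array(classes, dtype="S"))
        f.create_dataset("participants", data=epochs.participants.astype(np.int32))
        f.create_dataset("times", data=epochs.times.astype(np.float64))
        g = f.create_group("montage")
        g.create_dataset("labels", data=np.array(epochs.montage.channel_labels, dtype="S"))
        g.create_dataset("positions", data=epochs.montage.positions)
        f.attrs["sampling_rate_hz"] = float(epochs.sampling_rate)


def read_epochs(path) -> EpochsSet:
    """Read the HDF5 epochs container; missing pieces are named in the error."""
    with h5py.File(path, "r") as f:
        for key in ("data", "labels", "label_names", "participants", "times",
                    "montage/labels", "montage/positions"):
            if key not in f:
                raise KeyError(f"epochs file is missing dataset /{key}")
        if "sampling_rate_hz" not in f.attrs:
            raise KeyError("epochs file is missing attribute sampling_rate_hz")
        names = [s.decode() for s in f["label_names"][()]]
        codes = f["labels"][()]
        labels = np.array([names[c] for c in codes])
        montage = Montage(tuple(s.decode() for s in f["montage/labels"][()]),
                          f["montage/positions"][()])
        return EpochsSet(f["data"][()].astype(float), labels,
                         f["participants"][()].astype(int), f["times"][()],
                         montage, float(f.attrs["sampling_rate_hz"]))


def write_montage_csv(montage: Montage, path) -> None:
    pd.DataFrame({"label": montage.channel_labels,
                  "x": montage.positions[:, 0],
                  "y": montage.positions[:, 1],
                  "z": montage.positions[:, 2]}).to_csv(path, index=False)


def read_montage_csv(path) -> Montage:
    df = pd.read_csv(path)
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise KeyError(f"montage CSV missing columns: {sorted(missing)}")
    return Montage(tuple(df["label"].astype(str)), df[["x", "y", "z"]].to_numpy(float))


def export_epochs_fif(epochs: EpochsSet, path, head_radius_m: float = 0.095) -> None:
    """Optional export to the FIF epochs format for EEG viewers."""
    import mne

    mne.set_log_level("ERROR")
    info = mne.create_info(list(epochs.montage.channel_labels),
                           sfreq=epochs.sampling_rate, ch_types="eeg")
    dig = mne.channels.make_dig_montage(
        ch_pos={ch: p * head_radius_m for ch, p in
                zip(epochs.montage.channel_labels, epochs.montage.positions)},
        coord_frame="head")
    classes = sorted(np.unique(epochs.labels).tolist())
    events = np.column_stack([np.arange(epochs.n_trials),
                              np.zeros(epochs.n_trials, int),
                              [classes.index(l) + 1 for l in epochs.labels]])
    ep = mne.EpochsArray(epochs.data * 1e-6, info, events=events,
                         event_id={c: i + 1 for i, c in enumerate(classes)},
                         tmin=float(epochs.times[0]))
    ep.set_montage(dig)
    ep.save(path, overwrite=True)


# --------------------------------------------------------------------------
# decoder serialisation
# --------------------------------------------------------------------------


def save_decoder(trained: TrainedDecoder, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "spec": dataclasses.asdict(trained.spec),
        "fold_id": trained.fold_id,
        "class_names": list(trained.class_names),
        "train_participants": list(map(int, trained.train_participants)),
        "val_participants": list(map(int, trained.val_participants)),
        "estimator_params": {k: v for k, v in trained.estimator.get_params().items()
                             if isinstance(v, (int, float, str, bool, type(None)))},
        "scale": float(getattr(trained.estimator, "scale_", 1.0)),
        "input_shape": [int(trained.estimator.n_channels_),
                        int(trained.estimator.n_samples_)],
    }
    with open(out / "decoder.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    np.savez(out / "weights.npz", **trained.net.state_dict())
    trained.history.to_csv(out / "history.csv", index=False)


def load_decoder(in_dir) -> TrainedDecoder:
    src = Path(in_dir)
    with open(src / "decoder.json") as fh:
        meta = json.load(fh)
    spec = ArchitectureSpec(**meta["spec"])
    est = build_decoder(spec, meta["input_shape"][0], meta["input_shape"][1],
                        len(meta["class_names"]))
    est.set_params(**{k: v for k, v in meta["estimator_params"].items()
                      if k in est.get_params()})
    rng = np.random.default_rng(0)
    est.classes_ = np.array(meta["class_names"])
    est.n_channels_, est.n_samples_ = meta["input_shape"]
    est.net_ = est._build(meta["input_shape"][0], meta["input_shape"][1],
                          len(meta["class_names"]), rng)
    est.scale_ = meta["scale"]
    with np.load(src / "weights.npz") as w:
        est.net_.load_state_dict({k: w[k] for k in w.files})
    history = pd.read_csv(src / "history.csv")
    est.history_ = history
    est.best_epoch_ = int(history["epoch"].iloc[-1]) if len(history) else -1
    return TrainedDecoder(estimator=est, spec=spec, history=history,
                          fold_id=meta["fold_id"],
                          class_names=tuple(meta["class_names"]),
                          train_participants=tuple(meta["train_participants"]),
                          val_participants=tuple(meta["val_participants"]))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_SIM_SCALARS = ("n_participants", "trials_per_class_per_participant", "sampling_rate",
                "noise_sd", "noise_spectral_exponent", "latency_jitter_sd",
                "participant_amplitude_sd", "participant_topography_sd", "seed")


@dataclass
class RunConfig:
    """Validated configuration for the end-to-end pipeline."""

    dataset: str = "visual"  # visual (3-class) | prepost (2-class)
    sim: SimConfig = None  # filled from dataset preset + overrides
    families: tuple[str, ...] = ("eegnet_style",)
    methods: tuple[str, ...] = ("saliency", "gradcam")
    layers: tuple[str, ...] = ("early", "intermediate", "late")
    train: TrainConfig = field(default_factory=TrainConfig)
    laplacian: LaplacianParams = field(default_factory=LaplacianParams)
    alpha: float = 0.05
    n_folds: int = 5
    split_fractions: tuple[float, float, float] = (0.81, 0.10, 0.09)
    seed: int = 0
    verbose: bool = False
    out_dir: str = "report"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.dataset not in ("visual", "prepost"):
            raise ValueError("dataset must be 'visual' or 'prepost'")
        if self.sim is None:
            preset = (default_visual_config if self.dataset == "visual"
                      else default_prepost_config)
            self.sim = preset(seed=self.seed)


def _known_keys(cls):
    return {f.name for f in fields(cls)}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected by key path.

    An empty (or absent) file yields the documented defaults.  The ``sim``
    section accepts scalar overrides of the dataset preset.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    allowed = _known_keys(RunConfig)
    for key in raw:
        if key not in allowed:
            raise KeyError(f"unknown config key: {key}")
    sim_over = raw.pop("sim", {}) or {}
    train_over = raw.pop("train", {}) or {}
    lap_over = raw.pop("laplacian", {}) or {}
    for section, over, ok in (("sim", sim_over, set(_SIM_SCALARS)),
                              ("train", train_over, _known_keys(TrainConfig)),
                              ("laplacian", lap_over, _known_keys(LaplacianParams))):
        for key in over:
            if key not in ok:
                raise KeyError(f"unknown config key: {section}.{key}")
    for key in ("families", "methods", "layers", "split_fractions"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    if sim_over:
        preset = (default_visual_config if cfg.dataset == "visual"
                  else default_prepost_config)
        base = preset(seed=int(sim_over.get("seed", cfg.seed)))
        tpc = sim_over.pop("trials_per_class_per_participant", None)
        if tpc is not None:
            sim_over["trials_per_class_per_participant"] = int(tpc)
        cfg.sim = replace(base, **sim_over)
    cfg.train = replace(TrainConfig(), **train_over) if train_over else cfg.train
    cfg.laplacian = (replace(LaplacianParams(), **lap_over)
                     if lap_over else cfg.laplacian)
    return cfg


def effective_config_dict(cfg: RunConfig) -> dict:
    """The fully resolved configuration (defaults included) for provenance."""
    out = dataclasses.asdict(cfg)
    out["sim"]["components"] = [
        {"name": c["name"], "peak_latency": c["peak_latency"],
         "temporal_width": c["temporal_width"], "amplitude": c["amplitude"],
         "class_selector": list(c["class_selector"])}
        for c in out["sim"]["components"]]
    out["sim"].pop("montage", None)
    return out
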