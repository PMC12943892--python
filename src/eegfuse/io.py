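"""Container I/O: HDF5 recordings/features, EDF reading, CSV label tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .features import FeatureTensor

__all__ = [
    "read_recording", "write_recording", "write_features", "read_features",
    "read_label_table", "config_hash", "write_tracker_diagnostics",
    "save_model", "load_model",
]

LABEL_COLUMNS = ("trial_id", "subject_id", "session", "label")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_recording(path: str | Path) -> tuple[np.ndarray, float]:
    """Load a (channels, samples) recording and its sample rate.

    Supports HDF5 containers (dataset ``signal`` or the first 2-D dataset,
    with a ``sample_rate`` attribute) and EDF files (via mne, if installed).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "reading EDF requires the 'edf' extra (mne)") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return raw.get_data(), float(raw.info["sfreq"])
    with h5py.File(path, "r") as f:
        if "signal" in f:
            ds = f["signal"]
        else:
            names = [k for k in f if isinstance(f[k], h5py.Dataset)
                     and f[k].ndim == 2]
            if not names:
                raise ValueError(f"no 2-D dataset found in {path}")
            ds = f[names[0]]
        fs = ds.attrs.get("sample_rate", f.attrs.get("sample_rate"))
        if fs is None:
            raise ValueError(f"{path} carries no sample_rate attribute")
        return np.asarray(ds), float(fs)


def write_recording(path: str | Path, signal: np.ndarray, fs: float,
                    config: dict | None = None,
                    extra_attrs: dict | None = None) -> None:
    """Write a (channels, samples) recording with provenance attributes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=np.asarray(signal))
        ds.attrs["sample_rate"] = float(fs)
        ds.attrs["package_version"] = __version__
        if config is not None:
            ds.attrs["config_hash"] = config_hash(config)
        for key, val in (extra_attrs or {}).items():
            ds.attrs[key] = val


def write_features(path: str | Path, features: FeatureTensor) -> None:
    """Persist a feature tensor with labels, lengths and band names."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features.values)
        f.create_dataset("trial_lengths", data=features.trial_lengths)
        if features.labels is not None:
            f.create_dataset("labels", data=features.labels)
        if features.subject_ids is not None:
            f.create_dataset("subject_ids", data=features.subject_ids)
        f.attrs["band_names"] = ",".join(features.band_names)
        f.attrs["package_version"] = __version__


def read_features(path: str | Path) -> FeatureTensor:
    with h5py.File(path, "r") as f:
        return FeatureTensor(
            values=np.asarray(f["features"]),
            trial_lengths=np.asarray(f["trial_lengths"]),
            labels=np.asarray(f["labels"]) if "labels" in f else None,
            subject_ids=(np.asarray(f["subject_ids"])
                         if "subject_ids" in f else None),
            band_names=tuple(f.attrs["band_names"].split(",")),
        )


def write_tracker_diagnostics(path: str | Path, spectrogram,
                              params=None) -> None:
    """Run the noise tracker over a spectrogram and dump traces to HDF5.

    Writes per-(frame, bin) signal-presence probabilities and the real
    trace of the tracked noise covariance — the quantities one inspects
    when tuning the tracker on a new recording setup.
    """
    from dataclasses import asdict

    from .mcra import McraParams, iter_tracker

    params = params or McraParams()
    spps, traces = [], []
    for _, r_nn, spp in iter_tracker(spectrogram, params):
        spps.append(spp)
        traces.append(np.real(np.trace(r_nn, axis1=-2, axis2=-1)))
    with h5py.File(path, "w") as f:
        f.create_dataset("spp", data=np.stack(spps))
        f.create_dataset("noise_trace", data=np.stack(traces))
        f.attrs["package_version"] = __version__
        f.attrs["mcra_config_hash"] = config_hash(asdict(params))


def save_model(path: str | Path, model, config: dict | None = None) -> None:
    """Checkpoint a trained model's parameters to a portable .npz container."""
    state = model.state_dict()
    meta = {
        "__input_mean__": np.float64(model.input_mean),
        "__input_std__": np.float64(model.input_std),
    }
    np.savez(path, __config_hash__=config_hash(config or {}),
             __package_version__=__version__, **meta, **state)


def load_model(path: str | Path, model):
    """Restore parameters saved by :func:`save_model` into a matching model."""
    with np.load(path, allow_pickle=False) as data:
        state = {k: data[k] for k in data.files if not k.startswith("__")}
        model.load_state_dict(state)
        model.input_mean = float(data["__input_mean__"])
        model.input_std = float(data["__input_std__"])
    return model


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Trial label table (columns trial_id, subject_id, session, label)."""
    df = pd.read_csv(path)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return df
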