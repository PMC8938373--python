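"""Hierarchical binary container (HDF5) for the pipeline's array-bearing objects.

Each file stores named arrays plus a JSON metadata block and a version tag;
tables (events, trial metadata) are embedded as JSON with a schema so dtypes
round-trip.  Write-then-read returns a structurally identical object with
bit-identical arrays.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .erp import Evoked
from .ica import CleaningMontage, ICAModel
from .preprocess import ContinuousRecording, EpochSet

CONTAINER_VERSION = 1


class ContainerError(ValueError):
    """Malformed, truncated, or version-incompatible container file."""


def _write_frame(g: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g.create_dataset(name, data=np.bytes_(df.to_json(orient="table")))


def _read_frame(g: h5py.Group, name: str) -> pd.DataFrame:
    raw = bytes(g[name][()]).decode()
    df = pd.read_json(io.StringIO(raw), orient="table")
    return df.reset_index(drop=True)


def save_container(obj, path) -> Path:
    """Write a supported dataset object to ``path``; returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["container_version"] = CONTAINER_VERSION
        if isinstance(obj, ContinuousRecording):
            f.attrs["kind"] = "ContinuousRecording"
            f.attrs["metadata"] = json.dumps(
                dict(sfreq=obj.sfreq, ch_names=list(obj.ch_names))
            )
            f.create_dataset("data", data=obj.data)
            _write_frame(f, "events", obj.events)
        elif isinstance(obj, EpochSet):
            f.attrs["kind"] = "EpochSet"
            f.attrs["metadata"] = json.dumps(
                dict(sfreq=obj.sfreq, ch_names=list(obj.ch_names), tmin_ms=obj.tmin_ms)
            )
            f.create_dataset("data", data=obj.data)
            f.create_dataset("valid", data=obj.valid)
            _write_frame(f, "trial_metadata", obj.metadata)
        elif isinstance(obj, ICAModel):
            f.attrs["kind"] = "ICAModel"
            f.attrs["metadata"] = json.dumps(
                dict(ch_names=list(obj.ch_names), n_components=obj.n_components,
                     seed=obj.seed, removed=list(obj.removed), notes=list(obj.notes))
            )
            for name in ("unmixing", "mixing", "mean", "sources"):
                f.create_dataset(name, data=getattr(obj, name))
            if obj.suspects is not None:
                f.create_dataset("suspects", data=obj.suspects)
            for prefix, d in (("corr", obj.corr), ("z", obj.zscores)):
                for k, v in d.items():
                    f.create_dataset(f"{prefix}_{k}", data=v)
        elif isinstance(obj, CleaningMontage):
            f.attrs["kind"] = "CleaningMontage"
            f.attrs["metadata"] = json.dumps(
                dict(ch_names=list(obj.ch_names), bad_channels=list(obj.bad_channels),
                     provenance=obj.provenance)
            )
            for name in ("removal", "interpolation", "composed"):
                f.create_dataset(name, data=getattr(obj, name))
        elif isinstance(obj, Evoked):
            f.attrs["kind"] = "Evoked"
            f.attrs["metadata"] = json.dumps(
                dict(condition=obj.condition, ch_names=list(obj.ch_names),
                     n_trials=obj.n_trials)
            )
            f.create_dataset("data", data=obj.data)
            f.create_dataset("times_ms", data=obj.times_ms)
        else:
            raise TypeError(f"unsupported object type {type(obj).__name__}")
    return path


def load_container(path):
    """Read a container written by :func:`save_container`."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise ContainerError(f"cannot open container {path}: {e}") from e
    with f:
        if "container_version" not in f.attrs:
            raise ContainerError("missing 'container_version' attribute")
        if int(f.attrs["container_version"]) != CONTAINER_VERSION:
            raise ContainerError(
                f"container version {f.attrs['container_version']} != {CONTAINER_VERSION}"
            )
        if "kind" not in f.attrs:
            raise ContainerError("missing 'kind' attribute")
        if "metadata" not in f.attrs:
            raise ContainerError("missing 'metadata' block")
        kind = str(f.attrs["kind"])
        meta = json.loads(f.attrs["metadata"])
        try:
            if kind == "ContinuousRecording":
                return ContinuousRecording(meta["sfreq"], list(meta["ch_names"]),
                                           f["data"][()], _read_frame(f, "events"))
            if kind == "EpochSet":
                return EpochSet(meta["sfreq"], list(meta["ch_names"]), meta["tmin_ms"],
                                f["data"][()], _read_frame(f, "trial_metadata"),
                                f["valid"][()])
            if kind == "ICAModel":
                m = ICAModel(
                    ch_names=list(meta["ch_names"]), n_components=meta["n_components"],
                    unmixing=f["unmixing"][()], mixing=f["mixing"][()],
                    mean=f["mean"][()], sources=f["sources"][()], seed=meta["seed"],
                    removed=list(meta["removed"]), notes=list(meta["notes"]),
                )
                if "suspects" in f:
                    m.suspects = f["suspects"][()].astype(bool)
                for key in f:
                    if key.startswith("corr_"):
                        m.corr[key[5:]] = f[key][()]
                    elif key.startswith("z_"):
                        m.zscores[key[2:]] = f[key][()]
                return m
            if kind == "CleaningMontage":
                return CleaningMontage(
                    ch_names=list(meta["ch_names"]), removal=f["removal"][()],
                    interpolation=f["interpolation"][()], composed=f["composed"][()],
                    bad_channels=list(meta["bad_channels"]),
                    provenance=meta["provenance"],
                )
            if kind == "Evoked":
                return Evoked(meta["condition"], list(meta["ch_names"]),
                              f["data"][()], f["times_ms"][()], meta["n_trials"])
        except KeyError as e:
            raise ContainerError(f"container missing block {e}") from e
    raise ContainerError(f"unknown container kind {kind!r}")


def import_bdf(path) -> ContinuousRecording:
    """Import a BioSemi BDF recording (microvolt scaling, no events required)."""
    import mne

    raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return ContinuousRecording(float(raw.info["sfreq"]), list(raw.ch_names), data)
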