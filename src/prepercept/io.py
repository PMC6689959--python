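"""HDF5 / CSV serialization of epochs and analysis results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivitySpectrum
from .decoding import DecodingResult
from .simulate import TrialEpochs

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_labels_csv",
    "write_decoding",
    "read_decoding",
    "connectivity_to_frame",
    "write_json",
]


def write_epochs(path: str | Path, epochs: TrialEpochs) -> None:
    """Write a TrialEpochs container: datasets ``data``, ``time_s``, ``labels``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, dtype="f8")
        f.create_dataset("time_s", data=epochs.time_s, dtype="f8")
        f.create_dataset(
            "labels", data=np.asarray(epochs.labels, dtype=h5py.string_dtype("utf-8"))
        )
        f.attrs["sample_rate"] = epochs.sample_rate
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["channel_kind"] = epochs.channel_kind
        if epochs.channel_names is not None:
            f.attrs["channel_names"] = list(epochs.channel_names)


def read_epochs(path: str | Path) -> TrialEpochs:
    with h5py.File(path, "r") as f:
        names = f.attrs.get("channel_names")
        return TrialEpochs(
            f["data"][()],
            f["time_s"][()],
            np.array([s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]),
            float(f.attrs["sample_rate"]),
            str(f.attrs["channel_kind"]),
            str(f.attrs["subject_id"]),
            tuple(names) if names is not None else None,
        )


def write_labels_csv(path: str | Path, epochs: TrialEpochs) -> None:
    pd.DataFrame({"trial": np.arange(epochs.n_trials), "label": epochs.labels}).to_csv(
        path, index=False
    )


def write_decoding(path: str | Path, result: DecodingResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times_s", data=result.times_s)
        f.create_dataset("auc", data=result.auc)
        f.create_dataset("weights", data=result.weights)
        if result.patterns is not None:
            f.create_dataset("patterns", data=result.patterns)
        f.create_dataset("fold_assignment", data=result.fold_assignment)


def read_decoding(path: str | Path) -> DecodingResult:
    with h5py.File(path, "r") as f:
        return DecodingResult(
            f["times_s"][()],
            f["auc"][()],
            f["weights"][()],
            f["patterns"][()] if "patterns" in f else None,
            f["fold_assignment"][()],
        )


def connectivity_to_frame(spectra: list[ConnectivitySpectrum]) -> pd.DataFrame:
    """Tidy table: subject, condition, freq_hz, measure, value."""
    rows = []
    for cs in spectra:
        for measure, values in (
            ("coherence", cs.coherence),
            ("imag_coherency", cs.imag_coherency),
            ("granger_ff", cs.granger_ff),
            ("granger_fb", cs.granger_fb),
        ):
            for f, v in zip(cs.freqs_hz, values):
                rows.append((cs.subject_id, cs.condition, float(f), measure, float(v)))
    return pd.DataFrame(rows, columns=["subject", "condition", "freq_hz", "measure", "value"])


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
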