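"""Readers and writers for recordings, feature matrices and results.

Recordings travel as HDF5: datasets ``/eeg`` (Q x samples) and ``/emg``
(M x samples), root attributes ``fs`` and ``subject_id``, label datasets
``/eeg_labels`` and ``/emg_labels``, and a ``/trials`` group holding the
per-trial, per-EMG-channel ``onsets`` (seconds) and ``classes``.  Trials
may instead be supplied as a CSV manifest with one row per trial: a
``class`` column plus one ``onset_<emg label>`` column per EMG channel.

Feature matrices travel as a CSV (one row per trial; first columns
``subject``/``label``, then one column per feature, named
``<muscle>_<channel>_<band>``) with a JSON sidecar recording the layout
(M, Q, band scheme, channel labels) so the index map round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coherence import BandScheme, FeatureMatrix
from .preprocessing import Recording


# ------------------------------------------------------------ recordings ---

def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("eeg", data=rec.eeg)
        fh.create_dataset("emg", data=rec.emg)
        fh.attrs["fs"] = rec.fs
        fh.attrs["subject_id"] = rec.subject_id
        fh.create_dataset("eeg_labels", data=[s.encode() for s in rec.eeg_labels])
        fh.create_dataset("emg_labels", data=[s.encode() for s in rec.emg_labels])
        g = fh.create_group("trials")
        g.create_dataset("onsets", data=rec.onsets)
        g.create_dataset("classes", data=np.asarray(rec.trial_classes, dtype=int))


def read_recording(path, trial_manifest=None) -> Recording:
    """Read an HDF5 recording; trials from ``/trials`` or a CSV manifest."""
    with h5py.File(path, "r") as fh:
        for name in ("eeg", "emg", "eeg_labels", "emg_labels"):
            if name not in fh:
                raise KeyError(f"recording file {path} is missing dataset /{name}")
        eeg = fh["eeg"][()]
        emg = fh["emg"][()]
        fs = float(fh.attrs["fs"])
        subject = str(fh.attrs.get("subject_id", Path(path).stem))
        eeg_labels = tuple(s.decode() for s in fh["eeg_labels"][()])
        emg_labels = tuple(s.decode() for s in fh["emg_labels"][()])
        if trial_manifest is None:
            if "trials" not in fh:
                raise KeyError(
                    f"recording file {path} has no /trials group and no "
                    "manifest was provided"
                )
            onsets = fh["trials/onsets"][()]
            classes = fh["trials/classes"][()]
        else:
            onsets, classes = read_trial_manifest(trial_manifest, emg_labels)
    return Recording(
        eeg=eeg, emg=emg, fs=fs, eeg_labels=eeg_labels, emg_labels=emg_labels,
        onsets=onsets, trial_classes=classes, subject_id=subject,
    )


def read_trial_manifest(path, emg_labels) -> tuple[np.ndarray, np.ndarray]:
    """CSV manifest -> (onsets (n, M), classes (n,))."""
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise KeyError("trial manifest must have a 'class' column")
    cols = [f"onset_{m}" for m in emg_labels]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"trial manifest is missing onset columns: {missing}")
    return df[cols].to_numpy(dtype=float), df["class"].to_numpy(dtype=int)


def write_trial_manifest(path, rec: Recording) -> None:
    df = pd.DataFrame(
        {"class": np.asarray(rec.trial_classes, dtype=int)}
        | {f"onset_{m}": rec.onsets[:, i] for i, m in enumerate(rec.emg_labels)}
    )
    df.to_csv(path, index=False)


# -------------------------------------------------------- feature matrix ---

def write_feature_matrix(csv_path, fm: FeatureMatrix, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    df = pd.DataFrame(fm.values, columns=fm.column_names())
    df.insert(0, "label", fm.labels)
    df.insert(0, "subject", fm.subject_ids)
    df.to_csv(csv_path, index=False)
    meta = {
        "M": fm.M,
        "Q": fm.Q,
        "bands": [[n, lo, hi] for n, lo, hi in fm.scheme.bands],
        "emg_labels": list(fm.emg_labels),
        "eeg_labels": list(fm.eeg_labels),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def read_feature_matrix(csv_path, sidecar_path=None) -> FeatureMatrix:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    scheme = BandScheme(tuple((n, float(lo), float(hi)) for n, lo, hi in meta["bands"]))
    df = pd.read_csv(csv_path)
    return FeatureMatrix(
        values=df.drop(columns=["subject", "label"]).to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
        subject_ids=df["subject"].to_numpy(dtype=str),
        M=int(meta["M"]),
        Q=int(meta["Q"]),
        scheme=scheme,
        emg_labels=tuple(meta["emg_labels"]),
        eeg_labels=tuple(meta["eeg_labels"]),
    )
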