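"""Readers and writers for the package's on-disk formats.

Native recording format: a plain TSV sample matrix (channels as columns,
one row per time point, microvolts) plus a YAML sidecar header carrying
sampling rate, labels, condition and subject id.  EDF and BrainVision
recordings are read through MNE when it is installed (optional extra
``taugraph[eeg-io]``); channel labels are preserved verbatim.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix
from .preprocess import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "read_recording_edf",
    "read_recording_brainvision",
    "write_epochs",
    "read_epochs",
    "write_adjacency",
    "read_adjacency",
]


def write_recording(rec: Recording, path_prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (samples) and ``<prefix>.yaml`` (header)."""
    prefix = Path(path_prefix)
    tsv = prefix.with_suffix(".tsv")
    hdr = prefix.with_suffix(".yaml")
    pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels)).to_csv(
        tsv, sep="\t", index=False, float_format="%.6f")
    with open(hdr, "w") as fh:
        yaml.safe_dump(
            {"fs": float(rec.fs), "condition": rec.condition,
             "subject_id": rec.subject_id,
             "channel_labels": list(rec.channel_labels),
             "unit": "uV"},
            fh, sort_keys=False)
    return tsv, hdr


def read_recording(path_prefix) -> Recording:
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".yaml")) as fh:
        hdr = yaml.safe_load(fh)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    labels = hdr["channel_labels"]
    return Recording(samples=df[labels].to_numpy().T, fs=float(hdr["fs"]),
                     channel_labels=labels, condition=hdr["condition"],
                     subject_id=hdr.get("subject_id", ""))


def _require_mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extra
        raise ImportError(
            "reading EDF/BrainVision requires mne; install taugraph[eeg-io]"
        ) from exc
    return mne


def _from_mne_raw(raw, condition: str, subject_id: str) -> Recording:
    data = raw.get_data(units="uV") if hasattr(raw, "get_data") else raw.get_data()
    return Recording(samples=np.asarray(data), fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), condition=condition,
                     subject_id=subject_id)


def read_recording_edf(path, condition: str = "eyes_closed",
                       subject_id: str = "") -> Recording:
    mne = _require_mne()
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _from_mne_raw(raw, condition, subject_id)


def read_recording_brainvision(vhdr_path, condition: str = "eyes_closed",
                               subject_id: str = "") -> Recording:
    mne = _require_mne()
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return _from_mne_raw(raw, condition, subject_id)


def write_epochs(ep, path) -> Path:
    """Compressed epoched-data container (.npz): the epochs x channels x
    time array plus sampling rate, labels and epoch length."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(
        path, data=ep.data, fs=ep.fs, epoch_length_s=ep.epoch_length_s,
        channel_labels=np.array(list(ep.channel_labels)),
        condition=ep.condition, subject_id=ep.subject_id)
    return path


def read_epochs(path):
    from .preprocess import EpochedData

    with np.load(Path(path), allow_pickle=False) as z:
        return EpochedData(
            data=z["data"], fs=float(z["fs"]),
            channel_labels=[str(c) for c in z["channel_labels"]],
            epoch_length_s=float(z["epoch_length_s"]),
            condition=str(z["condition"]), subject_id=str(z["subject_id"]))


def write_adjacency(W: ConnectivityMatrix, path) -> Path:
    """Square TSV with labels as header row and first column."""
    path = Path(path)
    df = pd.DataFrame(W.W, index=list(W.channel_labels),
                      columns=list(W.channel_labels))
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_adjacency(path, band=(8.0, 13.0), condition="eyes_closed",
                   subject_id: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(W=df.to_numpy(), channel_labels=list(df.columns),
                              band=tuple(band), condition=condition,
                              subject_id=subject_id)
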