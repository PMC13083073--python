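"""Event-locked epoch container and its on-disk archive format.

An :class:`EpochArray` holds one subject's trials for one condition and band
context as a ``trial x channel x sample`` array. Sample indexing is 0-based
with half-open windows ``[start, end)``; ``onset_index`` marks t = 0.

The packaged archive is one ``.npz`` file per container: the raw float64
array under ``data`` plus a JSON metadata block under ``meta`` — it
round-trips bit-exactly. Vendor recordings (BrainVision, EDF+) are read
through :mod:`mne` and epoched with :func:`epochs_from_raw`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

GROUPS = ("HC", "PD_MCI", "PDD", "DLB")
CONDITIONS = ("target", "nontarget")
BAND_CONTEXTS = ("delta", "theta")

#: analysis window in seconds around stimulus onset, per band context
CONTEXT_WINDOWS = {"delta": (-3.0, 3.0), "theta": (-1.0, 1.0)}


def context_n_samples(band_context: str, fs: float) -> int:
    lo, hi = CONTEXT_WINDOWS[band_context]
    return int(round((hi - lo) * fs))


@dataclass
class EpochArray:
    subject_id: str
    group: str
    condition: str
    band_context: str
    fs: float
    data: np.ndarray  # (n_trials, n_channels, n_samples)
    onset_index: int
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.band_context not in BAND_CONTEXTS:
            raise ValueError(f"unknown band context {self.band_context!r}")
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trial x channel x sample")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one trial")
        expected = context_n_samples(self.band_context, self.fs)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"{self.band_context} context at {self.fs} Hz requires {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length must match channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time in seconds relative to stimulus onset."""
        return (np.arange(self.data.shape[2]) - self.onset_index) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def with_data(self, data: np.ndarray) -> "EpochArray":
        return replace(self, data=np.asarray(data, dtype=np.float64))


def write_epochs(epochs: EpochArray, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "condition": epochs.condition,
        "band_context": epochs.band_context,
        "fs": epochs.fs,
        "onset_index": epochs.onset_index,
        "channel_labels": epochs.channel_labels,
    }
    with open(path, "wb") as fh:
        np.savez(fh, data=epochs.data, meta=json.dumps(meta, sort_keys=True))
    return path


def read_epochs_archive(path: str | Path) -> EpochArray:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        data = npz["data"]
    return EpochArray(data=data, **meta)


def epochs_from_raw(
    raw,
    onsets: np.ndarray,
    band_context: str,
    *,
    subject_id: str,
    group: str,
    condition: str,
) -> EpochArray:
    """Cut an :class:`EpochArray` out of an mne Raw object at the given onset samples.

    Events whose window would cross the record bounds are dropped with a
    logged warning.
    """
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    from .preprocess import segment  # local import to avoid a cycle

    return segment(
        data,
        np.asarray(onsets, dtype=int),
        band_context,
        fs=fs,
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        group=group,
        condition=condition,
    )


def read_epochs(
    path: str | Path,
    format: str = "archive",
    *,
    band_context: str = "delta",
    subject_id: str = "",
    group: str = "HC",
    condition: str = "target",
    target_code: str | None = None,
) -> EpochArray:
    """Read epochs from the packaged archive or a vendor recording.

    For ``brainvision``/``edf`` the recording's annotations supply stimulus
    onsets; ``target_code`` selects the annotation description to epoch on
    (default: all annotations).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "archive":
        return read_epochs_archive(path)
    import mne

    if format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown epoch format {format!r}")
    ann = raw.annotations
    if len(ann) == 0:
        raise ValueError(f"no event markers found in {path}")
    mask = np.ones(len(ann), bool)
    if target_code is not None:
        mask = np.array([d == target_code for d in ann.description])
        if not mask.any():
            raise ValueError(f"no markers with code {target_code!r} in {path}")
    onsets = np.round(ann.onset[mask] * raw.info["sfreq"]).astype(int)
    return epochs_from_raw(
        raw, onsets, band_context, subject_id=subject_id, group=group, condition=condition
    )
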