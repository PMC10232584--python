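"""Epoched multichannel recordings and their plain-text serialization.

An :class:`EpochSet` is the unit of exchange between the simulation,
preprocessing, spectral and connectivity stages: a stack of fixed-length
multichannel voltage epochs for one participant and one condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EpochSet", "write_epochs_txt", "read_epochs_txt"]


@dataclass
class EpochSet:
    """Fixed-length multichannel epochs for one participant/condition.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel (or region) labels, one per channel axis entry.
    participant : str
        Participant identifier.
    condition : str
        Condition label, e.g. ``"control"`` or ``"negative"``.
    epoch_onset_s : float
        Time of the first sample relative to the trigger (default −0.2 s).
    ground_truth : dict
        Optional generator-side ground truth (realized envelope
        correlations, band amplitudes, ...) carried alongside the data.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    participant: str = "P00"
    condition: str = "control"
    epoch_onset_s: float = -0.2
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_epochs, n_channels, n_samples), got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[1]} channels but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the trigger."""
        return self.epoch_onset_s + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the (n_epochs, n_samples) data of one channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channel_labels}") from None
        return self.data[:, idx, :]

    def copy_with(self, **kwargs) -> "EpochSet":
        return replace(self, **kwargs)


def write_epochs_txt(es: EpochSet, path: str | Path) -> None:
    """Write an EpochSet as a delimited text file plus a JSON sidecar.

    The data file holds one row per (epoch, channel) pair with the samples
    as columns — axis order epoch-major, channel-minor.  Metadata (fs,
    labels, shape, ground truth) goes to ``<path>.json``.
    """
    path = Path(path)
    flat = es.data.reshape(es.n_epochs * es.n_channels, es.n_samples)
    np.savetxt(path, flat, fmt="%.8g", delimiter="\t")
    meta = {
        "n_epochs": es.n_epochs,
        "n_channels": es.n_channels,
        "n_samples": es.n_samples,
        "fs": es.fs,
        "channel_labels": es.channel_labels,
        "participant": es.participant,
        "condition": es.condition,
        "epoch_onset_s": es.epoch_onset_s,
        "ground_truth": _jsonable(es.ground_truth),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_epochs_txt(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs_txt`."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    flat = np.loadtxt(path, delimiter="\t", ndmin=2)
    data = flat.reshape(meta["n_epochs"], meta["n_channels"], meta["n_samples"])
    return EpochSet(
        data=data,
        fs=meta["fs"],
        channel_labels=list(meta["channel_labels"]),
        participant=meta["participant"],
        condition=meta["condition"],
        epoch_onset_s=meta["epoch_onset_s"],
        ground_truth=meta.get("ground_truth", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
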