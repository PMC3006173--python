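"""Trial-epoched data model and its HDF5 container.

A recording session is stored as one HDF5 file::

    /lfp           float32 [trials, channels, samples]
    /labels        int16   [trials]           direction class index 0..K-1
    /channel_mask  uint8   [channels]         optional; 1 = usable
    /spikes/unit<k>/trial<j>  float32 arrays  optional; spike times, ms
    attrs: fs (Hz), alignment, t0_ms, session_id

Direction is stored as a class index; the angle of class ``k`` is
``k * 360 / K`` degrees with 0 deg = +x, counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List

import h5py
import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "TrialSet",
    "SpikeSet",
    "read_trialset",
    "write_trialset",
    "screen_line_noise",
]


@dataclass
class TrialSet:
    """Epoched multichannel signal with per-trial direction labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltage traces (arbitrary scale).
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, shape (n_trials,)
        Direction class index in ``[0, n_classes)``.
    alignment : str
        Name of the event sample 0 is referenced to
        (``"cue_onset"`` or ``"movement_onset"``).
    t0_ms : float
        Time of the first sample relative to the alignment event, ms.
    channel_mask : ndarray of bool, shape (n_channels,)
        True for channels usable in analysis.
    session_id : int
    n_classes : int
        Number of direction classes (8 targets spaced 45 deg by default).
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    alignment: str = "movement_onset"
    t0_ms: float = 0.0
    channel_mask: np.ndarray | None = None
    session_id: int = 0
    n_classes: int = 8

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        self.validate()

    # shape helpers -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def angles(self) -> np.ndarray:
        """Per-trial direction angle in radians."""
        return self.labels * (2.0 * np.pi / self.n_classes)

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError("data must be [trials, channels, samples]")
        if self.labels.shape != (self.data.shape[0],):
            raise ValidationError(
                f"labels length {self.labels.shape} does not match "
                f"n_trials {self.data.shape[0]}"
            )
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValidationError(
                f"labels must lie in [0, {self.n_classes})"
            )
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.channel_mask.shape != (self.data.shape[1],):
            raise ValidationError("channel_mask length must equal n_channels")

    def with_mask(self, mask: np.ndarray) -> "TrialSet":
        return replace(self, channel_mask=np.asarray(mask, dtype=bool))


@dataclass
class SpikeSet:
    """Sorted spike times per unit per trial, ms relative to the alignment event."""

    units: List[List[np.ndarray]]  # units[u][trial] -> sorted times (ms)
    labels: np.ndarray
    alignment: str = "movement_onset"
    session_id: int = 0
    n_classes: int = 8

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return self.labels.size

    def angles(self) -> np.ndarray:
        return self.labels * (2.0 * np.pi / self.n_classes)

    def validate(self) -> None:
        for u, trials in enumerate(self.units):
            if len(trials) != self.labels.size:
                raise ValidationError(
                    f"unit {u} has {len(trials)} trials, expected {self.labels.size}"
                )
            for j, t in enumerate(trials):
                t = np.asarray(t)
                if t.size > 1 and np.any(np.diff(t) < 0):
                    raise ValidationError(
                        f"spike times not sorted in unit {u} trial {j}"
                    )
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValidationError(f"labels must lie in [0, {self.n_classes})")


# ------------------------------------------------------------------
# HDF5 round trip
# ------------------------------------------------------------------

_REQUIRED_ATTRS = ("fs", "alignment", "t0_ms", "session_id")


def write_trialset(T: TrialSet, path, spikes: SpikeSet | None = None):
    """Write a validated :class:`TrialSet` (and optional spikes) to *path*."""
    T.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=T.data.astype(np.float32))
        f.create_dataset("labels", data=T.labels.astype(np.int16))
        f.create_dataset("channel_mask", data=T.channel_mask.astype(np.uint8))
        f.attrs["fs"] = float(T.fs)
        f.attrs["alignment"] = T.alignment
        f.attrs["t0_ms"] = float(T.t0_ms)
        f.attrs["session_id"] = int(T.session_id)
        f.attrs["n_classes"] = int(T.n_classes)
        if spikes is not None:
            g = f.create_group("spikes")
            for u, trials in enumerate(spikes.units):
                gu = g.create_group(f"unit{u}")
                for j, t in enumerate(trials):
                    gu.create_dataset(
                        f"trial{j}", data=np.asarray(t, dtype=np.float32)
                    )
    return path


def read_trialset(path) -> TrialSet:
    """Read and validate a :class:`TrialSet` from an HDF5 session file."""
    with h5py.File(path, "r") as f:
        for name in ("lfp", "labels"):
            if name not in f:
                raise FormatError(f"missing required dataset '{name}'")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"missing required attribute '{name}'")
        data = f["lfp"][()]
        labels = f["labels"][()]
        mask = f["channel_mask"][()].astype(bool) if "channel_mask" in f else None
        return TrialSet(
            data=data,
            fs=float(f.attrs["fs"]),
            labels=labels,
            alignment=str(f.attrs["alignment"]),
            t0_ms=float(f.attrs["t0_ms"]),
            channel_mask=mask,
            session_id=int(f.attrs["session_id"]),
            n_classes=int(f.attrs.get("n_classes", 8)),
        )


def read_spikeset(path) -> SpikeSet:
    """Read the optional /spikes group of a session file."""
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise FormatError("file has no /spikes group")
        labels = f["labels"][()]
        g = f["spikes"]
        units = []
        for u in range(len(g)):
            gu = g[f"unit{u}"]
            units.append([gu[f"trial{j}"][()] for j in range(len(gu))])
        return SpikeSet(
            units=units,
            labels=labels,
            alignment=str(f.attrs["alignment"]),
            session_id=int(f.attrs["session_id"]),
            n_classes=int(f.attrs.get("n_classes", 8)),
        )


# ------------------------------------------------------------------
# Channel screening
# ------------------------------------------------------------------

def screen_line_noise(
    T: TrialSet, line_freq: float = 60.0, ratio_threshold: float = 10.0
) -> np.ndarray:
    """Flag channels dominated by power-line noise.

    A channel is marked unusable when its mean power within
    ``line_freq +/- 1`` Hz exceeds ``ratio_threshold`` times its median
    broadband power. Channels already masked false stay false — the
    screen only removes channels, never restores them.

    Returns the new boolean mask (does not modify *T*).
    """
    if not line_freq < T.fs / 2:
        raise ValidationError("line_freq must be below Nyquist")
    from scipy.signal import welch

    mask = T.channel_mask.copy()
    # average periodogram over trials per channel
    nper = min(T.n_samples, int(T.fs))  # ~1 Hz resolution
    f, pxx = welch(T.data, fs=T.fs, nperseg=nper, axis=-1)
    pxx = pxx.mean(axis=0)  # channels x freqs
    band = (f >= line_freq - 1.0) & (f <= line_freq + 1.0)
    line_power = pxx[:, band].mean(axis=1)
    broadband = np.median(pxx, axis=1)
    flagged = line_power > ratio_threshold * broadband
    mask[flagged] = False
    return mask
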