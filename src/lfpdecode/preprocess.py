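"""Sub-band decomposition of trial-epoched LFP.

The pipeline converts raw 1 kHz trial tensors into per-band amplitude or
envelope tensors at 100 Hz:

1. subtract the per-trial, per-channel mean (removes DC offsets);
2. if the input is above 500 Hz, low-pass at 220 Hz and decimate to 500 Hz;
3. band-pass with a linear-phase Blackman-window FIR applied forward only,
   the group delay removed by advancing the output by N/2 samples;
4. for bands above the delta range, take the Hilbert-transform envelope;
5. low-pass at 30 Hz (anti-alias) and decimate to 100 Hz.

The window method puts the -6 dB point of the FIR response on the cutoff
frequency at any order, so the order only controls the transition width.
Default orders per band are chosen so the filter fits inside a few-second
trial epoch; the 0.3 Hz lower edge of the delta band is too close to DC to
be resolved by any epoch-length filter and is instead covered by the
recording chain's high-pass together with trial-mean removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError
from .io import TrialSet

__all__ = [
    "SubBandSpec",
    "SubbandTensor",
    "default_bands",
    "remove_trial_mean",
    "design_bandpass",
    "filter_zero_phase",
    "hilbert_envelope",
    "preprocess_subband",
    "preprocess_bands",
    "time_frequency_map",
]

FS_OUT = 100.0  # final feature-domain rate, Hz
FS_MID = 500.0  # rate at which the band-pass runs, Hz
ANTIALIAS_HZ = 30.0
STAGE1_LOWPASS_HZ = 220.0
_STAGE_LP_ORDER = 100  # taps of the 30 Hz / 220 Hz low-pass stages


@dataclass(frozen=True)
class SubBandSpec:
    """One analysis band.

    ``filter_order`` is the FIR order N (even; the filter has N+1 taps).
    When None the order follows the Blackman main-lobe rule
    ``N = ceil_even(5.5 * fs / df)`` with transition width
    ``df = min(high - low, max(0.2 * low, 2 Hz))``.
    """

    low: float
    high: float
    use_envelope: bool = True
    filter_order: int | None = None
    name: str = ""

    def validated(self, fs: float) -> "SubBandSpec":
        if not (0 < self.low < self.high < fs / 2):
            raise ConfigurationError(
                f"band {self.name or (self.low, self.high)} invalid for fs={fs}"
            )
        if self.filter_order is not None and (
            self.filter_order < 2 or self.filter_order % 2
        ):
            raise ConfigurationError("filter_order must be even and >= 2")
        return self


def default_bands() -> List[SubBandSpec]:
    """The five analysis bands; only the delta band keeps raw amplitude.

    Orders are for the 500 Hz band-pass stage.
    """
    return [
        SubBandSpec(0.3, 4.0, use_envelope=False, filter_order=744, name="delta"),
        SubBandSpec(4.0, 10.0, use_envelope=True, filter_order=500, name="theta"),
        SubBandSpec(14.0, 22.0, use_envelope=True, filter_order=700, name="beta1"),
        SubBandSpec(22.0, 30.0, use_envelope=True, filter_order=700, name="beta2"),
        SubBandSpec(48.0, 200.0, use_envelope=True, filter_order=300, name="gamma"),
    ]


def informative_bands() -> List[SubBandSpec]:
    """Delta + high-gamma, the two bands that carry directional information."""
    b = default_bands()
    return [b[0], b[4]]


def bands_from_config(cfg: Sequence[dict]) -> List[SubBandSpec]:
    """Build band specs from a JSON-style list of dicts."""
    out = []
    for d in cfg:
        out.append(
            SubBandSpec(
                low=float(d["low"]),
                high=float(d["high"]),
                use_envelope=bool(d.get("envelope", True)),
                filter_order=d.get("order"),
                name=str(d.get("name", f"{d['low']}-{d['high']}Hz")),
            )
        )
    return out


@dataclass
class SubbandTensor:
    """Per-band preprocessed tensor at 100 Hz.

    ``edge_ms`` is the span at each end of the epoch still influenced by
    filter transients (total group delay of all FIR stages); feature
    windows should avoid it when the epoch allows.
    """

    data: np.ndarray  # trials x channels x samples(100 Hz)
    fs_out: float
    band: SubBandSpec
    t0_ms: float
    channel_indices: np.ndarray  # original channel index per row
    edge_ms: float = 0.0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def sample_index(self, t_ms: float) -> int:
        """Index of the output sample closest to *t_ms* (alignment-relative)."""
        return int(round((t_ms - self.t0_ms) * self.fs_out / 1000.0))

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        i0 = self.sample_index(start_ms)
        i1 = self.sample_index(end_ms)
        if i0 < 0 or i1 > self.n_samples or i1 - i0 < 2:
            raise ValidationError(
                f"window [{start_ms}, {end_ms}] ms outside epoch "
                f"[{self.t0_ms}, {self.t0_ms + 1000 * self.n_samples / self.fs_out}] ms"
            )
        return slice(i0, i1)

    def select_trials(self, idx) -> "SubbandTensor":
        return replace(self, data=self.data[idx])


# ------------------------------------------------------------------
# primitive operations
# ------------------------------------------------------------------

def remove_trial_mean(T: TrialSet) -> TrialSet:
    """Subtract each trial's per-channel mean (idempotent)."""
    data = T.data - T.data.mean(axis=-1, keepdims=True)
    return replace(T, data=data)


def _auto_order(band: SubBandSpec, fs: float) -> int:
    df = min(band.high - band.low, max(0.2 * band.low, 2.0))
    n = math.ceil(5.5 * fs / df)
    return n + (n % 2)


def design_bandpass(band: SubBandSpec, fs: float) -> np.ndarray:
    """Blackman-window linear-phase FIR band-pass; -6 dB at the cutoffs.

    Returns the N+1 symmetric coefficients. Raises
    :class:`ConfigurationError` when an explicit order is too small for
    the main lobe to fit inside the band (the passband would collapse).
    """
    band.validated(fs)
    N = band.filter_order if band.filter_order is not None else _auto_order(band, fs)
    n_min = math.ceil(5.5 * fs / (band.high - band.low))
    if N < n_min:
        raise ConfigurationError(
            f"order {N} too small for band {band.low}-{band.high} Hz at "
            f"fs={fs}; need at least {n_min + (n_min % 2)}"
        )
    return sps.firwin(
        N + 1, [band.low, band.high], window="blackman", pass_zero=False, fs=fs
    )


def _lowpass(cutoff: float, fs: float, order: int = _STAGE_LP_ORDER) -> np.ndarray:
    return sps.firwin(order + 1, cutoff, window="blackman", fs=fs)


def filter_zero_phase(x: np.ndarray, h: np.ndarray, N: int | None = None) -> np.ndarray:
    """Forward FIR pass with the N/2 group delay removed.

    The input is zero-padded, convolved in the forward direction only,
    and the output advanced by N/2 samples, so a linear-phase filter
    leaves passband components phase-aligned with the input. Output has
    the same length as the input. Works on the last axis of an
    n-dimensional array.
    """
    x = np.asarray(x)
    h = np.asarray(h, dtype=float)
    if N is None:
        N = h.size - 1
    n = x.shape[-1]
    if n <= N:
        raise ValidationError(f"signal length {n} must exceed filter order {N}")
    hh = h.reshape((1,) * (x.ndim - 1) + (-1,))
    if x.ndim == 1:
        hh = h
    y = sps.fftconvolve(x, hh, mode="full", axes=-1)
    return y[..., N // 2 : N // 2 + n]


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal along the last axis."""
    return np.abs(sps.hilbert(np.asarray(x, dtype=float), axis=-1))


# ------------------------------------------------------------------
# full per-band pipeline
# ------------------------------------------------------------------

def preprocess_subband(T: TrialSet, band: SubBandSpec) -> SubbandTensor:
    """Run one band through the full pipeline; masked-out channels dropped.

    Output sample count is ``ceil(n_samples * 100 / fs)``.
    """
    band.validated(min(T.fs, FS_MID))
    if T.fs < FS_MID:
        raise ConfigurationError(f"fs={T.fs} below the 500 Hz working rate")
    ch_idx = np.flatnonzero(T.channel_mask)
    if ch_idx.size == 0:
        raise ValidationError("no usable channels after masking")

    x = T.data[:, ch_idx, :].astype(np.float64)
    x = x - x.mean(axis=-1, keepdims=True)
    fs = T.fs
    edge = 0.0  # accumulated transient half-width, ms

    if fs > FS_MID:
        step = int(round(fs / FS_MID))
        if abs(fs / step - FS_MID) > 1e-9:
            raise ConfigurationError(f"fs={fs} is not an integer multiple of 500 Hz")
        h1 = _lowpass(STAGE1_LOWPASS_HZ, fs)
        x = filter_zero_phase(x, h1)
        x = x[..., ::step]
        fs = FS_MID
        edge += 1000.0 * (_STAGE_LP_ORDER / 2) / T.fs

    h = design_bandpass(band, fs)
    N = h.size - 1
    x = filter_zero_phase(x, h, N)
    edge += 1000.0 * (N / 2) / fs

    if band.use_envelope:
        x = hilbert_envelope(x)

    h2 = _lowpass(ANTIALIAS_HZ, fs)
    x = filter_zero_phase(x, h2)
    edge += 1000.0 * (_STAGE_LP_ORDER / 2) / fs
    step = int(round(fs / FS_OUT))
    x = x[..., ::step]

    return SubbandTensor(
        data=np.ascontiguousarray(x),
        fs_out=FS_OUT,
        band=band,
        t0_ms=T.t0_ms,
        channel_indices=ch_idx,
        edge_ms=edge,
    )


def preprocess_bands(T: TrialSet, bands: Sequence[SubBandSpec]) -> List[SubbandTensor]:
    """Preprocess every band of *bands* (trial order preserved)."""
    return [preprocess_subband(T, b) for b in bands]


# ------------------------------------------------------------------
# time-frequency maps
# ------------------------------------------------------------------

def time_frequency_map(
    T: TrialSet,
    baseline_window: tuple[float, float],
    channel: int,
    win_ms: float = 256.0,
    overlap: float = 0.75,
):
    """Baseline-normalized spectrogram of one channel, averaged over trials.

    Entry (f, t) is the percent power change relative to the mean
    baseline power at that frequency:
    ``100 * (P(f, t) - Pbar_base(f)) / Pbar_base(f)``.

    Returns ``(freqs, times_ms, map)`` where ``map`` is [freq x time].
    """
    nwin = int(round(win_ms * T.fs / 1000.0))
    nover = int(round(overlap * nwin))
    f, t, sxx = sps.spectrogram(
        T.data[:, channel, :], fs=T.fs, window="hann",
        nperseg=nwin, noverlap=nover, axis=-1,
    )
    p = sxx.mean(axis=0)  # freq x time, trial-averaged
    times_ms = T.t0_ms + 1000.0 * t
    b0, b1 = baseline_window
    in_base = (times_ms >= b0) & (times_ms <= b1)
    if not in_base.any():
        raise ValidationError("baseline window outside the epoch")
    base = p[:, in_base].mean(axis=1)
    if np.any(base <= 0):
        raise ValidationError("zero baseline power in at least one frequency bin")
    return f, times_ms, 100.0 * (p - base[:, None]) / base[:, None]
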