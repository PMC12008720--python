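"""Deterministic EEG signal conditioning.

Fixed pipeline order: resample -> average re-reference -> broadband
band-pass -> epoching -> (optional narrowband filtering).  All filters are
zero-phase (forward-backward), which is mandatory because phase-based
connectivity metrics are computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochedData",
    "PowerSpectrum",
    "clean_recording",
    "resample",
    "rereference_average",
    "bandpass",
    "epoch_recording",
    "welch_psd",
    "relative_band_power",
]

#: Canonical analysis bands (Hz).
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "broadband": (0.5, 40.0)}


@dataclass
class Recording:
    """One subject/condition multichannel EEG block.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Montage labels (10-5 system); must be unique.
    condition : str
        ``"eyes_closed"`` or ``"eyes_open"``.
    subject_id : str
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    condition: str = "eyes_closed"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] < 2:
            raise ValueError("a Recording requires at least 2 channels")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain NaN or infinite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        labels = list(self.channel_labels)
        if len(labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        self.channel_labels = labels

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochedData:
    """Non-overlapping, time-ordered fixed-length epochs.

    ``data`` has shape (n_epochs, n_channels, n_samples_per_epoch).
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    epoch_length_s: float
    band: str = "broadband"
    condition: str = "eyes_closed"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be 3-D (epochs x channels x time)")
        expected = int(round(self.epoch_length_s * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"each epoch must hold exactly {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        self.channel_labels = list(self.channel_labels)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class PowerSpectrum:
    """Welch power spectral density per channel (microvolt^2 / Hz)."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs), >= 0
    channel_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2 or self.power.shape[1] != self.frequencies.size:
            raise ValueError("power must be (n_channels, n_freqs)")
        if (self.power < 0).any():
            raise ValueError("power must be non-negative")


def clean_recording(rec: Recording, cleaner=None) -> Recording:
    """Artifact-removal hook.

    The pipeline itself performs no artifact detection (synthetic data are
    artifact-free and real recordings are expected pre-cleaned); a
    site-specific cleaner — e.g. an ICA-based routine — can be plugged in
    as a callable Recording -> Recording.  With no cleaner this is the
    identity.
    """
    if cleaner is None:
        return rec
    out = cleaner(rec)
    if not isinstance(out, Recording):
        raise TypeError("cleaner must return a Recording")
    return out


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase down-sampling to ``target_fs``.

    Upsampling is refused; ``target_fs == fs`` is the identity.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling requested ({rec.fs} -> {target_fs} Hz); only "
            "down-sampling is supported"
        )
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return replace(rec, samples=out, fs=float(target_fs))


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over channels (common average)."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return replace(rec, samples=out)


def _design_bandpass(lo: float, hi: float, fs: float, order: int) -> np.ndarray:
    if not (0 < lo < hi < fs / 2):
        raise ValueError(
            f"invalid band [{lo}, {hi}] Hz for sampling rate {fs} Hz"
        )
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: Recording, lo: float, hi: float, order: int = 6) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    sos = _design_bandpass(lo, hi, rec.fs, order)
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=out)


def bandpass_array(x: np.ndarray, lo: float, hi: float, fs: float,
                   order: int = 6, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass on a bare array (helper for epochs/synthesis)."""
    sos = _design_bandpass(lo, hi, fs, order)
    return signal.sosfiltfilt(sos, x, axis=axis)


def epoch_recording(rec: Recording, discard_s: float = 60.0,
                    epoch_s: float = 20.0) -> EpochedData:
    """Drop the first ``discard_s`` seconds, then cut whole non-overlapping
    ``epoch_s`` epochs; trailing remainder samples are discarded."""
    n_discard = int(round(discard_s * rec.fs))
    n_epoch = int(round(epoch_s * rec.fs))
    usable = rec.n_samples - n_discard
    if usable <= 0:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than the "
            f"{discard_s:.0f} s discard interval"
        )
    n_epochs = usable // n_epoch
    if n_epochs == 0:
        raise ValueError(
            f"no complete {epoch_s:.0f} s epoch fits into the "
            f"{usable / rec.fs:.1f} s remaining after the {discard_s:.0f} s discard"
        )
    x = rec.samples[:, n_discard:n_discard + n_epochs * n_epoch]
    data = x.reshape(rec.n_channels, n_epochs, n_epoch).transpose(1, 0, 2)
    return EpochedData(
        data=data, fs=rec.fs, channel_labels=rec.channel_labels,
        epoch_length_s=epoch_s, condition=rec.condition,
        subject_id=rec.subject_id,
    )


def welch_psd(ep: EpochedData, window_s: float = 0.5,
              overlap_frac: float = 0.5) -> PowerSpectrum:
    """Welch PSD with a Hamming taper, averaged over segments and epochs.

    Frequency resolution is 1/window_s (2 Hz at the 500 ms default).
    """
    nper = int(round(window_s * ep.fs))
    if nper < 8:
        raise ValueError("Welch window must span at least 8 samples")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    if nper > ep.data.shape[2]:
        raise ValueError(
            f"Welch window ({window_s} s) longer than the epoch "
            f"({ep.epoch_length_s} s)"
        )
    noverlap = int(round(overlap_frac * nper))
    freqs, pxx = signal.welch(
        ep.data, fs=ep.fs, window=signal.get_window("hamming", nper),
        nperseg=nper, noverlap=noverlap, detrend=False, axis=2,
        scaling="density",
    )
    return PowerSpectrum(
        frequencies=freqs, power=pxx.mean(axis=0),
        channel_labels=ep.channel_labels,
    )


def relative_band_power(ps: PowerSpectrum, band: tuple[float, float],
                        total: tuple[float, float] = (0.5, 40.0)) -> np.ndarray:
    """Band power divided by total-band power, per channel.

    Power is integrated as a df-weighted sum over the bins whose centers
    fall in the closed interval (each bin carries its full width, so a
    spectral peak sitting on a band-edge bin counts fully toward that
    band); the band must lie inside the total interval.
    """
    lo, hi = band
    tlo, thi = total
    if not (tlo <= lo < hi <= thi):
        raise ValueError(f"band {band} must be contained in total {total}")

    def _integrate(a: float, b: float) -> np.ndarray:
        m = (ps.frequencies >= a) & (ps.frequencies <= b)
        if m.sum() < 2:
            raise ValueError(
                f"fewer than two frequency bins fall inside [{a}, {b}] Hz"
            )
        return ps.power[:, m].sum(axis=1)

    return _integrate(lo, hi) / _integrate(tlo, thi)
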