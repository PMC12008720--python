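"""Weighted Phase Lag Index (wPLI) connectivity in sensor space.

The wPLI (Vinck et al. 2011) weights the sign of each phase lag by the
magnitude of the imaginary cross-spectrum, which makes it insensitive to
instantaneous (zero-lag, volume-conduction-like) mixing:

    wPLI_ij(f) = | E[ Im X_ij(f) ] | / E[ | Im X_ij(f) | ]

The expectation runs over Welch segments within an epoch; per-epoch band
matrices are then averaged across epochs into the subject adjacency.
Both conventions (segment pooling, 0/0 -> 0) are fixed here so results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .preprocess import EpochedData

__all__ = [
    "CrossSpectra",
    "ConnectivityMatrix",
    "cross_spectra",
    "wpli_band",
    "subject_adjacency",
    "wpli_matrix",
]


@dataclass
class CrossSpectra:
    """Per-epoch, per-segment complex channel spectra.

    ``spectra`` has shape (n_epochs, n_segments, n_channels, n_freqs); the
    pairwise cross-spectrum X_ij(f) = S_i(f) * conj(S_j(f)) is materialized
    on demand via :meth:`cross` (storing it densely for 128 channels would
    take gigabytes).
    """

    spectra: np.ndarray
    frequencies: np.ndarray
    channel_labels: Sequence[str]
    condition: str = "eyes_closed"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.spectra.ndim != 4:
            raise ValueError("spectra must be 4-D (epochs, segments, channels, freqs)")
        self.channel_labels = list(self.channel_labels)

    @property
    def n_segments(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[2]

    def cross(self, i: int, j: int) -> np.ndarray:
        """X_ij(f) per epoch and segment, shape (n_epochs, n_segments, n_freqs)."""
        return self.spectra[:, :, i, :] * np.conj(self.spectra[:, :, j, :])


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative |wPLI| adjacency with zero diagonal."""

    W: np.ndarray
    channel_labels: Sequence[str]
    band: tuple[float, float] = (8.0, 13.0)
    condition: str = "eyes_closed"
    n_epochs: int = 1
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if (np.diag(self.W) != 0).any():
            raise ValueError("W must have a zero diagonal")
        if (self.W < -1e-12).any() or (self.W > 1 + 1e-9).any():
            raise ValueError("wPLI weights must lie in [0, 1]")
        self.W = np.clip(self.W, 0.0, 1.0)
        self.channel_labels = list(self.channel_labels)


def cross_spectra(ep: EpochedData, window_s: float = 0.5,
                  overlap_frac: float = 0.5) -> CrossSpectra:
    """Hamming-tapered overlapping-segment spectra per epoch.

    With 20 s epochs, 500 ms windows and 50% overlap this yields
    floor((20 - 0.5) / 0.25) + 1 = 79 segments per epoch.
    """
    fs = ep.fs
    nper = int(round(window_s * fs))
    if nper < 8 or nper > ep.data.shape[2]:
        raise ValueError("Welch window must fit inside the epoch")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    step = nper - int(round(overlap_frac * nper))
    n_seg = (ep.data.shape[2] - nper) // step + 1
    if n_seg < 2:
        raise ValueError(
            "fewer than 2 Welch segments per epoch; the wPLI expectation "
            "is undefined"
        )
    win = signal.get_window("hamming", nper)
    # (epochs, channels, segments, nper) view, then taper + FFT
    segs = np.lib.stride_tricks.sliding_window_view(ep.data, nper, axis=2)
    segs = segs[:, :, ::step, :][:, :, :n_seg, :]
    spec = np.fft.rfft(segs * win, axis=3)  # (epochs, channels, segments, freqs)
    spec = spec.transpose(0, 2, 1, 3)  # -> (epochs, segments, channels, freqs)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return CrossSpectra(
        spectra=spec, frequencies=freqs, channel_labels=ep.channel_labels,
        condition=ep.condition, subject_id=ep.subject_id,
    )


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    idx = np.where((freqs >= lo) & (freqs <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"no frequency bins inside [{lo}, {hi}] Hz")
    return idx


def wpli_band(cs: CrossSpectra, band: tuple[float, float] = (8.0, 13.0),
              debiased: bool = False) -> list[ConnectivityMatrix]:
    """Per-epoch wPLI adjacency in ``band``.

    For each pair and bin, |sum_k Im X| / sum_k |Im X| over Welch segments k
    (0 when the denominator vanishes: identical signals are not lag-coupled);
    the matrix entry is the unweighted mean over bins whose centers lie in
    the closed band interval.  ``debiased=True`` switches to the debiased
    squared estimator (sample-size-bias-corrected; negative values, which
    the unbiased estimator can produce under the null, are clipped to 0).
    """
    idx = _band_bins(cs.frequencies, band)
    out: list[ConnectivityMatrix] = []
    for e in range(cs.spectra.shape[0]):
        S = cs.spectra[e][:, :, idx]  # (segments, channels, bins)
        # Im X_ij = Im(S_i conj(S_j)), computed per segment and bin
        imx = np.einsum("kib,kjb->kijb", S.imag, S.real) - np.einsum(
            "kib,kjb->kijb", S.real, S.imag)
        if debiased:
            sum_sq = (imx ** 2).sum(axis=0)
            num = imx.sum(axis=0) ** 2 - sum_sq
            den = np.abs(imx).sum(axis=0) ** 2 - sum_sq
        else:
            num = np.abs(imx.sum(axis=0))
            den = np.abs(imx).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / den, 0.0)
        W = np.clip(w, 0.0, 1.0).mean(axis=2)
        np.fill_diagonal(W, 0.0)
        W = 0.5 * (W + W.T)  # symmetric up to roundoff by construction
        out.append(ConnectivityMatrix(
            W=W, channel_labels=cs.channel_labels, band=band,
            condition=cs.condition, n_epochs=1, subject_id=cs.subject_id,
        ))
    return out


def subject_adjacency(per_epoch: Sequence[ConnectivityMatrix],
                      ) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch wPLI matrices (the subject graph)."""
    if len(per_epoch) == 0:
        raise ValueError("need at least one epoch matrix")
    labels = per_epoch[0].channel_labels
    for m in per_epoch[1:]:
        if list(m.channel_labels) != list(labels):
            raise ValueError("channel labels differ across epoch matrices")
    W = np.mean([m.W for m in per_epoch], axis=0)
    first = per_epoch[0]
    return ConnectivityMatrix(
        W=W, channel_labels=labels, band=first.band,
        condition=first.condition, n_epochs=len(per_epoch),
        subject_id=first.subject_id,
    )


def wpli_matrix(ep: EpochedData, band: tuple[float, float] = (8.0, 13.0),
                window_s: float = 0.5, overlap_frac: float = 0.5,
                ) -> ConnectivityMatrix:
    """Convenience chain: cross_spectra -> per-epoch wPLI -> epoch average."""
    return subject_adjacency(wpli_band(cross_spectra(ep, window_s, overlap_frac), band))
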