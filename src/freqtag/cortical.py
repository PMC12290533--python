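"""Inter-trial phase coherence (ITPC) spectra and tagged-frequency read-out.

ITPC at a frequency bin is the length of the mean of per-epoch unit
phase vectors: 0 for random phase across epochs, 1 for identical phase.
A Hann-windowed FFT of each epoch supplies the complex coefficients;
each is normalized to unit length before averaging, so amplitude
differences between epochs carry no weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preproc import EpochSet

__all__ = ["ITPCSpectrum", "compute_itpc", "select_channels", "extract_tagged"]

#: Frontocentral cluster reported by the channel-selection procedure.
FRONTOCENTRAL_9 = ("AF4", "F3", "Fz", "F4", "FC1", "FC2", "FC5", "Cz", "C3")


@dataclass
class ITPCSpectrum:
    """Phase-coherence values per channel and DFT bin."""

    freqs: np.ndarray  # Hz
    itpc: np.ndarray  # channels x freqs, in [0, 1]
    labels: list
    n_epochs: int
    epoch_length: float  # s

    def to_frame(self, participant: str = "") -> pd.DataFrame:
        """Tidy long table (participant, channel, freq, itpc)."""
        ch = np.repeat(self.labels, len(self.freqs))
        return pd.DataFrame(
            {
                "participant": participant,
                "channel": ch,
                "freq": np.tile(self.freqs, len(self.labels)),
                "itpc": self.itpc.ravel(),
            }
        )


def compute_itpc(epochs: EpochSet, window: str | None = "hann") -> ITPCSpectrum:
    """ITPC per channel and frequency bin over the retained epochs.

    Each epoch is (optionally Hann-) windowed and Fourier transformed;
    the coefficient at each bin is scaled to a unit vector and averaged
    across epochs.  Bins where an epoch's coefficient is exactly zero
    contribute no vector there; the mean is renormalized by the count of
    non-zero epochs so the result stays in [0, 1].
    """
    data = epochs.retained_data()
    n_ep = data.shape[0]
    if n_ep < 2:
        raise ValueError("ITPC requires at least 2 retained epochs")
    n = data.shape[2]
    if window == "hann":
        w = np.hanning(n)
        w = w / np.sqrt(np.mean(w**2))  # unit-energy; irrelevant to phase
        data = data * w
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(data, axis=2)
    mag = np.abs(spec)
    nz = mag > 0
    unit = np.where(nz, spec, 0) / np.where(nz, mag, 1.0)
    counts = nz.sum(axis=0)
    vec = np.abs(unit.sum(axis=0)) / np.maximum(counts, 1)
    vec[counts == 0] = 0.0
    return ITPCSpectrum(
        freqs=np.fft.rfftfreq(n, 1.0 / epochs.fs),
        itpc=vec,
        labels=list(epochs.labels),
        n_epochs=int(n_ep),
        epoch_length=epochs.epoch_length,
    )


def _nearest_bins(freqs: np.ndarray, targets) -> np.ndarray:
    return np.array([int(np.argmin(np.abs(freqs - t))) for t in np.atleast_1d(targets)])


def select_channels(spectra, tagged_freqs, k: int = 9) -> list:
    """Top-k channels by ITPC averaged over the tagged bins and all
    participants' spectra.  Ties break by montage (input) order.

    All spectra must share channel labels and binning.
    """
    spectra = list(spectra)
    labels = spectra[0].labels
    if any(s.labels != labels for s in spectra):
        raise ValueError("spectra must share an identical channel set")
    if not 1 <= k <= len(labels):
        raise ValueError("k out of range")
    score = np.zeros(len(labels))
    for s in spectra:
        bins = _nearest_bins(s.freqs, tagged_freqs)
        score += s.itpc[:, bins].mean(axis=1)
    score /= len(spectra)
    order = np.argsort(-score, kind="stable")  # stable sort = montage-order ties
    return [labels[i] for i in order[:k]]


def extract_tagged(spectrum: ITPCSpectrum, target_freqs, channels=None) -> pd.DataFrame:
    """Mean ITPC over a channel cluster at the nearest bin to each
    target frequency; the bin mismatch is reported alongside."""
    if channels is None:
        idx = np.arange(len(spectrum.labels))
    else:
        idx = np.array([spectrum.labels.index(c) for c in channels])
    bins = _nearest_bins(spectrum.freqs, target_freqs)
    rows = []
    for t, b in zip(np.atleast_1d(target_freqs), bins):
        rows.append(
            {
                "target_freq": float(t),
                "bin_freq": float(spectrum.freqs[b]),
                "mismatch_hz": float(spectrum.freqs[b] - t),
                "itpc": float(spectrum.itpc[idx, b].mean()),
            }
        )
    return pd.DataFrame(rows)
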