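"""Frequency-following response (FFR) measures.

Two complementary quantities are computed from the three-F0-cycle
epochs of the FFR chain:

* band ITPC over 200-250 Hz — phase locking at the first harmonic of
  the 110.88-Hz fundamental (2*F0 = 221.76 Hz), where the response is
  largest;
* non-phase-locked amplitude over 100-500 Hz ("neural noise") — the
  across-epoch mean waveform (ERP) is subtracted from every epoch and
  the residual single-epoch amplitude spectra are averaged.

FFR epochs span an integer number of F0 cycles, so harmonics are
bin-aligned and no taper is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cortical import compute_itpc
from .preproc import EpochSet

__all__ = ["FFRResult", "ffr_itpc", "nonlocked_amplitude", "analyze_ffr"]

ITPC_BAND = (200.0, 250.0)  # Hz, first harmonic of 110.88 Hz
NOISE_BAND = (100.0, 500.0)  # Hz


@dataclass
class FFRResult:
    itpc_band: float  # mean ITPC over the harmonic band, in [0, 1]
    noise_amplitude: float  # mean non-phase-locked amplitude, uV
    n_epochs_per_polarity: dict
    peak_freq: float  # Hz of the max-ITPC bin within the band


def _band_bins(freqs: np.ndarray, band) -> np.ndarray:
    lo, hi = band
    if lo >= freqs[-1]:
        raise ValueError(f"band {band} lies outside the epoch bandwidth (max {freqs[-1]:.1f} Hz)")
    sel = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if len(sel) == 0:
        raise ValueError(f"no DFT bins inside band {band}")
    return sel


def ffr_itpc(epochs: EpochSet, band=ITPC_BAND):
    """Mean ITPC over the band on rectangular-window epoch spectra.

    Returns ``(band_mean, spectrum)``; the spectrum is channel x bin as
    in the cortical analysis (FFR epochs carry a single channel).
    """
    spectrum = compute_itpc(epochs, window=None)
    sel = _band_bins(spectrum.freqs, band)
    return float(spectrum.itpc[:, sel].mean()), spectrum


def nonlocked_amplitude(epochs: EpochSet, band=NOISE_BAND):
    """Mean residual single-epoch spectral amplitude over the band (uV).

    The ERP (mean over retained epochs) is subtracted from each epoch;
    single-sided amplitude spectra 2|X|/n of the residuals are averaged
    across epochs, then across the band's bins.
    """
    data = epochs.retained_data()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 retained epochs")
    n = data.shape[2]
    resid = data - data.mean(axis=0, keepdims=True)
    amp = 2.0 * np.abs(np.fft.rfft(resid, axis=2)) / n
    mean_amp = amp.mean(axis=0)  # channels x bins
    freqs = np.fft.rfftfreq(n, 1.0 / epochs.fs)
    sel = _band_bins(freqs, band)
    return float(mean_amp[:, sel].mean()), (freqs, mean_amp)


def analyze_ffr(epochs: EpochSet, itpc_band=ITPC_BAND, noise_band=NOISE_BAND) -> FFRResult:
    """Band ITPC plus neural-noise amplitude for a balanced epoch set."""
    band_mean, spectrum = ffr_itpc(epochs, itpc_band)
    noise, _ = nonlocked_amplitude(epochs, noise_band)
    sel = _band_bins(spectrum.freqs, itpc_band)
    peak = spectrum.freqs[sel[np.argmax(spectrum.itpc[:, sel].mean(axis=0))]]
    if epochs.polarity is not None:
        kept = epochs.retained
        counts = {
            "+1": int(np.sum(kept & (epochs.polarity == 1))),
            "-1": int(np.sum(kept & (epochs.polarity == -1))),
        }
    else:
        counts = {"+1": int(epochs.retained.sum()), "-1": 0}
    return FFRResult(
        itpc_band=band_mean,
        noise_amplitude=noise,
        n_epochs_per_polarity=counts,
        peak_freq=float(peak),
    )
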