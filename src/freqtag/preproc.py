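"""EEG preprocessing: resampling, re-referencing, zero-phase filtering,
epoching, and amplitude-based artifact rejection.

Two chains are provided.  The cortical chain (for phase-coherence
analysis of the slow tagged rates) downsamples to 512 Hz, re-references
to averaged earlobes, applies a 30-Hz low-pass (order 6) and a 0.5-Hz
high-pass (order 4) zero-phase Butterworth filter, cuts non-overlapping
1.2-s epochs, and rejects epochs exceeding +/-100 uV.  The
frequency-following-response (FFR) chain band-passes 70-3000 Hz, cuts
non-overlapping three-F0-cycle epochs from each qualifying stimulus,
rejects epochs above 35 uV, and balances epoch counts across stimulus
polarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .stimgen import EventList

__all__ = [
    "EEGRecording",
    "EpochSet",
    "downsample",
    "rereference",
    "filter_cortical",
    "filter_ffr",
    "epoch",
    "reject_amplitude",
    "epoch_ffr",
    "balance_polarity",
]


@dataclass
class EEGRecording:
    """Multichannel EEG time series in microvolts."""

    labels: list
    fs: float
    data: np.ndarray  # channels x samples, uV
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be channels x samples matching labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, labels) -> "EEGRecording":
        idx = [self.labels.index(l) for l in labels]
        return EEGRecording(list(labels), self.fs, self.data[idx].copy(), self.reference)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, data=self.data, fs=self.fs, labels=np.array(self.labels), reference=self.reference
        )

    @classmethod
    def load_npz(cls, path) -> "EEGRecording":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                labels=[str(l) for l in z["labels"]],
                fs=float(z["fs"]),
                data=z["data"],
                reference=str(z["reference"]),
            )


@dataclass
class EpochSet:
    """Segmented epochs with a rejection mask.

    ``rejected`` epochs stay in ``data`` but are excluded by
    ``retained_data``; ``reject_reason`` holds one code per epoch
    ("" = retained).
    """

    data: np.ndarray  # epochs x channels x samples, uV
    labels: list
    fs: float
    epoch_onsets: np.ndarray  # s
    epoch_length: float  # realized length, s
    rejected: np.ndarray = None  # bool per epoch
    reject_reason: np.ndarray = None  # str per epoch
    polarity: np.ndarray | None = None  # +1/-1 per epoch (FFR chain)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rejected is None:
            self.rejected = np.zeros(self.n_epochs, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * self.n_epochs, dtype=object)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def retained(self) -> np.ndarray:
        return ~self.rejected

    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            labels=list(self.labels),
            fs=self.fs,
            epoch_onsets=self.epoch_onsets.copy(),
            epoch_length=self.epoch_length,
            rejected=self.rejected.copy(),
            reject_reason=self.reject_reason.copy(),
            polarity=None if self.polarity is None else self.polarity.copy(),
        )

    def rejection_report(self) -> dict:
        reasons, counts = np.unique(self.reject_reason[self.rejected], return_counts=True)
        return {
            "n_epochs": int(self.n_epochs),
            "n_retained": int(self.retained.sum()),
            "by_reason": {str(r): int(c) for r, c in zip(reasons, counts)},
        }


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Decimate to ``target_fs`` with a Chebyshev-I order-8 anti-alias
    prefilter applied forward-backward (zero phase)."""
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the current sampling rate")
    q = rec.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"sampling-rate ratio {q} is not an integer")
    out = signal.decimate(rec.data, int(round(q)), n=8, ftype="iir", zero_phase=True, axis=1)
    return EEGRecording(list(rec.labels), float(target_fs), out, rec.reference)


def rereference(rec: EEGRecording, refs=("A1", "A2")) -> EEGRecording:
    """Subtract the mean of the reference channels from every channel."""
    missing = [r for r in refs if r not in rec.labels]
    if missing:
        raise ValueError(f"reference channels not found: {missing}")
    idx = [rec.labels.index(r) for r in refs]
    ref = rec.data[idx].mean(axis=0)
    return EEGRecording(
        list(rec.labels), rec.fs, rec.data - ref, reference=f"avg({','.join(refs)})"
    )


def _sos_filtfilt(data: np.ndarray, fs: float, cutoff, btype: str, order: int) -> np.ndarray:
    nyq = fs / 2.0
    hi = max(np.atleast_1d(cutoff))
    if hi >= nyq:
        raise ValueError(f"cutoff {hi} Hz at or above Nyquist ({nyq} Hz)")
    sos = signal.butter(order, np.asarray(cutoff) / nyq, btype=btype, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def filter_cortical(
    rec: EEGRecording,
    lp_cutoff: float = 30.0,
    lp_order: int = 6,
    hp_cutoff: float = 0.5,
    hp_order: int = 4,
) -> EEGRecording:
    """Zero-phase low-pass (30 Hz, order 6) then high-pass (0.5 Hz, order 4)."""
    out = _sos_filtfilt(rec.data, rec.fs, lp_cutoff, "lowpass", lp_order)
    out = _sos_filtfilt(out, rec.fs, hp_cutoff, "highpass", hp_order)
    return EEGRecording(list(rec.labels), rec.fs, out, rec.reference)


def filter_ffr(
    rec: EEGRecording,
    hp_cutoff: float = 70.0,
    lp_cutoff: float = 3000.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase band-pass for the FFR band (70 Hz HP + 3000 Hz LP)."""
    out = _sos_filtfilt(rec.data, rec.fs, hp_cutoff, "highpass", order)
    out = _sos_filtfilt(out, rec.fs, lp_cutoff, "lowpass", order)
    return EEGRecording(list(rec.labels), rec.fs, out, rec.reference)


def epoch(rec: EEGRecording, length: float, onsets=None) -> EpochSet:
    """Cut epochs of ``round(length*fs)`` samples.

    With ``onsets=None`` the record is tiled with non-overlapping epochs
    from t=0; a trailing partial epoch is dropped.  The realized epoch
    length (sample count / fs) is recorded, which matters when
    ``length*fs`` is non-integer (e.g. 1.2 s at 512 Hz -> 614 samples).
    """
    n = int(round(length * rec.fs))
    if n < 1:
        raise ValueError("epoch length too short")
    if onsets is None:
        n_ep = rec.n_samples // n
        starts = np.arange(n_ep) * n
    else:
        starts = np.round(np.asarray(onsets, float) * rec.fs).astype(int)
        if np.any(starts + n > rec.n_samples) or np.any(starts < 0):
            raise ValueError("epoch extends beyond the recording")
    data = np.stack([rec.data[:, s : s + n] for s in starts]) if len(starts) else np.zeros(
        (0, len(rec.labels), n)
    )
    return EpochSet(
        data=data,
        labels=list(rec.labels),
        fs=rec.fs,
        epoch_onsets=starts / rec.fs,
        epoch_length=n / rec.fs,
    )


def reject_amplitude(epochs: EpochSet, threshold: float, channels=None) -> EpochSet:
    """Mask epochs whose absolute amplitude exceeds ``threshold`` uV on
    any of the given channels (default: all).  Idempotent."""
    out = epochs.copy()
    if channels is None:
        idx = slice(None)
    else:
        idx = [out.labels.index(c) for c in channels]
    bad = np.any(np.abs(out.data[:, idx, :]) > threshold, axis=(1, 2))
    newly = bad & ~out.rejected
    out.rejected |= bad
    out.reject_reason[newly] = "amplitude"
    return out


def epoch_ffr(
    rec: EEGRecording,
    events: EventList,
    f0: float = 110.88,
    n_cycles: int = 3,
    channel: str = "Cz",
    onset_offset: float = 0.0,
    f0_tol: float = 0.5,
) -> EpochSet:
    """Cut consecutive non-overlapping ``n_cycles``-of-F0 epochs from
    every stimulus whose F0 matches ``f0`` (within ``f0_tol`` Hz).

    Each qualifying stimulus of duration d contributes
    ``floor(d / (n_cycles/f0))`` epochs starting at its onset (plus the
    optional ``onset_offset``); epochs inherit the stimulus polarity.
    """
    if channel not in rec.labels:
        raise ValueError(f"channel {channel} not in recording")
    ch = rec.labels.index(channel)
    n = int(round(n_cycles * rec.fs / f0))
    win_s = n_cycles / f0
    starts, pols = [], []
    for i in range(len(events)):
        if abs(events.f0_hz[i] - f0) > f0_tol:
            continue
        k = int(np.floor(events.duration_ms[i] / 1000.0 / win_s))
        t0 = events.onset[i] + onset_offset
        for j in range(k):
            s = int(round((t0 + j * win_s) * rec.fs))
            if s + n <= rec.n_samples:
                starts.append(s)
                pols.append(events.polarity[i])
    starts = np.asarray(starts, int)
    data = (
        np.stack([rec.data[ch : ch + 1, s : s + n] for s in starts])
        if len(starts)
        else np.zeros((0, 1, n))
    )
    return EpochSet(
        data=data,
        labels=[channel],
        fs=rec.fs,
        epoch_onsets=starts / rec.fs,
        epoch_length=n / rec.fs,
        polarity=np.asarray(pols, int),
    )


def balance_polarity(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Retain an equal number of artifact-free epochs per stimulus
    polarity, dropping a seeded random subset of the majority polarity."""
    if epochs.polarity is None:
        raise ValueError("epochs carry no polarity tags")
    out = epochs.copy()
    keep = out.retained
    idx_pos = np.flatnonzero(keep & (out.polarity == 1))
    idx_neg = np.flatnonzero(keep & (out.polarity == -1))
    m = min(len(idx_pos), len(idx_neg))
    if m == 0:
        raise ValueError("no artifact-free epochs of one polarity")
    rng = np.random.default_rng(seed)
    for idx in (idx_pos, idx_neg):
        if len(idx) > m:
            drop = rng.choice(idx, size=len(idx) - m, replace=False)
            out.rejected[drop] = True
            out.reject_reason[drop] = "polarity-balance"
    return out
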