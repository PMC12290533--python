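"""Synthetic EEG and behavior with known ground truth.

Every analysis stage in this package is validated against data from
this module: steady-state cortical components phase-locked at the
tagged rates with controllable per-epoch phase jitter and a
frontocentral topography, 1/f background noise, transient
high-amplitude artifacts, an FFR-band harmonic complex at the stimulus
F0, oddball-detection key presses, and Bernoulli categorization
responses generated from known cue weights.

Phase jitter is wrapped-normal per analysis epoch, so the expected ITPC
of a component with jitter SD sigma has the closed form exp(-sigma^2/2)
(the mean resultant length of a wrapped normal distribution), which the
ground-truth records alongside each simulated component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import ResponseLog, rescale_2sd
from .preproc import EEGRecording
from .stimgen import EventList

__all__ = [
    "BIOSEMI32",
    "EARLOBES",
    "CorticalSimConfig",
    "FFRSimConfig",
    "BehaviorSimConfig",
    "simulate_cortical",
    "simulate_ffr",
    "simulate_oddball_responses",
    "simulate_categorization",
    "one_over_f_noise",
]

#: 32-channel 10/20 scalp montage (BioSemi ordering).
BIOSEMI32 = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)
EARLOBES = ("A1", "A2")

_FRONTOCENTRAL = ("AF4", "F3", "Fz", "F4", "FC1", "FC2", "FC5", "Cz", "C3")


def _frontocentral_topography(labels, high: float = 1.0, low: float = 0.3) -> dict:
    """Scalp gains peaking over frontocentral sites; earlobes carry none."""
    topo = {}
    for l in labels:
        if l in EARLOBES:
            topo[l] = 0.0
        elif l in _FRONTOCENTRAL:
            topo[l] = high
        else:
            topo[l] = low
    return topo


@dataclass(frozen=True)
class ComponentSpec:
    """One phase-locked steady-state component."""

    freq: float  # Hz
    amplitude: float  # uV at gain 1
    phase_jitter_sd: float = 0.0  # radians, per analysis epoch
    topography: dict | None = None  # label -> gain; None = frontocentral

    @property
    def expected_itpc(self) -> float:
        """Mean resultant length of the wrapped-normal phase jitter."""
        return float(np.exp(-self.phase_jitter_sd**2 / 2.0))


@dataclass
class CorticalSimConfig:
    """Synthetic cortical EEG around the frequency-tagging analysis.

    fs defaults to 600 Hz so the 1.2-s analysis epochs hold exactly 720
    samples and the tagged rates 2.5 and 1.6667 Hz fall exactly on DFT
    bins 3 and 2.
    """

    channel_labels: tuple = BIOSEMI32 + EARLOBES
    fs: float = 600.0
    duration: float = 96.0  # s
    components: tuple = ()
    epoch_length: float = 1.2  # s; jitter is redrawn per epoch
    noise_exponent: float = 1.0  # 1/f^alpha spectral slope
    noise_scale: float = 10.0  # uV RMS per channel
    artifact_rate: float = 0.0  # bursts per minute
    artifact_amplitude: float = 150.0  # uV peak
    artifact_duration: float = 0.3  # s
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.components:
            if c.freq >= self.fs / 2:
                raise ValueError(f"component at {c.freq} Hz at or above Nyquist")
            if c.phase_jitter_sd < 0:
                raise ValueError("phase jitter sd must be >= 0")


def one_over_f_noise(
    n: int, fs: float, exponent: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^exponent, RMS ``scale``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms) if rms > 0 else x


def _jittered_component(
    freq: float,
    amplitude: float,
    sigma: float,
    n: int,
    fs: float,
    epoch_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sinusoid whose phase is re-drawn each analysis epoch with
    wrapped-normal jitter around a common base phase."""
    base = rng.uniform(0, 2 * np.pi)
    out = np.empty(n)
    n_blocks = int(np.ceil(n / epoch_samples))
    jit = rng.normal(0.0, sigma, size=n_blocks) if sigma > 0 else np.zeros(n_blocks)
    t_local = np.arange(epoch_samples) / fs
    for b in range(n_blocks):
        lo = b * epoch_samples
        hi = min(lo + epoch_samples, n)
        out[lo:hi] = amplitude * np.cos(2 * np.pi * freq * t_local[: hi - lo] + base + jit[b])
    return out


def simulate_cortical(cfg: CorticalSimConfig, events: EventList | None = None):
    """Multichannel synthetic cortical EEG plus a ground-truth record.

    Returns ``(EEGRecording, ground_truth)``; the ground truth lists per
    component its frequency, jitter SD, expected ITPC exp(-sigma^2/2)
    and topography, plus the injected artifact times.
    """
    if events is not None and events.total_duration > cfg.duration + 1e-9:
        raise ValueError("events span exceeds the simulated duration")
    rng = np.random.default_rng(cfg.seed)
    labels = list(cfg.channel_labels)
    n = int(round(cfg.duration * cfg.fs))
    ep = int(round(cfg.epoch_length * cfg.fs))
    data = np.zeros((len(labels), n))

    gt_components = []
    for comp in cfg.components:
        topo = comp.topography or _frontocentral_topography(labels)
        wave = _jittered_component(
            comp.freq, comp.amplitude, comp.phase_jitter_sd, n, cfg.fs, ep, rng
        )
        for i, l in enumerate(labels):
            g = topo.get(l, 0.0)
            if g:
                data[i] += g * wave
        gt_components.append(
            {
                "freq": comp.freq,
                "phase_jitter_sd": comp.phase_jitter_sd,
                "expected_itpc": comp.expected_itpc,
                "topography": dict(topo),
            }
        )

    if cfg.noise_scale > 0:
        for i in range(len(labels)):
            data[i] += one_over_f_noise(n, cfg.fs, cfg.noise_exponent, cfg.noise_scale, rng)

    artifact_times = []
    if cfg.artifact_rate > 0:
        n_art = rng.poisson(cfg.artifact_rate * cfg.duration / 60.0)
        burst_n = int(round(cfg.artifact_duration * cfg.fs))
        burst = cfg.artifact_amplitude * np.hanning(burst_n)
        scalp = [i for i, l in enumerate(labels) if l not in EARLOBES]
        for _ in range(n_art):
            t0 = rng.uniform(0, cfg.duration - cfg.artifact_duration)
            s = int(round(t0 * cfg.fs))
            ch = rng.choice(scalp)
            data[ch, s : s + burst_n] += burst * rng.choice([-1, 1])
            artifact_times.append(float(t0))

    rec = EEGRecording(labels, cfg.fs, data)
    ground_truth = {
        "components": gt_components,
        "artifact_times": sorted(artifact_times),
        "epoch_length": cfg.epoch_length,
    }
    return rec, ground_truth


@dataclass
class FFRSimConfig:
    """Synthetic frequency-following response around a 110.88-Hz F0."""

    f0: float = 110.88  # Hz
    fs: float = 8000.0
    harmonic_amplitudes: tuple = (0.0, 0.1)  # uV per harmonic (1*f0, 2*f0, ...)
    phase_jitter_sd: float = 0.0  # radians per 3-cycle epoch
    nonlocked_noise_sd: float = 0.05  # uV, white, not phase-locked
    n_cycles: int = 3  # epoch span used for per-epoch jitter
    # envelope-following components (default) keep their sign across the
    # alternating stimulus polarity and survive collapsing polarities;
    # fine-structure components flip and cancel in the mixed-polarity average
    fine_structure: bool = False
    earlobe_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be >= 0")
        if self.f0 * len(self.harmonic_amplitudes) >= self.fs / 2:
            raise ValueError("highest harmonic at or above Nyquist")


def simulate_ffr(cfg: FFRSimConfig, events: EventList):
    """Cz-dominant FFR recording time-locked to the qualifying stimuli.

    Within each stimulus matching the configured F0, every consecutive
    ``n_cycles``-long window carries the harmonic complex with its own
    wrapped-normal phase jitter; fine-structure components flip sign
    with the stimulus polarity.  White non-phase-locked noise is added
    throughout.  Returns ``(EEGRecording, ground_truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = ["Cz", *EARLOBES]
    n = int(round(events.total_duration * cfg.fs))
    data = np.zeros((3, n))
    win_s = cfg.n_cycles / cfg.f0
    win_n = int(round(win_s * cfg.fs))
    base = rng.uniform(0, 2 * np.pi, size=len(cfg.harmonic_amplitudes))
    t_local = np.arange(win_n) / cfg.fs
    n_epochs = 0
    for i in range(len(events)):
        if abs(events.f0_hz[i] - cfg.f0) > 0.5:
            continue
        k = int(np.floor(events.duration_ms[i] / 1000.0 / win_s))
        pol = events.polarity[i] if cfg.fine_structure else 1
        for j in range(k):
            s = int(round((events.onset[i] + j * win_s) * cfg.fs))
            if s + win_n > n:
                continue
            jit = rng.normal(0.0, cfg.phase_jitter_sd) if cfg.phase_jitter_sd > 0 else 0.0
            seg = np.zeros(win_n)
            for h, amp in enumerate(cfg.harmonic_amplitudes, start=1):
                if amp:
                    seg += amp * np.cos(2 * np.pi * h * cfg.f0 * t_local + base[h - 1] + jit)
            data[0, s : s + win_n] += pol * seg
            n_epochs += 1
    if cfg.nonlocked_noise_sd > 0:
        data[0] += rng.normal(0.0, cfg.nonlocked_noise_sd, size=n)
    if cfg.earlobe_noise_sd > 0:
        data[1] += rng.normal(0.0, cfg.earlobe_noise_sd, size=n)
        data[2] += rng.normal(0.0, cfg.earlobe_noise_sd, size=n)
    rec = EEGRecording(labels, cfg.fs, data)
    ground_truth = {
        "expected_itpc": float(np.exp(-cfg.phase_jitter_sd**2 / 2.0)),
        "harmonic_freqs": [h * cfg.f0 for h in range(1, len(cfg.harmonic_amplitudes) + 1)],
        "n_epochs": n_epochs,
        "nonlocked_noise_sd": cfg.nonlocked_noise_sd,
    }
    return rec, ground_truth


@dataclass
class BehaviorSimConfig:
    """Known-truth behavioral responders."""

    hit_prob: float = 0.95
    fa_rate_per_s: float = 0.005  # false-alarm Poisson rate
    rt_mean: float = 0.5  # s
    rt_sd: float = 0.15
    # cue weights on the 2-SD-rescaled predictor scale (log odds / SD... see docs)
    b0: float = 0.0
    b_pitch: float = 2.0
    b_dur: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.hit_prob <= 1:
            raise ValueError("hit_prob must be in [0, 1]")
        if self.fa_rate_per_s < 0:
            raise ValueError("fa_rate_per_s must be >= 0")


def simulate_oddball_responses(cfg: BehaviorSimConfig, events: EventList) -> ResponseLog:
    """Key presses to the amplitude oddballs.

    Each oddball elicits a response with probability ``hit_prob`` at a
    latency drawn from Normal(rt_mean, rt_sd) truncated to (0, 1.25];
    false alarms form a homogeneous Poisson process over the session.
    """
    rng = np.random.default_rng(cfg.seed)
    times = []
    for onset in events.onset[events.is_oddball]:
        if rng.uniform() < cfg.hit_prob:
            for _ in range(100):
                lat = rng.normal(cfg.rt_mean, cfg.rt_sd)
                if 0 < lat <= 1.25:
                    times.append(onset + lat)
                    break
    # false alarms land outside the oddball hit windows
    odd = events.onset[events.is_oddball]
    n_fa = rng.poisson(cfg.fa_rate_per_s * events.total_duration)
    placed = 0
    while placed < n_fa:
        t = rng.uniform(0, events.total_duration)
        if not np.any((t > odd) & (t <= odd + 1.25)):
            times.append(t)
            placed += 1
    return ResponseLog(
        times=np.sort(np.asarray(times, float)), session_duration=events.total_duration
    )


def simulate_categorization(
    cfg: BehaviorSimConfig,
    n_levels: int = 4,
    n_trials_per_cell: int = 10,
    task: str = "beats",
) -> pd.DataFrame:
    """Bernoulli categorization trials over the pitch x duration grid.

    The response probability is logistic(b0 + b_pitch*p~ + b_dur*d~)
    with p~, d~ the 2-SD-rescaled level columns, i.e. the configured
    weights are the log-odds change per rescaled unit.
    """
    rng = np.random.default_rng(cfg.seed)
    pitch, dur = np.meshgrid(np.arange(1, n_levels + 1), np.arange(1, n_levels + 1))
    pitch = np.repeat(pitch.ravel(), n_trials_per_cell)
    dur = np.repeat(dur.ravel(), n_trials_per_cell)
    p_s = rescale_2sd(pitch.astype(float))
    d_s = rescale_2sd(dur.astype(float))
    logit = cfg.b0 + cfg.b_pitch * p_s + cfg.b_dur * d_s
    prob = 1.0 / (1.0 + np.exp(-logit))
    resp = (rng.uniform(size=len(prob)) < prob).astype(int)
    order = rng.permutation(len(prob))
    return pd.DataFrame(
        {
            "task": task,
            "pitch_level": pitch[order],
            "duration_level": dur[order],
            "response": resp[order],
        }
    )
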