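"""Tagged auditory stimulus sequences and tone synthesis.

Builds the token grids (2x2 pitch-by-duration tone/vowel grids, 4x4
musical-beat grids), event lists for the frequency-tagging, selective
attention and musical-beat paradigms, and renders the event lists to
audio with amplitude-oddball and polarity transforms.

A tagging sequence presents one sound every ``soa`` seconds while the
pitch and duration of the sounds alternate between two levels at fixed,
dimension-specific rates (e.g. a change every 2 sounds at a 5-Hz
presentation rate tags that dimension at 2.5 Hz).  Occasional
*repetitions* (a dimension failing to change at its scheduled point)
break predictability, and a few quiet *oddballs* (-12.04 dB) support a
concurrent detection task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Token",
    "TokenGrid",
    "SequenceSpec",
    "EventList",
    "BeatLevelTable",
    "TONE_GRID",
    "VOWEL_GRID",
    "BEAT_TABLE",
    "synth_tone",
    "build_tagging_sequence",
    "build_attention_sequence",
    "build_beat_sequence",
    "render_sequence",
    "write_wav",
]

ODDBALL_SCALE = 0.25  # linear amplitude factor; 20*log10(0.25) = -12.04 dB
ODDBALL_GUARD_S = 4.8  # no oddball near edges or within this gap of another


@dataclass(frozen=True)
class Token:
    """A single sound: harmonic complex defined by F0 and duration."""

    f0: float  # Hz
    duration: float  # ms
    kind: str = "tone"  # "tone" | "vowel-placeholder"
    n_harmonics: int = 4

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class TokenGrid:
    """Pitch-level x duration-level grid of tokens."""

    pitch_levels: tuple  # Hz, strictly increasing
    duration_levels: tuple  # ms, strictly increasing
    kind: str = "tone"
    n_harmonics: int = 4

    def __post_init__(self) -> None:
        for levels, name in ((self.pitch_levels, "pitch"), (self.duration_levels, "duration")):
            if len(levels) < 2 or np.any(np.diff(levels) <= 0):
                raise ValueError(f"{name} levels must be strictly increasing with >=2 entries")

    def token(self, pitch_level: int, duration_level: int) -> Token:
        """Token at 0-based (pitch, duration) level indices."""
        return Token(
            f0=float(self.pitch_levels[pitch_level]),
            duration=float(self.duration_levels[duration_level]),
            kind=self.kind,
            n_harmonics=self.n_harmonics,
        )


#: Synthesized tones matched to the vowel stimuli (F0 in Hz, duration in ms).
TONE_GRID = TokenGrid(pitch_levels=(110.88, 124.72), duration_levels=(70.0, 175.0))

#: Placeholder grid carrying the natural-vowel F0/duration values; the tokens
#: are rendered as harmonic complexes (no speech resynthesis).
VOWEL_GRID = TokenGrid(
    pitch_levels=(110.88, 124.40),
    duration_levels=(70.58, 175.83),
    kind="vowel-placeholder",
)


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters of a tagged sound sequence.

    ``pitch_period`` / ``duration_period`` are the change periods in
    sounds (a change every k sounds tags the dimension at
    ``1/(k*soa)`` Hz).
    """

    soa: float = 0.2  # s between onsets (5 Hz presentation)
    total_duration: float = 96.0  # s
    pitch_period: int = 2  # sounds between scheduled pitch changes
    duration_period: int = 3
    n_repetitions: int = 20  # per dimension
    n_oddballs: int = 2
    oddball_guard: float = ODDBALL_GUARD_S  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soa <= 0:
            raise ValueError("soa must be positive")
        if self.oddball_guard < 0:
            raise ValueError("oddball_guard must be >= 0")
        if self.pitch_period < 1 or self.duration_period < 1:
            raise ValueError("change periods must be >= 1 sound")
        n = self.total_duration / self.soa
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_duration must be an integer multiple of soa")

    @property
    def n_events(self) -> int:
        return int(round(self.total_duration / self.soa))

    @property
    def pitch_rate(self) -> float:
        """Tagged pitch-change rate in Hz."""
        return 1.0 / (self.pitch_period * self.soa)

    @property
    def duration_rate(self) -> float:
        return 1.0 / (self.duration_period * self.soa)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__)

    @classmethod
    def from_yaml(cls, text: str) -> "SequenceSpec":
        return cls(**yaml.safe_load(text))


@dataclass
class EventList:
    """Timed stimulus events of one sequence.

    All per-event fields are parallel arrays.  ``polarity`` alternates
    +1/-1 event to event; ``f0_hz``/``duration_ms`` are the resolved
    token acoustics.
    """

    onset: np.ndarray  # s
    pitch_level: np.ndarray  # 0-based index
    duration_level: np.ndarray
    is_pitch_repetition: np.ndarray  # bool
    is_duration_repetition: np.ndarray
    is_oddball: np.ndarray
    polarity: np.ndarray  # +1 / -1
    f0_hz: np.ndarray
    duration_ms: np.ndarray
    soa: float
    total_duration: float
    trial_type: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.onset) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset)

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset/duration in seconds)."""
        return pd.DataFrame(
            {
                "onset": self.onset,
                "duration": self.duration_ms / 1000.0,
                "pitch_level": self.pitch_level,
                "duration_level": self.duration_level,
                "is_pitch_rep": self.is_pitch_repetition.astype(int),
                "is_dur_rep": self.is_duration_repetition.astype(int),
                "is_oddball": self.is_oddball.astype(int),
                "polarity": self.polarity,
                "f0_hz": self.f0_hz,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, soa: float | None = None, total_duration: float | None = None) -> "EventList":
        df = pd.read_csv(path, sep="\t")
        onset = df["onset"].to_numpy(float)
        if soa is None:
            soa = float(np.median(np.diff(onset))) if len(onset) > 1 else 0.0
        if total_duration is None:
            total_duration = float(onset[-1] + soa) if len(onset) else 0.0
        return cls(
            onset=onset,
            pitch_level=df["pitch_level"].to_numpy(int),
            duration_level=df["duration_level"].to_numpy(int),
            is_pitch_repetition=df["is_pitch_rep"].to_numpy(bool),
            is_duration_repetition=df["is_dur_rep"].to_numpy(bool),
            is_oddball=df["is_oddball"].to_numpy(bool),
            polarity=df["polarity"].to_numpy(int),
            f0_hz=df["f0_hz"].to_numpy(float),
            duration_ms=df["duration"].to_numpy(float) * 1000.0,
            soa=soa,
            total_duration=total_duration,
        )


@dataclass(frozen=True)
class BeatLevelTable:
    """Pitch and duration patterns of the 4-level musical-beat space.

    Level 1 most strongly cues a three-note (waltz) grouping; level 4
    most strongly cues a two-note (march) grouping.
    """

    pitch_patterns: tuple  # 4 tuples of 6 Hz values
    duration_patterns: tuple  # 4 tuples of 6 ms values

    def __post_init__(self) -> None:
        for pats in (self.pitch_patterns, self.duration_patterns):
            if len(pats) != 4 or any(len(p) != 6 for p in pats):
                raise ValueError("each dimension needs 4 patterns of 6 entries")


A4, B4, CS5 = 440.0, 493.9, 554.4  # equal-tempered A, B, C# references

BEAT_TABLE = BeatLevelTable(
    pitch_patterns=(
        (CS5, A4, A4, CS5, A4, A4),  # C#-A-A-C#-A-A: strong groups of three
        (B4, A4, A4, B4, A4, A4),
        (B4, A4, B4, A4, B4, A4),
        (CS5, A4, CS5, A4, CS5, A4),  # C#-A-C#-A-C#-A: strong groups of two
    ),
    duration_patterns=(
        (200.0, 50.0, 50.0, 200.0, 50.0, 50.0),
        (100.0, 50.0, 50.0, 100.0, 50.0, 50.0),
        (100.0, 50.0, 100.0, 50.0, 100.0, 50.0),
        (200.0, 50.0, 200.0, 50.0, 200.0, 50.0),
    ),
)


def synth_tone(
    f0: float,
    duration: float,
    n_harmonics: int = 4,
    ramp: float = 10.0,
    fs: float = 44100.0,
    peak: float = 0.9,
) -> np.ndarray:
    """Equal-amplitude harmonic complex with raised-cosine on/off ramps.

    Parameters
    ----------
    f0 : fundamental frequency in Hz.
    duration : tone duration in ms.
    ramp : on/off ramp duration in ms.
    peak : peak normalization level of the returned waveform.
    """
    if duration < 2 * ramp:
        raise ValueError(f"duration {duration} ms shorter than twice the {ramp}-ms ramp")
    top = f0 * n_harmonics
    if top >= fs / 2:
        raise ValueError(
            f"harmonic {n_harmonics} at {top:.2f} Hz is at or above Nyquist ({fs / 2:.1f} Hz)"
        )
    n = int(round(duration * fs / 1000.0))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        wave += np.sin(2 * np.pi * k * f0 * t)
    r = int(round(ramp * fs / 1000.0))
    if r > 1:
        env = 0.5 * (1 - np.cos(np.pi * np.arange(r) / (r - 1)))
        wave[:r] *= env
        wave[-r:] *= env[::-1]
    m = np.max(np.abs(wave))
    if m > 0:
        wave *= peak / m
    return wave


def _level_sequence(n_events: int, period: int, n_reps: int, rng: np.random.Generator):
    """Two-level alternation with ``n_reps`` held change points.

    The stream is a run of slots, each ``period`` sounds long; at every
    slot boundary the level toggles, except at repetition slots where
    the previous level is held for one extra slot (the change phase
    resets afterwards).  Returns (levels, rep_flags) per event; the
    repetition flag marks the first sound of the held slot.
    """
    n_slots = n_events // period
    rep_slots: set[int] = set()
    if n_reps:
        # candidate slots exclude the first and last change period; two
        # adjacent repetitions would merge into an un-flaggable triple run
        candidates = np.arange(1, n_slots - 1)
        # min-gap transform: sorted distinct draws from a shrunken range,
        # re-expanded so no two picks are adjacent (uniform, no retries)
        m = len(candidates) - (n_reps - 1)
        if m < n_reps:
            raise ValueError("too many repetitions for the sequence length")
        pick = np.sort(rng.choice(m, size=n_reps, replace=False)) + np.arange(n_reps)
        rep_slots = set(int(candidates[p]) for p in pick)
    levels = np.zeros(n_events, dtype=int)
    reps = np.zeros(n_events, dtype=bool)
    level = 0
    for s in range(n_slots):
        if s > 0 and s not in rep_slots:
            level = 1 - level
        lo, hi = s * period, min((s + 1) * period, n_events)
        levels[lo:hi] = level
        if s in rep_slots:
            reps[lo] = True
    tail = n_slots * period
    if tail < n_events:  # partial trailing slot keeps alternating
        levels[tail:] = 1 - level
    return levels, reps


def _place_oddballs(spec: SequenceSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw oddball event indices honoring the edge and spacing guards.

    Sampling uses the min-gap transform: draw sorted distinct indices
    from a shrunken range, then re-expand by the gap, which yields a
    uniform draw over all admissible configurations without retries.
    """
    if spec.n_oddballs == 0:
        return np.zeros(0, dtype=int)
    n = spec.n_events
    onsets = np.arange(n) * spec.soa
    ok = (onsets >= spec.oddball_guard) & (onsets < spec.total_duration - spec.oddball_guard)
    candidates = np.flatnonzero(ok)
    if len(candidates) == 0:
        raise ValueError("no admissible oddball positions under the guard constraints")
    k = spec.n_oddballs
    gap = int(np.ceil(spec.oddball_guard / spec.soa))  # min index spacing
    m = len(candidates) - (k - 1) * (gap - 1)
    if m < k:
        raise ValueError("oddball count infeasible under the spacing guard")
    picks = np.sort(rng.choice(m, size=k, replace=False))
    return candidates[picks + np.arange(k) * (gap - 1)]


def build_tagging_sequence(spec: SequenceSpec, grid: TokenGrid = TONE_GRID) -> EventList:
    """Frequency-tagging sequence: both dimensions alternate at their
    tagged rates, with inserted repetitions and amplitude oddballs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    p_lvl, p_rep = _level_sequence(n, spec.pitch_period, spec.n_repetitions, rng)
    d_lvl, d_rep = _level_sequence(n, spec.duration_period, spec.n_repetitions, rng)
    odd = np.zeros(n, dtype=bool)
    odd[_place_oddballs(spec, rng)] = True
    polarity = np.where(np.arange(n) % 2 == 0, 1, -1)
    f0 = np.asarray(grid.pitch_levels, float)[p_lvl]
    dur = np.asarray(grid.duration_levels, float)[d_lvl]
    return EventList(
        onset=np.arange(n) * spec.soa,
        pitch_level=p_lvl,
        duration_level=d_lvl,
        is_pitch_repetition=p_rep,
        is_duration_repetition=d_rep,
        is_oddball=odd,
        polarity=polarity,
        f0_hz=f0,
        duration_ms=dur,
        soa=spec.soa,
        total_duration=spec.total_duration,
    )


def build_attention_sequence(
    spec: SequenceSpec,
    grid: TokenGrid = TONE_GRID,
    repetition_dims: frozenset | set = frozenset(),
) -> EventList:
    """Selective-attention trial at a 2-Hz presentation rate.

    Exactly one repetition is inserted per dimension named in
    ``repetition_dims`` (the listener reports whether the attended
    dimension contained one); the trial is labeled with its four-way
    type.
    """
    bad = set(repetition_dims) - {"pitch", "duration"}
    if bad:
        raise ValueError(f"unknown repetition dims: {bad}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    p_lvl, p_rep = _level_sequence(
        n, spec.pitch_period, 1 if "pitch" in repetition_dims else 0, rng
    )
    d_lvl, d_rep = _level_sequence(
        n, spec.duration_period, 1 if "duration" in repetition_dims else 0, rng
    )
    polarity = np.where(np.arange(n) % 2 == 0, 1, -1)
    labels = {
        frozenset(): "none",
        frozenset({"pitch"}): "pitch-only",
        frozenset({"duration"}): "duration-only",
        frozenset({"pitch", "duration"}): "both",
    }
    return EventList(
        onset=np.arange(n) * spec.soa,
        pitch_level=p_lvl,
        duration_level=d_lvl,
        is_pitch_repetition=p_rep,
        is_duration_repetition=d_rep,
        is_oddball=np.zeros(n, dtype=bool),
        polarity=polarity,
        f0_hz=np.asarray(grid.pitch_levels, float)[p_lvl],
        duration_ms=np.asarray(grid.duration_levels, float)[d_lvl],
        soa=spec.soa,
        total_duration=spec.total_duration,
        trial_type=labels[frozenset(repetition_dims)],
    )


def build_beat_sequence(
    pitch_level: int, duration_level: int, table: BeatLevelTable = BEAT_TABLE
) -> EventList:
    """Musical-beat stimulus: six tones repeated three times (18 events),
    tones played back to back so each onset follows the previous tone."""
    if not (1 <= pitch_level <= 4 and 1 <= duration_level <= 4):
        raise ValueError("beat levels must be in 1..4")
    f0 = np.tile(np.asarray(table.pitch_patterns[pitch_level - 1], float), 3)
    dur = np.tile(np.asarray(table.duration_patterns[duration_level - 1], float), 3)
    onset = np.concatenate([[0.0], np.cumsum(dur[:-1]) / 1000.0])
    n = len(f0)
    return EventList(
        onset=onset,
        pitch_level=np.full(n, pitch_level - 1),
        duration_level=np.full(n, duration_level - 1),
        is_pitch_repetition=np.zeros(n, dtype=bool),
        is_duration_repetition=np.zeros(n, dtype=bool),
        is_oddball=np.zeros(n, dtype=bool),
        polarity=np.ones(n, dtype=int),
        f0_hz=f0,
        duration_ms=dur,
        soa=float(np.median(np.diff(onset))),
        total_duration=float(dur.sum() / 1000.0),
    )


def render_sequence(
    events: EventList,
    grid: TokenGrid | None = None,
    fs: float = 44100.0,
    oddball_scale: float = ODDBALL_SCALE,
    n_harmonics: int = 4,
    ramp: float = 10.0,
    peak: float = 0.9,
    apply_polarity: bool = True,
) -> np.ndarray:
    """Render an event list to a waveform.

    Each token is synthesized at its event's F0/duration, peak-normalized,
    scaled by ``oddball_scale`` if the event is an oddball, multiplied by
    the event's polarity, and placed at its onset; gaps are silence.
    """
    if grid is not None:
        n_harmonics = grid.n_harmonics
    n_total = int(round(events.total_duration * fs))
    out = np.zeros(n_total)
    onsets = events.onset
    limits = np.append(onsets[1:], events.total_duration)
    cache: dict[tuple, np.ndarray] = {}
    for i in range(len(events)):
        dur_s = events.duration_ms[i] / 1000.0
        if dur_s > limits[i] - onsets[i] + 1e-12:
            raise ValueError(
                f"event {i}: token duration {dur_s:.4f} s exceeds gap to next onset"
            )
        key = (events.f0_hz[i], events.duration_ms[i])
        if key not in cache:
            cache[key] = synth_tone(key[0], key[1], n_harmonics, ramp, fs, peak)
        tone = cache[key]
        if events.is_oddball[i]:
            tone = tone * oddball_scale
        if apply_polarity:
            tone = tone * events.polarity[i]
        start = int(round(onsets[i] * fs))
        out[start : start + len(tone)] += tone
    return out


def write_wav(path, wave: np.ndarray, fs: float = 44100.0) -> None:
    """Write a mono float32 PCM WAV file."""
    from scipy.io import wavfile

    wavfile.write(path, int(fs), wave.astype(np.float32))
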