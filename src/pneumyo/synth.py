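"""Synthetic bladder-pressure traces for six locomotion modes.

The generator emulates the qualitative phenomenology of circumferential
thigh-bladder pressure during standing, walking, jogging, uphill walking,
stair ascent and squatting, on a 20 or 30 kPa static baseline sampled at
100 Hz:

* standing      -- flat baseline plus sensor noise;
* walking/jogging/uphill -- periodic oscillation at a mode-specific cadence
  and amplitude, with low-order harmonics shaping the cycle;
* stairs        -- a cycle sequence in which each cycle is either a stair
  "surge" cycle or, with probability ``landing_fraction``, a walking-like
  cycle (the landings between flights, the known source of stairs/walking
  label noise);
* squatting     -- large slow raised-cosine pressure surges separated by
  rest at baseline.

All waveform parameters are synthetic design choices, not measured values;
they are chosen so the modes' cadence/amplitude statistics are pairwise
distinct, which is what makes the downstream classifier testable without
the original recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MODES",
    "ActivityProfile",
    "PressureTrace",
    "default_profiles",
    "mode_waveform",
    "generate_session",
]

#: Canonical class vocabulary, alphabetical (fixed class-to-index mapping).
MODES = ("jogging", "squatting", "stairs", "standing", "uphill", "walking")

SAMPLING_RATE_HZ = 100.0


@dataclass(frozen=True)
class ActivityProfile:
    """Waveform parameters for one locomotion mode.

    Parameters
    ----------
    mode:
        One of :data:`MODES`.
    baseline_kpa:
        Static bladder pressure the oscillation rides on (20 or 30 kPa in
        the device's two configurations).
    cadence_hz:
        Cycle rate of the periodic component (surge repetition rate for
        squatting).
    amplitude_kpa:
        Peak oscillation (or surge) amplitude.
    harmonics:
        ``(multiple, relative_amplitude, phase)`` triples added on top of
        the fundamental to shape the cycle.
    surge_duration_s:
        Active raised-cosine surge length within one squat cycle.
    landing_fraction:
        Probability that a stair cycle is drawn walking-like (landing).
    noise_sd_kpa:
        Additive white Gaussian sensor noise.
    drift_kpa_per_min:
        Slow linear baseline drift.
    """

    mode: str
    baseline_kpa: float = 20.0
    cadence_hz: float = 1.0
    amplitude_kpa: float = 0.0
    harmonics: Sequence[tuple[float, float, float]] = field(default_factory=tuple)
    surge_duration_s: float = 3.0
    landing_fraction: float = 0.0
    noise_sd_kpa: float = 0.1
    drift_kpa_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.baseline_kpa <= 0:
            raise ValueError("baseline_kpa must be > 0")
        if self.amplitude_kpa < 0:
            raise ValueError("amplitude_kpa must be >= 0")
        if not 0.0 <= self.landing_fraction < 1.0:
            raise ValueError("landing_fraction must be in [0, 1)")


@dataclass
class PressureTrace:
    """Uniformly sampled bladder-pressure stream.

    ``values`` are kPa at ``sampling_rate_hz``; ``labels`` (optional) hold a
    per-sample mode string; ``meta`` records provenance (seed, profile, ...).
    """

    values: np.ndarray
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pressure values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.values.shape:
                raise ValueError("labels must align with values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate_hz


def default_profiles(baseline_kpa: float = 20.0) -> dict[str, ActivityProfile]:
    """Default per-mode waveform parameter table (synthetic design choices).

    Cadences and amplitudes follow the qualitative ordering of the six
    modes: standing is flat; walking is slow and shallow; jogging faster and
    larger; uphill walking slow with a strongly asymmetric cycle; stair
    ascent has large surged cycles with occasional walking-like landing
    cycles; squatting shows rare, large, slow surges.
    """
    p = dict(baseline_kpa=baseline_kpa)
    return {
        "standing": ActivityProfile(mode="standing", amplitude_kpa=0.0, **p),
        "walking": ActivityProfile(
            mode="walking", cadence_hz=0.9, amplitude_kpa=1.5,
            harmonics=((2.0, 0.25, 0.6),), **p,
        ),
        "jogging": ActivityProfile(
            mode="jogging", cadence_hz=1.4, amplitude_kpa=3.0,
            harmonics=((2.0, 0.2, 0.3),), **p,
        ),
        "uphill": ActivityProfile(
            mode="uphill", cadence_hz=0.85, amplitude_kpa=2.5,
            harmonics=((2.0, 0.5, 1.2), (3.0, 0.2, 0.6)), **p,
        ),
        "stairs": ActivityProfile(
            mode="stairs", cadence_hz=0.7, amplitude_kpa=3.5,
            landing_fraction=0.15, **p,
        ),
        "squatting": ActivityProfile(
            mode="squatting", cadence_hz=0.1, amplitude_kpa=6.0,
            surge_duration_s=3.0, **p,
        ),
    }


def _periodic(profile: ActivityProfile, t: np.ndarray) -> np.ndarray:
    """Fundamental sinusoid plus shaping harmonics, zero-mean."""
    w = 2.0 * np.pi * profile.cadence_hz
    s = np.sin(w * t)
    for mult, rel, phase in profile.harmonics:
        s = s + rel * np.sin(mult * w * t + phase)
    return profile.amplitude_kpa * s


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-amplitude raised-cosine bump over n samples, zero at both ends."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _squat(profile: ActivityProfile, n: int, fs: float) -> np.ndarray:
    period = int(round(fs / profile.cadence_hz))
    surge_len = int(round(profile.surge_duration_s * fs))
    surge_len = min(surge_len, period)
    cycle = np.zeros(period)
    cycle[:surge_len] = profile.amplitude_kpa * _raised_cosine(surge_len)
    reps = int(np.ceil(n / period))
    return np.tile(cycle, reps)[:n]


def _stair_cycle(profile: ActivityProfile, fs: float) -> np.ndarray:
    """One surged stair-ascent cycle: asymmetric push-off bump plus dip."""
    n = int(round(fs / profile.cadence_hz))
    u = np.arange(n) / n
    bump = np.where(u < 0.55, np.sin(np.pi * u / 0.55) ** 2, 0.0)
    dip = np.where(u >= 0.55, -0.25 * np.sin(np.pi * (u - 0.55) / 0.45), 0.0)
    return profile.amplitude_kpa * (bump + dip)


def _walking_cycle(walk: ActivityProfile, fs: float) -> np.ndarray:
    n = int(round(fs / walk.cadence_hz))
    return _periodic(walk, np.arange(n) / fs)


def _stairs(profile: ActivityProfile, n: int, fs: float, rng: np.random.Generator,
            walking_profile: Optional[ActivityProfile]) -> np.ndarray:
    if walking_profile is None:
        walking_profile = default_profiles(profile.baseline_kpa)["walking"]
    stair = _stair_cycle(profile, fs)
    landing = _walking_cycle(walking_profile, fs)
    parts: list[np.ndarray] = []
    total = 0
    while total < n:
        cyc = landing if rng.random() < profile.landing_fraction else stair
        parts.append(cyc)
        total += cyc.size
    return np.concatenate(parts)[:n]


def mode_waveform(
    profile: ActivityProfile,
    duration_s: float,
    seed: int,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
    walking_profile: Optional[ActivityProfile] = None,
) -> PressureTrace:
    """Generate one labeled pressure trace for a single mode.

    Deterministic given ``seed``; noise, drift and (for stairs) the landing
    cycle draws all derive from it.  ``walking_profile`` supplies the shape
    of stair landing cycles (defaults to the default walking profile at the
    same baseline).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    fs = float(sampling_rate_hz)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    if profile.mode == "standing":
        signal = np.zeros(n)
    elif profile.mode in ("walking", "jogging", "uphill"):
        signal = _periodic(profile, t)
    elif profile.mode == "squatting":
        signal = _squat(profile, n, fs)
    elif profile.mode == "stairs":
        signal = _stairs(profile, n, fs, rng, walking_profile)
    else:  # pragma: no cover - guarded by ActivityProfile.__post_init__
        raise ValueError(f"unknown mode {profile.mode!r}")

    values = profile.baseline_kpa + signal
    values = values + profile.drift_kpa_per_min * (t / 60.0)
    if profile.noise_sd_kpa > 0:
        values = values + rng.normal(0.0, profile.noise_sd_kpa, size=n)

    labels = np.full(n, profile.mode, dtype=object)
    meta = {"mode": profile.mode, "seed": int(seed), "baseline_kpa": profile.baseline_kpa}
    return PressureTrace(values=values, sampling_rate_hz=fs, labels=labels, meta=meta)


def generate_session(
    profiles: Sequence[ActivityProfile],
    durations_s: Sequence[float],
    seed: int,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
) -> PressureTrace:
    """Concatenate labeled per-mode segments into one session stream.

    Each segment receives an independent child seed spawned from ``seed``,
    so the session is reproducible as a whole and per segment.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be non-empty")
    if len(profiles) != len(durations_s):
        raise ValueError("profiles and durations_s must have equal length")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(profiles)) % (2**31)
    segments = [
        mode_waveform(p, d, int(s), sampling_rate_hz)
        for p, d, s in zip(profiles, durations_s, child_seeds)
    ]
    values = np.concatenate([seg.values for seg in segments])
    labels = np.concatenate([seg.labels for seg in segments])
    meta = {"seed": int(seed), "segments": [seg.meta for seg in segments]}
    return PressureTrace(values=values, sampling_rate_hz=float(sampling_rate_hz),
                         labels=labels, meta=meta)
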