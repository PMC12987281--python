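"""sEMG linear-envelope chain and net metabolic cost.

The envelope chain follows standard surface-EMG practice: MVC
normalization, 20--500 Hz band-pass, full-wave rectification, 6 Hz low-pass
(the "linear envelope"), all filters 4th-order Butterworth applied
forward--backward for zero phase.  Metabolic power uses the Brockway
energy equivalents (16.58 kJ/L O2, 4.51 kJ/L CO2), normalized to body mass
and referenced to a standing baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "EmgTrace",
    "MetabolicSample",
    "emg_envelope",
    "rms_activity",
    "gait_cycle_resample",
    "net_metabolic_rate",
]

BANDPASS_HZ = (20.0, 500.0)
ENVELOPE_LOWPASS_HZ = 6.0
FILTER_ORDER = 4

#: Brockway energy equivalents, kJ per litre of gas exchanged.
KJ_PER_L_O2 = 16.58
KJ_PER_L_CO2 = 4.51

RER_BOUNDS = (0.6, 1.3)


@dataclass
class EmgTrace:
    """Raw surface-EMG recording (mV) with its MVC reference amplitude."""

    values: np.ndarray
    sampling_rate_hz: float = 2000.0
    mvc_reference: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate_hz <= 2 * BANDPASS_HZ[1]:
            raise ValueError(
                f"sampling rate {self.sampling_rate_hz} Hz too low for the "
                f"{BANDPASS_HZ[1]} Hz band edge"
            )
        if self.mvc_reference <= 0:
            raise ValueError("mvc_reference must be > 0")


@dataclass(frozen=True)
class MetabolicSample:
    """Breath-averaged gas exchange with the subject's mass and standing baseline.

    vo2/vco2 in mL/min, body_mass in kg, standing_baseline in W/kg.
    """

    vo2: float
    vco2: float
    body_mass: float
    standing_baseline: float

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if self.vo2 < 0 or self.vco2 < 0:
            raise ValueError("gas volumes must be >= 0")


def emg_envelope(trace: EmgTrace) -> np.ndarray:
    """Linear envelope of an sEMG trace, in %MVC.

    Pipeline: divide by the MVC reference, band-pass 20--500 Hz, full-wave
    rectify, low-pass 6 Hz; zero-phase (forward-backward) Butterworth
    filters throughout.  Small negative excursions introduced by the final
    smoothing are clipped to 0.
    """
    x = trace.values / trace.mvc_reference * 100.0
    if x.size == 0:
        return x
    nyq = trace.sampling_rate_hz / 2.0
    sos_bp = sps.butter(FILTER_ORDER, [BANDPASS_HZ[0] / nyq, BANDPASS_HZ[1] / nyq],
                        btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos_bp, x)
    x = np.abs(x)
    sos_lp = sps.butter(FILTER_ORDER, ENVELOPE_LOWPASS_HZ / nyq, btype="lowpass",
                        output="sos")
    env = sps.sosfiltfilt(sos_lp, x)
    return np.clip(env, 0.0, None)


def rms_activity(envelope: np.ndarray) -> float:
    """Root-mean-square of an envelope (%MVC) -- the scalar activity summary."""
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        raise ValueError("envelope must be non-empty")
    return float(np.sqrt(np.mean(env**2)))


def gait_cycle_resample(
    envelope: np.ndarray, cycle_boundaries: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average an envelope over gait cycles on a 0--100% cycle axis.

    ``cycle_boundaries`` are sample indices of consecutive cycle starts
    (``k`` boundaries delimit ``k-1`` complete cycles).  Each cycle is
    linearly resampled to 101 points; returns the across-cycle mean curve
    and its per-point standard deviation.
    """
    env = np.asarray(envelope, dtype=float)
    bounds = np.asarray(cycle_boundaries, dtype=int)
    if bounds.size < 2:
        raise ValueError("need at least one complete cycle (two boundaries)")
    if np.any(np.diff(bounds) <= 0) or bounds[0] < 0 or bounds[-1] > env.size - 1:
        raise ValueError("cycle boundaries must be increasing indices into the envelope")
    grid = np.linspace(0.0, 1.0, 101)
    curves = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = env[a : b + 1]
        u = np.linspace(0.0, 1.0, seg.size)
        curves.append(np.interp(grid, u, seg))
    stack = np.vstack(curves)
    return stack.mean(axis=0), stack.std(axis=0)


def net_metabolic_rate(sample: MetabolicSample) -> float:
    """Net mass-specific metabolic power, W/kg.

    Gross power from the Brockway equation (16.58 kJ/L * VO2 + 4.51 kJ/L *
    VCO2, per minute, converted to watts), divided by body mass, minus the
    standing baseline.  A respiratory exchange ratio outside [0.6, 1.3]
    triggers a warning (non-physiological steady state).
    """
    if sample.vo2 > 0:
        rer = sample.vco2 / sample.vo2
        if not RER_BOUNDS[0] <= rer <= RER_BOUNDS[1]:
            warnings.warn(
                f"respiratory exchange ratio {rer:.3f} outside physiological "
                f"bounds {RER_BOUNDS}", stacklevel=2,
            )
    kj_per_min = KJ_PER_L_O2 * sample.vo2 / 1000.0 + KJ_PER_L_CO2 * sample.vco2 / 1000.0
    watts = kj_per_min * 1000.0 / 60.0
    return watts / sample.body_mass - sample.standing_baseline
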