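"""Mapping control variables to optical stimuli and rendering light traces.

The excitatory control variable U_C in [0, 1] jointly modulates the frequency,
width and intensity of 465 nm pulse trains:

    pulse frequency = 10 * U_C + 10   (Hz)
    pulse width     = 5 * U_C         (ms)
    pulse power     = 13.2 * U_C      (mW / mm^2)

The inhibitory control variable U_H in [0, 1] sets the forward current of the
590 nm LED channel directly (amperes); a configurable current-to-irradiance
curve (linear to 10.8 mW/mm^2 at 1 A by default) gives the effective power at
the preparation.  For fiber-coupled single-unit control the scalar output u is
converted directly to light power through a per-fiber gain G.

Beyond the standard square pulse train, U_C can be mapped onto a family of
alternative 465 nm waveforms (all peaking at 13.4 * U_C mW/mm^2):

* ``triangle`` — 10 Hz symmetric ramps with a 0.22 mW ms^-1 mm^-2 rising slope;
* ``sine``     — half-wave-rectified 13.4 * U_C * sin(2 pi 10 t);
* ``prbs``     — binary {0, 13.4 * U_C} levels redrawn at 150 Hz from a
  maximal-length linear-feedback shift register;
* ``continuous`` — constant 13.4 * U_C.

Streaming variants (the ``*Player`` classes) keep phase and register state
across calls so the closed-loop engine can change U_C every control period
without phase discontinuities or pulse pile-up.

The module also renders the punctate whisker-deflection waveform used for
sensory stimulation in vivo: exponential rising and falling phases, 8 degrees
total excursion, 99% rise/fall complete in 5 ms (1600 deg/s average rising
velocity), repeated at the train frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PulseTrainCommand", "LEDCommand", "FiberCalibration", "WaveformSpec",
    "OpticalTrace", "map_Uc_to_pulse_params", "map_UH_to_led_current",
    "map_u_to_fiber_power", "render_waveform", "render_whisker_deflection",
    "PulseTrainPlayer", "WaveformPlayer", "Lfsr",
]

#: Eq.-style continuous mapping coefficient (mW/mm^2 at U_C = 1).
PULSE_POWER_COEFF = 13.2
#: Peak-power coefficient of the waveform family and on-off pulses.
WAVEFORM_PEAK_COEFF = 13.4
#: Default current-to-irradiance slope of the 590 nm channel (mW/mm^2 per A).
YELLOW_POWER_PER_AMP = 10.8


@dataclass(frozen=True)
class PulseTrainCommand:
    """Parametric description of a periodic optical pulse train."""

    freq: float          # Hz
    width: float         # ms
    power: float         # mW/mm^2
    wavelength: float = 465.0

    def __post_init__(self) -> None:
        if self.freq < 0 or self.width < 0 or self.power < 0:
            raise ValueError("pulse parameters must be non-negative")
        if self.freq > 0 and self.width / 1000.0 > 1.0 / self.freq:
            raise ValueError("pulse width exceeds the pulse period")


@dataclass(frozen=True)
class LEDCommand:
    """Yellow (590 nm) channel command: drive current and effective power."""

    current: float                       # amperes
    power: float                         # mW/mm^2
    wavelength: float = 590.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.current <= 1.0):
            raise ValueError("LED current must lie in [0, 1] A")


@dataclass(frozen=True)
class FiberCalibration:
    """Optical-fiber gain: light power = G * u (mW/mm^2 per unit output)."""

    G: float

    def __post_init__(self) -> None:
        if not (self.G > 0):
            raise ValueError("fiber gain G must be positive")


@dataclass(frozen=True)
class OpticalTrace:
    """Sampled light-power (or angle) trace with a fixed sample interval."""

    sample_interval: float
    samples: np.ndarray
    units: str = "mW/mm^2"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_interval


@dataclass(frozen=True)
class WaveformSpec:
    """Waveform family selector and its per-kind parameters."""

    kind: str                         # square | triangle | sine | prbs | continuous
    carrier_freq: float = 10.0        # Hz, periodic kinds
    rising_slope: float = 0.22        # mW ms^-1 mm^-2, triangle
    peak_coeff: float = WAVEFORM_PEAK_COEFF
    prbs_update: float = 150.0        # Hz
    prbs_order: int = 15

    def __post_init__(self) -> None:
        if self.kind not in ("square", "triangle", "sine", "prbs", "continuous"):
            raise ValueError(f"unknown waveform kind: {self.kind!r}")
        if min(self.carrier_freq, self.rising_slope, self.peak_coeff, self.prbs_update) < 0:
            raise ValueError("waveform parameters must be non-negative")
        if self.prbs_order < 2:
            raise ValueError("prbs_order must be >= 2")


def _check_unit_interval(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0) or not math.isfinite(x):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def map_Uc_to_pulse_params(U_C: float, power_coeff: float = PULSE_POWER_COEFF) -> PulseTrainCommand:
    """Excitatory mapping: U_C -> (frequency, width, power) of the blue train."""
    _check_unit_interval(U_C, "U_C")
    return PulseTrainCommand(
        freq=10.0 * U_C + 10.0,
        width=5.0 * U_C,
        power=power_coeff * U_C,
    )


def map_UH_to_led_current(
    U_H: float, power_per_amp: float = YELLOW_POWER_PER_AMP
) -> LEDCommand:
    """Inhibitory mapping: U_H -> LED current (A) and effective 590 nm power."""
    _check_unit_interval(U_H, "U_H")
    return LEDCommand(current=U_H, power=power_per_amp * U_H)


def map_u_to_fiber_power(u: float, cal: FiberCalibration) -> float:
    """Fiber-coupled mapping: light power = G * u (mW/mm^2)."""
    _check_unit_interval(u, "u")
    return cal.G * u


# ---------------------------------------------------------------------------
# Maximal-length shift register for PRBS stimuli
# ---------------------------------------------------------------------------

#: Feedback taps (1-based bit positions) giving maximal-length sequences.
_MAXIMAL_TAPS = {
    5: (5, 3), 7: (7, 6), 9: (9, 5), 11: (11, 9), 15: (15, 14), 20: (20, 17),
}


class Lfsr:
    """Fibonacci linear-feedback shift register emitting a maximal-length
    binary sequence of period 2**order - 1."""

    def __init__(self, order: int = 15, seed: int = 1):
        if order not in _MAXIMAL_TAPS:
            raise ValueError(f"no maximal taps tabled for order {order}")
        self.order = order
        self.taps = _MAXIMAL_TAPS[order]
        mask = (1 << order) - 1
        self.state = (int(seed) & mask) or 1  # never the all-zero lock-up state
        self._mask = mask

    def next_bit(self) -> int:
        bit = 0
        for tap in self.taps:
            bit ^= (self.state >> (tap - 1)) & 1
        self.state = ((self.state << 1) | bit) & self._mask
        return bit

    def bits(self, n: int) -> np.ndarray:
        return np.fromiter((self.next_bit() for _ in range(n)), dtype=np.int8, count=n)


# ---------------------------------------------------------------------------
# Streaming renderers
# ---------------------------------------------------------------------------


class PulseTrainPlayer:
    """Streaming square-pulse renderer with a continuous phase accumulator.

    Phase advances as phi += freq * dt and a pulse fires on wraparound, so
    raising the commanded frequency mid-train never piles pulses up.  Pulse
    width may be a non-integer number of samples; the trailing sample is
    scaled by its fractional overlap so the energy per second equals
    freq * width * power up to one sample's quantisation.
    """

    def __init__(self) -> None:
        self.phase = 1.0            # fire immediately on first nonzero freq
        self._remaining_ms = 0.0
        self._power = 0.0

    def step(self, cmd: PulseTrainCommand, dt: float) -> float:
        dt_ms = dt * 1000.0
        out = 0.0
        if self._remaining_ms > 0.0:
            out = self._power * min(1.0, self._remaining_ms / dt_ms)
            self._remaining_ms -= dt_ms
        if cmd.freq > 0.0:
            self.phase += cmd.freq * dt
            if self.phase >= 1.0:
                self.phase -= math.floor(self.phase)
                if cmd.width > 0.0 and cmd.power > 0.0 and self._remaining_ms <= 0.0:
                    self._remaining_ms = cmd.width
                    self._power = cmd.power
                    out = cmd.power * min(1.0, cmd.width / dt_ms)
                    self._remaining_ms -= dt_ms
        return out


class WaveformPlayer:
    """Streaming renderer for the waveform family under time-varying U_C."""

    def __init__(self, spec: WaveformSpec, rng_seed: int = 1):
        self.spec = spec
        self.phase = 0.0
        self._pulses = PulseTrainPlayer()
        self._lfsr = Lfsr(spec.prbs_order, seed=rng_seed)
        self._prbs_level = 0
        self._prbs_clock = 0.0

    def step(self, U_C: float, dt: float) -> float:
        spec = self.spec
        peak = spec.peak_coeff * U_C
        if spec.kind == "square":
            return self._pulses.step(map_Uc_to_pulse_params(U_C), dt)
        if spec.kind == "continuous":
            return peak
        if spec.kind == "sine":
            self.phase = (self.phase + spec.carrier_freq * dt) % 1.0
            return peak * max(0.0, math.sin(2.0 * math.pi * self.phase))
        if spec.kind == "triangle":
            self.phase = (self.phase + spec.carrier_freq * dt) % 1.0
            period_ms = 1000.0 / spec.carrier_freq
            rise_ms = min(peak / spec.rising_slope if spec.rising_slope > 0 else 0.0,
                          period_ms / 2.0)
            peak_eff = rise_ms * spec.rising_slope
            t_ms = self.phase * period_ms
            if t_ms < rise_ms:
                return spec.rising_slope * t_ms
            if t_ms < 2.0 * rise_ms:
                return peak_eff - spec.rising_slope * (t_ms - rise_ms)
            return 0.0
        # prbs
        self._prbs_clock += dt * spec.prbs_update
        while self._prbs_clock >= 1.0:
            self._prbs_clock -= 1.0
            self._prbs_level = self._lfsr.next_bit()
        return peak * self._prbs_level


def render_waveform(
    spec: WaveformSpec,
    U_C: float,
    duration: float,
    sample_interval: float = 0.001,
    rng_seed: int = 1,
) -> OpticalTrace:
    """Render a constant-U_C optical trace of the given kind."""
    _check_unit_interval(U_C, "U_C")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / sample_interval))
    player = WaveformPlayer(spec, rng_seed=rng_seed)
    samples = np.empty(n)
    for i in range(n):
        samples[i] = player.step(U_C, sample_interval)
    return OpticalTrace(sample_interval=sample_interval, samples=samples)


# ---------------------------------------------------------------------------
# Whisker deflection waveform
# ---------------------------------------------------------------------------


def _deflection_profile(sample_interval: float, excursion: float,
                        rise_time: float) -> np.ndarray:
    """One punctate deflection: exponential rise to the full excursion over
    ``rise_time`` (99% criterion), mirrored exponential fall."""
    tau = rise_time / math.log(100.0)           # 99% complete at rise_time
    t = np.arange(0.0, rise_time, sample_interval)
    rise = excursion * np.minimum(1.0, (1.0 - np.exp(-t / tau)) / 0.99)
    peak = np.array([excursion])
    fall = rise[::-1]
    return np.concatenate([rise, peak, fall])


def render_whisker_deflection(
    train_freq: float,
    duration: float,
    sample_interval: float = 0.0001,
    excursion: float = 8.0,
    rise_time: float = 0.005,
) -> OpticalTrace:
    """Angular-position trace (degrees) of a punctate deflection train.

    Each deflection rises exponentially to ``excursion`` degrees within
    ``rise_time`` (99% criterion; average rising velocity excursion/rise_time
    = 1600 deg/s at the defaults) and falls symmetrically; deflections repeat
    at ``train_freq`` (Hz).  A zero train frequency yields a flat zero trace.
    """
    if duration <= 0 or sample_interval <= 0:
        raise ValueError("duration and sample_interval must be positive")
    if train_freq < 0:
        raise ValueError("train_freq must be non-negative")
    if train_freq > 0 and 1.0 / train_freq < 2.0 * rise_time:
        raise ValueError("train frequency too high for the deflection duration")
    n = int(round(duration / sample_interval))
    trace = np.zeros(n)
    if train_freq > 0:
        profile = _deflection_profile(sample_interval, excursion, rise_time)
        period = int(round(1.0 / train_freq / sample_interval))
        for start in range(0, n, period):
            stop = min(start + profile.size, n)
            trace[start:stop] = profile[: stop - start]
    return OpticalTrace(sample_interval=sample_interval, samples=trace, units="deg")
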