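"""Firing-rate estimation and the four feedback control laws.

The controlled variable is the population firing rate in Hz per sorted unit.
Every ``dt`` (4 ms by default) the instantaneous binned rate is passed through
a first-order exponential averaging filter

    f[t] = alpha * r[t] + (1 - alpha) * f[t - dt],      alpha = 1 - exp(-dt/tau)

and the error e[t] = f* - f[t] against the target (setpoint) f* feeds one of:

* a velocity-form PI controller,
      u[t] = u[t-1] + K * (e[t] - e[t-1] + (Ts/Ti) * e[t]),
  whose scalar output is split into an excitatory and an inhibitory control
  variable, U_C = clip(u + delta1, 0, 1) and U_H = clip(-u + delta2, 0, 1);
* a pure integral controller (proportional term zero), u clipped to [0, 1],
  used for single-unit control through an optical fiber;
* an excitatory on-off (bang-bang) controller that emits a fixed blue pulse
  whenever the accumulated error is positive, at most every 100 ms (10 Hz);
* an inhibitory on-off controller that gates continuous yellow light on
  whenever the accumulated error is negative.

Anti-windup: for the PI controller the integrating state u itself is clipped
to the interval [-delta2, 1 - delta1] that keeps both split outputs in [0, 1],
so saturation cannot accumulate error.  The on-off accumulator is clipped at a
configurable magnitude bound for the same reason.

All step functions are pure in the sense that they return a new state and
never mutate their argument, which makes them directly usable in streaming
loops and trivially checkable against literal transcriptions of the update
equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "RateFilterConfig", "RateEstimate", "TargetSchedule", "PIConfig", "PIState",
    "OnOffState", "IntegralConfig", "OnOffPulse",
    "compute_alpha", "update_rate_estimate", "pi_step", "split_control",
    "onoff_excitatory_step", "onoff_inhibitory_step", "integral_step",
]

#: Minimum interval between excitatory on-off pulse onsets (s) -> 10 Hz cap.
ONOFF_MIN_PULSE_INTERVAL = 0.1
#: Excitatory on-off pulse parameters: width (ms), power (mW/mm^2), wavelength (nm).
ONOFF_PULSE_WIDTH_MS = 5.0
ONOFF_PULSE_POWER = 13.4
ONOFF_PULSE_WAVELENGTH = 465.0


def compute_alpha(dt: float, tau: float) -> float:
    """Smoothing weight of the first-order rate filter, 1 - exp(-dt/tau).

    Parameters
    ----------
    dt : float
        Filter update interval in seconds (> 0).
    tau : float
        Filter time constant in seconds (> 0).
    """
    if not (dt > 0) or not (tau > 0):
        raise ValueError(f"dt and tau must be positive, got dt={dt}, tau={tau}")
    return 1.0 - math.exp(-dt / tau)


@dataclass(frozen=True)
class RateFilterConfig:
    """Parameters of the exponential firing-rate filter.

    ``alpha`` is derived from ``dt`` and ``tau`` unless given explicitly, in
    which case it must agree with 1 - exp(-dt/tau) to 1e-12.
    """

    dt: float = 0.004
    tau: float = 2.5
    n_units: int = 1
    alpha: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.dt > 0) or not (self.tau > 0):
            raise ValueError("dt and tau must be positive")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        expected = compute_alpha(self.dt, self.tau)
        if self.alpha is None:
            object.__setattr__(self, "alpha", expected)
        elif not (0.0 < self.alpha < 1.0) or abs(self.alpha - expected) > 1e-12:
            raise ValueError(
                f"alpha={self.alpha} inconsistent with 1-exp(-dt/tau)={expected}"
            )


@dataclass(frozen=True)
class RateEstimate:
    """Smoothed population rate f and the latest binned rate, both Hz/unit."""

    f: float = 0.0
    r_inst: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.f < 0 or self.r_inst < 0:
            raise ValueError("rates must be non-negative")


def update_rate_estimate(
    state: RateEstimate, cfg: RateFilterConfig, n_spikes: int
) -> RateEstimate:
    """One filter tick: bin the spike count and blend it into the estimate."""
    if n_spikes < 0:
        raise ValueError(f"negative spike count: {n_spikes}")
    r_inst = n_spikes / (cfg.n_units * cfg.dt)
    f_new = cfg.alpha * r_inst + (1.0 - cfg.alpha) * state.f
    return RateEstimate(f=f_new, r_inst=r_inst, t=state.t + cfg.dt)


@dataclass(frozen=True)
class TargetSchedule:
    """Piecewise-constant target firing rate, Hz/unit.

    ``segments`` is an ordered list of (start time s, target Hz/unit) pairs
    with strictly increasing start times.  The target before the first
    segment equals the first segment's rate.
    """

    segments: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        starts = [s for s, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(r < 0 for _, r in self.segments):
            raise ValueError("target rates must be non-negative")
        object.__setattr__(self, "segments", tuple((float(s), float(r)) for s, r in self.segments))

    @classmethod
    def constant(cls, rate: float) -> "TargetSchedule":
        return cls(segments=[(0.0, rate)])

    def target_at(self, t: float) -> float:
        rate = self.segments[0][1]
        for start, r in self.segments:
            if t >= start:
                rate = r
            else:
                break
        return rate


@dataclass(frozen=True)
class PIConfig:
    """PI controller parameters.

    K is the dimensionless proportional gain, Ti the integral time constant
    (s), Ts the control period (s), and delta1/delta2 the split offsets that
    set the overlap between excitatory and inhibitory channel activation.
    """

    K: float = 0.1
    Ti: float = 1.0
    Ts: float = 0.01
    delta1: float = 0.25
    delta2: float = 0.25
    u_min: float = 0.0
    u_max: float = 1.0

    def __post_init__(self) -> None:
        if self.Ti <= 0 or self.Ts <= 0:
            raise ValueError("Ti and Ts must be positive")
        if not (0.0 <= self.delta1 <= 1.0 and 0.0 <= self.delta2 <= 1.0):
            raise ValueError("delta1 and delta2 must lie in [0, 1]")

    @property
    def u_lo(self) -> float:
        """Lower anti-windup bound on u: keeps U_H = -u + delta2 <= u_max."""
        return -(self.u_max - self.delta2)

    @property
    def u_hi(self) -> float:
        """Upper anti-windup bound on u: keeps U_C = u + delta1 <= u_max."""
        return self.u_max - self.delta1


@dataclass(frozen=True)
class PIState:
    """Controller output u and the previous error sample."""

    u: float = 0.0
    e_prev: float = 0.0


def pi_step(state: PIState, cfg: PIConfig, e: float) -> PIState:
    """Velocity-form PI update with anti-windup clipping of u itself."""
    if not math.isfinite(e):
        raise ValueError(f"non-finite error input: {e}")
    u = state.u + cfg.K * (e - state.e_prev + (cfg.Ts / cfg.Ti) * e)
    u = min(max(u, cfg.u_lo), cfg.u_hi)
    return PIState(u=u, e_prev=e)


def split_control(u: float, cfg: PIConfig) -> tuple[float, float]:
    """Split the scalar control output into (U_C, U_H), each clipped to [0, 1]."""
    if not math.isfinite(u):
        raise ValueError(f"non-finite control value: {u}")
    u_c = min(max(u + cfg.delta1, cfg.u_min), cfg.u_max)
    u_h = min(max(-u + cfg.delta2, cfg.u_min), cfg.u_max)
    return u_c, u_h


@dataclass(frozen=True)
class IntegralConfig:
    """Pure integral controller (proportional component zero); u in [0, 1]."""

    Ti: float = 1.0
    Ts: float = 0.01
    u_min: float = 0.0
    u_max: float = 1.0

    def __post_init__(self) -> None:
        if self.Ti <= 0 or self.Ts <= 0:
            raise ValueError("Ti and Ts must be positive")


def integral_step(state: PIState, cfg: IntegralConfig, e: float) -> PIState:
    """u[t] = clip(u[t-1] + (Ts/Ti) * e[t])."""
    if not math.isfinite(e):
        raise ValueError(f"non-finite error input: {e}")
    u = state.u + (cfg.Ts / cfg.Ti) * e
    u = min(max(u, cfg.u_min), cfg.u_max)
    return PIState(u=u, e_prev=e)


@dataclass(frozen=True)
class OnOffPulse:
    """Blue pulse emitted by the excitatory on-off controller."""

    t: float
    width_ms: float = ONOFF_PULSE_WIDTH_MS
    power: float = ONOFF_PULSE_POWER
    wavelength: float = ONOFF_PULSE_WAVELENGTH


@dataclass(frozen=True)
class OnOffState:
    """Accumulated error I_f (Hz*s/unit) and pulse bookkeeping.

    The error accumulator integrates e*dt at the filter rate and is clipped at
    ``i_bound`` in magnitude so that long saturation episodes cannot wind up.
    """

    mode: str = "excitatory"  # "excitatory" | "inhibitory"
    I_f: float = 0.0
    t_last_pulse: float = -math.inf
    gate: bool = False
    i_bound: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown on-off mode: {self.mode!r}")
        if self.i_bound <= 0:
            raise ValueError("i_bound must be positive")


def _accumulate(state: OnOffState, e: float, dt: float) -> float:
    if not math.isfinite(e):
        raise ValueError(f"non-finite error input: {e}")
    I_f = state.I_f + e * dt
    return min(max(I_f, -state.i_bound), state.i_bound)


def onoff_excitatory_step(
    state: OnOffState, e: float, dt: float, t: float
) -> tuple[OnOffState, Optional[OnOffPulse]]:
    """Accumulate error; emit a 5 ms blue pulse when I_f > 0, at most at 10 Hz."""
    if state.mode != "excitatory":
        raise ValueError("state is not in excitatory mode")
    I_f = _accumulate(state, e, dt)
    pulse = None
    # 1 ns slack absorbs float jitter in accumulated tick times
    if I_f > 0.0 and t - state.t_last_pulse >= ONOFF_MIN_PULSE_INTERVAL - 1e-9:
        pulse = OnOffPulse(t=t)
        state = replace(state, I_f=I_f, t_last_pulse=t, gate=True)
    else:
        state = replace(state, I_f=I_f, gate=False)
    return state, pulse


def onoff_inhibitory_step(
    state: OnOffState, e: float, dt: float
) -> tuple[OnOffState, bool]:
    """Accumulate error; yellow light is ON exactly while I_f < 0."""
    if state.mode != "inhibitory":
        raise ValueError("state is not in inhibitory mode")
    I_f = _accumulate(state, e, dt)
    light_on = I_f < 0.0
    return replace(state, I_f=I_f, gate=light_on), light_on
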