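"""Closed-loop orchestration: controller-plant loops on a multi-rate clock.

The simulation advances on a 1 ms master grid.  The firing-rate filter ticks
every 4 ms, controllers tick every 10 ms (both configurable), and the
controller reads a rate estimate delayed by the loop latency (5 ms by
default, emulating the online spike-classification latency of the real-time
system).  The engine supports

* plain closed-loop runs (:func:`run_closed_loop`), optionally preceded by a
  conditioning "pre-pulse": a 10 s train of U_C = 1 stimuli ending 10 s
  before control onset;
* open-loop replay of a recorded trial's optical traces against a
  (re-seeded) plant (:func:`replay_open_loop`);
* control locking (:func:`lock_control`): feedback runs normally up to a
  lock time, then the stimulus is frozen at its most recent value or at the
  first-half mean for the remainder of the trial;
* single-parameter sweeps over K, Ti or tau with per-value stability
  summaries (:func:`sweep_parameters`).

Every run is deterministic given its seed, and the complete trial — spikes,
rate/target/control traces, optical traces, config snapshot — is returned as
a :class:`TrialRecord`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .controllers import (
    IntegralConfig,
    OnOffState,
    PIConfig,
    PIState,
    RateFilterConfig,
    TargetSchedule,
    compute_alpha,
    integral_step,
    onoff_excitatory_step,
    onoff_inhibitory_step,
    pi_step,
    split_control,
)
from .controllers import ONOFF_PULSE_POWER, ONOFF_PULSE_WIDTH_MS
from .metrics import SpikeEventList, SettlingConfig, rms_tracking_error, settling_time
from .plants import NetworkPlant, TCUPlant
from .stimulus import (
    FiberCalibration,
    WaveformPlayer,
    WaveformSpec,
    map_UH_to_led_current,
    map_u_to_fiber_power,
)

__all__ = [
    "LoopTiming", "TrialRecord", "ConfigurationError",
    "PIRateController", "IntegralRateController",
    "OnOffExcitatoryController", "OnOffInhibitoryController",
    "make_controller", "run_closed_loop", "replay_open_loop", "lock_control",
    "sweep_parameters",
]

#: Continuous 590 nm power during the inhibitory on-off "on" phase (mW/mm^2).
ONOFF_YELLOW_POWER = 11.8


class ConfigurationError(ValueError):
    """Raised for incompatible controller/plant/timing configurations."""


@dataclass(frozen=True)
class LoopTiming:
    """Multi-rate clock: simulation, filter and control periods plus latency."""

    sim_step: float = 0.001
    filter_step: float = 0.004
    control_step: float = 0.01
    loop_latency: float = 0.005

    def __post_init__(self) -> None:
        for name in ("sim_step", "filter_step", "control_step"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.loop_latency < 0:
            raise ConfigurationError("loop_latency must be non-negative")
        for name in ("filter_step", "control_step"):
            ratio = getattr(self, name) / self.sim_step
            if abs(ratio - round(ratio)) > 1e-9:
                raise ConfigurationError(
                    f"{name} must be an integer multiple of sim_step")


# ---------------------------------------------------------------------------
# Controller wrappers: control law + stimulus synthesis, streaming interface
# ---------------------------------------------------------------------------


class PIRateController:
    """PI law with channel splitting; blue rendered as the configured
    waveform kind (standard square pulse train by default), yellow as
    continuously modulated LED power."""

    uses_yellow = True
    updates_at_filter_rate = False
    kind = "pi"

    def __init__(
        self,
        cfg: PIConfig = PIConfig(),
        tau: float = 2.5,
        waveform: Optional[WaveformSpec] = None,
    ):
        self.cfg = cfg
        self.tau = tau
        self.waveform = waveform or WaveformSpec(kind="square")
        self.reset(0)

    def reset(self, seed: int) -> None:
        self.state = PIState()
        self.U_C = 0.0
        self.U_H = 0.0
        self._player = WaveformPlayer(self.waveform, rng_seed=seed + 1)
        self._forced = False

    @property
    def u(self) -> float:
        return self.state.u

    def update(self, e: float, t: float) -> None:
        if self._forced:
            return
        self.state = pi_step(self.state, self.cfg, e)
        self.U_C, self.U_H = split_control(self.state.u, self.cfg)

    def force_u(self, u: float) -> None:
        self.state = PIState(u=u, e_prev=self.state.e_prev)
        self.U_C, self.U_H = split_control(u, self.cfg)
        self._forced = True

    def light(self, dt: float) -> tuple[float, float]:
        blue = self._player.step(self.U_C, dt)
        yellow = map_UH_to_led_current(self.U_H).power
        return blue, yellow

    def pre_pulse_light(self, dt: float) -> tuple[float, float]:
        return self._player.step(1.0, dt), 0.0

    def describe(self) -> dict:
        return {"type": self.kind, "tau": self.tau,
                **dataclasses.asdict(self.cfg),
                "waveform": dataclasses.asdict(self.waveform)}


class IntegralRateController:
    """Pure integral law driving continuous fiber-coupled blue light."""

    uses_yellow = False
    updates_at_filter_rate = False
    kind = "integral"

    def __init__(
        self,
        cfg: IntegralConfig = IntegralConfig(),
        tau: float = 0.8,
        fiber: FiberCalibration = FiberCalibration(G=20.0),
    ):
        self.cfg = cfg
        self.tau = tau
        self.fiber = fiber
        self.reset(0)

    def reset(self, seed: int) -> None:
        self.state = PIState()
        self._forced = False

    @property
    def u(self) -> float:
        return self.state.u

    @property
    def U_C(self) -> float:
        return self.state.u

    U_H = 0.0

    def update(self, e: float, t: float) -> None:
        if self._forced:
            return
        self.state = integral_step(self.state, self.cfg, e)

    def force_u(self, u: float) -> None:
        self.state = PIState(u=min(max(u, 0.0), 1.0), e_prev=self.state.e_prev)
        self._forced = True

    def light(self, dt: float) -> tuple[float, float]:
        return map_u_to_fiber_power(self.state.u, self.fiber), 0.0

    def pre_pulse_light(self, dt: float) -> tuple[float, float]:
        return self.fiber.G, 0.0

    def describe(self) -> dict:
        return {"type": self.kind, "tau": self.tau, "G": self.fiber.G,
                **dataclasses.asdict(self.cfg)}


class OnOffExcitatoryController:
    """Bang-bang excitation: fixed 5 ms blue pulse whenever the integrated
    error is positive, capped at 10 Hz.  Error accumulates at the filter rate."""

    uses_yellow = False
    updates_at_filter_rate = True
    kind = "onoff_excitatory"

    def __init__(self, tau: float = 2.5, i_bound: float = 10.0,
                 pulse_power: float = ONOFF_PULSE_POWER):
        self.tau = tau
        self.i_bound = i_bound
        self.pulse_power = pulse_power
        self.reset(0)

    def reset(self, seed: int) -> None:
        self.state = OnOffState(mode="excitatory", i_bound=self.i_bound)
        self._pulse_remaining_ms = 0.0
        self.U_C = 0.0

    @property
    def u(self) -> float:
        return self.state.I_f

    U_H = 0.0

    def update(self, e: float, t: float, dt: float) -> None:
        self.state, pulse = onoff_excitatory_step(self.state, e, dt, t)
        if pulse is not None:
            self._pulse_remaining_ms = pulse.width_ms
        self.U_C = 1.0 if pulse is not None else 0.0

    def light(self, dt: float) -> tuple[float, float]:
        if self._pulse_remaining_ms <= 0.0:
            return 0.0, 0.0
        dt_ms = dt * 1000.0
        out = self.pulse_power * min(1.0, self._pulse_remaining_ms / dt_ms)
        self._pulse_remaining_ms -= dt_ms
        return out, 0.0

    def pre_pulse_light(self, dt: float) -> tuple[float, float]:
        return self.pulse_power, 0.0

    def describe(self) -> dict:
        return {"type": self.kind, "tau": self.tau, "i_bound": self.i_bound,
                "pulse_power": self.pulse_power,
                "pulse_width_ms": ONOFF_PULSE_WIDTH_MS}


class OnOffInhibitoryController:
    """Bang-bang suppression: continuous yellow light while the integrated
    error is negative."""

    uses_yellow = True
    updates_at_filter_rate = True
    kind = "onoff_inhibitory"

    def __init__(self, tau: float = 2.5, i_bound: float = 10.0,
                 yellow_power: float = ONOFF_YELLOW_POWER):
        self.tau = tau
        self.i_bound = i_bound
        self.yellow_power = yellow_power
        self.reset(0)

    def reset(self, seed: int) -> None:
        self.state = OnOffState(mode="inhibitory", i_bound=self.i_bound)
        self.light_on = False
        self.U_C = 0.0

    @property
    def u(self) -> float:
        return self.state.I_f

    @property
    def U_H(self) -> float:
        return 1.0 if self.light_on else 0.0

    def update(self, e: float, t: float, dt: float) -> None:
        self.state, self.light_on = onoff_inhibitory_step(self.state, e, dt)

    def light(self, dt: float) -> tuple[float, float]:
        return 0.0, self.yellow_power if self.light_on else 0.0

    def pre_pulse_light(self, dt: float) -> tuple[float, float]:
        return 0.0, 0.0

    def describe(self) -> dict:
        return {"type": self.kind, "tau": self.tau, "i_bound": self.i_bound,
                "yellow_power": self.yellow_power}


def make_controller(kind: str, **kwargs):
    """Build a controller wrapper from a flat config dict (CLI / sweeps)."""
    if kind == "pi":
        cfg = PIConfig(
            K=kwargs.get("K", 0.1), Ti=kwargs.get("Ti", 1.0),
            Ts=kwargs.get("Ts", 0.01),
            delta1=kwargs.get("delta1", 0.25), delta2=kwargs.get("delta2", 0.25))
        wf = kwargs.get("waveform")
        if isinstance(wf, str):
            wf = WaveformSpec(kind=wf)
        elif isinstance(wf, dict):
            wf = WaveformSpec(**wf)
        return PIRateController(cfg, tau=kwargs.get("tau", 2.5), waveform=wf)
    if kind == "integral":
        cfg = IntegralConfig(Ti=kwargs.get("Ti", 1.0), Ts=kwargs.get("Ts", 0.01))
        return IntegralRateController(
            cfg, tau=kwargs.get("tau", 0.8),
            fiber=FiberCalibration(G=kwargs.get("G", 20.0)))
    if kind == "onoff_excitatory":
        return OnOffExcitatoryController(
            tau=kwargs.get("tau", 2.5), i_bound=kwargs.get("i_bound", 10.0))
    if kind == "onoff_inhibitory":
        return OnOffInhibitoryController(
            tau=kwargs.get("tau", 2.5), i_bound=kwargs.get("i_bound", 10.0))
    raise ConfigurationError(f"unknown controller kind: {kind!r}")


# ---------------------------------------------------------------------------
# Trial record
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """Complete log of one closed- or open-loop trial."""

    seed: int
    duration: float
    pre_roll: float
    timing: LoopTiming
    spikes: SpikeEventList
    f_times: np.ndarray
    f: np.ndarray
    target: np.ndarray
    u_times: np.ndarray
    u: np.ndarray
    U_C: np.ndarray
    U_H: np.ndarray
    blue: np.ndarray
    yellow: np.ndarray
    whisker: Optional[np.ndarray] = None
    controller_config: dict = field(default_factory=dict)
    plant_config: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    @property
    def light_times(self) -> np.ndarray:
        n = self.blue.size
        return np.arange(n) * self.timing.sim_step - self.pre_roll

    def rms_error(self, window: Optional[tuple[float, float]] = None) -> float:
        """RMS tracking error of the rate estimate; defaults to the final
        half of the control epoch (the final 30 s of a 60 s trial)."""
        if window is None:
            window = (self.duration / 2.0, self.duration)
        return rms_tracking_error(self.f_times, self.f, self.target, window)

    def settling_time(self, cfg: SettlingConfig = SettlingConfig()) -> Optional[float]:
        mask = self.f_times >= 0
        return settling_time(self.f_times[mask], self.f[mask],
                             float(self.target[mask][-1]), cfg, onset=0.0)


# ---------------------------------------------------------------------------
# Core loop
# ---------------------------------------------------------------------------


def _check_pairing(plant, controller, timing: LoopTiming) -> None:
    if isinstance(plant, TCUPlant) and controller.uses_yellow:
        raise ConfigurationError(
            "the single-unit plant has no inhibitory opsin; pair it with an "
            "integral or excitatory on-off controller")
    ts = getattr(getattr(controller, "cfg", None), "Ts", None)
    if ts is not None and abs(ts - timing.control_step) > 1e-12:
        raise ConfigurationError(
            f"controller Ts={ts} does not match timing.control_step="
            f"{timing.control_step}")


def _run_loop(
    plant,
    controller,
    schedule: TargetSchedule,
    duration: float,
    timing: LoopTiming,
    seed: int,
    pre_pulse: bool,
    whisker: Optional[np.ndarray] = None,
    replay: Optional[tuple[np.ndarray, np.ndarray]] = None,
    lock_at: Optional[float] = None,
    lock_mode: str = "last-value",
    annotations: Optional[dict] = None,
) -> TrialRecord:
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if replay is None:
        _check_pairing(plant, controller, timing)
    dt = timing.sim_step
    filter_every = round(timing.filter_step / dt)
    control_every = round(timing.control_step / dt)
    pre_roll = 20.0 if pre_pulse else 0.0
    n_pre = round(pre_roll / dt)
    n_total = n_pre + round(duration / dt)
    is_tcu = isinstance(plant, TCUPlant)

    plant.reset(seed)
    if controller is not None:
        controller.reset(seed)

    filt = RateFilterConfig(
        dt=timing.filter_step,
        tau=getattr(controller, "tau", 2.5) if controller is not None else 2.5,
        n_units=plant.n_units,
    )
    alpha = filt.alpha
    f = 0.0
    f_hist: list[float] = []
    bin_count = 0

    blue_tr = np.zeros(n_total)
    yellow_tr = np.zeros(n_total)
    f_times, f_vals, tgt_vals = [], [], []
    u_times, u_vals, uc_vals, uh_vals = [], [], [], []
    sp_times: list[float] = []
    sp_units: list[int] = []

    lock_u: Optional[float] = None
    latency = timing.loop_latency
    t_start = -pre_roll

    for i in range(n_total):
        t = i * dt - pre_roll
        # --- filter tick: close the previous 4 ms bin ---------------------
        if i % filter_every == 0 and i > 0:
            r_inst = bin_count / (plant.n_units * timing.filter_step)
            f = alpha * r_inst + (1.0 - alpha) * f
            bin_count = 0
            f_hist.append(f)
            f_times.append(t)
            f_vals.append(f)
            tgt_vals.append(schedule.target_at(t))
        # --- controller ticks ---------------------------------------------
        if controller is not None and t >= 0.0:
            locked = lock_at is not None and t >= lock_at
            if locked and lock_u is None:
                if lock_mode == "last-value":
                    lock_u = controller.u
                elif lock_mode == "first-half-mean":
                    lock_u = float(np.mean(u_vals)) if u_vals else controller.u
                else:
                    raise ConfigurationError(f"unknown lock_mode: {lock_mode!r}")
                controller.force_u(lock_u)
            idx = math.floor((t - latency - t_start) / timing.filter_step) - 1
            f_delayed = f_hist[idx] if 0 <= idx < len(f_hist) else 0.0
            e = schedule.target_at(t) - f_delayed
            if controller.updates_at_filter_rate:
                if i % filter_every == 0 and not locked:
                    controller.update(e, t, timing.filter_step)
            elif i % control_every == 0:
                if not locked:
                    controller.update(e, t)
                u_times.append(t)
                u_vals.append(controller.u)
                uc_vals.append(controller.U_C)
                uh_vals.append(controller.U_H)
            if controller.updates_at_filter_rate and i % control_every == 0:
                u_times.append(t)
                u_vals.append(controller.u)
                uc_vals.append(controller.U_C)
                uh_vals.append(controller.U_H)
        # --- stimulus for this step ---------------------------------------
        if replay is not None:
            blue = replay[0][i] if i < replay[0].size else 0.0
            yellow = replay[1][i] if i < replay[1].size else 0.0
        elif controller is None:
            blue = yellow = 0.0
        elif t < 0.0:
            if -20.0 <= t < -10.0:   # conditioning pre-pulse train
                blue, yellow = controller.pre_pulse_light(dt)
            else:
                blue = yellow = 0.0
        else:
            blue, yellow = controller.light(dt)
        blue_tr[i] = blue
        yellow_tr[i] = yellow
        # --- plant ---------------------------------------------------------
        if is_tcu:
            w = whisker[i] if whisker is not None and i < whisker.size else 0.0
            spike = plant.step(blue, w, dt)
            if spike:
                sp_times.append(t)
                sp_units.append(0)
                bin_count += 1
        else:
            counts = plant.step(blue, yellow, dt)
            total = int(counts.sum())
            if total:
                bin_count += total
                for unit in np.repeat(np.nonzero(counts)[0],
                                      counts[np.nonzero(counts)[0]]):
                    sp_times.append(t)
                    sp_units.append(int(unit))

    spikes = SpikeEventList(
        times=np.array(sp_times), units=np.array(sp_units, dtype=int),
        t_start=t_start, t_end=duration, n_units=plant.n_units)
    ann = dict(annotations or {})
    ann["schedule"] = [list(s) for s in schedule.segments]
    if pre_pulse:
        ann["pre_pulse_window"] = (-20.0, -10.0)
    if lock_at is not None:
        ann["lock_window"] = (lock_at, duration)
        ann["lock_mode"] = lock_mode
        ann["lock_u"] = lock_u
    return TrialRecord(
        seed=seed, duration=duration, pre_roll=pre_roll, timing=timing,
        spikes=spikes,
        f_times=np.array(f_times), f=np.array(f_vals), target=np.array(tgt_vals),
        u_times=np.array(u_times), u=np.array(u_vals),
        U_C=np.array(uc_vals), U_H=np.array(uh_vals),
        blue=blue_tr, yellow=yellow_tr,
        whisker=None if whisker is None else np.asarray(whisker, float),
        controller_config=(controller.describe() if controller is not None
                           else {"type": "open_loop"}),
        plant_config=(dataclasses.asdict(plant.params)
                      if dataclasses.is_dataclass(plant.params) else {}),
        annotations=ann,
    )


def run_closed_loop(
    plant,
    controller,
    schedule: TargetSchedule,
    duration: float,
    timing: LoopTiming = LoopTiming(),
    seed: int = 0,
    pre_pulse: bool = False,
    whisker: Optional[np.ndarray] = None,
) -> TrialRecord:
    """Run one closed-loop trial; see module docstring for loop semantics."""
    return _run_loop(plant, controller, schedule, duration, timing, seed,
                     pre_pulse, whisker=whisker)


def replay_open_loop(plant, recorded: TrialRecord, seed: int = 0) -> TrialRecord:
    """Drive the plant open-loop with a recorded trial's optical traces."""
    if recorded.blue.size == 0:
        raise ValueError("record lacks optical traces; cannot replay")
    # reconstruct the target schedule from the recorded target trace
    seg = [(float(recorded.f_times[0]), float(recorded.target[0]))]
    for t, r in zip(recorded.f_times, recorded.target):
        if r != seg[-1][1]:
            seg.append((float(t), float(r)))
    schedule = TargetSchedule(segments=seg)
    rec = _run_loop(
        plant, None, schedule, recorded.duration, recorded.timing, seed,
        pre_pulse=recorded.pre_roll > 0,
        whisker=recorded.whisker,
        replay=(recorded.blue, recorded.yellow),
        annotations={"replay_of_seed": recorded.seed},
    )
    rec.controller_config = {"type": "open_loop_replay",
                             "source": recorded.controller_config}
    return rec


def lock_control(
    plant,
    controller,
    schedule: TargetSchedule,
    lock_mode: str = "last-value",
    lock_at: float = 15.0,
    duration: float = 30.0,
    timing: LoopTiming = LoopTiming(),
    seed: int = 0,
) -> TrialRecord:
    """Closed-loop until ``lock_at``, then the stimulus is frozen."""
    if not (0.0 < lock_at < duration):
        raise ConfigurationError("lock_at must lie strictly inside the trial")
    if lock_mode not in ("last-value", "first-half-mean"):
        raise ConfigurationError(f"unknown lock_mode: {lock_mode!r}")
    if not hasattr(controller, "force_u"):
        raise ConfigurationError(
            f"{controller.kind} controller does not support locking")
    return _run_loop(plant, controller, schedule, duration, timing, seed,
                     pre_pulse=False, lock_at=lock_at, lock_mode=lock_mode)


_SWEEPABLE = ("K", "Ti", "tau")


def sweep_parameters(
    plant,
    base_config: dict,
    grid: dict,
    trial_duration: float = 30.0,
    seeds: tuple[int, ...] = (0, 1, 2, 3),
    schedule: Optional[TargetSchedule] = None,
    timing: LoopTiming = LoopTiming(),
    iqr_multiple: float = 3.0,
    transient_skip: float = 5.0,
) -> pd.DataFrame:
    """Sweep exactly one of K, Ti, tau; summarise tracking and stability.

    Rate variance / IQR and ``rate_rms`` are computed from the 1 s binned
    population rate after ``transient_skip`` seconds, giving a common readout
    across filter time constants (``rms_error`` uses the controller's own
    rate estimate and is therefore tau-dependent).  A grid value is flagged unstable when its median IQR
    exceeds ``iqr_multiple`` times the nominal-parameter median IQR (the
    nominal value is taken from ``base_config`` and run as a reference if it
    is not part of the grid).
    """
    keys = [k for k in grid if grid[k] is not None and len(grid[k])]
    if len(keys) != 1:
        raise ConfigurationError("exactly one parameter must be swept")
    param = keys[0]
    if param not in _SWEEPABLE:
        raise ConfigurationError(f"sweepable parameters are {_SWEEPABLE}")
    values = list(grid[param])
    kind = base_config.get("type", "pi")
    nominal = base_config.get(param, {"K": 0.1, "Ti": 1.0,
                                      "tau": 0.8 if kind == "integral" else 2.5}[param])
    schedule = schedule or TargetSchedule.constant(base_config.get("target", 4.0))
    run_values = values if nominal in values else values + [nominal]

    rows = []
    for value in run_values:
        cfg = {k: v for k, v in base_config.items() if k not in ("type", "target")}
        cfg[param] = value
        for seed in seeds:
            controller = make_controller(kind, **cfg)
            rec = run_closed_loop(plant, controller, schedule, trial_duration,
                                  timing=timing, seed=seed)
            centers, rate = rec.spikes.population_rate(1.0)
            keep = centers >= min(transient_skip, trial_duration / 2.0)
            rate = rate[keep]
            q1, q3 = np.percentile(rate, [25, 75])
            tgt = np.array([schedule.target_at(t) for t in centers[keep]])
            rows.append({
                "parameter": param, "value": value, "seed": seed,
                "rms_error": rec.rms_error(),
                "rate_rms": float(np.sqrt(np.mean((rate - tgt) ** 2))),
                "rate_variance": float(np.var(rate)),
                "rate_iqr": float(q3 - q1),
                "settled": rec.settling_time() is not None,
                "nominal": value == nominal,
            })
    df = pd.DataFrame(rows)
    ref_iqr = df[df["nominal"]].groupby("value")["rate_iqr"].median().iloc[0]
    med = df.groupby("value")["rate_iqr"].median()
    df["unstable"] = df["value"].map(med > iqr_multiple * ref_iqr)
    df = df[df["value"].isin(values)].reset_index(drop=True)
    return df
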