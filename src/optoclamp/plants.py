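"""Synthetic spiking preparations ("plants") that the controllers act on.

Two plants are provided, matching the two preparations the control laws were
validated against:

``NetworkPlant``
    A doubly-stochastic Poisson model of a dissociated cortical network on a
    microelectrode array.  Per-unit conditional intensity

        lambda_i = E_sess * [ spont * burst_env + g_i * D(blue) * a_i ] * S(yellow)

    where ``burst_env`` is a two-state (burst/quiescent) envelope producing
    aperiodic network bursting, ``g_i`` are log-normal per-unit gains,
    ``D`` is a saturating Hill-type dose-response of low-pass-filtered
    (opsin-kinetics) blue power, ``a_i`` is a multiplicative adaptation state
    that decays under drive and recovers with a slow time constant, ``S`` is
    a monotone suppression curve of filtered yellow power, and ``E_sess`` is
    a per-seed session-excitability factor emulating preparation-to-
    preparation variability.  ``D`` and ``S`` are calibrated numerically at
    construction so that sustained pulsed drive at the published excitatory
    saturation point (U_C = 0.47) yields the published saturation rate
    (12.5 Hz/unit) at trial start, and sustained yellow light at the
    inhibitory saturation point (U_H = 0.15) yields the published suppression
    floor (0.04 Hz/unit).  Drug conditions (CNQX, AP5, bicuculline) rescale
    spontaneous rate, evoked ceiling and burstiness.

``TCUPlant``
    A single thalamocortical unit under fiber-optic drive: Poisson firing
    with an absolute refractory period, a bursty spontaneous mode (elevated
    CV_ISI under anaesthesia), linear opsin drive with adaptation and slow
    stochastic excitability drift, and short-latency sensory-evoked spikes
    time-locked to whisker-deflection onsets.

Both plants are deterministic given (seed, parameters, input traces): the
same seed replays the same spikes.  Light inputs are instantaneous power
densities (mW/mm^2) sampled on the simulation grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .stimulus import PulseTrainPlayer, map_Uc_to_pulse_params, map_UH_to_led_current

__all__ = [
    "DrugCondition", "DRUG_CONDITIONS", "NetworkPlantParams", "NetworkPlant",
    "TCUPlantParams", "TCUPlant", "apply_drug",
]


@dataclass(frozen=True)
class DrugCondition:
    """Pharmacological modifier of network excitability.

    Defaults encode the published shifts in spontaneous rate under synaptic
    blockade (CNQX -74.2%, AP5 -66.6%, bicuculline +357%) and bicuculline's
    collapse of the evoked dynamic range to 5.1 Hz/unit.
    """

    name: str = "none"
    spont_multiplier: float = 1.0
    dose_max_override: Optional[float] = None
    burst_gain_multiplier: float = 1.0


DRUG_CONDITIONS = {
    "none": DrugCondition("none"),
    "CNQX": DrugCondition("CNQX", spont_multiplier=1.0 - 0.742,
                          burst_gain_multiplier=0.5),
    "AP5": DrugCondition("AP5", spont_multiplier=1.0 - 0.666,
                         burst_gain_multiplier=0.5),
    "bicuculline": DrugCondition("bicuculline", spont_multiplier=1.0 + 3.57,
                                 dose_max_override=5.1,
                                 burst_gain_multiplier=2.0),
}


@dataclass(frozen=True)
class NetworkPlantParams:
    """Parameters of the synthetic cultured-network plant.

    Rates are Hz per unit; times are seconds.  ``dose_half`` is the U_C whose
    cycle-averaged blue power sits at the half point of the dose-response;
    ``suppress_half`` the U_H at half suppression.  ``sat_Uc``/``sat_Uh`` are
    the published saturation points the calibration anchors to.
    """

    n_units: int = 40
    spont_rate: float = 2.0
    dose_half: float = 0.25
    dose_max: float = 12.5
    hill_coeff: float = 3.0
    suppress_floor: float = 0.04
    suppress_half: float = 0.02
    sat_Uc: float = 0.47
    sat_Uh: float = 0.15
    adapt_tau: float = 25.0
    adapt_depth: float = 0.25
    burst_rate: float = 6.0            # bursts / min
    burst_gain: float = 5.0
    burst_duration: float = 0.3
    unit_gain_spread: float = 0.5      # CV of per-unit gains
    session_cv: float = 0.2            # CV of per-seed excitability factor
    opsin_tau_blue: float = 0.02       # ChR2 off-kinetics low-pass (s)
    opsin_tau_yellow: float = 0.01
    network_tau: float = 0.12          # recurrent-recruitment integration (s)
    suppress_fade_tau: float = 3600.0  # Cl- accumulation / pump desensitisation
    suppress_recover_tau: float = 1800.0
    drug: DrugCondition = field(default_factory=lambda: DRUG_CONDITIONS["none"])

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not (0.0 <= self.adapt_depth < 1.0):
            raise ValueError("adapt_depth must lie in [0, 1)")
        for name in ("spont_rate", "dose_max", "suppress_floor", "burst_rate",
                     "burst_gain", "burst_duration", "adapt_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def apply_drug(params: NetworkPlantParams, drug: DrugCondition | str) -> NetworkPlantParams:
    """Return a copy of ``params`` with the drug condition's shifts applied."""
    if isinstance(drug, str):
        if drug not in DRUG_CONDITIONS:
            raise ValueError(
                f"unknown drug {drug!r}; known: {sorted(DRUG_CONDITIONS)}")
        drug = DRUG_CONDITIONS[drug]
    kwargs = dict(
        spont_rate=params.spont_rate * drug.spont_multiplier,
        burst_gain=params.burst_gain * drug.burst_gain_multiplier,
        drug=drug,
    )
    if drug.dose_max_override is not None:
        kwargs["dose_max"] = drug.dose_max_override
    return replace(params, **kwargs)


def _mean_pulse_power(U_C: float) -> float:
    """Cycle-averaged 465 nm power of the standard pulse train at U_C."""
    cmd = map_Uc_to_pulse_params(U_C)
    return cmd.freq * (cmd.width / 1000.0) * cmd.power


class NetworkPlant:
    """Stateful synthetic cultured network; see module docstring for the model."""

    def __init__(self, params: NetworkPlantParams, seed: int = 0):
        self.params = params
        self._calibrate()
        self.reset(seed)

    # -- calibration -------------------------------------------------------

    def _hill(self, b: float) -> float:
        bh = b ** self.params.hill_coeff
        return bh / (bh + self._b50h)

    def _calibrate(self) -> None:
        p = self.params
        self._b50h = _mean_pulse_power(p.dose_half) ** p.hill_coeff
        # Yellow: S(y) = floor + (1 - floor) * exp(-y / y_scale), anchored so
        # the half-suppression point sits at suppress_half.
        self._s_floor = min(1.0, p.suppress_floor / max(p.spont_rate, 1e-12))
        y_half = map_UH_to_led_current(p.suppress_half).power
        self._y_scale = y_half / math.log(2.0)
        # Blue: simulate the deterministic opsin response to the standard
        # pulse train at the published saturation point and scale the drive
        # so the fresh (a = 1) population mean equals dose_max there.
        dt = 0.001
        player = PulseTrainPlayer()
        cmd = map_Uc_to_pulse_params(p.sat_Uc)
        b = 0.0
        h_acc = 0.0
        n_warm, n_meas = 2000, 3000
        k = dt / p.opsin_tau_blue
        for i in range(n_warm + n_meas):
            b += (player.step(cmd, dt) - b) * k
            if i >= n_warm:
                h_acc += self._hill(b)
        self._h_sat = h_acc / n_meas
        self._drive_scale = max(p.dose_max - p.spont_rate, 0.0) / self._h_sat

    # -- state -------------------------------------------------------------

    def reset(self, seed: int) -> None:
        p = self.params
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        sigma_g = math.sqrt(math.log(1.0 + p.unit_gain_spread ** 2))
        self.gains = self.rng.lognormal(-0.5 * sigma_g ** 2, sigma_g, p.n_units)
        sigma_s = math.sqrt(math.log(1.0 + p.session_cv ** 2))
        self.session_excitability = float(
            self.rng.lognormal(-0.5 * sigma_s ** 2, sigma_s))
        self.a = np.ones(p.n_units)
        self.b_filt = 0.0
        self.y_filt = 0.0
        self.h_net = 0.0               # network-lagged evoked drive
        self.s_net = 1.0               # network-lagged suppression
        self.in_burst = False
        self.suppress_efficacy = 1.0
        self.t = 0.0
        # burst envelope normalisation: steady-state burst duty cycle
        r = p.burst_rate / 60.0
        duty = r * p.burst_duration / (1.0 + r * p.burst_duration)
        self._env_mean = 1.0 + duty * (p.burst_gain - 1.0)

    @property
    def n_units(self) -> int:
        return self.params.n_units

    def suppression(self, y: float) -> float:
        """Multiplicative suppression factor S(yellow power).

        ``suppress_efficacy`` scales the effective yellow drive: chloride
        accumulation and pump desensitisation under sustained illumination
        weaken the photocurrent, not the floor."""
        return self._s_floor + (1.0 - self._s_floor) * math.exp(
            -self.suppress_efficacy * y / self._y_scale)

    def step(self, blue_power: float, yellow_power: float, dt: float) -> np.ndarray:
        """Advance one simulation step; return per-unit spike counts."""
        p = self.params
        rng = self.rng
        # opsin kinetics
        self.b_filt += (blue_power - self.b_filt) * (dt / p.opsin_tau_blue)
        self.y_filt += (yellow_power - self.y_filt) * (dt / p.opsin_tau_yellow)
        # burst envelope (telegraph process)
        if self.in_burst:
            if rng.random() < dt / p.burst_duration:
                self.in_burst = False
        elif rng.random() < p.burst_rate / 60.0 * dt:
            self.in_burst = True
        env = (p.burst_gain if self.in_burst else 1.0) / self._env_mean
        # dose-response, network-recruitment lag, adaptation
        H = self._hill(self.b_filt)
        k_net = dt / p.network_tau
        self.h_net += (H - self.h_net) * k_net
        a_inf = 1.0 - p.adapt_depth * self.h_net
        self.a += (a_inf - self.a) * (dt / p.adapt_tau)
        # slow loss of suppression efficacy under sustained yellow light
        if yellow_power > 0.0:
            self.suppress_efficacy -= self.suppress_efficacy * dt / p.suppress_fade_tau
        else:
            self.suppress_efficacy += (1.0 - self.suppress_efficacy) * dt / p.suppress_recover_tau
        self.s_net += (self.suppression(self.y_filt) - self.s_net) * k_net
        lam = (p.spont_rate * env + self._drive_scale * self.h_net * self.a * self.gains)
        lam *= self.session_excitability * self.s_net * dt
        self.t += dt
        return rng.poisson(lam)


@dataclass(frozen=True)
class TCUPlantParams:
    """Parameters of the synthetic thalamocortical unit.

    ``opsin_gain`` converts fiber light power to firing drive (Hz per
    mW/mm^2).  The spontaneous burst parameters are set so the spontaneous
    CV_ISI is around 1.7, the elevated interval variability seen under
    anaesthesia; under steady optical drive the unit fires Poisson-like
    (CV_ISI near 1).  The sensory kernel adds ``kernel_amplitude`` expected
    spikes per whisker deflection at ``kernel_latency`` after deflection
    onset, spread over ``kernel_width``.
    """

    baseline: float = 5.0              # Hz
    opsin_gain: float = 2.0            # Hz per mW/mm^2
    refractory: float = 0.002          # s
    kernel_latency: float = 0.005      # s
    kernel_amplitude: float = 1.0      # spikes per deflection
    kernel_width: float = 0.003        # s (Gaussian SD)
    burst_event_rate: float = 0.4      # bursts / s (spontaneous mode)
    burst_duration: float = 0.02       # s
    burst_gain: float = 100.0
    adapt_tau: float = 10.0
    adapt_depth: float = 0.4
    drift_tau: float = 10.0            # OU excitability drift (s)
    drift_sd: float = 0.25
    session_cv: float = 0.3
    opsin_tau: float = 0.02

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.opsin_gain < 0:
            raise ValueError("rates and gains must be non-negative")
        if not (0.0 <= self.adapt_depth < 1.0):
            raise ValueError("adapt_depth must lie in [0, 1)")


class TCUPlant:
    """Stateful single thalamocortical unit; emits 0/1 spikes per step."""

    n_units = 1

    def __init__(self, params: TCUPlantParams, seed: int = 0):
        self.params = params
        # quiescent multiplier keeping the spontaneous mean at baseline
        r, d, g = params.burst_event_rate, params.burst_duration, params.burst_gain
        duty = r * d / (1.0 + r * d)
        self._quiet_mult = max(0.0, (1.0 - duty * g) / (1.0 - duty))
        self.reset(seed)

    def reset(self, seed: int) -> None:
        p = self.params
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        sigma_s = math.sqrt(math.log(1.0 + p.session_cv ** 2))
        self.session_excitability = float(
            self.rng.lognormal(-0.5 * sigma_s ** 2, sigma_s))
        self.a = 1.0
        self.drift = 0.0               # OU log-excitability drift
        self.b_filt = 0.0
        self.in_burst = False
        self.t_last_spike = -math.inf
        self._prev_whisker = 0.0
        self._onsets: list[float] = []
        self.t = 0.0

    def _evoked_rate(self, t: float) -> float:
        p = self.params
        if not self._onsets:
            return 0.0
        horizon = p.kernel_latency + 5.0 * p.kernel_width
        self._onsets = [t0 for t0 in self._onsets if t - t0 < horizon]
        rate = 0.0
        norm = p.kernel_amplitude / (p.kernel_width * math.sqrt(2.0 * math.pi))
        for t0 in self._onsets:
            z = (t - t0 - p.kernel_latency) / p.kernel_width
            rate += norm * math.exp(-0.5 * z * z)
        return rate

    def step(self, blue_power: float, whisker_pos: float, dt: float) -> int:
        p = self.params
        rng = self.rng
        t = self.t
        # deflection-onset detection (rising crossing of 0.5 deg)
        if whisker_pos > 0.5 and self._prev_whisker <= 0.5:
            self._onsets.append(t)
        self._prev_whisker = whisker_pos
        # opsin kinetics, adaptation, slow excitability drift
        self.b_filt += (blue_power - self.b_filt) * (dt / p.opsin_tau)
        drive = p.opsin_gain * self.b_filt
        sat = drive / (drive + p.baseline + 1e-12)
        self.a += ((1.0 - p.adapt_depth * sat) - self.a) * (dt / p.adapt_tau)
        self.drift += (-self.drift * dt / p.drift_tau
                       + p.drift_sd * math.sqrt(2.0 * dt / p.drift_tau)
                       * rng.standard_normal())
        # spontaneous burst envelope
        if self.in_burst:
            if rng.random() < dt / p.burst_duration:
                self.in_burst = False
        elif rng.random() < p.burst_event_rate * dt:
            self.in_burst = True
        env = p.burst_gain if self.in_burst else self._quiet_mult
        lam = (p.baseline * env + drive * self.a) * math.exp(self.drift)
        lam *= self.session_excitability
        lam += self._evoked_rate(t)
        self.t = t + dt
        if t - self.t_last_spike < p.refractory:
            return 0
        if rng.random() < -math.expm1(-lam * dt):
            self.t_last_spike = t
            return 1
        return 0
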