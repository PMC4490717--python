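# Methods

This note documents the models behind `optoclamp`: the control laws, the
multi-rate loop, the synthetic preparations and their calibration, the
metrics, and the numerical and design choices that were genuinely open.

## Controllers and rate estimation

The controlled variable is the population firing rate in Hz per sorted unit,
estimated by an exponential moving average of 4 ms spike-count bins with
weight α = 1 − exp(−dt/τ).  Defaults: τ = 2.5 s for network control, 0.8 s
for single-unit control in the in-vivo configuration.  Four control laws are
implemented (`optoclamp.controllers`):

* **PI (velocity form)** — u[t] = u[t−1] + K(e[t] − e[t−1] + (Ts/Ti)e[t]);
  K = 0.1, Ti = 1 s, Ts = 10 ms.  The output splits into excitatory and
  inhibitory channel commands U_C = clip(u + Δ₁, 0, 1),
  U_H = clip(−u + Δ₂, 0, 1) with Δ₁ = Δ₂ = 0.25 setting the channel overlap.
* **Integral** — the same recursion with the proportional component removed,
  u clipped to [0, 1]; drives fiber-coupled light as power = G·u
  (G = 20 mW·mm⁻² per unit output by default, a mid-range fiber gain).
* **Excitatory on-off** — integrates e·dt and emits a fixed blue pulse
  (5 ms, 13.4 mW·mm⁻², 465 nm) whenever the integral is positive, never more
  often than every 100 ms (a 10 Hz cap).
* **Inhibitory on-off** — gates continuous yellow light (≈11.8 mW·mm⁻²,
  590 nm) on while the integral is negative.

Anti-windup: the integrating state itself is clipped — for the PI law to
u ∈ [−Δ₂, 1−Δ₁], the interval on which neither split output clips — rather
than clipping U_C/U_H after letting u run away.  Bounding the state is what
actually prevents windup; clipping only the outputs would let saturation
accumulate error indefinitely.

The on-off accumulator is a discrete sum in its original statement, which is
step-size dependent and unbounded.  We accumulate e·dt at the filter rate
(units Hz·s/unit) and clip its magnitude at 10 Hz·s/unit by default; both
choices are configurable.  Controllers start neutral (u = 0, e_prev = 0,
I_f = 0) at control onset, and controller state is *not* reset at
target-schedule boundaries — the control signal is continuous across target
switches.  An optional "pre-pulse" conditioning (a 10 s train of U_C = 1
stimuli ending 10 s before onset) is available for startup conditioning.

### Error-sign convention

e = f* − f everywhere, so positive error (rate too low) drives excitation.

## Loop timing

The published update rates differ between the rate filter (4 ms) and the
controller (10 ms).  The engine therefore runs a 1 ms master grid: the
filter ticks every 4 ms, controllers every 10 ms using the most recent
estimate, and the controller reads the estimate delayed by the loop latency
(default 5 ms, matching the online spike-classification latency of the
real-time system; placement of the delay in the loop is a modeling choice).
On-off controllers accumulate error at the filter rate, the finer of the two
printed clocks; the 10 Hz pulse cap is exact on this grid.

## The synthetic network plant

`NetworkPlant` is a doubly-stochastic Poisson model, *not* a synaptically
coupled network: the controllers only observe the population rate, and this
is the simplest plant family that reproduces every phenomenon the control
laws were validated against — saturating excitation, steep suppression,
within-trial adaptation, aperiodic network bursting, drug-induced
excitability shifts, preparation-to-preparation variability, and a
recruitment lag that bounds the stable controller-gain range.  Per-unit
conditional intensity:

    λ_i = E_sess · [ spont · burst_env + g_i · D_net · a_i ] · S_net

* **Spontaneous activity and bursting** — spont = 2 Hz/unit; a two-state
  telegraph envelope (6 bursts/min, 300 ms, 5× gain, normalised to unit
  mean) produces aperiodic population bursts.  Values are typical of
  3–4-week-old dissociated cortical cultures.
* **Unit heterogeneity** — per-unit gains g_i are log-normal with unit mean
  and CV 0.5 (wide per-unit rate spreads are the norm in sorted MEA data);
  n_units = 40, a typical sorted-unit yield.
* **Session excitability** — E_sess is a log-normal factor (CV 0.2) drawn
  per seed, standing in for the day-to-day excitability drift of real
  preparations.  It is what makes open-loop replay fail against a re-seeded
  plant.
* **Excitatory dose–response** — blue light passes a 20 ms first-order
  filter (ChR2 off-kinetics), a Hill function D(b) = b³/(b³ + b₅₀³) with
  half-point at the cycle-averaged power of U_C = 0.25, and a 120 ms
  "network recruitment" low-pass (recurrent amplification builds over
  ~100 ms).  The drive scale is calibrated *numerically at construction*:
  the deterministic opsin response to the standard pulse train at U_C = 0.47
  is simulated and the scale set so the fresh-plant population mean equals
  dose_max = 12.5 Hz/unit there.  This anchors the saturation point
  regardless of ripple and waveform details.
* **Adaptation** — multiplicative per-unit states a_i relax toward
  1 − adapt_depth·drive with adapt_tau = 25 s, adapt_depth = 0.25: open-loop
  stimuli visibly lose efficacy across a 60 s trial while leaving closed-loop
  headroom across the 1–8 Hz/unit target range.  The magnitude is calibrated
  qualitatively (the source experiments do not quantify it).
* **Suppression** — yellow light passes a 10 ms filter and a saturating
  curve S(y) = s_floor + (1 − s_floor)·exp(−y/y_scale), with s_floor set so
  the fully suppressed rate is 0.04 Hz/unit and y_scale anchored to a
  half-suppression point at U_H = 0.02 (suppression is nearly complete by
  U_H = 0.15, the published saturation point).  Sustained illumination
  slowly scales down the effective yellow drive (default time constant 1 h,
  recovery 30 min), standing in for chloride accumulation and pump
  desensitisation; it is negligible within minutes and substantial over
  multi-hour clamps.
* **Drugs** — `apply_drug` rescales spontaneous rate (CNQX ×0.258,
  AP5 ×0.334, bicuculline ×4.57, the published shifts), caps the evoked
  ceiling at 5.1 Hz/unit under bicuculline, and scales burst gain (halved
  under glutamatergic blockade, doubled under bicuculline — qualitative).

### What the closed-loop instability boundary comes from

With only opsin-speed dynamics the simulated loop is stable far beyond the
gains at which real preparations oscillate, because a memoryless Poisson
plant lacks the network's integration lag.  The 120 ms recruitment low-pass
(applied to both the evoked-drive and suppression pathways) supplies that
lag; with it, proportional gains of K ≳ 1 raise the steady-state rate
variance, filter time constants τ ≳ 10 s produce large slow oscillations,
and τ ≲ 0.5 s breaks control.  At small τ the failure in this plant
manifests mostly as estimator-noise-driven tracking failure (RMS error well
above the 0.5 Hz/unit success bound) rather than as large binned-rate
variance: the recruitment lag filters controller jitter out of the spike
rate, whereas a biological network amplifies it.  Sweep tables therefore
report both the controller's own RMS error and bin-based statistics
(variance, IQR, RMS on a common 1 s binned rate) so that readouts are
comparable across filter settings.

## The synthetic thalamocortical unit

`TCUPlant` is a single Poisson unit with an absolute refractory period
(2 ms) and intensity

    λ = E_sess · exp(drift) · [ baseline · burst_env + opsin_gain · b · a ] + evoked(t)

* **Spontaneous mode** — baseline 5 Hz modulated by a burst envelope
  (0.4 bursts/s, 20 ms, 100× gain, quiescent multiplier keeping the mean at
  baseline).  These values are calibrated so the spontaneous CV_ISI is ≈1.9,
  within the published anaesthetized-thalamus range (1.72 ± 0.43): thalamic
  relay cells fire low-rate tonic spikes broken by high-frequency bursts
  under anaesthesia.
* **Optical drive** — fiber power through a 20 ms opsin filter with gain
  2 Hz per mW·mm⁻², with drive-dependent adaptation (depth 0.4, 10 s) and a
  slow Ornstein–Uhlenbeck excitability drift (SD 0.25, 10 s) reproducing the
  non-stationary open-loop responses of real units.  Because drive bypasses
  the burst envelope, clamped firing is Poisson-like (CV_ISI ≈ 1.1):
  feedback drive mimics the alert, tonic state.
* **Sensory responses** — whisker-deflection onsets (rising crossings of
  0.5°) add a Gaussian intensity kernel (latency 5 ms, SD 3 ms, integral
  1 spike per deflection), giving stimulus-locked spikes that ride on top of
  the controlled baseline.

## Metrics

All metrics operate on plain (time, unit) event lists and sampled traces.
Notable definitions:

* **Settling time** — first time the LOWESS-smoothed rate (tri-cube weights,
  2.5 s window — computed with `statsmodels`' lowess) enters the target
  ± 0.25 Hz/unit band and never leaves it.
* **Cross-correlogram** — pairwise lag histograms with symmetric bins and a
  zero-centred bin, averaged over pairs; normalised by reference spike count
  and bin width to a conditional rate (Hz) by default, raw counts optional.
* **Synchrony index** — N_cc/√((N_i² + N_j²)/2) with N_cc the number of
  spike *pairs* within ±10 ms; each pair counts once and a spike may join
  several pairs (semantics pinned by an exhaustive-enumeration oracle in the
  tests).
* **CV_ISI** — population (ddof = 0) standard deviation over mean of the
  interspike intervals; the estimator is configurable since the source
  analyses do not state it.
* **STA / FWHM** — spike-aligned signal averages excluding truncated
  windows; FWHM is measured on the baseline-subtracted curve (baseline =
  mean of the first 10% of the pre-window) with linear interpolation at the
  half-maximum crossings; flat or peak-less curves return an explicit
  undefined result rather than a number.
* **Burst detection** — threshold on the binned population rate (default 2×
  the median), merging bursts separated by < 100 ms; the source figures name
  no algorithm, so a simple transparent rule was chosen.

## Numerical choices

* Pulse trains use a continuous phase accumulator (φ += freq·dt, pulse on
  wraparound) so frequency changes mid-train never pile pulses up; fractional
  pulse-width samples are scaled by their overlap so delivered energy matches
  freq·width·power to one sample's quantisation.
* The sinusoidal waveform is half-wave rectified (light power cannot be
  negative); PRBS stimuli come from a maximal-length LFSR (order 15 by
  default, re-seeded per trial; order-n sequences are balanced to one bit
  over a full period).
* The triangle waveform rises at 0.22 mW·ms⁻¹·mm⁻² and falls symmetrically;
  if a full rise-fall cannot fit the 10 Hz carrier period the peak is capped
  rather than introducing a discontinuity.
* Two peak-power coefficients coexist in the source material: the continuous
  excitatory mapping uses 13.2 mW·mm⁻², the waveform family and on-off
  pulses 13.4.  Both are kept, each where it is printed, and both are
  configurable.
* The whisker deflection rises as a saturating exponential reaching the full
  8° excursion at the 5 ms (99%) rise time and falls symmetrically; the
  average rising velocity is excursion/rise-time = 1600 °/s.
* The on-off refractory comparison carries 1 ns of slack to absorb float
  jitter in accumulated tick times; pulse spacing on the 4 ms grid is
  exactly 100 ms.
* Records serialise with 1 µs time resolution and full float precision
  (`%.17g`), so written records re-read value-identically.

## What passing tests do and do not show

The plants are generative stand-ins calibrated to published operating
points, not fitted to recordings.  They omit, among other things: true
synaptic coupling and its pathology (epileptiform bicuculline dynamics are
reduced to parameter shifts), opsin photocycle detail, spatial light
heterogeneity, spike-sorting errors and unit drift, and electrode-level
noise.  Closed-loop results on these plants demonstrate that the control
laws, timing, anti-windup and stimulus mappings are implemented correctly
and behave as reported *under the modeled dynamics*; they do not predict
quantitative tracking error on any particular biological preparation.
Tracking error here (median RMS ≈ 0.06 Hz/unit on 60 s trials) is better
than typically achieved in vitro because the model's disturbances are
milder than biological reality.

## Problem sizes

Simulation batches were sized for a desk run on one CPU: 20 trials × 60 s
for the closed-loop success and replay comparisons, 30 s trials × 5 seeds
per grid value for parameter sweeps, 40-unit networks throughout.  All are
parameters, not limits; multi-hour on-off scenarios run with the same engine
at the same resolution.
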