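# optoclamp

Simulation of closed-loop optogenetic control of neuronal firing rate
("optoclamping"), for control and systems neuroscientists who want to
prototype, tune, or teach firing-rate feedback before (or instead of) running
it on a rig.  The package pairs the published control laws with synthetic
spiking preparations — a cultured cortical network on a multielectrode array
and a single thalamocortical unit in vivo — and the full set of spike-train
metrics used to judge control quality.

## The control problem

A preparation expresses an excitatory opsin (ChR2, driven by 465 nm light)
and an inhibitory opsin (eNpHR3.0/Arch3.0, driven by 590 nm light).  Spiking
is detected in real time and the population firing rate *f*[*t*] (Hz per
sorted unit) is estimated every *dt* = 4 ms with a first-order filter:

    f[t] = α r[t] + (1 − α) f[t − dt],      α = 1 − exp(−dt/τ),  τ = 2.5 s

where *r*[*t*] is the binned instantaneous rate.  The error
*e*[*t*] = *f*\* − *f*[*t*] against the target rate *f*\* feeds a
velocity-form PI controller (period *T*ₛ = 10 ms):

    u[t] = u[t−1] + K (e[t] − e[t−1] + (Tₛ/Tᵢ) e[t]),   K = 0.1, Tᵢ = 1 s

whose scalar output is split into two bounded control variables,

    U_C = clip(u + Δ₁, 0, 1),    U_H = clip(−u + Δ₂, 0, 1),   Δ₁ = Δ₂ = 0.25,

with *u* itself clipped to the interval that keeps both outputs in [0, 1]
(anti-windup).  U_C jointly modulates blue pulse frequency (10·U_C + 10 Hz),
width (5·U_C ms) and power (13.2·U_C mW·mm⁻²); U_H sets the yellow LED
current (U_H amperes).  Variants included: a pure integral controller for
fiber-coupled single-unit control (light power = G·u), and excitatory /
inhibitory on-off (bang-bang) controllers that accumulate the error and gate
fixed stimuli on its sign, with a 10 Hz cap on pulse delivery.

The synthetic plants are doubly-stochastic Poisson models calibrated to the
published operating points: evoked population rate saturates near
12.5 Hz/unit at U_C ≈ 0.47, suppression saturates near 0.04 Hz/unit at
U_H ≈ 0.15, stimuli lose efficacy within each trial (adaptation), networks
burst aperiodically, excitability varies across preparations, and synaptic
blockers (CNQX, AP5, bicuculline) shift spontaneous rate and dynamic range.
See `docs/methods.md` for the model and every default.

## Worked example

```python
from optoclamp import NetworkPlant, NetworkPlantParams, TargetSchedule, run_closed_loop
from optoclamp.engine import make_controller

plant = NetworkPlant(NetworkPlantParams(), seed=0)
controller = make_controller("pi")        # K=0.1, Ti=1 s, tau=2.5 s
schedule = TargetSchedule(segments=[(0.0, 2.0), (30.0, 6.0)])
rec = run_closed_loop(plant, controller, schedule, duration=60.0, seed=42)

for t0, t1, target in [(10, 30, 2.0), (40, 60, 6.0)]:
    mask = (rec.f_times >= t0) & (rec.f_times < t1)
    print(f"target {target:.0f} Hz/unit: mean rate "
          f"{rec.f[mask].mean():.2f} Hz/unit, RMS error "
          f"{rec.rms_error((t0, t1)):.3f} Hz/unit")
print(f"spikes recorded: {len(rec.spikes)} from {rec.spikes.n_units} units")
```

prints

```
target 2 Hz/unit: mean rate 2.00 Hz/unit, RMS error 0.073 Hz/unit
target 6 Hz/unit: mean rate 6.00 Hz/unit, RMS error 0.062 Hz/unit
spikes recorded: 10111 from 40 units
```

The controller holds the network at 2 Hz/unit, then tracks the mid-trial
step to 6 Hz/unit; both segments sit well inside the 0.5 Hz/unit RMS bound
used to call a trial successful.  `rec` carries the complete trial — spikes,
rate/target/control traces, light traces — and feeds directly into
`optoclamp.metrics` (cross-correlograms, synchrony, CV_ISI, spike-triggered
averages, settling time, burst profiles) or onto disk via
`optoclamp.io.save_record`.

The same loops run from the shell:

```
optoclamp clamp run.yaml -o out/trial1        # closed-loop trial
optoclamp replay out/trial1 -o out/replay --reseed 7
optoclamp lock run.yaml -o out/lock --lock-at 15
optoclamp sweep run.yaml -o sweep.csv --param K --values 0.1,1.0,2.0
optoclamp metrics out/trial1 -o metrics.csv
optoclamp demo -o out/demo                    # regenerate demo scenarios
```

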