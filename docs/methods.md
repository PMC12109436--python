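# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## The circulation model

The mock flow loop is represented as a linear lumped-parameter (0-D)
network of four two-element Windkessel compartments — upper systemic,
lower systemic, right pulmonary, left pulmonary — each a compliance chamber
(C, mL/mmHg) with a single resistance (R, mmHg·min/L). The topology is:

```
pump ──► aortic node (C_a) ──R_up──►  upper chamber (C_up) ──r_v──┐
                      └─────R_low──►  lower chamber (C_low) ──r_v──┤
                                                                   ▼
                                                      TCPC junction (ideal)
                                                                   │
              reservoir ◄──r_d── RPA chamber (C_rpa) ◄──R_rpa──────┤
              reservoir ◄──r_d── LPA chamber (C_lpa) ◄──R_lpa──────┘
```

* The systemic compartment resistances sit on the **arterial inlet**; they
  absorb most of the ~80 mmHg arterial-to-venous drop and set the
  upper/lower split. The pulmonary resistances sit on the **branch inlet**
  from the junction and set the RPA/LPA split.
* The TCPC junction is an ideal zero-resistance node; its pressure is
  eliminated algebraically, so the state vector is exactly the five node
  pressures `(p_aortic, p_upper, p_lower, p_rpa, p_lpa)`.
* Fixed "plumbing" elements close the loop and are never tuned: a small
  stiff pump-outlet chamber (0.8 mL/mmHg — a piston pump feeding purely
  resistive lines would otherwise produce unphysical pressure spikes),
  venous lines from each systemic chamber to the junction (2 mmHg·min/L),
  and drain lines from each pulmonary chamber to the atrial reservoir
  (2.25 mmHg·min/L, reservoir at 5 mmHg).
* Compliances tap from each node to ambient reference; the canonical
  parallel-RC form is assumed (the rig's exact internal topology is not
  published).
* An external injection enters the RPA branch **between the junction and
  the distal flow sensor**, so the measured RPA flow includes the injected
  flow, and the injection back-pressures the network (the transient dips
  in the systemic channels during injection emerge from this volume
  bookkeeping, not from any ad-hoc term).

The pump is a half-sine ejection pulse occupying 30% of the cardiac period
with the pulse area constrained to the stroke volume, so cycle-averaged
output is exactly heart rate × stroke volume (80 bpm × 30 mL =
2.4 L/min). Only rate and stroke volume are physically specified for the
rig; the half-sine shape is a standard piston-pump approximation.

### Parameter values

No compartment R/C values are published for this rig; the shipped defaults
(`data/default_lpm.yaml`) were produced by the package's tuning procedure
against the stated operating point — CO 2.4 L/min, 30% of CO to the upper
body, 50/50 pulmonary split — and land the chamber pressures in the
measured ranges (venous ≈ 17–19 mmHg, pulmonary ≈ 7.7 mmHg, aortic
≈ 97 mmHg). Compliances reflect **benchtop compliance chambers**, which
are far stiffer than in-vivo venous beds (a few mL/mmHg rather than tens):
this matters dynamically, because the loop must re-equilibrate within a
few seconds of an injection step — as the measured plateaus of 15–30 s
injections show — whereas physiological venous compliances would give the
loop a ~30 s charging time constant.

### Numerics

* Integrator: `scipy.integrate.solve_ivp` (LSODA), `max_step ≤ T/200`
  (3.75 ms at 80 bpm), rtol 1e−7, output resampled on the sensor grid.
* Initialization: the network is LTI, so the no-injection cycle map is
  affine, `x(T) = expm(A·T)·x(0) + d`; its fixed point is computed directly
  and used as the initial state, placing the simulation exactly on the
  periodic orbit. Periodicity is still verified (consecutive pre-injection
  cycle means of every flow channel within 0.5% relative after 10 settle
  cycles) and a convergence error names the worst channel.
* Tuning: two sequential 1-D Brent root searches on a log resistance scale
  (upper-systemic R for the systemic split, then RPA R for the pulmonary
  split — independent in this topology), tolerance 1e−3 on the split
  fraction. The tuner returns its input unchanged when the residual is
  already inside tolerance, making re-tuning exactly idempotent. No
  randomness anywhere in the model or tuner.
* Cycle averages truncate the window to a whole number of cardiac cycles.

## Injection protocol and injector dynamics

The 20-case protocol spans rates 5/10/15/20 mL/s (0.3–1.2 L/min):
12 continuous cases at 50/100/150 mL and 8 pulsed cases of five bursts at
15 or 20 mL per burst. Rectangular rate commands are passed through a
first-order injector lag (default time constant 0.2 s, volume-conserving
in the long-time limit, evaluated analytically per segment). Two timing
parameters the experiment does not state are defaults here and
configurable: the inter-burst gap (5 s — an order of magnitude beyond the
largest sub-second fall time, so bursts are separable) and the injection
start (15 s, after periodicity is established).

## The synthetic rig emulator

`synthetic_mfl` stands in for the benchtop rig and provides the ground
truth that makes the pipeline testable:

```
q_rpa(t) = [no-injection LPM RPA flow] + [lagged injection] + E(t) + noise
```

E(t) is a first-order envelope locked to the injection command: plateau E0
(negative for blockage), time constant τ_rise on activation and τ_fall on
shutoff. All other channels come from a with-injection LPM run. Sensor
noise is per-channel white Gaussian (defaults 0.05 L/min flows,
0.5 mmHg pressures) plus a 60 Hz mains tone (0.1 L/min / 1 mmHg)
synthesized in continuous time — at the default 100 Hz sampling it appears
aliased at 40 Hz, exactly as a real DAQ records it, and either way far
above the 15 Hz low-pass cutoff. Identical seeds give bitwise-identical
records; seeds change only the noise.

For standard protocol sweeps the programmed E0 of each case is the
**published measured entrainment** for that (mode, rate, volume) cell, so a
full sweep reproduces the published entrainment landscape; envelope time
constants default to 0.35/0.15 s, inside the measured sub-second relaxation
range. The emulator also stores the reference rise/fall/relaxation times of
its own noiseless composite in the record metadata (`gt_*` keys), because
the measurable response mixes the injector lag with the entrainment
envelope and is not a pure first-order shape.

**What passing recovery tests do and do not show.** They show the pipeline
(filter → segment → step metrics → entrainment) faithfully recovers known
plateaus and timings from realistically noisy records of a physically
consistent circulation. They do not validate the rig against a real
benchtop: real sensors drift, the rig's noise spectrum is unpublished, and
the emulator's entrainment is additive by construction rather than arising
from jet momentum transfer (the mechanistic CFD question is out of scope
here).

## Signal pipeline choices

* Filtering: Butterworth (order 4, 15 Hz ≈ 11 × heart frequency) applied
  forward-backward (`sosfiltfilt`, zero phase — essential so rise/fall
  timings are not shifted), then Savitzky–Golay (window 21 samples,
  polyorder 3). Order of stages: broadband/mains removal first, shape
  polish second. All parameters configurable; the experiment's own filter
  settings are unpublished, which is precisely why timing metrics are
  validated against synthetic ground truth instead of published tables.
* Segmentation: command-aligned mode uses the protocol schedule directly
  (used for synthetic validation and sweeps); signal-detected mode
  thresholds at baseline mean + 3 SD sustained for 10 samples (0.1 s at
  100 Hz), for records lacking protocol metadata.
* Step metrics: settling value = mean of the final quartile of the
  activation segment; rise time = 10%→90% of Δ = settling − baseline;
  fall time mirrors it with the same Δ (the alternative — normalizing the
  decay by its own amplitude — is not adopted); settling time = entry into
  the ±2%·Δ band; crossings located by linear interpolation between
  bracketing samples (sub-sample resolution); first-crossing convention
  under oscillation. Per-burst metrics of pulsed runs are averaged
  field-wise.
* Entrainment measurement: Q_meas,RPA is averaged over the burst on-phases
  with each burst's initial rise transient excluded (the plateau is what
  the entrainment definition addresses); continuous windows additionally
  truncate to whole cardiac cycles, while pulsed on-phases can be shorter
  than one cycle and use the plain time mean. Q_s defaults to the measured
  pre-injection systemic flow (a flag selects the nominal pump output
  instead). Eq-level dead band of 1e−6 L/min separates "neutral" from the
  entrainment/blockage labels.

## Validation tolerances and problem sizes

The test suite validates step metrics against closed forms
(rise = τ·ln 9, settling = τ·ln 50, within 2 samples at 100 Hz; the
discretization error is O(1/fs²) and is checked to at least halve from
100 to 200 Hz on a grid-phase-averaged basis). Parameter recovery runs 50
seeded trials at default noise on a 1.2 L/min continuous case (noise SD
≈ 4% of Q_inj): the mean recovered entrainment falls within 5% of the
programmed value with the correct sign in every trial, and the mean
recovered relaxation time within 2 samples of the composite ground truth.
Single-trial relaxation times scatter by ~0.04 s because the 90%
thresholds sit on the flat part of the response, where noise moves the
first crossing most — the reason the experiment itself reports
trial-averaged tables. The full 20-case × 3-trial sweep with analysis runs
in well under a minute on one CPU.

## Known limitations

* The model is linear: no pressure-dependent resistances, no inertance,
  no respiratory modulation, no fenestration.
* Absolute relaxation-time tables from the benchtop are not reproduction
  targets: they depend on the rig's unpublished filter and sampling
  settings; only signs and trends are comparable.
* The published pulsed-table row labels (0.015 / 0.2 L) are interpreted as
  per-burst volumes (0.015 / 0.020 L); the packaged fixture keeps the
  printed labels.
* A printed companion table of in-vitro flow rates duplicates the pressure
  table's values and is inconsistent with CO ≈ 2.4 L/min; it is treated as
  a publication erratum and not packaged.
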