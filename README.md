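# fontanjet

Reduced-order simulation and signal analysis for **injection-jet-assisted
Fontan circulation**.

Patients palliated with a Fontan procedure live with a total cavopulmonary
connection (TCPC): systemic venous return flows passively into the pulmonary
arteries without a subpulmonary ventricle. One proposed way to energize this
fragile circulation is an injection jet shunt (IJS): a high-velocity jet of
systemic (aortic) blood injected into the pulmonary pathway to entrain the
slow venous co-flow by momentum transfer. Whether a given injection actually
*entrains* flow — or instead *blocks* it and risks volume buildup — depends
on the injection rate, volume and modality (continuous vs pulsed).

`fontanjet` packages the benchtop side of that question for in-silico use:

* **`lpm_core`** — a four-compartment Windkessel (resistance–compliance)
  model of the mock flow loop: upper/lower systemic and right/left pulmonary
  beds around an ideal TCPC junction, driven by a pulsatile piston pump
  (80 bpm, 30 cc stroke, CO ≈ 2.4 L/min), with a deterministic resistance
  tuner that enforces the 30/70 systemic and 50/50 pulmonary flow splits.
* **`injection_protocol`** — the 20-case clinical protocol (12 continuous,
  8 five-burst pulsed injections at 5–20 mL/s) with first-order injector
  spool-up dynamics.
* **`synthetic_mfl`** — a sensor-record emulator with programmable
  ground-truth entrainment and seeded noise, so the whole analysis chain can
  be validated by parameter recovery.
* **`signal_processing` / `segmentation` / `jet_characterization` /
  `entrainment`** — the waveform pipeline: zero-phase Butterworth +
  Savitzky–Golay denoising, three-stage (pre/active/post) and per-burst
  segmentation, step-response metrics, and the entrainment quantities

  ```
  Q_ent  = Q_meas,RPA − (Q_baseline,RPA + Q_inj)        (entrainment rate)
  t_rel  = t_rise − t_fall                              (jet relaxation time)
  ```

  where `Q_baseline,RPA = Q_s × pulmonary split`. Positive `Q_ent` means the
  jet entrains co-flow; negative means blockage. Negative `t_rel` flags
  likely fluid buildup across repeated pulses.
* **`reporting` / `cli`** — end-to-end protocol sweeps (cases × trials) with
  deterministic per-trial seeds, result matrices over the
  (volume × rate) grid, and the published benchtop result tables packaged as
  reference fixtures.

## Worked example

Emulate protocol case 13 (continuous injection, 10 mL/s = 0.6 L/min,
100 cc), run the full analysis, and print the jet quantities:

```python
import fontanjet as fj
from fontanjet.reporting import default_emulation_for_case, analyze_record

params = fj.default_parameters()            # tuned rig (CO 2.4, 30/70, 50/50)
proto = fj.get_case(13)                     # continuous, 0.6 L/min, 0.1 L
emu = default_emulation_for_case(proto)     # programmed ground truth
rec = fj.emulate_mfl(params, proto, fj.SensorModel(seed=42), emu)
metrics, result = analyze_record(rec, proto)
```

Output of this exact snippet:

```
programmed E0      = +0.0389 L/min
Q_meas,RPA         = 1.8424 L/min
Q_baseline,RPA     = 1.2005 L/min
Q_ent              = +0.0419 L/min  (entrainment)
normalized         = +0.0698
t_rise = 0.425 s, t_fall = 0.453 s, t_rel = -0.028 s
```

Reading: the measured RPA flow during the active window (1.84 L/min) exceeds
the superposition prediction (1.20 baseline + 0.60 injected) by
+0.042 L/min, so this injection mildly entrains co-flow — and the recovered
value sits within noise of the programmed ground truth (+0.039). The jet
rise and fall times are nearly symmetric here, so `t_rel ≈ 0`.

The same pipeline is scriptable from the shell:

```bash
fontanjet fixtures --case 13 --seed 42 --out case13.csv
fontanjet filter --in case13.csv --out case13_filt.csv
fontanjet entrain --in case13_filt.csv --case 13
fontanjet sweep --cases all --trials 3 --seed 1 --out results/sweep
```

The sweep writes per-trial long-form CSV, trial-averaged entrainment and
relaxation matrices for each injection mode, and a manifest with every
derived seed; identical configuration and seed reproduce byte-identical
outputs.

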