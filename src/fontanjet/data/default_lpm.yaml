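# Default rig parameterization, version 1.
#
# No published resistance/compliance values exist for this rig, so the
# defaults below were produced by the package's own tuning procedure
# (tune_resistances) against the stated operating point:
#   - pump 80 bpm x 30 cc stroke  ->  CO = 2.4 L/min
#   - 30% of CO to the upper body, 70% to the lower body
#   - 50/50 RPA/LPA split of pulmonary return
#   - venous chamber pressures ~17-20 mmHg, pulmonary chambers ~7-8 mmHg,
#     aortic-analogue ~95-100 mmHg (failing-Fontan range)
# Compliances reflect benchtop compliance chambers, which are far stiffer
# than in-vivo venous beds (a few mL/mmHg): the loop then re-equilibrates
# within a few seconds of an injection step, as the measured plateaus of
# 15-30 s injections require.  The small stiff pump-outlet chamber lives
# under plumbing, together with the venous and drain line resistances.
pump:
  heart_rate: 80.0                 # beats/min
  stroke_volume: 30.0              # mL
  ejection_fraction_of_cycle: 0.3  # half-sine ejection occupies 30% of cycle
venous_reference_pressure: 5.0     # mmHg, atrial reservoir
systemic_split_target: 0.30
pulmonary_split_target: 0.50
plumbing:
  aortic_compliance: 0.8           # mL/mmHg, pump outlet chamber
  venous_resistance: 2.0           # mmHg.min/L, each systemic chamber -> TCPC
  drain_resistance: 2.25           # mmHg.min/L, each pulmonary chamber -> reservoir
compartments:
  upper_systemic:
    resistance: 110.0              # mmHg.min/L (tuned: 30% upper split)
    compliance: 5.0                # mL/mmHg
  lower_systemic:
    resistance: 46.0               # mmHg.min/L
    compliance: 8.0                # mL/mmHg
  rpa:
    resistance: 6.9                # mmHg.min/L (tuned: 50% RPA split)
    compliance: 5.0                # mL/mmHg
  lpa:
    resistance: 6.9                # mmHg.min/L
    compliance: 5.0                # mL/mmHg
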