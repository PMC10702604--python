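# venosim

Simulation and analysis toolkit for conductance-balloon lumen sizing and
venous compliance profiling.

A multi-electrode sizing balloon measures luminal cross-sectional area
(CSA) by Ohm's law: a constant AC current is driven between the outermost
electrodes of a saline-filled balloon, and the voltage drop across each
adjacent detection-electrode pair gives the conductance of the saline
column, hence `CSA = I·L / (σ·ΔV)` per pair. Inflating the balloon in
pressure steps and re-sizing at each step yields an axially resolved
pressure–area (compliance) profile that distinguishes healthy, venous-
hypertensive and post-thrombotic (low-compliance, plateauing) vessel
segments.

No measured data ship with this package; a forward physics simulator and
synthetic phantom/vein generators stand in for the hardware and the
animal model, so the whole chain is testable end to end.

## Modules

| module | contents |
|---|---|
| `venosim.device` | electrode geometry, excitation constants, `device.json` config I/O |
| `venosim.forward` | series-conductor conductance, voltage simulation, carrier synthesis, noise, recording CSV I/O |
| `venosim.sizing` | lock-in demodulation, conductivity calibration, CSA/diameter inversion, minimal-lumen and reference-diameter detection |
| `venosim.mechanics` | rigid phantoms, linear-with-plateau vein constitutive laws, worked-example vein, synthetic cohort generator |
| `venosim.compliance` | stepwise pressure protocol, stretch ratios, ΔCSA/ΔP slopes, plateau detection |
| `venosim.stats` | accuracy/repeatability reports, origin-forced regression, Bland-Altman, one-way ANOVA |
| `venosim.cli` | `venosim simulate / size / compliance / validate` |

Units: lengths mm, areas mm², conductivity S/mm, current A (µA in
configs), voltage V, pressure cm H₂O.

## CLI quick start

```sh
# synthetic recordings: 17 rigid phantoms, a stenotic worked-example
# vein over 0-40 cmH2O, or an 18-limb three-state cohort
venosim simulate --scenario worked_example --seed 1 --out runs/we
venosim simulate --scenario cohort --noise 0.01 --seed 1 --out runs/cohort

# size one recording (known saline conductivity, or calibrate from a
# reference phantom recording)
venosim size runs/we/worked_example.csv --pressure 0 --out profile.csv

# compliance analysis (+ per-pressure-step state ANOVA for a cohort dir)
venosim compliance runs/cohort --out runs/comp

# agreement statistics against ground truth (id,value CSVs)
venosim validate --truth truth.csv --measurements meas.csv --out runs/val
```

All commands are deterministic given `--seed`.

## Fixtures

`fixtures/worked_example.json` is the serialized worked-example vein
(regenerable via `venosim.mechanics.make_worked_example_vein().save(...)`).
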