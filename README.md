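# tesplan

A planning toolkit for **reciprocity-targeted transcranial electrical
stimulation (TES)** with dense electrode arrays, exercised entirely on
synthetic head phantoms and synthetic cohorts.

Conventional tDCS pushes current between two large sponge electrodes; where
that current actually polarizes the folded cortical sheet is uncertain, and
so is whether a target even receives "anodal" or "cathodal" current.  With a
volume-conductor head model and a dense (up to 256-channel) geodesic
electrode array, the montage can instead be derived from the **EEG/TES
reciprocity principle**: the scalp voltage topography that a dipole at the
cortical target would generate tells you, electrode by electrode, where to
inject and withdraw current to maximize the current density along that
dipole's orientation.  `tesplan` implements that full planning chain plus
the dosimetry and motor-evoked-potential (MEP) statistics used to assess
slow pulsed protocols:

* **`tesplan.phantom`** — voxel head models: concentric-shell phantoms
  (scalp / skull / CSF / gray matter, default radii 92 / 85 / 80 / 78 mm)
  with literature conductivities (S/m): scalp 0.44, skull 0.018, CSF 1.79,
  gray matter 0.25, white matter 0.35, eyeball 1.5, air 0; plus
  Fibonacci-spiral geodesic electrode layouts projected onto the scalp.
* **`tesplan.fdm`** — the quasi-static current-flow equation
  ∇·(σ∇φ) = −s discretized with a 7-point finite-difference stencil
  (harmonic-mean face conductances, insulating air boundary) and solved by
  preconditioned conjugate gradients; lead-field matrices **L** (electrodes ×
  cortical patches, volts per A·m) built from one reciprocal solve per
  electrode.
* **`tesplan.analytic`** — Legendre-series potentials for layered spheres
  (dipole, interior monopole, and surface injection sources), the
  independent oracle the solver is validated against.
* **`tesplan.cortex`** — parcellation of a cortical surface mesh into
  ~1 cm² patches with area-weighted average normals, the dipole
  orientations used for targeting.
* **`tesplan.targeting`** — the ranked-weighting montage rule: sort
  electrodes by the target's scalp projection, take the N strongest
  positive as sources and M strongest negative as sinks, weight each by
  voltage relative to the side maximum times the 200 µA per-channel cap,
  re-balance the larger side so the montage sums to zero, and rescale if
  the one-sided total exceeds the requested total or the 2 mA safety cap.
  Includes sham (placebo) montage construction and montage evaluation
  (normal/tangential current density per patch).
* **`tesplan.dosimetry`** — waveform descriptors (tDCS, pulsed tPCS,
  slow-oscillatory so-tDCS, sham, conditioning) with total
  current-injection time and charge; presets for the published protocols
  they are compared against.
* **`tesplan.mep`** — MEP after-effect analysis (min/max-trimmed block
  means, baseline normalization, one-tailed paired t-tests, exact binomial
  goodness-of-fit) and a synthetic 12-participant crossover cohort
  generator (cathodal / anodal / placebo ratio means 0.79 / 0.93 / 1.10).

## Worked example

Rank-and-weight a montage by hand from a scalp projection of
`[10, 8, 6, −9, −3, −1]` µV with two sources, two sinks, a 200 µA channel
cap and a 2 mA requested total:

```python
import numpy as np
from tesplan.targeting import SafetyLimits, select_and_weight, balance_and_cap

v = np.array([10.0, 8.0, 6.0, -9.0, -3.0, -1.0])
montage = balance_and_cap(select_and_weight(v, 2, 2, SafetyLimits()), 2.0, SafetyLimits())
for eid, c in zip(montage.electrode_ids, montage.currents_ua):
    if c:
        print(f"{eid}: {c:+8.2f} uA")
```

```
E001:  +148.15 uA
E002:  +118.52 uA
E004:  -200.00 uA
E005:   -66.67 uA
```

The two sinks keep weights −1.0 and −1/3 of the cap (−200, −66.67 µA,
266.67 µA total); the source side, initially 360 µA, is scaled down by
266.67/360 so the montage sums to exactly zero while every channel stays
under the cap.  Dosimetry of the slow pulsed protocol this montage would
deliver (100 ms pulses at 0.5 Hz for 17 min at the cohort-mean 1.16 mA):

```python
from tesplan.dosimetry import preset_protocols, injection_time, total_charge, mean_current_density
p = preset_protocols()["present_tpcs"]
print(injection_time(p), total_charge(p), mean_current_density(1.16, 8))
```

```
51.0 59.16 0.15
```

i.e. 51 s of actual current flow, 59.16 mC of charge — roughly a fifth of
the charge of a classical 5-minute 1 mA cathodal tDCS session (300 mC) —
at a mean current density of 0.15 mA/cm².  An end-to-end plan on the
synthetic 4-shell phantom (phantom → lead field → montage → sham → dose →
evaluation) is one call:

```bash
tesplan run --out-dir plan_out --spacing-mm 4 --n-electrodes 64
tesplan dose --protocol present_tpcs
tesplan mep --simulate --seed 7
```

## Scope

The toolkit operates on synthetic phantoms: there is no MRI segmentation,
CT atlas warping, TMS neuronavigation, electrode digitization, or EMG
signal processing here.  Head geometry enters as voxel label volumes
(NIfTI) or shell specs (JSON); cortical surfaces as PLY/STL meshes;
electrodes as CSV/.sfp tables; MEP amplitudes as tidy CSV.
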