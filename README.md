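# holoperf

Quantitative analysis of holmium-microsphere distribution in machine-perfused
livers, with a synthetic phantom that makes every stage testable.

Holmium-166 microspheres are delivered through the hepatic artery (HA) in
transarterial radioembolisation (TARE). How evenly they spread through liver
tissue depends on hemodynamics: the HA flow rate governs how completely
spheres mix with blood before each vessel bifurcation, and poor mixing at low
flow leaves clustered, proximal deposits. Because the spheres are
paramagnetic, their concentration can be mapped voxel-by-voxel with MRI.
`holoperf` is for imaging scientists and dosimetry researchers who want an
open, tested implementation of that analysis chain:

- **R2\* mapping** — voxel-wise weighted log-linear fits to multi-echo
  gradient-echo magnitude data (10 echoes, TE₁ = 1.7 ms, ΔTE = 1.35 ms by
  default), with invalid-voxel flagging and signal-void guards.
- **Concentration and fictive dose maps** — ΔR2\* is linear in holmium
  concentration (relaxivity r₂\*); absorbed dose under the local-deposition
  model is

  D [Gy] = k_Ho · C · SA / ρ

  with C the microsphere concentration (mg/mL), SA the (fictive) specific
  activity (12 MBq/mg), ρ the tissue density (1.04 g/mL) and
  k_Ho = 15.87 Gy·kg/GBq the ¹⁶⁶Ho full-decay factor. Under these defaults a
  60 Gy whole-liver mean dose corresponds to 0.33 mg/mL of microspheres, and
  a 300 Gy superselective (one-lobe) dose to 1.64 mg/mL.
- **DCE-MRI perfusion** — per-lobe time-intensity curves from a 200-frame,
  0.86 s dynamic series; percent enhancement PE = 100·(S₁ − S₀)/S₁ (note the
  post-injection denominator, implemented exactly as this convention reads;
  the conventional S₀ denominator is available behind a flag); the maximum
  wash-in slope of the PE curve is the relative perfusion-rate measure.
- **Dose-homogeneity statistics** — DVH percentiles with the radiotherapy
  convention (Dp% = dose exceeded by p% of the volume), the homogeneity
  index HI = (D2% − D98%)/Dmean (lower = more homogeneous), and HI
  trajectories against administered mg per mL of tissue.
- **Perfusion–deposition association** — lobe microsphere counts from the
  concentration map (a 30 µm, 1.4 g/mL sphere is 1.98·10⁻⁵ mg), Pearson
  correlation with relative perfusion, and the interpretation bins
  (0–0.1 none … 0.8–1 very strong, r = 1 perfect).
- **A mechanistic phantom** — five porcine-style lobes (left lateral, left
  medial, right medial, right lateral, caudate), Murray-law arterial trees,
  and a packet-based deposition simulator in which a mixing parameter
  (increasing with HA flow: 0.02, 0.15, 0.22 mL/min/g conditions) trades
  flow-proportional routing against streamline bias and proximal lodging.
  The phantom synthesises multi-echo, dynamic-contrast and micro-CT images
  with known ground truth.

## Worked example

```python
import numpy as np
from holoperf import (concentration_for_dose, dose_map, homogeneity_index,
                      correlate_perfusion_deposition, microsphere_counts)
from holoperf.perfusion import analyze_dce
from holoperf.phantom import (build_liver_phantom, grow_arterial_tree,
                              simulate_deposition, synthesize_dce,
                              FlowCondition, FractionSchedule, DceParams)

print("60 Gy  ->", round(concentration_for_dose(60.0), 2), "mg/mL")
print("300 Gy ->", round(concentration_for_dose(300.0), 2), "mg/mL")

labels = build_liver_phantom(shape=(48, 48, 32), spacing=2.0,
                             target_volume_ml=300.0, seed=1)
trees = {lobe: grow_arterial_tree(labels.lobe_mask(lobe), labels.spacing,
                                  generations=7, seed=100 + lobe)
         for lobe in range(1, 6)}
scale = labels.liver_volume_ml() / 2600.0          # preserve mg per mL
schedule = FractionSchedule(masses_mg=(250.0 * scale,) * 5)

for name in ("low", "high"):
    truth = simulate_deposition(labels, trees, schedule,
                                FlowCondition.from_name(name), seed=0)
    conc = truth.true_concentration[-1]
    stats = homogeneity_index(dose_map(conc).dose, mask=labels.liver_mask)
    dce = synthesize_dce(labels, truth.lobe_perfusion_fraction, DceParams())
    perf = analyze_dce(dce, labels)
    counts = microsphere_counts(conc, labels, truth.spheres)
    assoc = correlate_perfusion_deposition(perf, counts)
    print(f"{name:>4}: HI = {stats.hi:.2f}   r = {assoc.r:.3f} ({assoc.category})")
```

prints

```
60 Gy  -> 0.33 mg/mL
300 Gy -> 1.64 mg/mL
 low: HI = 4.32   r = 0.949 (very strong)
high: HI = 1.83   r = 0.997 (very strong)
```

The dose-limit conversions are the closed-form inversions of the voxel dose
law. The two simulated administrations show the central hemodynamic effect:
five fractions at the low-flow condition give a heterogeneous dose map
(HI ≈ 4.3) and a weaker perfusion–deposition correlation, while the
high-flow condition homogenises the deposit (HI ≈ 1.8) and pushes the
lobe-level correlation toward 1.

A CLI exposes each stage (`holoperf simulate | r2star | dose | dce |
metrics | microct | associate | hemo | run`); `holoperf run --outdir out/`
executes the full phantom-to-report chain and writes NIfTI volumes, CSV
tables, and a JSON summary that is byte-identical for identical
(config, seed) pairs.

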