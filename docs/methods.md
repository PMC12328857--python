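# Methods

This note documents the models behind `holoperf`, the defaults and why they
were chosen, what the synthetic phantom does and does not emulate, and the
numerical conventions that matter for reproducing its outputs.

## Dosimetry model

Holmium concentration elevates the effective transverse relaxation rate
linearly, R2\* = R2\*₀ + r₂\*·C. The analysis chain estimates R2\* per voxel
from multi-echo magnitude data by weighted least squares on ln S vs TE with
weights ∝ S² — the first-order noise-propagation weighting for
log-transformed magnitude data. Echoes at or below a configurable noise
floor are excluded; voxels with fewer than three usable echoes are flagged
invalid (NaN), never zeroed; fitted rates are clipped to [0, 2000 s⁻¹] as a
signal-void guard. A nonlinear refinement was considered and rejected: at
phantom SNR the log-linear estimator is already unbiased to well under 2%,
and it is deterministic and fast.

Concentration is C = max(0, R2\*post − R2\*baseline)/r₂\*. Negative ΔR2\*
(noise) is clamped to zero and counted in a QC record, because deposited
spheres cannot produce a negative shift. When no baseline scan exists, a
scalar global tissue estimate may substitute.

Dose uses the local-deposition assumption — every voxel absorbs its own
decay energy — appropriate at voxel scales much larger than the ¹⁶⁶Ho beta
range:

    D [Gy] = k_Ho · C·SA/ρ,       C·SA/ρ in MBq/g ≡ GBq/kg.

Defaults: SA = 12 MBq/mg (the fictive specific activity assigned to
nonradioactive spheres), k_Ho = 15.87 Gy·kg/GBq (standard ¹⁶⁶Ho full-decay
factor), ρ = 1.04 g/mL (physiologic soft-tissue density). The pair
(k_Ho, ρ) is not uniquely identified by the two printed dose–concentration
correspondences (0.33 mg/mL ↔ 60 Gy, 1.64 mg/mL ↔ 300 Gy); the defaults are
literature values that reproduce both at two decimals, and all three
constants are config-exposed rather than asserted. The relaxivity default
(90 s⁻¹ per mg/mL at 1.5 T) matters only through the consistency of
synthesis and analysis; a deliberately mis-specified analysis relaxivity
produces exactly the expected linear bias, which the suite checks.

## Perfusion model

Per-lobe time-intensity curves are averaged over lobe ROIs; the first 10
frames (configurable) define the pre-contrast baseline S₀. Percent
enhancement is computed with the post-injection denominator,
PE = 100·(S₁ − S₀)/S₁. That denominator is unusual — the conventional form
divides by S₀ — but it is the convention this pipeline pins (and regression
tests assert: S₀ = 100, S₁ = 400 gives 75, not 300); the conventional form
is available behind a flag for sensitivity analysis.

The perfusion-rate measure is the maximum slope of the PE curve inside the
wash-in window, taken as the span from the last frame below 5% of the curve
maximum to the first frame reaching 95% of it (these bounds are a design
choice, config-exposed). The slope is the maximum over sliding 5-frame
(≈ 4.3 s) linear regressions — wide enough to be robust at 0.86 s sampling,
narrow enough to track the wash-in. Relative perfusion is the slope vector
normalised to sum to one. Flat curves (max PE at or below a noise
threshold) are flagged non-enhancing with slope zero rather than fitted.

## Homogeneity metrics

Dp% follows the radiotherapy DVH convention: the dose exceeded by exactly
p% of the masked volume, i.e. the (100 − p)-th percentile of voxel doses
with linear interpolation between order statistics. All in-mask voxels
enter the statistics, including zero-dose voxels — cold lobes are part of
the organ and their effect on HI is real. HI = (D2% − D98%)/Dmean is
scale-invariant; a zero mean dose yields a flagged NaN. Micro-CT
segmentation thresholds at 350 HU with 26-connectivity (standard for thin
tubular structures); the per-component radius estimate is the maximum of
the Euclidean distance transform — the largest inscribed sphere, which for
a filled cylinder recovers the vessel radius and for a thin deposit sheet
its half-thickness.

## The phantom

The phantom provides ground truth the ex vivo experiments cannot: true
voxel concentrations, true per-vessel deposited mass, and true lobe
perfusion shares.

**Anatomy.** A smooth organ (ellipsoid perturbed by a low-frequency
Gaussian random field) is partitioned into five lobes by a weighted Voronoi
iteration driven to target volume fractions 0.30/0.20/0.20/0.22/0.08. The
default grid (96×96×64 at 2 mm) hosts ≈ 2,600 mL, a porcine liver after
perfusion-related weight gain; the test suite uses ≈ 300 mL grids.

**Trees.** Each lobe gets a complete binary tree (7 generations → 64
terminals) grown by recursive 2-means splitting of the lobe voxel cloud.
Branch flow fractions start from the tissue-volume shares of the daughter
clouds and are perturbed by a lognormal calibre-variability factor
(σ = 0.30): real vessel calibres are not set by served volume alone, and
this mismatch between flow and territory volume is the mechanism that
leaves residual dose heterogeneity even under perfect mixing. Radii follow
Murray's law (r³ conserved across bifurcations), so flow ∝ r³ exactly.
Terminal territories are the nearest-terminal partition of the lobe.

**Transport.** Microspheres travel as packets (10⁴ per 250 mg fraction;
packet count scales with fraction mass so every packet carries the same
sphere mass). At each bifurcation, including the lobe-level split at the
catheter tip, the packet chooses child c with probability
mixing·f_c + (1 − mixing)·g_c, where g_c ∝ f_c^γ (γ = 3) exaggerates the
dominant branch when mixing is poor. Before each bifurcation the packet
lodges in its current segment with probability
λ·(1 − mixing)·exp(−gen/τ_g) (λ = 0.25, τ_g = 2). Mass is conserved exactly
for every seed and schedule. The mixing values assigned to the flow
conditions (low → 0.25, medium → 0.65, high → 0.90) and the trio (γ, λ,
calibre σ) are free parameters: no quantitative mixing law exists for this
system, so they were calibrated once against the qualitative
homogeneity-index bands (low-flow HI ≈ 3.5–5.0, high-flow ≈ 1.5–2.5) and
are not measurements.

**Rasterisation.** Terminal packets deposit at uniformly random voxels of
their territory — discrete cluster formation in the capillary bed — and
non-terminal mass is painted along segment centrelines; each lobe's map is
then blurred (σ = 1 voxel), confined to its own lobe (spheres cannot cross
lobar vascular territories), and renormalised so lobe mass is exact. The
random within-territory placement is what makes early fractions spotty and
lets homogeneity improve as fractions accumulate, flattening once counting
noise falls below the systematic flow-vs-volume mismatch — at roughly
1 mg/mL administered loading.

**Signal synthesis.** Multi-echo magnitude: S(TE) = S₀·exp(−R2\*·TE) with
Rician noise (the magnitude-MR noise model). Dynamic contrast: per-lobe
percent-enhancement curves A_l·w((t − t₀)/T) with w a quintic smoothstep
(compact support — exactly flat baseline within a finite acquisition, which
an infinite-tailed logistic cannot give) and amplitude A_l proportional to
the lobe's perfusion share; the voxel signal is the inversion
S = S₀/(1 − PE/100) of the pipeline's own PE transform. Because all lobes
share t₀ and T, sampling and windowing biases cancel in the slope ratios
and noiseless analysis recovers the perfusion shares to machine precision;
the analytic maximum PE slope is A_l·(15/8)/T. Gaussian temporal noise is
added per voxel. Micro-CT: lodged mass renders as a packed plug at the
distal end of its segment (plug volume = mass / (1.4 mg/mm³ × 0.6 packing),
1,200 HU) on N(40, 15) HU parenchyma; sub-voxel plugs are painted with
partial-volume attenuation and naturally fall below the 350 HU threshold,
so sparse deposits in large vessels are invisible, as on real
reconstructions.

**What the phantom does not emulate.** Computational fluid dynamics,
pulsatile or portal-vein transport, vessel tortuosity and non-binary
branching, organ deterioration, registration error between series (all
phantom series are born co-registered), partial-volume and susceptibility
artefacts beyond mono-exponential decay, and scanner reconstruction.
Passing tests therefore demonstrate the correctness and internal
consistency of the analysis chain and the directional physics of the
transport model — not quantitative agreement with any particular ex vivo
organ.

## Problem sizes and reproducibility

The suite and the worked examples run desk-scale phantoms: 48×48×32 grids
(≈ 300 mL liver), 7-generation trees, 10⁴ packets per fraction, with
fraction masses scaled by liver volume so the administered mg per mL of
tissue matches the full-scale schedule (five 250 mg fractions, optionally
four more of 1,000 mg, into ≈ 2,600 mL). Homogeneity indices are computed
on the organ mask (the whole-mask choice is deliberate; see above).
All randomness flows from one top-level seed through named substreams
(anatomy, tree, perfusion, deposition, noise, dce, microct), and a full
pipeline run is a pure function of (config, seed) — repeated runs write
byte-identical summaries (floats rounded to 10 significant decimals in the
JSON for cross-platform stability).

## Known limitations

- The deposition parameters are qualitative calibrations; different (γ, λ,
  σ) triples can produce the same HI ordering.
- Lobe-level correlation in the simulator is driven by the biased lobe
  split; within-lobe heterogeneity does not feed back on lobe totals.
- The Dp% convention and the 5%/95% wash-in window are documented choices;
  other conventions shift absolute HI and slope values slightly.
- With per-segment capacities enabled, overflow redistributes upstream and
  a saturated root raises a stasis error; study-level loadings never
  approach capacity, so this path is exercised only synthetically.
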