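# Methods

## The model

The question modelled is whether a triplefin-sized observer that focuses
downwelling sunlight into a bright iris patch (an "ocular spark") can
perceive the extra light that this patch throws back out of a scorpionfish's
retroreflective pupil, and out to what distance.

### Radiometric chain

All spectra live on a closed 400–700 nm grid at 1 nm (301 samples); every
spectral integral is a rectangle sum (value × 1 nm). Inputs are assumed to
be calibrated photon-unit radiances/irradiances or dimensionless
proportions; no energy-to-photon conversion is offered.

Two photon paths are propagated, strictly on-axis (observer and target
pupils facing each other), with small-angle solid angles Ω = A/d²:

* **Baseline path** — the target pupil's own radiance L_base:
  Φ₂(λ) = L_base·A_sp·A_tf/d². Exact d⁻² scaling.
* **Spark path** — the spark patch is a diffuse Lambertian reflector,
  L_spark = R_spark·E_down/π. It irradiates the target pupil
  (E_t = L_spark·A_spark/d²), which returns L_r = E_t·R_retro/π toward the
  source; the observer pupil collects Φ_r = L_r·A_sp·A_tf/d². Exact d⁻⁴
  scaling.

The retroreflector is *not* modelled as an angular lobe: the narrow return
beam is absorbed into the magnitude of R_retro, which is expressed relative
to a diffuse white standard and may therefore exceed 1. This is also how
the sensitivity grid's retroreflectance axis reads. Measured spark
radiances can be supplied directly in place of the R·E/π construction. No
water attenuation or cosine obliquity is applied over the 1–15 cm path.

These choices constitute the package's normative interpretation of the
chain (logged at run time): they reproduce every property the system is
known to have — diffuse spark, proportional reflectance above 1, per-nm
fluxes, inverse-square baseline vs inverse-fourth-power spark path — and
every stage is auditable against closed-form oracles in the test suite.

### Visual model

Quantum catches: qᵢ = Σ Φ·T·Sᵢ·Δλ with ocular-media transmission T and
sensitivities Sᵢ for SWS, MWS, LWS channels. Chromatic discriminability
between spark-on and spark-off scenes uses the receptor-noise-limited model
in its logarithmic (Vorobyev–Osorio) form: fᵢ = ln(qᵢ,₁/qᵢ,₂),

ΔS = √[(e₁²(f₂−f₃)² + e₂²(f₁−f₃)² + e₃²(f₁−f₂)²) /
       ((e₁e₂)² + (e₁e₃)² + (e₂e₃)²)]   (JND)

with eᵢ = ω·√(η_max/ηᵢ). The single reported Weber fraction (ω = 0.05) is
anchored to the most abundant class — the double-cone members, η = (1,4,4)
— the standard convention when one ω is published. The log form was chosen
over the linear small-signal form as the field standard; at the contrasts
involved the difference is negligible. The double cones act as two
independent chromatic channels and, summed, as the achromatic channel,
compared via Michelson contrast C = (Q₁−Q₂)/(Q₁+Q₂).

### Detection distances

Contrasts are evaluated at each millimetre from 10 to 150 mm. "First value
at which the contrast meets the threshold" is implemented as the **maximum**
grid distance satisfying it (a descending scan): contrast decreases
monotonically in distance, so an ascending reading would trivially stop at
1 cm, inconsistent with maximum-discernible-distance semantics. Thresholds:
0.008 (Michelson), 1.0 JND (chromatic); both configurable. The solver
evaluates catches once and rescales by the exact d⁻²/d⁻⁴ laws, which is
algebraically identical to re-running the chain per distance; the test
suite checks it against a 0.1-mm brute-force oracle that does recompute the
raw formulas per distance.

The sensitivity grid scales a unit-peak spark spectrum and unit-peak
retroreflectance spectrum over level grids (default 0–2 in 0.05 steps —
axis ranges are user-set since the original figure's are graphical) and is
monotone non-decreasing along both axes. Facing orientation (north/south)
enters only as an ambient-irradiance scaling. The iris control runs the
identical machinery with the diffuse iris reflectance in both roles
(baseline R·E/π radiance, no retro gain).

## Synthetic data: what it emulates and what it does not

* **Ambient light** — flat surface spectrum under Beer–Lambert attenuation
  E = E₀·exp(−K·z), K(λ) rising quadratically from 0.04 m⁻¹ (400 nm) to
  0.55 m⁻¹ (700 nm), clear-water-like; at the default 10 m this gives the
  blue-green shifted spectrum the model expects. Only this qualitative
  shape matters for the property-based acceptance; no fit to real water
  types is attempted.
* **Sensitivities** — Govardovskii A1 template (α and β bands),
  peak-normalised. λmax defaults (SWS 468, MWS 516, LWS 530 nm) are
  documented placeholders, user-overridable, not asserted as the species'
  true values (those live in primary references, not in any table shipped
  here). The default ocular media is a generic long-pass sigmoid (50% at
  410 nm).
* **Scene surfaces** — blue Gaussian spark (peak 475 nm, σ 45 nm, default
  peak reflectance 0.6); retroreflectance a gentle long-pass sigmoid of
  unit peak by default (may be scaled above 1); iris flat and dull (0.05);
  baseline pupil radiance modelled as the ambient-lit retroreflectance
  shape scaled by 0.003 — a nearly black pupil whose faint daytime eyeshine
  returns a few ‰ of a diffuse white standard. With these defaults the
  achromatic detection distance lands at 5.1 cm, inside the 1–15 cm scan
  window and of the order reported for the real system, while the chromatic
  signal stays below 1 JND at all distances (peak 0.66 JND at 1 cm) because
  the retro path's spectrum is dominated by the same ambient × pupil shapes
  as the baseline. These values were fixed once, from the physical
  reasoning above, before the acceptance checks were run.
* **Behaviour** — each fish's mean distance starts at the 25 cm release
  point of a 50 cm arena and drifts toward the far wall with a
  quadratic-in-time saturating retreat (default 0.5 cm/min initial rate,
  zero slope at 100 min); the shaded arm starts `treatment_effect_cm`
  (default 8 cm) closer, with the gap closing linearly by 50 min. Noise is
  stationary Gaussian AR(1) within individual (ρ = 0.5), applied on the
  logit of distance/arena so trajectories respect the bounds; the cm-scale
  noise SD (default 6 cm) is converted to logit units by the transform's
  slope at the release point. The generator does **not** emulate the
  initial attraction phase real fish showed (hopping toward the stimulus
  before retreating): its configuration deliberately pins the
  first-timepoint mean to the release point, so absolute proximity
  percentages at a 7 cm cut are not comparable to field values — only the
  *difference between arms* is meaningful, which is why the
  parameter-recovery analysis uses a threshold midway between the two arm
  means. A green recovery test therefore establishes correct effect
  direction and magnitude, not realistic approach kinematics.

## Numerical choices

* Zero-fill (never constant-fill) extrapolation when resampling: outside a
  measured support, sensitivities and transmissions are dark.
* Rectangle rule on the 1-nm grid for every integral; linearity and an
  erf-form Gaussian oracle bound the error in tests.
* The exact-test odds ratio is the conditional MLE on the noncentral
  hypergeometric with the exact conditional 95% CI (the convention of
  standard statistical software, which is what reproduces a printed OR of
  0.31 with CI 0.10–0.88 from the raw counts); the two-sided p sums all
  tables with probability ≤ the observed one. Degenerate margins return
  p = 1 with an undefined-OR boundary convention (OR 1, CI (0, ∞)).
* Proximity classification uses strict `distance < threshold`; an
  `inclusive` flag exposes the ≤ variant since the published cut
  ("approximately 7 cm") does not specify boundary handling.
* Detection "none" is represented as `None` (NaN in grid matrices); a
  reported distance always lies on the grid with contrast ≥ threshold
  there.

## Known limitations

* Supplementary measured field spectra (and true aperture areas) are not
  published as data; geometry defaults are order-of-magnitude placeholders,
  so absolute detection distances from the default scene are illustrative,
  not reproductions of the field values (6–8 cm). The property suite, not
  those headline numbers, is the acceptance surface.
* No off-axis or extended-source integration, polarization, temporal
  integration, psychometric (probabilistic) detection, or luminance-noise
  RNL variant.
* The mixed-model (LMM/GLMM) time-course analyses of the behavioural
  experiments are out of scope; only the immediate-response 2×2 analysis is
  implemented.
* Whether the original flux equations include a short-path water
  attenuation or cosine term cannot be determined from the running text;
  none is applied (flagged, not guessed).
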