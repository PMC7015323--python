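# photoloc

Visual and radiometric modelling of **diurnal active photolocation**: can a
small benthic fish improve its detection of a cryptic, sit-and-wait predator
by redirecting downwelling sunlight from a bright "ocular spark" on its iris
and perceiving the retroreflected glow in the predator's pupil?

The package is aimed at visual ecologists who want a tested, scriptable
implementation of the full chain from spectra to detection distances:

1. **Radiometry.** Two on-axis photon paths reach the observer's pupil from
   the predator's eye at eye-to-eye distance *d*:
   - baseline eyeshine: Φ₂(λ) = L_base(λ)·A_sp·A_tf / d²  (∝ d⁻²)
   - spark retroreflection: the Lambertian spark (L = R·E/π) illuminates the
     pupil (E_t = L·A_spark/d²), which returns it (L_r = E_t·R_retro/π, with
     R_retro expressed relative to a diffuse white standard and allowed to
     exceed 1), giving Φ_r(λ) = L_r(λ)·A_sp·A_tf / d²  (∝ d⁻⁴).

   flux₁ = Φ₂ + Φ_r (spark on), flux₂ = Φ₂ (spark off).
2. **Vision.** Per-cone quantum catches qᵢ = Σ_λ Φ(λ)·T(λ)·Sᵢ(λ)·Δλ over
   400–700 nm for an SWS single cone and MWS/LWS double-cone members
   (density 1:4:4). Chromatic discriminability between the two scenes uses
   the receptor-noise-limited model (log signals, ω = 0.05 on the most
   abundant class; output in JND); achromatic contrast is the Michelson
   contrast C = (Q₁−Q₂)/(Q₁+Q₂) on the summed double-cone catches.
3. **Detection.** Both contrasts are evaluated at every millimetre from 1 to
   15 cm; the maximum discernible distance is the largest distance whose
   contrast meets the threshold (1.0 JND chromatic, 0.008 Michelson), plus a
   spark-reflectance × pupil-retroreflectance sensitivity grid and a
   diffuse-iris control comparison.
4. **Behaviour.** Proximity classification of first-approach distances into
   a 2×2 treatment table and Fisher's exact test with the conditional-MLE
   odds ratio and exact 95% CI.

Because no field spectra or distance records ship with the package, a
synthetic-data module generates physically structured stand-ins (attenuated
underwater ambient light, A1 pigment-template sensitivities, blue-peaked
spark, retroreflectance above 1, AR(1) approach/retreat trajectories).

## Worked example

Fisher's exact analysis of published first-approach counts — 9 of 42
clear-hatted vs 18 of 38 shading-hatted fish within 7 cm of the predator:

```
$ photoloc stats behavior.csv --threshold-cm 7
{
  "table": {"a": 9, "b": 33, "c": 18, "d": 20},
  "percent_within": [21, 47],
  "p_value": 0.018527093060319876,
  "odds_ratio": 0.30781681050041454,
  "ci95": [0.10060821400290577, 0.8847289243417225]
}
```

So 21% of clear-hatted versus 47% of shaded fish came within 7 cm; the odds
of a close approach under the clear hat are 0.31 times those under the
shading hat (95% CI 0.10–0.88, p = 0.019): fish able to produce ocular
sparks kept a safer distance.

The default synthetic scene (10 m depth, spark peak reflectance 0.6, pupil
retroreflectance 1.0, pupil baseline a few ‰ of a white standard):

```
$ photoloc detect
{
  "max_detect_achromatic_mm": 51.0,
  "max_detect_chromatic_mm": null
}
```

The spark-induced luminance change in the pupil is achromatically
perceptible out to 5.1 cm, while the chromatic signal never reaches 1 JND —
the spark brightens the eyeshine without usefully recolouring it.

Other commands: `photoloc generate` (write synthetic inputs),
`photoloc grid` (sensitivity heat-map CSV/PNG), `photoloc run` (everything,
with a manifest and summary JSON). All constants live in a YAML config; see
`photoloc.pipeline.RunConfig`.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete default pipeline from scratch — synthetic generation,
detection scan, sensitivity grid and the exact contingency analysis — into
`results/run/` and writes the results JSON to the given path.
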