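# fluorox

Placental oximetry from multi-TR fluorine-19 MRI.

Placental hypoperfusion and hypoxia drive pregnancy complications such as
preeclampsia, and ¹⁹F MRI of an injected perfluorocarbon (PFCE) emulsion
measures the absolute partial pressure of oxygen (PO₂) in the placenta
noninvasively: the ¹⁹F longitudinal relaxation rate R₁ = 1/T₁ of PFCE rises
linearly with dissolved oxygen.  `fluorox` implements the full analysis
chain for such studies — from multi-TR magnitude ¹⁹F volumes and placenta
ROIs to per-placenta (S₀, T₁, PO₂) and nested mixed-effects group
statistics — together with a synthetic phantom generator so every stage is
testable with known ground truth.  It is aimed at preclinical MRI groups
analysing saturation-recovery ¹⁹F oximetry data (e.g. mouse models of
placental malfunction under a gas challenge).

## Method

For each imaging session (one mother at one O₂ breathing condition,
acquired at TR = 318/719/1398/5000 ms):

1. **Noise estimation** — magnitude noise σₘ is the SD in a signal-free
   ROI; the underlying Gaussian channel noise is σ_g = σₘ/√(2 − π/2).
2. **Rician-corrected SNR** — SNR = √(SIₘ² − σ_g²)/σ_g (Gudbjartsson–Patz),
   clamped to 0 below the noise floor.
3. **Interpolation** to the ¹H anatomical grid (cubic), **Gaussian
   smoothing** (SD 3 anatomical pixels, in-plane) and **exclusion** of all
   voxels with SNR < 5 on the TR = 5 s image.
4. **Saturation-recovery fit** per placenta ROI:
   SNR(TR) = S₀·(1 − e^(−TR/T₁)), nonlinear least squares.
5. **Calibration** — PO₂ [mmHg] = 470.81/T₁ [s] − 200.14 (PFCE in vitro
   calibration); impossible values (< 0 or > 760 mmHg) are flagged, never
   censored.
6. **Statistics** — linear mixed models per outcome (PO₂, T₁, SNR(TR₁..₄),
   S₀) with genotype (between), %O₂ (within), their interaction, and random
   intercepts for mother and placenta-within-mother (mothers are the
   independent unit); REML, Wald F tests with Satterthwaite denominator df,
   estimated marginal means with 95% CIs, post-hoc per-oxygen genotype
   models.

The synthetic phantom reproduces the study design (WT 3 mothers/19
placentas vs KO 4/17, 30/60/100% O₂, acquisition geometry with a 64×84×8
¹⁹F matrix inside a 196×256×20 anatomical matrix over a shared 39.2×51.2 mm
field of view) with Rician magnitude noise and ground-truth PO₂/T₁/S₀
linked exactly by the calibration.

## Worked example

```python
from fluorox import PhantomConfig, fit_full_model, fit_posthoc_model, simulate_records

records = simulate_records(PhantomConfig(), seed=8)   # 36 placentas x 3 conditions
full = fit_full_model(records, "po2_mmhg")
print(full.anova.round(4))
post = fit_posthoc_model(records[records.oxygen_percent == 30.0], "po2_mmhg")
print(post.emmeans.round(1))
```

prints

```
            source  num_df  den_df         F       p
          genotype       1  5.4491    3.6200  0.1107
            oxygen       2 67.9998 1255.9446  0.0000
 genotype_x_oxygen       2 67.9998   73.8574  0.0000

genotype  oxygen_percent  estimate   se  df  ci_lo  ci_hi
      WT            30.0     103.5 12.0 4.8   72.1  134.8
      KO            30.0      25.2 11.1 6.1   -1.9   52.2
```

Read: oxygen in breathing air strongly drives placental PO₂, the genotype
effect exists only at 30% O₂ (significant interaction, no main effect), and
the post-hoc model at 30% O₂ estimates knockout placentas ~78 mmHg below
wildtype — the simulated study carries a 64 mmHg deficit, recovered here
within its confidence interval.  The `examples/` directory walks through
each capability (calibration, phantom, noise correction, fitting, mixed
models, full imaging pipeline), and the `fluorox` CLI (`simulate`,
`run-all`, `stats`, `report`) runs the same pipeline from a YAML config.

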