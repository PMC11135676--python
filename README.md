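# pulchkit

Quantitative analysis of pulcherrimin regulation in *Bacillus subtilis*:
three assay pipelines, each exercised end-to-end on synthetic data with
known ground truth.

Pulcherrimin is an insoluble red iron-chelate pigment produced as cells
exit exponential growth; its biosynthesis genes (*yvmC*, *cypX*) are
repressed during exponential phase by the transition-state regulators
ScoC and AbrB and by the MarR-family repressor PchR. `pulchkit`
implements the three quantitative procedures used to dissect this
regulation:

1. **Production kinetics** (`pulchkit.kinetics`). Pigment is quantified
   as A410 of alkali-solubilized pellets along a growth curve. The
   exponential-to-stationary transition T0 is detected from log-linear
   sliding-window fits of OD600; each strain x replicate A410 course is
   fitted with the Zwietering modified-Gompertz model

   y(t) = y0 + (K − y0) · exp(−exp( μmax·e·(λ − t)/(K − y0) + 1 ))

   giving the baseline y0, plateau (carrying capacity) K, maximum
   production rate μmax, and lag λ. Derived per strain: production start
   relative to T0 (earliest sustained deviation of the predicted mutant
   curve from the wild-type reference), duration ((K − y0)/μmax via the
   inflection-tangent construction), μmax and K, with Bonferroni-corrected
   Welch t-tests between strains.

2. **Reporter gating** (`pulchkit.flow`). Single-cell P*yvmC*-GFP
   fluorescence is gated against a no-GFP control: the threshold is the
   control's maximum, and %GFP+ = 100 × #(events > threshold)/#events.

3. **Differential DNase I footprinting** (`pulchkit.footprint`). A
   5'-labeled promoter probe (−244..+9 relative to the ATG) is digested
   with and without protein and resolved by capillary electrophoresis with
   a LIZ500 ladder. The pipeline calibrates scan→bp from the ladder,
   detects and matches peaks, sum-normalizes heights, forms the
   differential D_i = n_i(with) − n_i(without) (protection < 0,
   hypersensitivity > 0), and calls protected/hypersensitive regions in
   zero-free TSS-relative promoter coordinates.

`pulchkit.synthio` generates all inputs with known truth — logistic
growth, Gompertz production, two-component log-normal fluorescence
mixtures, and peak-train electropherograms with a co-run ladder and a
multiplicative footprint — so every pipeline is validated by parameter
recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale
(`python analysis/01_simulate.py` first, then any of the others).
`02_production_kinetics.py` prints the per-strain kinetic summary:

```
    strain  start(h)  dur(h)  rate(1/h)  maxA410
    triple     -9.67    28.4     0.0279    0.800
 pchR_scoC     -6.67    18.5     0.0348    0.651
 scoC_abrB     -6.43    13.2     0.0598    0.800
 pchR_abrB     -5.53    25.4     0.0251    0.649
      pchR     -4.63    23.2     0.0216    0.508
      scoC     -3.77    14.3     0.0203    0.299
      abrB     -3.23    12.2     0.0198    0.251
        WT      ref.    16.8     0.0053    0.099
```

Start times are hours relative to T0 (negative = during exponential
growth); the triple *scoC abrB pchR* mutant begins producing earliest,
well before the transition, and WT plateaus at A410 ≈ 0.10.
`03_reporter_gating.py` recovers the generator's GFP-positive fractions
(WT 69.8 ± 0.5 %), and `04_footprinting.py` recovers the protected
windows exactly:

```
PchR: protected region(s) +6..+28 (253 matched peaks)
AbrB: protected region(s) -30..+60 (253 matched peaks)
ScoC: protected region(s) -10..+60 (253 matched peaks)
```

The same stages are available as a CLI (`pulchkit synth|growth|flow|
footprint|all --config cfg.yaml --seed 1 --outdir results/pipeline`),
driven by a YAML config; every output table carries provenance comment
lines (package version, config hash, master seed) and reruns are
byte-identical for a fixed config.

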