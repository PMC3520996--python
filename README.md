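# abaclim

Projecting the future distribution and abundance of two harvested
abalone species — blacklip (*Haliotis rubra*) and greenlip
(*H. laevigata*) — on a temperate coastline under contrasting
greenhouse-gas emissions scenarios.

`abaclim` is aimed at quantitative fisheries and climate-change
ecologists. It chains the pieces such a projection needs into one
tested pipeline:

1. **Climate-model skill ranking.** Candidate models are validated
   against an observed sea-surface-temperature (SST) baseline with four
   statistics — bias, pattern correlation, RMSE and centred RMSE
   (RMSE² = bias² + centred-RMSE²) — combined by *cumulative rank*
   (the sum of per-statistic ranks, smaller is better), screened by a
   leave-one-out outlier analysis, and the top *k* = 5 models averaged,
   unweighted, into the ensemble anomaly.
2. **Change-factor downscaling.** The coarse (2.5°) ensemble anomaly
   ΔT is bilinearly refined to 0.5° and added directly onto a fine
   (0.01°) baseline climatology: T₂₁₀₀(x) = T_base(x) + ΔT(parent of x).
   The baseline itself is built by thin-plate-spline smoothing with the
   smoothing parameter chosen by generalized cross-validation,
   GCV(λ) = n·RSS(λ)/(n − tr H(λ))².
3. **Ensemble species distribution models.** Abundance (counts per
   100 m²) is modelled with a negative-binomial GLM — log μ linear in
   August (winter) SST for blacklip, quadratic for greenlip — plus a
   boosted-regression-tree model; the two are combined with
   validation-deviance weights w_i ∝ exp(−Δ_i/2) and projected at
   decadal slices 2010–2100 under a high-emissions Reference (WRE750)
   and a mitigation Policy (LEV1) scenario, all non-climate covariates
   held at their fitting values.
4. **Fishery products.** Potential fishing grounds (cells ≥ 20
   individuals/100 m²), four-way change maps
   (retained/gained/lost/never), percent change in harvestable
   abundance, and a March (late-summer) SST overlay in <17 / 17–20 /
   ≥20 °C categories that flags projected expansion unlikely to
   survive summer thermal stress.
5. **Juvenile-mortality statistics.** One-way ANOVA on replicate-tank
   mortality at 17 °C vs 20 °C, its exact reconstruction from printed
   group summaries (mean, SE, n), and the mortality fold change.

A synthetic-data module generates every input — baseline
climatologies, per-model anomaly fields, abundance surveys with a known
ground-truth response, mortality replicates — so the whole chain runs
and is testable without any satellite, climate-model or survey
download.

## Worked example

Scripts under `examples/` each exercise one capability. The mortality
and overlay example:

```bash
$ python examples/04_mortality_and_overlay.py
ANOVA reconstructed from summaries: F(1,6) = 36.22, p = 0.0009
fold change at 20 °C vs 17 °C: 18.75
simulated replicate experiment: F = 112.50, p = 0.0000
March SST categories, present: <17 °C 13%, 17–20 °C 67%, ≥20 °C 20%
March SST categories, +1.1 °C: <17 °C 3%, 17–20 °C 45%, ≥20 °C 51%
```

The first two lines rebuild the temperature experiment's test from its
reported group summaries (3.1 ± 3.1 % mortality at 17 °C vs
58.12 ± 8.6 % at 20 °C, four tanks per group): warm-category summer
temperature raises juvenile mortality ~19-fold, F(1,6) ≈ 36. The last
two lines show why that matters spatially: a Reference-scale +1.1 °C
warming moves half the study area into the ≥20 °C March category that
the experiment identifies as lethal territory.

The abundance side (`examples/03_abundance_projection.py`) fits the
greenlip ensemble (fitted thermal optimum 16.90 °C against a 17.0 °C
truth), and under +1.1 °C of winter warming reports 2165 gained vs 76
lost ground cells and a +92.6 % change in harvestable abundance — the
winter-warming benefit that the March overlay then qualifies.

The full pipeline is also scriptable from a shell:

```bash
abaclim all --outdir out --seed 1          # or stage by stage:
abaclim synth ... ; abaclim gcm-rank ... ; abaclim downscale ...
```

Every stage writes its artifacts plus a `manifest.json` with content
hashes and the seeds used; a rerun with the same configuration is
bit-identical.

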