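# synergyscreen

Analysis pipeline for drug-combination synergy and expression-signature
survival association:

- **dose_response** — normalize raw plate signals to viability fractions of
  untreated controls and fit the two-parameter median-effect model
  (`fa/fu = (D/Dm)^m`) per agent by least squares on the log-log
  median-effect plot, yielding `Dm` (the IC50) and slope `m`.
- **synergy** — combination index for constant-ratio mixtures using the
  mutually nonexclusive isobologram form
  `CI = (D)1/(Dx)1 + (D)2/(Dx)2 + (D)1(D)2/[(Dx)1(Dx)2]`, with
  synergism/additive/antagonism classification (CI < 1 / = 1 / > 1).
- **signature_screen** — per-gene Pearson correlation against log10 IC50
  with t-transform p-values and Benjamini-Hochberg FDR; selection by strict
  p or q threshold.
- **pca_survival** — unit-norm PC1 signature loadings on standardized
  expression, per-sample scoring with drop-and-renormalize handling of
  missing genes, median-score dichotomization, Kaplan-Meier curves and the
  two-group log-rank test.
- **ihc_scoring** — product expression score (intensity × cellularity,
  grades 0–3), percentage-to-grade banding, and prevalence summaries.
  Bundled fixtures: a 79-sample primary-tumor score table, a 41-line
  cell-line grade table, and a 47-symbol response-signature gene list.
- **synthetic_data** — seeded generators for median-effect viability data
  with known `(Dm, m)`, constant-ratio mixtures with a prescribed true CI
  at the 50% effect level, expression matrices with genes planted at a
  target correlation to log10 IC50, and exponential survival with a
  group-dependent hazard ratio.

## Command-line usage

All stages exchange flat TSV files, so each is independently runnable:

```bash
# generate a synthetic scenario with ground truth
synergyscreen simulate --scenario scenario.yaml --out sim/

# fit median-effect curves and compute combination indices
synergyscreen fit --plates sim/viability.tsv --out fits.tsv
synergyscreen ci --fits fits.tsv --design sim/design.tsv --fa 0.5 --out ci.tsv

# correlation screen, signature scoring, survival association
synergyscreen screen --expr sim/expression.tsv --pheno sim/phenotype.tsv \
    --p 0.001 --out screen/
synergyscreen score --expr sim/expression.tsv \
    --genes screen/selected_genes.txt --out scores.tsv
synergyscreen survive --scores scores.tsv --surv sim/survival.tsv --out surv/

# or the whole pipeline from one config
synergyscreen run-all --config run.yaml
```

Every command writes a `manifest.json` (parameters, config hash, library
versions) next to its outputs; identical inputs and config produce
byte-identical outputs.

An example scenario YAML:

```yaml
seed: 13
dose_response:
  drugs:
    drugA: {Dm: 1.0, m: 1.2}
    drugB: {Dm: 4.0, m: 1.2}
  combinations:
    mix: {drug_a: drugA, drug_b: drugB, fraction_a: 0.5, m: 1.2, target_ci: 0.5}
expression:
  n_samples: 40
  target_r: 0.95
survival:
  hazard_ratio: 2.5
  censoring_rate: 0.2
```

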