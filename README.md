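# subtyperx

Subtype-stratified drug-specificity screening and downstream analyses for
cell-line panels, exercisable end-to-end on synthetic data with planted
ground truth.

The package implements, as reusable tested components:

- **drug_screen** — per-drug one-way ANOVA over subtype groups of IC50
  z-scores, Tukey HSD post-hoc (Tukey-Kramer for unbalanced groups), and a
  symmetric subtype-specificity rule (a drug is `<S>_specific` when subtype
  S has the strictly lowest mean and is significant against every other
  subtype).
- **geneset_scoring** — per-gene z-standardization, sum-of-z gene-set
  scores, raw-sum scores (including the fixed CLDN3/CLDN4/CLDN7/CDH1
  claudin score), and an expressed-gene filter.
- **sensitivity_assoc** — Pearson correlation with OLS line,
  mutation-stratified regression with an intercept-offset readout at the
  pooled mean, median/quantile dichotomization, and two-group log-rank
  survival comparison with Kaplan-Meier curves.
- **combination** — Chou-Talalay median-effect fitting
  (`log(fa/(1-fa)) = m log D - m log Dm`), effect-dose inversion, and
  combination-index surfaces (`CI = D1/Dx1 + D2/Dx2`) with
  synergy/additive/antagonism calls.
- **quantify** — blot activated-signal and phospho-ratio arithmetic,
  colony-assay percent-of-control summaries, and caliper tumor volume
  (`0.5 * length * width^2`).
- **synthetic_data** — seeded generators for drug-response matrices,
  expression matrices, dose-response grids (sham / Loewe-additive /
  synergy-factor constructions) and survival records, each with a
  machine-readable truth table.
- **io_formats** — TSV/CSV matrix readers and writers, GMT gene sets,
  sample annotations, and the shared domain types.

## CLI

All commands write their tables plus a `manifest.json` (inputs, parameters,
seed, version) under `--out-dir`.

```sh
# synthetic screen with one planted Basal-specific drug
cat > sim.yaml <<EOF
n_lines_per_subtype: {Basal: 20, HER2: 20, Luminal: 20}
n_drugs: 100
noise_sd: 0.5
planted:
  - {drug_id: drug_0000, subtype: Basal, shift: -1.0}
EOF
subtyperx simulate --kind drug --config sim.yaml --seed 7 --out-dir sim/
subtyperx screen --response sim/response.tsv --annotations sim/annotations.tsv \
    --alpha 0.05 --min-n 3 --out-dir screen/

# gene-set scores and per-subtype comparison
subtyperx score --expr expr.tsv --sets sets.gmt --kind z_sum --ann ann.tsv \
    --out-dir scores/

# score-vs-response association, optionally stratified by mutation status
subtyperx associate --scores scores/scores.tsv --response resp.tsv \
    --drug drug_0000 --strata ann.tsv --gene PIK3CA --out-dir assoc/

# survival split by a score (median by default)
subtyperx associate --scores scores/scores.tsv --survival ann.tsv \
    --rule median --out-dir surv/

# Chou-Talalay synergy on a checkerboard viability grid
subtyperx synergy --grid combo.tsv --out-dir synergy/

# quantification arithmetic
subtyperx quantify --kind tumor --in calipers.tsv --out-dir quant/
```

Editable GMT fixtures for the 22-gene YAP/TAZ-style target signature and the
claudin quartet ship under `src/subtyperx/data/`; gene-set content is
configuration, not a constant.

## File formats

- Expression matrix: TSV/CSV, first column gene symbols, header row sample
  ids; missing tokens `""`/`NA`/`NaN`/`null`.
- Drug response: wide (lines x drugs) or long (`line`, `drug`, `z`) layout,
  auto-detected from the header.
- Annotations: `sample_id`, `subtype`, optional `ihc_group`,
  `survival_time`/`survival_event`, and `mut_<GENE>` columns
  (`wild_type`/`mutant`/`unknown`).
- Gene sets: standard GMT.
- Synergy grids: `agent1_dose`, `agent2_dose`, `percent_of_control`, with
  zero-dose rows as single-agent margins/controls.
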