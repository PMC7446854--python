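# mbpredict — predictive analysis of zero-inflated microbiome count data

Microbiome studies ask whether a phenotype (disease status, a host
trait) can be predicted from an OTU count table — an n × m matrix of
16S read counts that is compositional, overdispersed and full of
zeros.  `mbpredict` implements, as a tested pipeline, three strategies
for this problem and the machinery to benchmark them:

1. **LASSO** — L1-penalized multinomial logistic regression on all
   transformed OTUs plus host covariates,

       P(y=k|x) = exp(βₖᵀx) / Σₗ exp(βₗᵀx),
       min −Σᵢ log P(yᵢ|xᵢ) + λ Σₖ ‖βₖ‖₁   (intercepts unpenalized),

   with λ chosen by cross-validated error rate over a 200-point grid;
2. **screening + GLM** — a per-OTU likelihood-ratio screen based on
   count GLMMs, followed by an unpenalized multinomial logistic fit on
   the selected OTUs;
3. **screening + LASSO** — the same screen followed by a LASSO fit on
   the selected subset.

The screen models each OTU's counts conditional on covariates and a
random intercept, with the log total reads as offset:

    f_NB(z; μ, θ) = Γ(z+θ)/(Γ(θ)Γ(z+1)) · (θ/(θ+μ))^θ (μ/(θ+μ))^z,
    log μᵢ = log Tᵢ + Xᵢβ + Wᵢb,   b ~ N(0, σ²_b),

as a plain NB, a zero-inflated NB (mixture with a point mass at zero,
probability φᵢ), or a two-part NB dispatched on the observed zero
proportion (NB ≤ 10% < hurdle ≤ 80% < logistic < 90% ≤ dropped).
Random intercepts are integrated out by a Laplace approximation with
exact analytic gradients; the phenotype effect is tested by LRT
(χ² with K−1 or 2(K−1) degrees of freedom, depending on how many model
components the phenotype enters), and p-values are converted to
Benjamini–Hochberg q-values with selection at q ≤ 0.05.

A Dirichlet-multinomial generator produces synthetic studies with
known signal taxa (20 of 587, effects ±Unif(1.5, 2) on the logit of a
Bernoulli phenotype, plus continuous, categorical and 5-group random
covariates), calibrated so that the majority class is 60% prevalent
(baseline error 0.4) and an oracle given the true taxa reaches test
error ≈ 0.04.  Evaluation is leakage-safe throughout: simulations use
stratified 80/20 splits with train-only screening and λ selection;
user data run under external cross-validation in which the whole
strategy is re-fit inside every training fold.

## Worked example

Generate a calibrated synthetic study, screen it, and run the
prediction strategies:

```bash
python analysis/01_calibrate_generator.py --seed 1
python analysis/02_screening_power.py --reps 10 --seed 1 --datasets 1
python analysis/03_prediction_dataset1.py --reps 10 --seed 1
```

The calibration prints the two fitted knobs (all stated effect sizes
are held fixed):

```
dataset 1: intercept offset -45.000, signal multiplier 40.29
```

The screening driver reports, per replicate and count model, how many
of the 20 true signal taxa pass q ≤ 0.05 and the power over the
testable (non-dropped) signals, e.g.

```
dataset 1 rep 0 tpnb: 12/20 true signals, power(testable) 0.67  [15s]
```

and the summary table (means over replicates) lands in
`results/screening_power_summary.tsv`.  The prediction driver writes
`results/prediction_dataset1_summary.tsv` with mean (SD) test-set
error rate, AUC and AUPRC per method × transform; at this operating
point the oracle sits near ER 0.03, the naive baseline at 0.41, the
arcsine-sqrt transform clearly beats presence/absence for every
strategy, and excluding the random factor from the predictors worsens
every method.

For a user-supplied study (counts TSV: samples × OTUs with a
`sample_id` column; metadata TSV with phenotype and covariates), the
same strategies run from the command line with external
cross-validation and declared factor types:

```bash
mbpredict screen  --counts counts.tsv --metadata meta.tsv \
    --phenotype disease --fixed age:continuous --fixed sex:categorical \
    --model tpnb --out screening.tsv
mbpredict predict --counts counts.tsv --metadata meta.tsv \
    --phenotype disease --fixed age:continuous --fixed sex:categorical \
    --strategy screen_lasso --transform binary --cv loo --out pred/
```

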