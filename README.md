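# reopair

Rank-based lncRNA-pair prognostic risk modelling for hepatocellular
carcinoma (HCC).

## The problem

Absolute expression values from bulk RNA-seq are hard to transfer between
cohorts and platforms: normalisation, batch effects and library chemistry
all shift them. The *relative expression ordering* (REO) of two transcripts
within one sample — "is lncRNA *a* expressed below lncRNA *b* in this
patient?" — is a qualitative, within-sample feature that is invariant to
any monotone normalisation, which makes pair-based signatures attractive
for clinical risk prediction.

`reopair` implements a complete pipeline that builds such a signature from
an expression table and clinical follow-up:

1. **Preprocessing** — drop samples with under 30 days or missing
   follow-up; TPM normalisation of counts; biotype-specific detection
   floors (count < 1 for mRNAs, < 0.5 for lncRNAs, in *all* samples);
   miRNA zero-fraction filtering with RPM normalisation; seeded
   train/validation split with a covariate-balance report.
2. **Subtype nomination** — Ward-linkage clustering of samples on a
   pyroptosis gene panel (z-scored log2(TPM+1)), log-rank comparison of the
   clusters, and limma-style moderated-*t* differential expression to
   nominate pyroptosis-related lncRNAs (|log2FC| > 1, BH FDR < 5%).
3. **Pair screen** — all C(k, 2) lncRNA pairs; the binary REO matrix
   X_ij = 1 iff expr(a_i) < expr(b_i) in sample j; removal of pairs whose
   "1" state occurs in < 20% or > 80% of samples; univariate Cox regression
   of overall survival on each remaining pair state (Breslow ties, Wald
   p < 0.005).
4. **Signature selection** — L1-penalised Cox over the screened pairs with
   the penalty chosen by ten-fold cross-validated partial-likelihood
   deviance, then a bidirectional stepwise search minimising
   AIC = −2·logPL + 2·|terms|, refit unpenalised. The risk score of sample
   j is the linear predictor Σᵢ βᵢ·X_ij.
5. **Thresholding and evaluation** — the cutoff maximising Youden's
   J = sensitivity + specificity − 1 on the time-dependent
   (cumulative-case / dynamic-control) ROC at a fixed horizon;
   Kaplan–Meier/log-rank comparison of the high/low groups; AUCs at fixed
   horizons; multivariable Cox adjustment for age, gender, stage and grade.
6. **Downstream** — exact hypergeometric overlap tests and assembly of
   prognostic lncRNA–miRNA–mRNA (ceRNA) axes from user-supplied
   interaction edge tables.

A published 11-pair HCC signature (22 lncRNAs, risk threshold 0.025 on the
five-year training ROC) ships with the package, and a synthetic-cohort
generator (`reopair.synthetic`) plants known subtypes, differential
lncRNAs and prognostic pair states under an exponential
proportional-hazards model, so every stage is recovery-testable without
any data download.

## Worked example

```python
import pandas as pd
import reopair as rp

model = rp.published_model()          # 11 pairs, 22 lncRNAs, threshold 0.025

# three synthetic samples: every pair state 1, every state 0, and mixed
ids = [g for a, b, _ in model.terms for g in (a, b)]
expr = rp.ExpressionMatrix(
    pd.DataFrame({"all_one":  [1.0, 2.0] * 11,
                  "all_zero": [2.0, 1.0] * 11,
                  "mixed":    [1.0, 2.0, 2.0, 1.0] * 5 + [1.0, 2.0]},
                 index=ids),
    pd.Series("lncRNA", index=ids), scale="log2p1")

scores = rp.compute_risk_scores(model, expr)
print(scores)
print(rp.classify(scores, model.threshold)["group"].to_dict())
print(rp.hypergeometric_overlap(240, 105, 35, 25))
```

prints

```
all_one     2.1542
all_zero    0.0000
mixed       0.9575
Name: risk_score, dtype: float64
{'all_one': 'high', 'all_zero': 'low', 'mixed': 'high'}
overlap 25 of |A|=105, |B|=35 in N=240: P(X >= 25) = 0.000346
```

`2.1542` is the sum of the eleven published coefficients — the score of a
patient in whom every signature pair sits in its risk orientation — and
`0` is its opposite; the mixed sample lands in between and is called high
risk because its score reaches the 0.025 cutoff. The last line is the
upper-tail hypergeometric probability that the 35-sample poor-prognosis
expression cluster and the 105-sample high-risk group of a 240-sample
training cohort share 25 members by chance.

A command-line front end covers the file-based stages:

```bash
reopair simulate --config sim.json --seed 1 --out cohort/
reopair score --expr cohort/expression.tsv --out scores.tsv   # published model
reopair classify --scores scores.tsv --threshold 0.025 --out groups.tsv
```

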