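# deqscreen

A pipeline for a question that comes up in longitudinal dementia cohorts:
**do circulating serum proteins mediate the APOE ε4 allele's prospective
effect on dementia severity?**

The severity phenotype is the latent variable δ ("delta"), defined as *the
cognitive correlates of functional status* — the variance shared between
cognitive test performance and everyday function. Its study-specific homolog
here is called **dEQ**. The package builds dEQ and its orthogonal residual
**g′** (general cognitive variance unrelated to function) from Wave-2
indicators, cleans a wide multiplex serum-protein panel, and screens every
analyte as a potential mediator of the APOE ε4 → dEQ association, with
split-half constrained replication. Everything runs on synthetic cohorts
with known ground truth, so each stage is testable end to end.

## The model

**Measurement.** A bifactor model over five Wave-2 indicators — Logical
Memory II (LMII), Visual Reproduction I (VRI), COWA verbal fluency, Digit
Span (DST) and IADL (everyday function):

```
y_i = λδ_i · dEQ + λg_i · g′ + ε_i          (λg_IADL ≡ 0,  dEQ ⊥ g′)
```

Both factors have unit variance; estimation is maximum likelihood on the
covariance structure, switching to full-information ML (FIML) over
missing-data patterns when indicator cells are missing. Regression-method
factor weights `W = Σ⁻¹ Λ Φ` turn the fit into per-subject composite scores
(dEQ_w2, g′_w2), validated by ROC AUC for AD vs NC and by correlation with
CDR sum of boxes. Factor determinacy (Grice) ≥ 0.80 is required for
composite scoring to be meaningful.

**Mediation.** For each QC-passed Wave-1 analyte M, a simultaneous path
model with exposure APOE (ε4 carrier = 1) and seven covariates Z (age,
education, ethnicity, gender, GDS, HCY, HgbA1c), all variables standardized:

```
M      = c·APOE + Γ₁'Z + e₁           (path c)
dEQ_w2 = a·APOE + b·M + Γ₂'Z + e₂     (paths a = direct, b = analyte → dEQ)
```

The indirect effect is the product `b·c` with the Sobel/MacKinnon
delta-method z = b·c / √(b²se_c² + c²se_b²); the proportion mediated is
`b·c / (b·c + a)`, reported as a percentage when the indirect and total
effects share a sign. Analytes are classified by a dual significance gate
(default p < 0.001 on both b and c): *mediator*, *APOE-independent dEQ
biomarker* (b only), or *unrelated*. Replication constrains a, b, c equal
across a random 50/50 subject split and tests the χ² worsening on 3 df.

**Panel QC** (fixed order): duplicate reads averaged, pairs differing by
>5% of their mean discarded → analytes >50% below detection dropped, other
LOW cells set to LDD/2 → values beyond 3 SD deleted (single pass, raw
scale) → log-transform when |skewness| > 1, then z-scoring → residualization
on batch dummies.

## Worked example

```bash
deqscreen run-all --seed 42 --out demo_out
```

generates a 3,000-subject cohort (ε4 prevalence 0.39, direct path −0.25,
one true mediator "CRP" with c = −0.15, b = 0.15, ten δ-only analytes, 89
nulls), injects assay artifacts, runs QC, builds dEQ, and screens the panel.
The run log reports `qc: 100/100 analytes retained`, and the manifest for
this seed records

```
determinacy: {'dEQ': 0.870, 'gprime': 0.682}
tables: {'mediator': 1, 'apoe_independent_delta_biomarker': 10, 'unrelated': 89}
```

— the three classes recover the planted partition exactly. The CRP row of
`demo_out/results.csv` reads a = −0.224, b = 0.130, c = −0.083, Sobel
z = −3.07, proportion mediated 4.6%, replication p = 0.42. The direct path
is the planted −0.25 attenuated by composite reliability (≈ 0.86); at this
particular seed the sampled c path happens to fall ~2 SE below its planted
−0.15, which drags the proportion below its Monte-Carlo mean of ≈ 8.5%
(see `scripts/acceptance.py`, which averages over 100 cohorts). A
replication p > 0.05 means the effect survives the split-half constrained
fit. Python users can drive the same stages via `deqscreen.generate`,
`run_qc`, `build_deq`, `screen_panel`.

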