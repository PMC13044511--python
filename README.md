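# shortcutaudit

Auditing shortcut learning in clinical models of breast-cancer intrinsic
subtype.

PAM50 intrinsic subtypes (Luminal A, Luminal B, HER2-enriched, Basal-like,
Normal-like) are defined by gene expression, but routinely collected
clinical covariates — ER/PR/HER2 receptor status, AJCC stage, age — are
strongly correlated with them. A model trained on clinical covariates alone
can therefore look accurate while relying on surrogate biomarkers instead
of biology ("shortcut learning"). `shortcutaudit` quantifies that reliance
and turns it into an operational audit:

1. **Baseline model.** A multinomial (baseline-category) logistic
   regression of subtype on the five clinical covariates, fit by exact
   Newton–Raphson maximum likelihood, with the standard diagnostics
   (McFadden pseudo-R², variance inflation factors, Wald tests,
   quasi-separation detection).
2. **Perturbation attribution ("pseudo-SHAP").** For each covariate *j*
   and patient *i*, the change in predicted class probability

   ΔP<sub>ijk</sub> = P(class k | x<sub>i</sub>, x<sub>ij</sub>→hi) − P(class k | x<sub>i</sub>, x<sub>ij</sub>→lo),

   averaged over the cohort into a feature × class table of directional
   importance scores. Binary covariates contrast set-to-positive against
   set-to-negative; stage shifts one grade (clamped at III); age shifts by
   one observed standard deviation.
3. **Exact Shapley oracle.** With only five covariates, interventional
   Shapley values φ<sub>j</sub> = Σ<sub>S⊆F∖{j}</sub> |S|!(p−|S|−1)!/p! ·
   [v(S∪{j}) − v(S)] are enumerated exactly over all 2⁵ coalitions against
   an empirical background sample. Rank concordance (Spearman) between the
   cheap perturbation scores and the oracle validates the approximation.
4. **Audit layer.** Label-shift cross-tabulations (which subtype a patient
   would flip to under a perturbation), threshold alerts when any
   |mean ΔP| exceeds a cutoff (default 0.25), and drift flags when a
   feature stays above the cutoff for k consecutive batches.

Because no public clinical table ships with the package, a seeded
synthetic-cohort generator with a known softmax ground truth (TCGA-like
marginals, MAR missingness confined to HER2 and age) makes every stage —
including MICE imputation with Rubin's-rules pooling — testable end to end.

Intended users: biostatisticians and ML-safety reviewers vetting clinical
prediction models; the library doubles as a reference implementation of
perturbation attribution validated against an exact Shapley computation.

## Worked example

```python
import shortcutaudit as sa

config = sa.default_tcga_like_config(n=691, seed=42)
cohort = sa.inject_missingness(sa.generate_cohort(config), config)

completed = sa.mice(cohort, sa.MiceConfig(m=5, seed=42))
tables = []
for c in completed:
    design = sa.encode_design_matrix(c)
    model = sa.fit_multinomial_logit(design)
    tables.append(sa.mean_attributions(model, design))
attr = sa.average_attribution_tables(tables)
print(attr.mean_delta_p.round(3))

shap = sa.mean_shapley(model, design, background_size=200, background_seed=42)
print(sa.concordance(tables[-1], shap))
for a in sa.threshold_alerts(attr, 0.25):
    print(a)
```

Output (printed by the code above):

```
            LumA   LumB  Her2E  Basal  Normal
age        0.034 -0.013  0.014 -0.029  -0.006
er_pos     0.084  0.016 -0.058 -0.038  -0.004
pr_pos     0.285  0.190 -0.021 -0.448  -0.005
her2_pos  -0.345  0.121  0.418 -0.146  -0.048
stage_ord  0.006  0.004  0.010 -0.004  -0.016
Spearman r vs exact Shapley oracle: 1.000 (25 pairs)
ALERT: pr_pos -> LumA, mean dP 0.28 > 0.25
ALERT: pr_pos -> Basal, mean dP -0.45 > 0.25
ALERT: her2_pos -> LumA, mean dP -0.35 > 0.25
ALERT: her2_pos -> Her2E, mean dP 0.42 > 0.25
```

Reading it: each row of the table sums to zero (probability mass is only
moved between subtypes). Toggling PR to positive moves, on average, 45
points of probability out of Basal-like and into the luminal classes;
toggling HER2 adds 42 points to HER2-enriched. ER, age and stage barely
move any class. The model is leaning on exactly two surrogate biomarkers —
the shortcut signature the audit is designed to flag — and the alert list
says so against the 0.25 quality-assurance cutoff. The Spearman r against
the exact Shapley oracle confirms the first-order perturbation scores rank
the feature–class effects the same way the coalition-exact computation
does.

The same pipeline is scriptable from a shell:

```sh
shortcut-audit pipeline --seed 42 --out-dir runs/demo   # exit code 2 = alerts fired
```

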