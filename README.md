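# crcsig

Integrative gene-expression signature analysis for colorectal cancer (CRC)
cohorts: single-sample signature scoring, consensus-molecular-subtype (CMS)
classification by nearest-template prediction, and the downstream
correlation, group-comparison and survival analyses — plus a synthetic
cohort generator so the whole pipeline can be exercised and validated
without any external data download.

## Who it is for

Computational oncologists working with bulk CRC expression cohorts
(Affymetrix-style probe-level arrays with a probe→gene map, or gene-level
RSEM RNA-seq matrices) who want reproducible signature scores — MEK-pathway
activation, MEK-inhibitor "bypass" resistance, SRC activation, dasatinib
sensitivity (Dasa-S), EMT, stemness signatures and the like — alongside CMS
calls and survival stratification.

## The model in brief

**Scoring.** For a signature *G* on expression matrix *X* (features ×
samples), the raw component score of sample *j* is the arithmetic mean over
*all* features mapping to *G* (probes pooled directly, not collapsed per
gene first). Signatures with up- and down-regulated components are scored
UP − DOWN; presence/absence signatures support the full composite
(UP + (+inf)) − (DOWN + (−inf)). Cohort scores are standardized as
(s − median(s)) / IQR(s) with IQR = Q3 − Q1 (interpolated quantiles), so
every column has median 0 and IQR 1. Cell-line panels can first be
ratio-normalized per probe by the probe's mean over all samples.

**CMS classification.** Each sample's cohort-standardized marker-gene
vector is compared against the four class templates (CMS1 MSI/immune,
CMS2 canonical, CMS3 metabolic, CMS4 mesenchymal):
dCMSk = (1 − cos(x, t_k))/2 ∈ [0, 1]. The nearest class gets a
permutation p-value (template gene labels shuffled within sample, add-one
smoothing), Benjamini–Hochberg FDR across samples, and label NA when
FDR > 0.05. Propensity scores are the affine transform CMSk\* = 1 − dCMSk.

**Statistics.** Pairwise-complete Spearman/Pearson correlation matrices,
Mann–Whitney (exact below n₁+n₂ ≤ 20, tie-corrected normal approximation
above), Welch's t, a Cochran–Armitage chi-square trend test with an exact
conditional branch, median-split quadrant summaries, a clinical summary
cross-tabulation with per-column denominators, Kaplan–Meier curves with
Greenwood variance and k-sample log-rank tests (quartile- and
CMS-stratified overall survival).

## Worked example

```python
from crcsig import RunConfig, SyntheticCohortConfig, run_pipeline

cfg = RunConfig(
    synthetic=SyntheticCohortConfig(n_samples=400, seed=1),
    n_perm=1000, seed=1, out_dir="demo_run",
)
arts = run_pipeline(cfg)
print(arts["cms"].labels.value_counts().to_dict())
print(round(float(arts["correlation"].rho.loc["MEKIBP", "SRC"]), 3))
print(round(float(arts["correlation"].rho.loc["MEK18", "MEKIBP"]), 3))
print([round(v, 4) for v in arts["quartile_survival"]["logrank"]])
```

prints

```
{'CMS2': 127, 'CMS4': 119, 'CMS3': 70, 'CMS1': 62, 'NA': 22}
0.886
0.022
[60.0654, 0.0]
```

i.e. the 400 synthetic tumors split across the four subtypes with 22
unclassifiable samples; the MEKi-bypass and SRC-activation scores are
strongly correlated (Spearman ρ = 0.886, close to the planted latent
correlation 0.9 after attenuation by gene-level noise) while the 18-gene
MEK-activation score is uncorrelated with bypass resistance (ρ = 0.022);
and overall survival differs sharply across SRC-score quartiles (log-rank
χ² = 60.1, p ≈ 6·10⁻¹³, reflecting the planted hazard gradient).
`demo_run/` contains the score table, CMS table, correlation heatmap,
quadrant tables, summary cross-tabulation, KM outputs and a
parameter-recovery report, all with provenance headers.

The same pipeline runs on real files from the shell:

```bash
crcsig simulate --seed 5 --n-samples 400 --out cohort/
crcsig run-all --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
    --gmt cohort/signatures.gmt --template cohort/template.tsv \
    --seed 5 --out run/
```

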