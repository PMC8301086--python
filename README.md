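# metanmr

Analysis pipeline for 1D ¹H-NMR metabolomics of tissue extracts:
spectral preprocessing, OSC-PLSDA multivariate discrimination, univariate
fold-change/significance tables, and differential Pearson-correlation
networks with structural-similarity grouping. The package is organised
around the multi-group designs common in pharmacological studies — here, a
five-group rat ischemic-stroke design (sham, MCAO model, and three
treatment doses TL/TM/TH) profiling 38 brain-extract metabolites — but
every stage accepts arbitrary groups, metabolites and comparisons.

A synthetic-data generator with exact ground truth (injected log₂ effect
sizes, within-group correlation blocks, Lorentzian peak rendering) makes
every stage verifiable without any instrument data.

## What it computes

**Preprocessing** (ASCII spectra → feature matrix): each spectrum is
referenced so the TSP standard sits at δ 0.00 ppm, integrated into
fixed-width chemical-shift bins (default 0.04 ppm, water region
4.70–4.90 ppm excluded), normalized per sample (total-area to 100, or PQN),
and collapsed onto named metabolites via a table of assignment windows.

**OSC-PLSDA**: for a two-class contrast with centred indicator *y*, Wold-type
orthogonal signal correction removes rank-one components *t pᵀ* whose scores
are orthogonalized against *y* (|corr(*t*, *y*)| < 10⁻⁸ by construction);
NIPALS PLS1 on the filtered, autoscaled matrix then yields scores *T*,
loadings *P*, weights *W*, with R²X per component, cumulative R²Y, and Q²
from stratified 7-fold cross-validation (scaling and OSC refitted inside
every fold). S-plots report per-feature p(cov) = cov(*t₁*, *x*ⱼ) and
p(corr) = corr(*t₁*, *x*ⱼ); coefficient loading plots color features by
|p(corr)|.

**Statistics**: per metabolite and comparison, log₂(FC) of arithmetic group
means; Welch t-test if both groups pass Shapiro–Wilk normality (α = 0.05),
Mann–Whitney U otherwise; Benjamini–Hochberg adjustment across metabolites
within each comparison; stars at p\_adj < 0.05 / 0.01 / 0.001.

**Networks**: per-group Pearson matrices with t-distribution p-values;
differential edges either where |r_A − r_B| > 0.65 with a significant
Fisher-z two-correlation test (mode `delta_r`) or where |r_A| > 0.65 with
correlation p < 0.05 (mode `per_pair_r`); node colors from the stats table;
structural groups by single-linkage over Tanimoto fingerprint similarity
strictly above 0.7; curated biochemical-reaction pairs overlaid as directed
edges. Exported as GraphML and TSV.

## Worked example

```python
import metanmr as mn

# synthetic five-group cohort, n=10/group, effects patterned on the study design
mn.simulate_cohort("demo", n_per_group=10, noise_cv=0.1, seed=42, points=8192)

cfg = mn.RunConfig(
    spectra_dir="demo/spectra",
    design_csv="demo/design.csv",
    output_dir="demo/results",
    comparisons=[("model", "sham"), ("TH", "model")],
    seed=42,
)
arts = mn.run_pipeline(cfg)
st = arts["stats"]
print(st[st.metabolite.isin(["Lactate", "ATP", "Formate"])].to_string(index=False))
```

which prints:

```
read 50 spectra from demo/spectra
integrated 38 metabolites over 220 bins
model model_vs_sham: R2Y=0.990 Q2=0.910 n_osc=1
network model_vs_sham: 35 differential edges (mode=delta_r)
model TH_vs_model: R2Y=0.995 Q2=0.956 n_osc=1
network TH_vs_model: 34 differential edges (mode=delta_r)

metabolite    comparison    log2fc test_used        p_raw        p_adj stars
   Lactate model_vs_sham  0.148496         t 1.167247e-02 2.425697e-02     *
       ATP model_vs_sham -0.145534         t 2.675480e-02 4.621284e-02     *
   Formate model_vs_sham  0.332683         t 6.928226e-05 2.925251e-04   ***
   Lactate   TH_vs_model -0.203115         t 1.616186e-03 5.781227e-03    **
       ATP   TH_vs_model  1.176020         t 1.046068e-09 3.975057e-08   ***
   Formate   TH_vs_model  0.565160         t 4.047038e-09 7.689372e-08   ***
```

Read: after the modelled insult, lactate rises and ATP falls versus sham;
the high-dose treatment reverses both (ATP log₂FC ≈ +1.18 vs model), and
both OSC-PLSDA contrasts separate cleanly (Q² ≈ 0.91–0.96). The estimates
track the injected ground-truth effects to within sampling noise at
n = 10/group.

The same pipeline runs from the shell:

```bash
metanmr simulate --out-dir demo --n-per-group 10 --seed 42
metanmr run-all --spectra-dir demo/spectra --design-csv demo/design.csv \
    --output-dir demo/results --seed 42
```

Real cohorts plug in the same way: a directory of two-column ASCII spectra
(ppm, intensity), a sample→group design CSV, and optionally custom
assignment-window / fingerprint / reaction CSVs replacing the packaged
38-metabolite tables.

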