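# Methods

This note documents the models, algorithms and design choices behind
`metanmr`, the assumptions they carry, and what the synthetic-data tests do
and do not demonstrate about real spectra.

## Synthetic cohorts

`synth.simulate_concentrations` draws samples-by-metabolite concentration
matrices for a multi-group design. Group *g*, metabolite *m* is

  c = baseline(m) · 2^effect(m, g) · exp(σ z − σ²/2),  σ² = ln(1 + CV²),

with *z* standard normal. Concentrations are positive and right-skewed, so
the noise is multiplicative log-normal; the −σ²/2 offset makes the
*arithmetic* group mean equal baseline · 2^effect exactly, so fold changes
estimated from arithmetic means recover the injected log₂ effects without
the usual log-normal bias. Within-group correlation blocks are injected via
a Gaussian copula: the latent *z* vectors are multiplied by the Cholesky
factor of an equicorrelation matrix, which delivers the target pairwise r
exactly in the latent space (and very nearly on the concentration scale at
the CV values used here, ≤ 0.3).

Defaults emulate the five-group rat stroke design the packaged effect table
is patterned on: groups sham / model / TH / TM / TL, 38 brain-extract
metabolites, a literature-patterned table of per-contrast log₂ fold
changes chained into sham-relative group effects, n = 10 per group (the
order of typical in-vivo cohorts — a declared default, configurable), and
noise CV 0.1.

`synth.render_spectra` renders each sample as a sum of concentration-scaled
area-normalized Lorentzian peaks (CPMG spectra are near-Lorentzian), plus a
reference peak at δ 0.00 and optional additive Gaussian baseline noise.
The packaged peak templates give each metabolite one or two singlet-like
peaks of HWHM 0.003 ppm (≈ 1.5 Hz at 500 MHz) at literature-inspired
chemical shifts, nudged where necessary so that single ±0.04 ppm assignment
windows never overlap. Default window −2…10 ppm at 32,768 points (12 ppm
sweep, 32K points, the common acquisition geometry); tests and fixtures use
4,096–16,384 points, which sample the narrowest peaks adequately and keep
runs fast.

*What this does not emulate:* J-coupling multiplets, peak-position jitter
with pH/ionic strength, baseline roll, water/solvent artifacts, or
cross-metabolite peak overlap beyond Lorentzian tail leakage. Passing tests
demonstrate the correctness of the computational chain against known ground
truth, not robustness to those instrumental effects.

## Preprocessing

- **Referencing**: the ppm axis is rigidly shifted so the apex of the
  tallest peak in a search window (default ±0.2 ppm) lands on 0.00; a
  window with no local maximum above a minimum prominence raises a
  referencing error for that sample. Apex localization is grid-resolution
  limited (no sub-grid interpolation); at 32K points over 12 ppm the grid
  step is 0.4 mHz-equivalent (≈ 0.0004 ppm), well below bin width.
- **Binning**: half-open [hi, lo) bins of default width 0.04 ppm walk down
  the axis over a default 9.5–0.5 ppm range; each bin integrates intensity
  trapezoidally with linear interpolation at the bin edges, so the sum of
  bins equals the integral over the binned range to machine precision
  (verified at 1e-6 relative). Bins whose midpoint falls in an exclusion
  interval (default 4.70–4.90 ppm, residual water) are dropped. Bin labels
  are midpoints rounded to three decimals. The bin width and exclusions are
  field-standard defaults, configurable; negative intensities are kept
  as-is (baseline correction is treated as upstream vendor processing).
- **Normalization**: total-area scaling to a target constant (default 100)
  or probabilistic quotient normalization (total-area first, then division
  by the median quotient against the median reference spectrum). PQN is
  preferred when single metabolites dominate total area; total-area is the
  default for continuity with common practice.
- **Integration**: metabolite values are sums of the bins whose midpoints
  fall inside the metabolite's assignment windows; metabolites capturing no
  bins are excluded with a warning. On rendered synthetic cohorts the
  integrated values track true concentrations at r² ≈ 0.9997 per sample.

## OSC-PLSDA

Scaling is mean-centering plus unit-variance by default (Pareto and
center-only offered). The OSC step follows the Wold construction: start
from the dominant principal-component score, orthogonalize it against the
centred class indicator y, compute a normalized weight from the
orthogonalized score, iterate to convergence, orthogonalize once more, and
deflate X by the resulting rank-one component. The final orthogonalization
makes |corr(t, y)| zero to machine precision by construction, and the
removed-variance fraction is recorded per component. If nothing orthogonal
to y remains (e.g. every column is a multiple of y), remaining components
are skipped rather than fabricated. Default one OSC component.

PLS is NIPALS PLS1 against the centred 0/1 indicator with p-deflation;
scores are mutually orthogonal, R²X contributions plus the residual
fraction sum to one (asserted at 1e-8), and with no OSC and one component
the weight vector reduces to the class-mean difference of the scaled data
(the classical PLS-DA identity, verified at cosine ≥ 0.999 and against
scikit-learn's NIPALS as an independent implementation). Default two
predictive components, matching two-dimensional score plots.

Q² uses stratified k-fold CV (default 7 folds, fold assignment from the
run seed). Because OSC uses y, the filter — and the scaling — are refitted
inside every training fold and applied to the held-out fold, so Q² is not
inflated by class-aware preprocessing. Predicted class is the side of the
0/1 midpoint. Constant features are dropped with a warning before fitting.
Where three groups share one score plot, the model is fitted on a stated
pair and other groups are projected through the fitted scaling/OSC/PLS
(`OscPlsModel.scores_frame`); which pair defines y is configuration.

## Univariate statistics

Fold change is log₂ of the ratio of arithmetic group means, computed as a
difference of logs so that FC(A,B) = −FC(B,A) holds exactly in floating
point. The normality gate runs Shapiro–Wilk per group at α = 0.05; the
t-test is Welch's by default (pooled-variance Student offered to match
older practice). BH adjustment is the step-up procedure, applied across
metabolites within each comparison (the table is organized per comparison;
a global scope is available). Stars reflect *adjusted* p-values — the
conservative reading where the source convention is ambiguous — and raw
p-values are always retained alongside.

## Differential networks

Group correlation matrices use the sample Pearson estimator with p-values
from the t-transform at n−2 degrees of freedom (groups need ≥ 4 samples;
zero-variance metabolites propagate as NA). Two edge rules are implemented
because the field uses both phrasings, and the run log records the active
mode:

- `delta_r` (default): |r_A − r_B| > 0.65 and a two-sided Fisher-z test
  for the difference of independent correlations significant at 0.05. The
  Fisher-z test is the standard choice where no test is prescribed for
  differential coefficients. Note an intrinsic property of this rule: with
  a true r = 0.9 in one group and independence in the other at n = 20 per
  group, the sampling SD of r̂ in the independent group (≈ 0.23) makes
  |Δr̂| > 0.65 fail in roughly 14% of draws even though the Fisher-z test
  is essentially always significant — sensitivity of the rule itself, not
  of the implementation. At n = 50 the rule clears 90% sensitivity.
- `per_pair_r`: |r_A| > 0.65 with correlation p < 0.05, the per-network
  reading; at the same design this recovers an injected r = 0.9 block with
  sensitivity ≈ 1.0 and false-edge rate ≈ 0.001.

Edge sign and width follow the differential coefficient (or r_A in
per-pair mode); node colors mark metabolites significantly increased or
decreased in the paired stats table. Structural groups are single-linkage
connected components over pairwise Tanimoto similarity strictly above 0.7,
computed on packaged 166-bit structural-key fingerprints (frozen from
author-curated SMILES; supplying a custom fingerprint CSV replaces them).
Curated reaction pairs (purine chain, glycolysis/TCA neighbours, amino-acid
interconversions) overlay as directed edges, deduplicated, never altering
correlation edges.

## Numerical choices and degenerate inputs

- Orthogonality tolerances: 1e-8 on normalized inner products, asserted on
  every fit (violations raise rather than warn).
- Correlations are clipped to |r| ≤ 1 − 1e-10 before arctanh/t transforms.
- Half-open interval conventions ([hi, lo) down the ppm axis for bins and
  windows) prevent double-counting at shared edges; strict inequalities are
  used at the Tanimoto cutoff ("over 0.7") and the network threshold
  ("over 0.65").
- Flat spectra fail referencing; zero-variance features are dropped (PLS)
  or flagged (S-plot, correlations); non-positive row sums fail
  normalization; group means must be positive for fold changes.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from explicit config seeds; repeated pipeline runs at a fixed
  seed are byte-identical (the provenance hash excludes the output path).

## Problem sizes in the test and verification suites

Stochastic properties are checked at sizes chosen to make the property's
expected margin comfortably larger than its Monte-Carlo error while keeping
the suites quick: feature-recovery and null-Q² fixtures at n = 30/group ×
60 features; type-I error over 200 replicates of 38-metabolite null cohorts
at n = 10/group; network recovery over 100 replicates at n = 20/group ×
12 metabolites; binning conservation on 20 rendered spectra; the golden run
on a 25-sample, 4,096-point cohort. Rendered fixtures use 4,096–16,384
points rather than the 32K default.

## Known limitations

- Multi-class PLS-DA, O-PLS (integrated orthogonal filtering), VIP scores
  and permutation-based model p-values are not implemented; comparisons are
  pairwise with projection of additional groups.
- The spectral simulator's singlet approximation means bin-level feature
  matrices are cleaner than real CPMG data; expect lower r² between
  integrals and concentrations on instruments, and prefer PQN when dilution
  varies.
- Fingerprints ship as data; regenerating them for new metabolites requires
  an external cheminformatics tool.
- The packaged assignment windows resolve the 38 packaged metabolites only
  because their template peaks were spaced to avoid overlap; real spectra
  of these metabolites overlap heavily, and quantitative deconvolution is
  out of scope.
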