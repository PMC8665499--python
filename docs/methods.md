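# Methods

This note records the models implemented in `refstab`, the numerical
conventions, the design choices made where conventions diverge, and what
the synthetic-data tests do and do not demonstrate.

## Screening statistics

All statistics are computed per gene over the samples of an FPKM matrix
after a dropout prefilter: a gene is removed when its count of exact
zeros strictly exceeds `n_samples × max_zero_fraction` (default 5%; with
1217 samples the cut falls at 60.85, i.e. removal from 61 zeros up).
The strict inequality matters only when `n × fraction` is an integer and
is chosen so that a gene exactly at the nominal fraction is kept.

- **CV** uses the sample (n−1) standard deviation, the convention of
  spreadsheet `STDEV` and of biological-replicate summaries; `ddof` is
  configurable.
- **FC-5%** is the ratio of tail means: with `k = round(0.05·n)`
  (half-away-from-zero, floored at 1), mean of the k largest values over
  mean of the k smallest.  A quantile-ratio variant
  (`fc_mode="quantile"`) is provided because "top 5% over bottom 5%" is
  ambiguous between the two readings; the tail-mean form is the default
  because it uses every tail observation.  Boundary ties are resolved by
  position after a stable sort, i.e. tails contain exactly k values.
- **DPM** is `cv/√(1+cv²)`, a strictly increasing map of [0, ∞) onto
  [0, 1) (equivalently SD/√(mean²+SD²)).  The transform reproduces, at
  the printed 2-decimal precision, all 16 published (CV, DPM) pairs of
  the candidate table bundled in `refstab.datasets`, which is the
  closed-form consistency check the test suite and the acceptance script
  run.  The formula is pluggable should a different dispersion variant
  be preferred.
- A consequence worth noting: the default DPM cut (0.3) corresponds to
  CV ≈ 0.3145 and is therefore *strictly stronger* than the CV cut
  (0.40).  The four filters are still reported separately because the
  Venn partition of pass sets is part of the screening report.
- Genes with zero mean have undefined CV/FC-5%; they are reported as
  `+inf` with a `degenerate` flag rather than dropped, so the caller
  decides.
- `cv_rank` is assigned by a stable sort on CV, ties broken by input
  gene order — reported orderings are therefore exactly reproducible.

## Ct handling

Technical replicates are averaged arithmetically per (gene, sample).
Replicate groups whose range exceeds 0.5 cycles (a plumbing default, not
a biological constant) are flagged in a QC table but still averaged;
qPCR practice varies here and exclusion rules are left to the user.
Descriptive Ct statistics use the sample SD and report quartiles
(linear-interpolation percentiles) for boxplot-style summaries.

Standard curves are ordinary least squares of Ct on log10 template
amount.  Amplification efficiency is `E = 10^(−1/S) − 1`, which is the
standard form giving E = 1 (100%) at the perfect-doubling slope
S = −log2(10) ≈ −3.3219.  (The variant `10^(1/S) − 1` sometimes seen in
print yields negative values for the conventional negative slope and is
treated as a typographical variant of the same quantity.)

## Stability estimators

All estimators operate on a collapsed genes × samples Ct matrix and
agree on orientation: lower value = more stable.  Per-method ranks are
strict permutations 1..n; ties are broken by input gene order, which
coincides with competition ranking whenever values are distinct.

**geNorm.** Quantities are `Q = E^(min Ct − ct)` with E = 2 by default
(100% efficiency), because efficiency-corrected Ct panels are rarely
available at selection time; per-primer efficiencies from standard
curves can be substituted via the `efficiency` argument.  The initial M
of gene j is the mean over partners k of the sample SD of
log2(Q_j/Q_k).  Stepwise exclusion removes the highest-M gene
(ties: the later gene in input order) and recomputes until two genes
remain; those two share their mutual pairwise SD as stepwise M, which is
a structural invariant the tests assert.  The combined stability table
reports stepwise M by default (`genorm_value="initial"` switches),
since exclusion-time M is what the classical tool prints.  Pairwise
variation V_k is the sample SD of log2(NF_k/NF_k+1) where NF_k is the
geometric mean of the k most stable genes' quantities.  Because every
statistic is built from within-sample ratios, all geNorm outputs are
invariant to per-sample additive Ct shifts — as is the ΔCt method, whose
statistic (mean pairwise SD of Ct differences) equals geNorm's initial M
exactly under E = 2.  That identity is used as a mutual oracle in the
tests.

**NormFinder.** Data are centred per sample (column mean over the l
genes subtracted), removing the shared loading component; the model then
decomposes the centred value z of gene i in group g into an intergroup
difference d_ig and intragroup noise.  The within-group sample variance
u_ig of z is a biased estimate of σ²_ig because the centring mixes
genes: E[u_ig] = σ²_ig(1 − 2/l) + S_g/l² with S_g = Σ_k σ²_kg.  Summing
over genes gives Σ_k u_kg = S_g(l−1)/l, so S_g is recovered first and
then σ̂²_ig = (u_ig − Ŝ_g/l²)·l/(l−2), floored at zero (hence l ≥ 3).
The intergroup difference d_ig (group mean of z minus size-weighted
overall mean) is shrunk towards zero with the empirical-Bayes factor
τ²_i/(τ²_i + σ̂²_ig/n_g), τ²_i = max(Σ_g d²_ig/(G−1) −
mean_g(σ̂²_ig/n_g), 0).  The stability value is

    ρ_i = mean over groups of ( |d̃_ig| + sqrt(σ̂²_ig / n_g) ),

penalising both condition dependence and noise.  With one group (or no
grouping) ρ reduces to σ̂_i, whose ranking equals ranking by the
variance of sample-centred Ct.  Groups of a single sample are excluded
with a warning.  This estimator follows the published
variance-decomposition model; small numerical differences from other
implementations (which differ among themselves in the bias and shrinkage
details) are expected and the tests therefore assert its contracts —
single-group reduction, monotone response to planted group shifts,
planted-truth recovery — rather than third-party output values.
Grouping defaults to the metadata `class_label` (the tissue-group or
cell-line levels); an ungrouped fallback is available since panel
designs do not always carry groups.

**BestKeeper.** Deliberately descriptive: per gene the arithmetic and
geometric mean Ct, extrema, the BestKeeper "SD" — the **mean absolute
deviation** from the arithmetic mean, not the sample SD (MAD ≤ sample
SD always; the tests check this Jensen-type bound) — CV% = SD/mean·100,
and the Pearson r (and r², p) of each gene against the BestKeeper index,
the per-sample geometric mean over genes.  Non-positive Ct values are an
error (geometric means would be undefined).

**Comprehensive score.** The exact aggregation formula of the original
comprehensive-ranking tool is not public, so the default here is an
explicit, documented stand-in (and labelled as such in reports): min–max
scale each method's values onto [0, 1] (0 = that method's most stable
gene) and average.  The score is invariant to per-method affine
rescaling, lies in [0, 1], and preserves any unanimous ordering.  Ties
are broken by mean per-method rank, then input order.  A
geometric-mean-of-ranks alternative (`scheme="rank_geomean"`) is
provided.  Published final-score columns are not expected to be
reproduced numerically by either scheme.

## Validation

The normalization factor of a reference set is the per-sample geometric
mean of the members' **Ct values**, and relative expression is
2^−(Ct_target − NF).  (Averaging Ct rather than quantities keeps the
primary quantity 2^−ΔCt; a calibrator sample can be layered on top for
ΔΔCt-style reporting.)  Between-group comparisons use two-sided
independent-sample t-tests, pooled-variance by default to match
spreadsheet defaults, Welch by flag; group mean ± SEM accompany the
p-value matrix.  Raw p-values are primary (the workflow this package
supports stars raw p < 0.05/0.01); Benjamini–Hochberg-adjusted values
can be added side by side.  Degenerate pairs (both groups constant and
equal) report p = 1 with a flag.

Normalizer concordance is the Pearson correlation of flattened result
vectors: relative-expression profiles are correlated on log2 scale by
default (raw 2^−ΔCt values are log-normal-ish and raw-scale correlations
are dominated by the largest samples; a raw-scale option is kept), while
p-value vectors are correlated on their raw scale.  Both expression- and
p-value-based concordance matrices are produced because either can be
the relevant "detection efficiency" summary; they are symmetric with
unit diagonal by construction.

## Synthetic data

`simulate_ct` draws `ct[g,s] = μ_g + φ_s + γ[g,c(s)] + ε[g,s]` on the
cycle scale — Ct is already logarithmic in template abundance, so
Gaussian noise on Ct corresponds to multiplicative noise on quantities.
Defaults emulate a tissue panel: 16 genes, 11 groups × 6 samples,
baselines spread over 16–26 cycles, shared sample-offset SD σ_φ = 1
cycle, one planted stable gene (σ = 0.1, γ = 0) and the rest spanning
σ up to 1.0 and condition-effect scale γ up to 1.5 cycles.  Group
effects are drawn once per (gene, group) and frozen into the returned
ground truth, so "instability" includes reproducible condition
dependence — the failure mode that disqualifies classical controls —
and the ground-truth ordering is the realised per-gene variance
excluding the shared offset (group-effect variance + σ²).

`simulate_fpkm` (defaults: 60 genes × 300 samples, 5 planted) plants
log-normal reference-like genes (median 50 FPKM, log-SD 0.2 → CV ≈ 0.20)
that pass all four filters with wide margins, among decoys: a
low-expression class (median 2), a dispersed class (log-SD 1.0,
violating CV and therefore DPM, usually FC-5% too), a moderate-dispersion
class rescaled to an empirical CV of exactly 0.37 — inside the window
between the DPM cut (CV 0.3145) and the CV cut (0.40), hence violating
DPM alone — a dropout-tail class (5% of samples at a tenth of baseline,
pushing FC-5% to ≈ 10 while CV stays ≈ 0.21, violating FC-5% alone), and
a zero-inflated class guaranteed to trip the dropout prefilter.  Note
that "one filter per decoy" is not achievable for the CV filter itself:
since DPM is a monotone transform of CV, any CV violation entails a DPM
violation, and a heavy *upper* tail cannot raise FC-5% past 5 while
keeping CV ≤ 0.40.  The low-end-dropout construction is used instead for
the FC-5%-only class.

What passing these tests shows — and does not.  Recovery of planted
orderings under Gaussian, homoscedastic-within-gene noise with frozen
group effects demonstrates the estimators' internal correctness and
their contracts, not their behaviour on real panels, where
heteroscedastic technical error, amplification-efficiency differences
between primers, outlier samples and correlated biology all occur and
none are simulated.  The 66-sample/11-group default gives comfortable
separation between a σ = 0.1 planted gene and σ ≥ 0.2 competitors; real
candidate panels are usually closer and rankings correspondingly less
certain.

## Problem sizes and numerics

The bundled checks run at desk scale: 50 simulated panels for rank
recovery, 20 cohorts of 60 × 300 for screening recovery, 100 random
matrices for the geNorm/ΔCt identity — sizes chosen so the full suite
runs in seconds while the binomial margins on the ≥ 90% recovery
assertions remain wide.  All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs (asserted for both simulators and the CLI).  Floating-point
conventions: sample SDs use ddof = 1 throughout except where a
population variance is part of a definition (ground-truth variance of
frozen group effects); exact-zero comparisons are used only where zeros
are exact by construction (FPKM dropouts, noiseless limits are asserted
with atol = 1e−12).

## Known limitations

- The measured 66-sample Ct panel of the motivating study is
  supplementary material that cannot be redistributed here; checks
  against its printed summary values (minimum mean Ct 16.35, SDs
  1.17/2.03, ΔCt 0.602, BestKeeper 0.992) run only when the user
  supplies that table (`refstab.datasets.load_measured_tissue_ct`), and
  fail with an explanatory error otherwise.
- Published geNorm-stepwise/NormFinder/comprehensive-score columns are
  not reproduced numerically: implementations of those tools differ in
  transform and aggregation details (some published panels even show
  method columns with mutually inconsistent magnitudes), so the package
  asserts structural identities and recovery properties instead.
- No efficiency correction is applied by default anywhere; all 2^±
  transforms assume 100% efficiency unless a standard-curve efficiency
  is passed explicitly.
- RDML or instrument-native file parsing is out of scope; inputs are
  plain CSV/TSV.
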