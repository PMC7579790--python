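# Methods

## Effect sizes

Each study contributes, per gene, the difference of mean log2 expression
between cases and controls (the log2 fold change, LFC). Its sampling
variance is the Welch two-sample form on sample variances,
v = s²_case/n_case + s²_control/n_control. The source analyses this package
generalises report per-study weights and confidence intervals but never
state an LFC variance; the Welch form is the standard variance of a
difference of means and is the package's own choice. Two numerical guards
apply: v is floored at 1e-8 so inverse-variance weights stay finite when a
gene is constant within groups, and a study in which a group has fewer than
two samples gets that group's variance imputed from the study-wide median
per-group sample variance, with the effect flagged (`var_imputed`).

Matrices of unknown scale are resolved before effects are computed: values
containing negatives, or whose 99th percentile is ≤ 30, are deemed already
log2 (linear array intensities run into the thousands, log2 values rarely
exceed ~20); anything else gets log2(x+1). The threshold is a heuristic and
is overridable per call. Quantile normalization is available but **off by
default**: only the log2 transform is always enforced, since the upstream
normalization of each public dataset is unknown and re-normalizing can
destroy real signal.

## Pooling and model selection

Fixed-effect pooling is the inverse-variance weighted mean with
w_i = 1/v_i; heterogeneity is Cochran's Q with df = k−1, and
I² = 100·(Q−df)/Q, set to 0 whenever Q ≤ df (the total dispersion is within
its pure-sampling expectation). Model selection is deliberately binary —
fixed-effect iff I² = 0, random-effects otherwise — with no intermediate I²
threshold. The between-study variance uses the DerSimonian–Laird moment
estimator, the canonical choice of the classic random-effects literature;
REML and Paule–Mandel are out of scope. The pooled p-value is a two-sided
normal z-test of estimate/SE (a t reference with df = k−1 is available via
`use_t`). `MegaResult` reports both `se_pooled` (the pooled estimate's
standard error) and `sd_between` (the sample SD of the k study LFCs),
because summary tables in this literature sometimes print either under a
single "SD" label.

Genes present in fewer than `min_k` studies (default 2, the minimum for Q)
are reported with a `low_k` flag rather than dropped; genes absent from
every study are simply not reported. The significance screen keeps
p < 0.005 **and** |pooled LFC| > 1 (both strict), on raw p-values;
a Benjamini–Hochberg column is emitted for information only, since the
screen this package reproduces operates on raw p.

## Gene-set overlap

The intersection of two symbol sets is tested against a hypergeometric
upper tail: population N (the gene universe), |A| successes, |B| draws,
P(X ≥ overlap). The universe is a required modelling input, default 20,000
(a protein-coding approximation); published enrichment p-values often leave
their background unstated, so `universe_sweep` tabulates p against N rather
than asserting any single background. Percentages of A that are shared or
specific are rounded (not truncated) to two decimals: 24/127 = 18.90%.

## Moderator regression

Per-study LFCs are regressed by OLS (intercept included) on four study-level
covariates: total sample size (n_case + n_control), organism, region
(country) and study age in years. The two categorical factors enter as
single alphabetical integer codes, not dummy blocks: with ~9 studies over
6 regions and 3 organisms a dummy expansion is rank-deficient, and a
one-p-value-per-factor summary implies a single-term encoding. This coding
is an interpretive reconstruction and makes the categorical coefficients
ordering-dependent; their p-values are the quantity of interest.
Constant covariates are dropped as collinear (and recorded); a design that
remains rank-deficient raises an error naming the collinear terms; fits with
rows ≤ covariates+1 are refused. CIs and p-values use the t distribution on
residual df. Weighted least squares with within-study variances (formal
meta-regression) is deliberately not the default, matching the plain-MLR
procedure this package reproduces. `moderator_table(standardize=True)`
z-scores the covariates, putting coefficients on the per-SD scale the
synthetic generator defines its moderator effects on.

## Pathway panels

A signed edge (regulator promotes/inhibits target) predicts the target's
direction as sign(regulator pooled LFC) × edge sign. The observed direction
is the sign of the target's pooled LFC when its p-value is below `p_panel`
(default 0.05, the conventional nominal level for this follow-up analysis;
an optional |LFC| noise floor defaults to 0). Edges whose target is absent
or unreadable are `not_evaluated`; otherwise `supported` iff directions
agree. The classification is invariant under jointly negating the regulator
LFC and every edge sign. A bundled ten-edge panel for the SP1 regulator
(seven promote-edges onto disease-inhibitor targets, three inhibit-edges
onto disease-promoter targets) serves as the default fixture.

## Synthetic generator

`SyntheticConfig`/`generate` draw K studies: per study i and gene g the true
effect is δ_ig = μ_g + u_ig + Σ β_m·x_im with u_ig ~ N(0, τ²); controls are
N(baseline_g, σ²_e) and cases N(baseline_g + δ_ig, σ²_e) on the log2 scale.
Moderator covariates are z-scored across studies before the βs apply, so a
β is a per-SD shift of the study effect and comparable across covariates.
Gene missingness is study-level (a platform-coverage metaphor), either at a
uniform rate or via an explicit per-gene presence map. A configurable
fraction of studies is emitted as 2^value with scale marked unknown, to
exercise the scale-inference path. Defaults: 11 studies (using the bundled
11-study manifest — 6 countries, 3 organisms, ages 6–13 years, groups from
1 to 69 samples), σ²_e = 1.0 (a typical log2-scale array variance),
baseline 7.0. Everything is driven by one `numpy` Generator seeded from the
config, so a seed fixes the output byte-for-byte.

What the generator does **not** emulate: real intensity distributions,
probe-level effects, batch structure, or gene–gene correlation. Passing
calibration tests on this generator therefore shows the statistical
machinery is correct under its stated model, not that real array data meet
that model.

## Calibration scale and seeds

Simulation checks run at sizes a laptop CPU handles in seconds: pooled-
estimate bias and 95% CI coverage at K=20 studies of 30/30 samples over 200
replicates; type-I error at 1000 null genes across 8 studies of 20/20;
moderator recovery (region β = 0.8) at K=30 over 300 replicates. Replicate
seeds are spawned from a single master `SeedSequence`, which both
de-correlates replicates and lets one integer reproduce an entire run.

The strongly-heterogeneous single-gene demonstration (μ = 1.34, τ² = 0.26,
present in 9 of 11 studies) uses σ²_e = 0.02: an I² near 95% requires
within-study variances roughly (Q/df − 1)⁻¹·τ² ≈ τ²/24 ≈ 0.01, and with the
bundled manifest's group sizes σ²_e = 0.02 places the within/between ratio
in that regime. Its recovery test averages 100 replicates (mean pooled LFC
within ±0.05 of 1.34, random model selected in >90% of replicates): a
single k=9 draw carries between-study noise τ/√9 ≈ 0.17, and DL standard
errors underestimate at small k, so a one-draw 2-SE check would be a
coin-flip on the seed rather than a test of the method.

## Known limitations

- Cross-species pooling is by uppercased symbol only; no orthology mapping.
- DL z-intervals undercover slightly at small k (measured ~94% at K=20
  here); Knapp–Hartung adjustments are out of scope.
- The categorical moderator coding collapses multi-level factors to one
  degree of freedom; p-values depend on the (alphabetical) level order.
- The probe-collapse rule (mean over duplicate symbols) is a simple
  convention; platform annotation files are out of scope.
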