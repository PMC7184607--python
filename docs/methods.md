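# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions that affect results.

## Rodent differential expression

The rodent arm assumes an already normalized, batch-corrected log2
expression matrix over a 2×2 design (parity × treatment, five animals
per group).  Raw-array preprocessing (RMA, batch correction) is out of
scope; the generators emit post-correction matrices directly.

**Filters.**  The intensity filter computes each gene's mean within each
of the four experimental groups, takes one global threshold — the 30th
percentile of the pooled distribution of all per-gene per-group means —
and keeps genes whose *maximum* group mean strictly exceeds it.  A
single pooled threshold keeps genes expressed in only one group (e.g.
parity-specific genes), which per-group thresholds would discard; the
convention is recorded in the run log because membership depends on it.
The IQR filter ranks genes by across-sample interquartile range and
keeps the top `ceil(keep_frac · n)`, ties at the cut broken by gene ID
so results are reproducible on constant data.

**Moderated t.**  Per gene, the pooled-variance two-sample t-statistic
is moderated by shrinking the residual variance toward a prior fitted
to the whole ensemble: s̃² = (d₀s₀² + d·s²)/(d₀+d), with the prior
(d₀, s₀²) from the method of moments on log residual variances
(digamma/trigamma matching, trigamma inverted by Newton iteration) and
p-values from t on d₀+d degrees of freedom.  d₀ = 0 recovers the
ordinary pooled t and d₀ = ∞ full shrinkage; both limits are exposed
for testing and pedagogy.  A unit test verifies the implementation
against the Bioconductor reference implementation of this moderation on
a shared fixture.  Tests are two-sided throughout; calls require both
BH FDR < 25% (lenient by design — the consensus step below supplies the
robustness) and fold change ≥ 1.5 on the anti-log scale
(|log2 FC| ≥ log2 1.5 ≈ 0.585).

**Subsample consensus.**  All C(5,4)² = 25 ways of dropping one animal
per arm are analyzed; a gene enters the consensus when called with a
consistent direction in at least `consensus_min_frac` of rounds
(default 0.8).  How the rounds are combined is a genuinely open design
point; the support-fraction rule with a reported per-gene fraction was
chosen so users can audit sensitivity to the cutoff rather than trust a
single hidden rule.  A gene reaching the threshold in both directions
(possible only for `consensus_min_frac` ≤ 0.5) is excluded with a
warning.  The top-100 ranking by |median difference| applies to the
parous consensus only; the nulliparous panel passes through unranked,
mirroring the asymmetric design of the original analysis.  Panel
merging requires direction agreement for shared genes and labels each
gene's origin (parous / nulliparous / both).

## nCounter normalization

Three steps, in assay-protocol order: (1) scale each sample so its
positive spike-in geometric mean equals the grand geometric mean;
(2) compute the per-sample background as mean + 2·SD (n−1 denominator)
of the scaled negative controls, flag endogenous values below it and
impute them to threshold/√2; (3) scale so the housekeeping geometric
mean (default CLTC, GAPDH, GUSB, HPRT1, PGK1, TUBB) is constant, then
log2.  "Below two standard deviations of the mean" is implemented as
*below mean + 2·SD* — the standard nCounter background convention; the
literal reading (mean − 2·SD) would impute almost nothing and is
available as `background_mode="mean_minus_sd"`.  Whether imputation
precedes or follows housekeeping scaling is not fully pinned by the
protocol narrative; imputation is applied on the positive-scaled
counts and the reported per-sample background is carried onto the
final scale, so a flagged cell equals log2(background/√2) bit-exactly.

Two fixed points hold after normalization: the positive-control and
housekeeping geometric means are constant across samples (checked to
1e−9 relative).  Because the scaling targets are grand geometric means
of the data, multiplying one of n lanes by c rescales *all* normalized
values by the common factor c^(1/n); between-sample contrasts — the
only quantities the downstream analyses use — are exactly invariant.

The detection filter keeps genes unflagged in strictly more than
`detection_frac` (default 0.75) of samples.

## Exposure association

Urinary MEP (ng/mL) is ln-transformed and quartiled on interpolated
quartile cut points; boundary values join the lower quartile
(deterministic, the common epidemiology convention; configurable since
slopes depend on it).  Each subject receives its quartile's median
ln-MEP, and each gene's log2 expression is regressed on this scalar by
ordinary least squares (the Gaussian identity-link GLM), with two-sided
p from the slope t on n−2 df.  Degenerate inputs are handled by
convention rather than NaN: a constant response reports slope 0 and
p = 1; an exact non-constant fit reports p = 0 with a `perfect_fit`
flag.  No covariates are adjusted: the univariate model is the target
analysis, and the candidate covariate list in the source material is
ambiguous, so adjustment is deliberately not guessed.  AR-positive
gating uses the fence form of Tukey's lower whisker (Q1 − 1.5·IQR,
subjects at or above it kept), which coincides in membership with the
"smallest non-outlier observation" form but does not depend on which
observations happen to exist.

Paired adjacent-vs-tumor testing uses the Wilcoxon signed-rank
statistic on per-pair differences, zeros dropped (Wilcoxon's rule;
Pratt's is not implemented), exact null for n ≤ 25 without ties in
|difference| and the continuity-corrected normal approximation
otherwise, BH across genes at FDR 5%.  Genes with fewer than three
nonzero pairs are reported without a p-value and a reason rather than
silently dropped.

## Factor analysis

The gene-gene Pearson correlation matrix is factored by iterated
principal-axis extraction (communalities initialized at squared
multiple correlations, iterated to 1e−7), followed by oblique oblimin
(quartimin) rotation via the gradient-projection algorithm and
regression-method (Thomson) factor scores.  These are the documented
defaults of the standard exploratory-FA toolchain for this analysis
style; the implementation is in-package and deterministic (identity
rotation start, factors ordered by explained sum of squares, columns
signed so loading sums are non-negative).  k is a required parameter —
the published analysis of this signature found seven factors — and a
parallel-analysis helper (95th-percentile null eigenvalues) suggests k
but never chooses it silently.  Assignment sends each gene to the
factor of its maximal |loading| when that loading ≥ 0.3, else to "no
factor assignment"; assignment is invariant to factor sign flips.

## Enrichment

One-sided Fisher's exact p = P(X ≥ a) from the hypergeometric tail,
with the sample odds ratio ad/bc (∞ when bc = 0 and ad > 0).  The
universe defaults to the measured panel — conditioning on what was
measurable — not the genome; library sets are intersected with the
universe before testing and BH is applied across all tested sets.
Printed p-values from external enrichment services depend on their
private set sizes and universe and are therefore not comparison
targets; the tests instead verify the structural phenomenon (a planted
TF-target set overlapping the query ranks first at small p).

## Synthetic generators

`gen_rat_experiment` draws per-gene baselines N(7, 1.5²) log2 units,
subtracts the planted fold change (default −1.0, i.e. 2-fold down,
matching the predominance of down-regulation the signature shows) from
treated groups of planted genes, and adds N(0, 0.3²) noise — so the
noise-free treated-minus-control mean equals the planted fold change
exactly.  Defaults are the study design: five animals per group, four
groups, 500 genes with 50 planted.

`gen_nanostring_cohort` emulates the human arm: 294 subjects of whom
243 carry a paired tumor column; ln-MEP ~ N(4.5, 1.1²) (median ≈ 90
ng/mL with a geometric SD of ≈ 3, typical of urinary MEP); menopause
assigned independently of MEP (the cohort showed no MEP difference by
menopausal status; dependence is configurable).  Endogenous log2
abundances follow a block latent-factor model: gene = a·F_block + u·ε
with a = σ√ρ, u = σ√(1−ρ), within-block correlation ρ = 0.7 and total
per-gene SD σ = 0.6 log2 units (a realistic tissue-cohort spread).
Factor scores and unique noise are residualized against the
quartile-median predictor so the planted slope (−0.15 log2 per
predictor unit, the magnitude of the published significant genes) holds
*exactly* in the noiseless latent matrix — the cohort analogue of the
rat generator's exact planted fold change; without it, chance
factor-predictor correlation shifts all block genes' slopes jointly.
Counts are Poisson draws of 2^(log2-mean) times a lognormal(0, 0.15)
lane factor: positive probes follow a 4-fold concentration ladder
(30000 down to ~29 expected counts), negatives are Poisson(8),
housekeeping probes sit at 2^9.5–2^11 with the six default names, and
~10% of endogenous genes are set near background so the detection
filter has real work.  Paired tumor columns subtract the per-gene
tumor shift (default: the association block −0.5, i.e. lower in
adjacent tissue, one other block +0.5, echoing the mixed up/down paired
results) plus N(0, 0.2²) pair noise.

What the generators do **not** emulate: raw-array intensities and batch
structure, estrous-cycle or litter effects, cartridge/batch effects on
counts, negative-binomial overdispersion beyond the lognormal-Poisson
mixture, covariate structure (contraceptive use, HRT, smoking), or any
real gene identities.  Passing tests therefore demonstrate that the
*procedures* recover planted structure under the stated noise model at
the study's design sizes — not that the original biological findings
re-derive from real data, which would require the original tissue
measurements.

## Problem sizes and numerics

Test and acceptance runs use the design sizes directly (500×20 rat
matrix over 25 subsample rounds; 294/243- and 189-subject cohorts;
null calibration with 25 experiments × 500 genes and 200 replicate
regressions), which complete in seconds.  All quantiles use linear
interpolation between order statistics (the numpy default); this
convention is logged because filter membership and quartile boundaries
depend on it.  Ties break lexicographically by gene ID wherever a
ranked list is truncated.  BH adjustment is delegated to statsmodels,
Wilcoxon and hypergeometric tails to scipy, each cross-checked in the
suite against brute-force enumeration oracles; the moderated t, the
consensus rule, the normalization chain, the quartile-median predictor
and the factor-analysis chain are implemented in-package.

## Known limitations

Two-arm contrasts only (no design matrices or covariate adjustment);
no Pratt handling of zero differences; exact Wilcoxon disabled in the
presence of tied |differences|; oblimin only (no promax/varimax);
factor-score indeterminacy means scores are comparable within a fitted
solution, not across solutions; the consensus-combination rule and the
pooled intensity-threshold reading are documented choices where the
original analysis left the procedure unstated.
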