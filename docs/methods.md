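# Methods

This note documents the statistical procedures, the simulator, the
numerical choices, and the limits of what the test suite demonstrates.

## Differential expression

The moderated t follows the standard empirical-Bayes treatment of
microarray variances.  Per gene, the two-group pooled variance s²_g has
d_g = n_a + n_b − 2 residual df.  The prior (d₀, s₀²) is estimated by
moment-matching the log sample variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over the
sampling floor ψ′(d_g/2) identifies d₀ through ψ′(d₀/2) = Var(e) −
ψ′(d_g/2), solved by bracketed (geometric) bisection to 1e-8, and s₀²
follows from the mean of e.  When the observed spread of log variances
does not exceed the sampling floor the prior df is infinite and all
genes share s₀² (full shrinkage); the test statistic is then referred
to a normal.  The implementation agrees with Bioconductor limma's
`eBayes` to ~1e-10 on both the prior and the per-gene statistics (test
`test_matches_r_limma`).

All three comparisons are run **unpaired**, including C/P where samples
are in fact paired: the selection stage mirrors a plain two-group
contrast structure, and pairing is exploited only by the survival
classifiers' C/P profile mode.  Probe→gene collapsing (duplicate index
rows reduced to the max-mean row) and missing-value imputation (row
mean) live in the loader, keeping the statistics platform-agnostic.
Two-sided p-values throughout; DEG thresholds are strict inequalities
(|log2FC| > 2, BH-adjusted p < 0.001).

The Venn partition decomposes each of the all/up/down diagrams into the
7 nonempty intersection cells.  Because a gene can be up in one
comparison and down in another, the up-diagram plus down-diagram totals
can exceed the all-diagram total; the suite reproduces this with a
planted sign-switching gene (strong shift in pericancerous tissue,
weaker in cancer).

## Enrichment

*Over-representation*: upper-tail, inclusive hypergeometric probability
P(X ≥ k) with the comparison's full measured gene list as universe and
the gene set intersected with the universe first.

*GSEA*: the weighted Kolmogorov–Smirnov-like running sum.  Member
increments |r|^p / N_R (p = 1 by default, r = moderated t), non-member
decrements 1/(N − N_H); the enrichment score is the signed maximum
deviation.  ES is evaluated only at hit positions and just before hits
(the only candidate extrema), verified against the full running sum.
Ranking ties break by gene ID for reproducibility.  The null is built
from gene-label permutations — random member position draws — shared
across all sets of equal size; 1000 permutations by default.

The permutation p-value is the add-one, magnitude-based count
p = (1 + #{|ES_null| ≥ |ES|}) / (1 + n_perm).  Because a null set is
exchangeable with the permutation draws, this p is uniform under the
null while still attaining the 1/(1 + n_perm) floor for a perfectly
concentrated set; a sign-conditional count with the same denominator
would double the nominal level (~0.10 at 0.05), which the calibration
test would reject.  NES divides ES by the mean |null ES| of matching
sign.

BH adjustment is applied within each (DEG group, criterion) family —
nine groups × two criteria — and a set is *enriched* for a group only
when both adjusted p-values are strictly below 0.05.

## miRNA consensus and substitution

Edges vote at the (miRNA, gene) interaction level; an edge is kept when
at least `min_votes` (default 3) of the supplied tables contain it.
Matching normalizes case and strips species prefixes (`hsa-` etc.) from
miRNA IDs and upper-cases gene symbols, while the first-seen original
spelling is preserved for output; -5p/-3p arms stay distinct.
Substitution is the union of consensus regulators over a gene list, so
it is monotone: a larger DEG list can only gain miRNAs.

The packaged per-edge fixture map is a synthetic reconstruction: the
curated tables record which miRNAs target each DEG *list*, not
individual pairs, so each miRNA was wired to at least one gene of the
smallest list containing it.  Set-level substitutions are exact;
individual edges are not real predictions.

## Survival

The risk score is the mean of per-feature z-scores (standardized across
patients, population SD); features with zero variance contribute
nothing, features absent from the cohort are dropped and counted, and
the evaluation proceeds on the remainder.  Profile modes: C uses cancer
expression directly; C/P the paired cancer−pericancerous difference
(patients without a complete pair are dropped with a warning); P/N and
C/N subtract the mean of the normal reference samples.  C/N appears in
one packaged classifier record and is implemented symmetrically with
P/N.

The univariate Cox fit maximizes the Efron-tie-corrected partial
likelihood by Newton iteration with step halving, tolerance 1e-8, at
most 50 iterations; non-convergence (e.g. monotone likelihood) raises
with diagnostics rather than returning a divergent estimate.  The Wald
p is two-sided normal.  Kaplan–Meier is the plain product-limit
estimator; the log-rank test uses the hypergeometric variance at each
distinct event time and equals the Cox score test at β = 0 for the
binary group indicator on tie-free data (tested).  The KM/log-rank
split is at the median score (group sizes differ by ≤ 1 for distinct
scores); the continuous-score Cox fit is the primary statistic, the
split presentational.  A classifier *validates* on a second cohort when
its Wald p < 0.05 with the same hazard-ratio sign as in discovery.

## Synthetic study design

The generator emulates the target cohort: `n_normal = 10` reference
samples and `n_pairs = 45` patients with one pericancerous and one
cancer sample each.  On the log2 scale, gene baselines are
N(8, 1.5) (typical array intensities), residual noise N(0, 0.8), and a
planted gradual gene shifts by δ/2 = 2 in pericancerous and δ = 4 in
cancer tissue (negated for down genes); 5% of genes are planted up and
5% down.  Defaults of 2000 genes, 150 miRNAs and 40 gene sets of 10–30
members keep every calibration target measurable in seconds; δ = 4
places the half-shift exactly on the DEG threshold, so the C/P and P/N
comparisons recover planted genes only partially — intentionally, as
that is what makes the progression "gradual" rather than binary.

Enriched sets draw 80% of members from the gradual pools (alternating
up/down); the first up-type enriched set is the prognostic set.  Only
that first set drives the hazard: event times are exponential with
h = h₀ exp(β z), β = `beta_surv` (default 1), z the standardized mean
cancer expression of the set's members, and h₀ = ln 2 / 24 months.
Censoring is independent U(0, c) with c solved by bisection from
E[(1 − e^{−hc})/(hc)] = `censor_frac` (default 0.2); times are reported
to 0.1 month, which introduces realistic ties for the Efron handling.
If `n_prognostic_sets` > 1 the extra sets are decoys with enriched
structure but no survival link.

Each of the six target databases keeps a true miRNA→gene edge with
probability `db_recall` (0.7) and reports each non-edge with
probability `db_fpr` (0.01), independently, so 3-of-6 consensus recall
has the closed form P(Bin(6, 0.7) ≥ 3) ≈ 0.929.  miRNA expression is
coupled to the centered mean expression of the miRNA's true targets
with coefficient −0.5, giving the substitution stage a signal of
realistic (modest) strength.

One RNG stream per generation stage is spawned from the master seed, so
outputs are bit-identical given the seed and adding a stage never
perturbs earlier draws.  A validation cohort reuses the planted truth
with fresh patients, noise and survival.

What the simulator does **not** model: probe-level effects, batch and
platform differences, intensity-dependent variance, correlated gene
blocks beyond set membership, non-proportional hazards, or informative
censoring.  Passing tests therefore demonstrate the correctness and
calibration of the procedures under the planted model, not performance
on real arrays.

## Problem sizes used by tests and the acceptance script

Simulation-based checks run at deliberately modest sizes chosen to keep
Monte-Carlo error within the asserted bands: 2000 null genes for type-I
error, 200 random sets (999 permutations) for GSEA null uniformity, 100
cohorts of 300 genes for the null-classifier rate, 50 cohorts of 400
genes for Cox log-HR recovery at the full n = 45 pairs, 800 true edges
for consensus recall, and 20 end-to-end pipeline runs at 500 genes /
10 sets / 150 permutations for the planted-set rediscovery rate.  The
cohort design (10 normal + 45 pairs) is never scaled down.

## Known limitations

* The enrichment stage attaches one GSEA result per (comparison, set)
  to all three of that comparison's DEG groups; a direction-specific
  one-sided variant is not implemented.
* The Cox fit is univariate by design; no clinical covariates.
* Real-data loaders accept series-matrix-style TSVs but ship untested
  against live repository downloads.
* The consensus vote treats databases symmetrically; no
  reliability weighting.
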