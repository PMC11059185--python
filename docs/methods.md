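# Methods

This note documents the models, parameter choices and numerical
decisions behind `cistrat`, and what the synthetic-data experiments do
and do not demonstrate.

## IHC profiles and stratification

A neuron-count record is one rater's tally of complex-I-positive vs
total neurons for one subject, region and sampling sub-region. Profiles
pool counts over sub-regions *before* dividing (per-neuron weighting,
not an average of averages) and average the two raters' percentages for
the primary value. Substantia-nigra measurements based on fewer than 25
pooled neurons are flagged `qc_pass=False` and excluded from group
analyses: with n < 25 a single misclassified neuron moves the estimate
by ≥4%, which is the order of the group differences of interest.

Stratification runs k-means (k = 3, 20 restarts, 100 iterations) on the
one-dimensional PFC percent-positive axis of cases and controls
jointly. We use restarted Lloyd iterations (scikit-learn): in one
dimension with 20 restarts this reaches the global optimum, which the
test suite verifies against an exact dynamic-programming solver on
random instances. After fitting, every point is reassigned to the
nearest center with centers sorted in descending order, so equidistant
ties resolve deterministically toward the higher (less deficient)
cluster. Clusters are labelled nCI / CI-mild / CI-severe by descending
center; only iPD subjects receive labels, and the two lower clusters
merge into CI-PD. k is configurable but defaults to 3; nothing in the
procedure chooses k from the data.

Regional summaries take group × region medians over QC-passing values
and cluster the region columns with Ward linkage on Euclidean distances
(the `ward.D2` criterion when applied to raw observations), returning
merge heights and a Newick rendering.

## Single-neuron mtDNA quantification

The duplex assay reads MTND1 (outside the mitochondrial major arc,
hence a total-copy-number proxy) and MTND4 (inside it) in the same
well. Standard curves are ordinary least squares of Ct on log10(copies)
over the 1e2–1e6 serial dilution; amplification efficiency is
`10^(−1/slope) − 1`. Replicate Cts are averaged on the Ct scale (Ct
noise is approximately additive) before conversion, and the deletion
fraction is `clamp(1 − ND4/ND1, 0, 1)`. "Total copy number" is reported
as the ND1 estimate. Group comparisons operate on per-subject centers
(median by default; mean available) of 8–16 neurons, never on pooled
neurons, using Welch's ANOVA with η² from the classical sums-of-squares
decomposition and Games–Howell post-hoc tests.

## Bulk analysis

Filtering removes (i) genes on non-canonical scaffolds or the
mitochondrial genome when annotation is supplied, (ii) genes holding
>0.6% of a sample's reads in more than half of the samples, and (iii)
genes with <5 reads in ≥80% of samples. The two count rules iterate to
a fixpoint, which makes the filter idempotent; on matrices of realistic
size one pass is already the fixpoint. The sex-specific noise threshold
is the maximum over the 95th percentiles of *XIST* expression in males
and *KDM5D*/*RPS4Y1* expression in females; the exact percentile is a
package decision.

MGP scores are the first principal component of each cell type's
markers, z-scored per marker across samples, on the
`log2(CPM + 1)` scale (the working transform is a package decision).
The sign is fixed by positive correlation with the mean standardized
marker expression, and the fraction of marker variance explained is
reported as a diagnostic. Types with fewer than three usable markers
are skipped. Raw first-PC scores (not rescaled) enter the group
regressions.

Group effects come from per-type OLS of the MGP on the group indicator
plus age, sex, PMI and cohort. The stepwise driver criterion — our
operationalization of a procedure whose exact form is open — is:
candidates are the types with a significant own group effect; each
candidate's MGP is added as a covariate to every other significant
type's model; candidates are ranked by how many of those effects they
render non-significant, ties broken toward the smaller own p-value.
The top candidate is the driver. Restricting candidacy to significant
types matches the interpretation that the driver is itself a changed
profile, and the tie-break makes the report deterministic and
order-invariant.

GSR enrichment scores a set by the mean `−log10 p` of its members and
compares it to `n_resample` random same-size draws from the expressed
universe; `p = (1 + #null ≥ observed) / (1 + n_resample)`, BH-adjusted
across sets. Sets are bounded to 20–500 members after intersection with
the universe. Directional analyses run the same machinery on signed
one-sided score lists. Differential expression itself is consumed from
external tools; a per-gene rank-sum test is provided for synthetic
workflows only.

## Droplet QC cascade

The cascade is a strict filtration; each barcode records the first
stage that removed it. "At least 500 transcripts" is read as ≥500
distinct detected genes, since a separate UMI threshold (≥1000)
coexists with it; the mitochondrial cut (<3%) is strict. Genes in fewer
than 10 kept droplets are dropped after the droplet pass.

Clustering normalizes to 10k UMIs, log1p-transforms, selects up to
2000 high-variance genes and projects to 50 PCs; the clustering backend
is pluggable (input PC scores, output integer labels) with k-means as
default — k = 28 suits realistic runs, small k the test fixtures.
Cluster annotation takes the marker panel with the highest mean
z-scored expression; a runner-up within 5% of the winner's score range
flags the cluster ambiguous rather than forcing a call. Purification
removes barcodes whose nearest cluster centroid in the first 5 PCs is
not their own cluster (exact ties keep). The per-droplet MGP of every
major type is min–max scaled to [0, 1] across droplets before the
ratio score — first-PC scores are signed, and without rescaling the
ratio would be undefined; this is the package's resolution of an
underspecified step. A droplet is kept when its annotated-type MGP
divided by the sum of the others is ≥0.4 (a vanishing denominator
counts as +∞, kept).

Overrepresentation uses the hypergeometric upper tail with each
cluster's own expressed genes as universe, BH within cluster.

## Synthetic data: what it emulates, and what it does not

Regional CI-positive proportions are Beta-distributed per group, with
parameters fitted by least-squares quantile matching to published group
medians and IQRs where available (PFC and SNpc control/combined values)
and to realistic interpolations for the subtype-specific and
additional-region values (cerebellar cortex and inferior olive stay
control-like in all groups). Within-subject cross-region correlation is
a Gaussian copula with exchangeable ρ = 0.7 (configurable; no joint
correlation structure is published). Subtype counts follow the
configured fractions exactly via largest-remainder allocation. Rater
noise acts on the logit of the true proportion (sd 0.25 by default),
which keeps proportions in (0, 1) and matches the multiplicative error
regime of values above 90%; section sizes are gamma-Poisson, with the
SNpc overdispersed (mean 60, shape 2.5) so the <25-neuron rule is
exercised.

qPCR plates share a known curve (intercept 38, slope −3.3219, i.e.
perfect efficiency). Because both targets of a duplex reaction amplify
in one physical well, half of the Ct noise variance is modelled as a
shared per-well effect (`well_correlation = 0.5`) that cancels in the
ND4/ND1 ratio; each channel's marginal noise sd stays `ct_sd`. The
deletion-recovery experiment spreads 1000 neurons over 10 plates with
per-plate standards and triplicate wells, matching how a 96-well study
is actually run; its median absolute deletion error at 0.1-cycle noise
is ≈0.02.

Bulk mixtures are negative-binomial (dispersion 0.05, typical of human
cortex cohorts) around `library × Σ_t proportion_t × signature`, with
markers 30-fold enriched in their own type (strong cortical markers are
20–100-fold specific) and Dirichlet proportion noise (concentration
40). The planted disease effect is a single truly shifted type — the
VIP/reelin GABAergic interneurons at factor 0.4, scaled by a latent
per-subject severity Beta(5, 2) — so every other type co-varies with it
only through compositional closure: the single-driver structure the
stepwise analysis is designed to detect. Sex genes are emitted
consistently with each subject's sex plus a 1% leak.

Droplet simulations place 7 cortical types (panel markers plus 30
synthetic markers each over ~1500 background genes and 13 MT- genes at
1% mass), cells at ~3500 UMIs with 5% ambient contamination, 7%
doublets (pairs drawn independently from the type distribution, so
~1/7 are homotypic and undetectable by design), and ambient-only
empties at ~100 UMIs. Doublet *detection* is deliberately out of scope;
truth labels let the cascade's incidental doublet removal be measured —
in practice the centroid-purification stage removes roughly 60% of
doublets, while the 0.4 MGP-ratio cutoff rarely fires on this clean
data even though doublets score clearly lower (the score contrast is
what the tests assert).

None of the generators model batch effects beyond a cohort label,
spatial structure, read-level errors, or empirical marker overlap
between related cell types; passing recovery tests on these data shows
the estimators are correct and well-calibrated under the stated model,
not that real tissue meets that model.

## Experiment sizes

Test and acceptance experiments use: 30 random instances for the 1-D
k-means optimality check; 20 seeded cohorts of 22 controls + 89 iPD for
subtype recovery (mean adjusted Rand reported); 10 × 100 neurons for
qPCR recovery; 60-sample bulk mixtures (the real bulk cohort had 98)
with 100 seeds for driver recovery; 2000 cells + 500 empties × 10 seeds
for the droplet cascade; and 200–1000 simulations for the null-
calibration suites. These sizes give stable Monte-Carlo estimates while
keeping a full run in minutes.

## Known limitations

* The Hartigan–Wong algorithm is not reimplemented; optimality in 1-D
  is guaranteed through restarts and checked against the DP solver.
* The stepwise driver criterion and the sex-noise percentile are
  documented interpretations of loosely specified procedures.
* ICC is fixed to the two-way random-effects, absolute-agreement,
  single-rater form ICC(2,1); other forms are available in pingouin if
  a different convention is needed.
* The MGP-ratio score depends on the min–max scaling population: scores
  are comparable within one dataset, not across datasets.
* Synthetic ICC (~0.95) runs higher than typical published two-rater
  agreement (~0.91) because rater noise is the only disagreement source
  modelled; no systematic rater bias or neuron-identification
  disagreement is simulated.
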