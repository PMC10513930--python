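# Methods

`lipidyn` reimplements, as a tested library, the analysis pipeline of a
longitudinal targeted plasma-lipidomics study: scheduled-MRM transition
intensities are converted to estimated concentrations via deuterated
spike-in standards, filtered on technical precision, completed by a
censoring-aware imputation, and fed into personalization, co-abundance,
association, trajectory and enrichment layers. A synthetic cohort generator
reproduces the statistical structure of such a study so that every layer can
be exercised and scored against planted ground truth without any external
data.

## Extraction and quantification

Each scheduled transition is acquired 20 times per sample. A transition
with more than two zero-intensity recordings among the 20 repeats is
reported as not available; otherwise the summary intensity is the mean over
the nonzero recordings. Zero means exactly zero counts — no epsilon.
Transitions are matched to species on (method, polarity, Q1, Q3, scan
index); matching is exact on the catalog key by default, with an optional
±0.01 Da tolerance for real instrument exports. PG/PS/PA and their lyso
forms are matched but excluded from analysis.

Concentrations are estimated as
`conc = (analyte / spike_area) * spike_conc` (nmol/ml). For complex lipids
with two identical fatty acyls the fragment-ion signal is doubled, so the
analyte intensity is halved before ratioing; the arithmetic placement
(halving the signal rather than the final concentration) is equivalent
either way and is fixed here for clarity. Spike-in standards missing in
strictly more than 5% of samples are replaced by a same-class alternate.

Lipid classes acquired without a class-matched standard are normalized
against a surrogate standard restricted to PC/PE/LPC/LPE, selected on QC
samples by a three-rule hierarchy: (1) the best-correlating standard (log10
Pearson) with at least 50% complete QC observations — the completeness
filter is applied *before* ranking; (2) else the standard matched to the
best-correlating same-class species; (3) else the globally best-correlating
standard. Pairwise correlations use samples where both series are observed;
fewer than three shared observations leaves r undefined and the candidate
unranked. Ties break by higher completeness, then name. Absolute scale for
these species comes from a pooled least-squares fit of log10(concentration)
on log10(normalized intensity) over all spike-quantified lipids; a pooled
(rather than per-sample) fit is used because per-sample fits are
unidentifiable with a handful of standards, and the monotone transform
preserves between-sample ordering per species.

## Precision, filtering and imputation

CVs (100·sd/mean) are computed on untransformed, non-imputed
concentrations: per species over QC samples; per participant across visits
(same-day duplicates excluded, at least three timepoints per participant
and three quantifications per species), summarized as the median over
participants; and pooled over all biosamples. "CV across the remaining
biosamples" is read as this pooled biosample CV.

Filters run in a fixed order: (1) biosamples with >25% missing values;
(2) species with <10% valid values; (3) the robust set keeps species with
QC CV ≤ 20% and QC CV below the biosample CV; (4) excluded classes (PA/LPA,
PS/LPS, PG/LPG) and individually excluded species. The order is a design
choice; each drop is recorded with its reason and filtering is idempotent.

Missing lipid values are treated as left-censored at a per-class detection
limit `D_c`, defined as the minimum observed untransformed concentration in
the class. Each missing cell is imputed by the conditional expectation of
the species' fitted log-normal below `log D_c`, shifted by the median
standardized residual of the k = 10 nearest neighbour samples (Euclidean
distance on z-scaled shared observed log values) scaled to the standard
deviation of the censored tail, then clipped at `log D_c` and
exponentiated. Scaling the neighbour shift by the *tail* sd (not the full
species sd) matters: the truncated mean already accounts for the distance
to the detection bound, and a full-sd shift would subtract it twice and
systematically undershoot. Species with fewer than three observations fall
back to a seeded uniform draw in `[0.5 D_c, D_c]`. Imputed values never
exceed `D_c`. Missing covariate series (e.g. weight) are completed by the
mean of the two adjacent timepoints, nearest value at the boundaries.

## Personalization

Per species, the fraction of variance attributable to participant identity
is estimated on log concentrations of healthy samples by the one-way
ANOVA method-of-moments estimator with the unbalanced-design correction
(`n0 = (N - Σn_i²/N)/(a-1)`), negative moment estimates truncated at zero.
A closed-form estimator was preferred over a likelihood fit because it is
deterministic and sufficient for ranking species. The embedding layer
delegates t-SNE (log2 transform, z-scaling, perplexity 5, Barnes–Hut
θ = 0.5) to scikit-learn; the bespoke part is the distance test: Euclidean
distances over same-participant sample pairs versus participant-centroid
pairs, compared by a Welch two-sided t test. Because centroids of randomly
labelled groups shrink toward the grand mean, the two distance populations
are not exchangeable under label permutation; the test is therefore
reported as a descriptive contrast, and the suite checks that permuted
labels never produce a spurious personalization signal.

## Co-abundance modules

An unsigned weighted network is built from `|r|^β` on log-transformed
healthy samples, with β the smallest power in 1..20 whose connectivity
distribution fits a power law with R² ≥ 0.8 (10 equal-count bins of k,
least squares of log10 p(k) on log10 k); if none passes, the argmax is used
with a warning. Topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1-a_ij)` converts the
adjacency into a similarity; modules are branches of an average-linkage
dendrogram of `1 - TOM`. Instead of a hybrid dynamic tree cut, the cut
height is chosen from a fixed grid of 99 quantile steps of the merge
heights, maximizing the number of clusters with ≥ 5 members and, among
ties, minimizing the unassigned pool; this static rule is deterministic and
recovers planted correlation blocks exactly in the test suite. Eigengenes
are the first principal component of z-scaled member profiles, oriented to
correlate positively with the module mean; modules with eigengene r > 0.8
are merged iteratively (most-correlated pair first, eigengene recomputed
after each merge). Module–clinical associations are partial Pearson
correlations after residualizing both sides on sex, age, ethnicity and BMI,
BH-corrected across all module × measure pairs.

## Association layers

All layers use natural-log concentrations. The SSPG layer has one sample
per participant, which makes a participant random intercept unidentifiable;
it is therefore fitted by OLS of the scaled log concentration on scaled
SSPG plus age at visit, sex, ethnicity and BMI, with BH FDR < 5%. The
infection layer fits, per species, a random-intercept mixed model of log
concentration on event phase (baseline / early [days 1–6] / late [7–14] /
recovery [15–35]) plus covariates, and tests the overall phase effect by a
likelihood-ratio test against the phase-free model (FDR < 10%); "weeks 3–5"
is mapped to days 15–35, contiguous with the late phase. The
cytokine–lipid layer regresses each scaled cytokine on each scaled lipid
plus BMI, sex and ethnicity with a participant random intercept, fitted by
maximum likelihood (not REML) with a normal-approximation Wald p on the
lipid coefficient; FDR-surviving pairs (5%) form the signed network edge
list.

The mixed models are fitted by an exact profiled-ML routine specialized to
a single random intercept: with variance ratio θ the covariance inverse is
block-closed-form, so β and σ² profile out and the likelihood is a 1-D
optimization. The fit is exact ML (cross-checked against statsmodels
MixedLM in the suite) and runs in milliseconds, so the thousand-replicate
error-control simulations finish in seconds.

The ageing (Δage) layer subtracts each participant's baseline (first
recorded visit) from later visits and regresses Δlog concentration by OLS
on Δyears, BMI and absolute storage length, with an intercept. Samples
more than 5 years past baseline and the single participant with a uniquely
large sample count are excluded before fitting. Class-level results sum
untransformed concentrations per detailed subclass (small/large TAG and
ether-PE kept separate) before the log; the 5-year percent change is
`100·(e^{5β} − 1)`. Strata (all, male, female, IR, IS) refit on row
subsets. The IR/IS differential-correlation layer standardizes both sides,
computes Pearson r within each group, tests the contrast by a two-sided
Fisher z test, and reports pairs with BH FDR < 5% *and* |Δr| > 0.2,
alongside the pooled correlation.

## Enrichment

Lipid names parse into structured identities (subclass, fatty acyls, ether
linkage, TAG total composition plus the transition-resolved FA), from which
five annotation families are derived: chain parity, omega class,
saturation (SFA d=0 / MUFA d=1 / PUFA d≥2 per constituent FA), detailed
subclass (small TAG ≤ 48 total acyl carbons, large ≥ 49; PE-O/PE-P
distinct) and constituent FA. Omega class ships as a fixed lookup table
because c:d alone cannot determine double-bond position; ambiguous FAs
(18:3, 22:5) default to unknown.

Enrichment splits model results into positive and negative foregrounds
(signed coefficient, FDR < 10%) against the background of all *tested*
species — conditioning on testability rather than the full catalog — and
runs a two-sided Fisher's exact test per category, across all lipids and
within each subclass (the catalog is TAG-heavy, and the global test alone
would be dominated by TAGs). BH correction is applied within each
(scope × direction) family at 5%. Infinite log2(odds) from empty cells are
imputed for display with 0.5× the minimum (−∞) or 0.5× the maximum (+∞)
finite value; a variant imputing 0.5× the directional mean is available
behind a flag. Categories significant in both directions display as 0 with
a dual flag.

## Trajectory clustering

Significant species' profiles (log2, z-scaled, phase-ordered) are clustered
by k-means (20 seeded restarts per k). For each candidate k the minimum
pairwise centroid distance is recorded; this curve collapses as soon as k
exceeds the number of underlying templates, so the elbow is taken as the k
preceding the point of maximal convexity (largest second difference) of the
curve. Cluster median profiles are correlated with clinical measures under
BH correction.

## Synthetic cohort generator

The generator plants every quantity the pipeline is later asked to
recover, and writes them to a ground-truth ledger. Log concentration per
sample and species is class median + species offset + participant random
effect + ageing slope × years + SSPG effect + infection-template effect +
residual noise. Defaults (chosen once, as study conditions):

* ~170 species across 20 subclasses with TAG-heavy proportions; class
  median concentrations (log10 nmol/ml) span 4 orders of magnitude, from
  FFA/SM (~2.5) down to LCER (~−1.2).
* Between-species spread 0.2–0.8 log10 per class; total biological sd 0.5
  (natural log) split by class ICC — high for TAG/SM/HCER/CE (0.5–0.6),
  low for FFA (0.1) — mirroring the observed participant-specificity
  hierarchy.
* 20 participants, half insulin-resistant (SSPG > 150 mg/dl), 8 quarterly
  healthy visits plus one infection episode sampled on days
  2/5/9/13/20/28; 40 QC samples drawn from one fixed stock.
* Technical noise split into a shared per-sample extraction/injection
  factor (6.5% CV, cancelled by the internal standards) and independent
  per-transition noise (2.5%), giving ~7% QC CV on intensities and ~3.5%
  on concentrations; replicate-level noise 3%.
* Replicate zeros drop out with probability logistic in
  (log censor bound − log signal) with width 0.1, the bound set at a
  per-class quantile (2% by default, 15% for the platform-excluded
  classes) — any monotone dropout model would exercise the zero rule; this
  one concentrates missingness just below the bound, as left-censoring
  does.
* Planted effects: ageing slopes per class (e.g. TAG +0.02/yr, PE-P
  −0.01/yr), SSPG effects on 30% of species at 0.5 SD per SD of SSPG,
  infection templates (early/late up/down) on 30% of species, two
  cytokines loading 15 species each at 0.3, clinical measures tracking
  SSPG, total TAG and total CE.
* Planted QC violations: one sample with forced 35% missingness, one
  species censored in 95% of samples, one species with 35% technical CV,
  and one species with near-zero biological variance but elevated QC-only
  noise — each exercising one filter reason. The ledger records the
  *realized* violations (censoring can push additional borderline species
  below 10% validity), so the filter report can be compared exactly.

What the generator does not emulate: chromatography and spectra, isotope
interference (the platform's own correction is below 6% and is not
modelled), cytokine batch effects, non-Gaussian biological tails,
covariance between technical noise and abundance beyond the censoring
model, and real lipid co-regulation beyond the planted block/loading
structure. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative assumptions, not robustness to
real-data pathologies.

## Problem sizes and numerical choices

The default test-suite study is ~320 samples × ~170 species; recovery
simulations use the designs stated in their tests (50×10 for ICC, 70
participants for SSPG, 60×8 for ageing, 500 samples for cytokine recall,
1,000 species-level replicates for error control) — sizes chosen to give
each estimator enough data for its stated tolerance while keeping the
default suite fast. Degenerate inputs are handled explicitly: constant
species are flagged and skipped in regression layers; a single participant
collapses the random intercept to OLS with a warning; all-identical
trajectory profiles return one cluster; empty enrichment backgrounds and
all-infinite odds raise errors. Determinism: every stochastic step takes a
seed (k-means restarts, imputation fallback draws, the generator), and the
fixture bundle is byte-identical per seed.

## Known limitations

The surrogate-standard route estimates only the abundance *range* of the
additional classes (no class-matched standard exists, so ionization
efficiency differences are uncorrected); between-sample comparisons per
species remain valid. The static dendrogram cut is a documented divergence
from the hybrid dynamic tree cut and may differ on real, less
block-structured data. The ICC estimator can be mildly biased for strongly
unbalanced designs. GAMM-based time-interval inference, cytokine batch
correction and microbiome associations are out of scope.
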