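# Methods

This note documents the statistical model behind each stage of
`breakbalance`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the decisions taken where the design
was genuinely open.

## Reporter quantification

Reads are assigned to reporters by a constant upstream anchor followed by a
barcode; a whitelist barcode matches when it is the *unique* entry within
one mismatch (ambiguous or unmatched barcodes are counted as unassigned,
never guessed).  The indel size is the observed spacing between two constant
anchors flanking the break-site window minus the reference spacing — an
anchor-spacing score, not a full alignment.  This is robust for the
error-free and low-error regime the assay operates in, and is exact on
simulated reads; it does not attempt to resolve complex indels that destroy
an anchor (such reads are counted unassigned).  Reads whose anchors are
missing or out of order are never scored.  The `v2` reporter dialect carries
8 extra constant nucleotides, handled as a fixed offset on the reference
spacing.

The balance of one reporter in one sample is `log2(counts[-7]/counts[+1])`,
defined only when both signature classes reach `min_reads_per_class`
(default 1 read; inhibitor experiments in sparse reporter pools use 40).
Reporter frequency is the reporter's share of the sample's assigned reads;
the published screen filters drop reporters below a frequency threshold
(0.0025 / 0.0075 in the two engineered reporter-pool lines) and reporters
absent from any of the three replicates of a condition.

## Delta scores and global effects

Δlog₂MMEJ:NHEJ is computed per replicate against the mean of the mock
controls *of that replicate* and then averaged over replicates (unweighted,
as the screen averages its three replicates).  Centring within replicate
makes the statistic invariant to replicate-wide batch shifts; per reporter,
the mock deltas average to zero by construction.  Missing reporter cells are
excluded from means, never imputed; cells supported by a single replicate
are kept but flagged in the support matrix.

A protein's global score is the mean delta over its reporters.  The test is
a z-test against the empirical mean and standard deviation of the mock
global scores — with 33 mocks the empirical null is stable and needs no
distributional assumption beyond normal tails.  Two-sided p-values are
Benjamini–Hochberg corrected across non-mock proteins (BH is used for every
multiple-testing step in the package); the default significance threshold is
FDR 0.001, and the direction labels follow the sign convention that a
knockout lowering the MMEJ:NHEJ ratio marks a protein that *favors MMEJ*.
Inhibitor designs have a single vehicle control per replicate, so the null
cannot be estimated from controls; there the test is a two-sided two-sample
t-test of per-replicate global scores.  With zero variance in both groups
and a nonzero difference the t statistic diverges; this degenerate case is
reported as p = 0 with a log warning rather than an exception.

## Three-step CCD model

**Step 1 (any-effect pre-filter).** Per protein, each reporter's delta is
z-scored against the per-reporter mock mean and sd; the omnibus statistic
Σz² is referred to a chi-square with as many degrees of freedom as available
reporters.  The BH cutoff is deliberately lenient (0.25): this step only
removes clearly inert proteins so that step 2, which controls the reported
FDR, is not burdened with them.

**Step 2 (principal-component regression).** The chromatin feature matrix
(reporters × features, z-scored per feature with the population sd) is
decomposed by PCA; the protein's delta vector is regressed on the smallest
number of components explaining ≥ 90% of feature variance, capped at
(number of reporters − 3) to keep residual degrees of freedom with only 19
observations.  The overall-model F-test p-value, BH-corrected across
proteins, is the CCD FDR; the default call threshold is 0.05 (a 0.25
threshold is appropriate for small reporter pools with ~10 reporters, where
power is much lower).  The F-test is computed in closed form so that a
perfect fit yields p = 0 and a constant delta vector p = 1.  Mock samples
run through the identical pipeline (BH within the mock set) and are reported
separately as negative controls; on all-null simulations the fraction of
proteins called at 5% FDR stays within binomial slack of 5%.

**Step 3 (synergy scores).** For significant proteins only, the slope of
the simple linear fit of delta against each standardized feature is the
synergy score (log₂ units per feature sd); slopes with two-sided p ≥ 0.05
are stored as exact zeros, without further correction across the 25
features — the protein-level FDR is already controlled in step 2, and the
sparsified vectors are what the cosine similarity downstream is designed
for.  Raw (unsparsified) slopes and intercepts are retained for diagnostics
and for `estimate_feature_delta`, which evaluates the step-3 fit at a
feature level of +1 sd by default (the natural "inside the chromatin state"
evaluation point; the level is a parameter).

Because chromatin features are correlated, a synergy planted on one feature
legitimately propagates to its correlated block partners; recovery is
therefore assessed against the correlation-propagated planted vector
(feature correlation matrix × planted β), not against the sparse β itself.

Synergy classes follow the sign rule: M if all significant slopes are
negative, N if all positive, mixed if both signs occur.  Hierarchical
clustering of synergy vectors uses Euclidean distance with average linkage,
rows pre-sorted by protein name so leaf order is deterministic.

## Similarity of CCD patterns

Cosine similarity is used because synergy vectors are zero-inflated and the
cosine depends only on the nonzero structure's direction.  The
interacting-pair test compares the mean cosine over physical-interaction
edges to the distribution of mean cosines of equally many random distinct
protein pairs (1000 draws; pairs sampled without replacement within a draw,
self-pairs excluded; known-interacting pairs are *not* excluded from the
null — with ~90 proteins and ~120 edges among ~4000 possible pairs the
contamination is negligible).  The p-value comes from a Gaussian fit to the
null means rather than the empirical tail: 1000 draws cannot resolve
probabilities below 0.001, and the null mean is itself an average of many
weakly dependent cosines, so its distribution is close to normal.  Maximal
cliques (≥ 4 proteins, fully pairwise-connected) are enumerated exactly and
verified against brute-force subset enumeration in the tests.

Cross-cell-type comparison restricts to features sufficiently sampled in
the second cell type's reporter pool — at least 2 reporters embedded in the
feature (z > 0.5) — and computes the signed cosine per matched protein; the
null redraws a random without-replacement set of screen proteins to stand in
for the matched ones in each of 1000 draws, and the observed mean is
reported against the null's 95% interval.

## Tumor compartment analysis

Deletions longer than 5 bp are MMEJ-signature when the junctional
microhomology is at least 2 bp and NHEJ-signature when it is absent; 1 bp of
homology is ambiguous and such deletions never enter any count, as do
deletions of 5 bp or shorter.  Microhomology is the maximum of the
left-side and right-side junctional homology (longest common suffix/prefix
of the deleted sequence with its flanks), capped at the deletion length —
the convention is isolated in `compute_microhomology` so an alternative
(e.g. right-alignment only) is a one-function change.  Compartment
assignment requires *full containment* in a labeled constitutive LAD
(heterochromatin) or inter-LAD (euchromatin) interval; boundary-spanning
deletions are excluded.  VCF deletions are converted from the 1-based
anchor-base convention to 0-based half-open coordinates on read; BED is
consumed natively.

Case samples carry a loss-of-function driver in exactly one of the genes of
interest and pass three cleanliness filters (no independent repair
deficiency, no treatment-associated mutational signature, ≥ 500 genome-wide
substitutions — the latter a proxy for adequate coverage and purity);
controls pass the same filters with no GOI driver of any kind.  A gene is
analysed only with ≥ 5 cases of which ≥ 3 share a cancer subtype.  Datasets
of one subtype are kept as separate strata because their baseline balances
differ measurably.

Counts are pooled over the samples of a group (pooling, not per-sample
averaging, because signature deletions are sparse per genome), and the
statistic is Δ = log₂(MMEJ/NHEJ)_Het − log₂(MMEJ/NHEJ)_Eu.  If any of the
four pooled counts is zero, 0.5 is added to all four (continuity correction,
flagged in the output) — preferred over dropping small strata.  The null is
a bootstrap: each of 1000 draws resamples *as many control samples as there
are cases* (with replacement) and recomputes the pooled statistic, so the
bootstrap distribution is the sampling distribution of a case-sized pool
under the control process; the case statistic is z-scored by the bootstrap
mean and sd.  This sizing is what makes the z-score calibrate to
approximately N(0,1) under the null (resampling the full control-set size
instead would understate the case pool's variance and inflate |z| by
roughly √(1 + n_ctrl/n_case)).  Subtype z-scores are combined per gene with
Stouffer's Z = Σz/√k, transformed to two-sided p-values, BH-corrected
across genes, and called at p_adj < 0.05.  Long microhomology-assisted
deletions (≥ 2 bp homology, 1.4–272.9 kb) are compared between cohorts with
the same bootstrap machinery on the Het:Eu count log-ratio.

## Synthetic data

The generators are pure functions of their seed and parameters.

*Chromatin*: reporters cycle through four states (euchromatin; triple
heterochromatin defined by H3K9me2/3, late replication and LMNB1; H3K27me3
heterochromatin; other), and the 25 features are elevated in their defining
state with a shared block latent term giving within-block correlations
around 0.8, then z-scored.  *Screens*: per condition, replicate and
reporter, total reads are negative binomial with mean 3000 and dispersion
0.2 (amplicon counts are overdispersed relative to Poisson); fixed fractions
0.2 / 0.3 go to a lumped "other" and the intact class (the full indel
spectrum is not modeled); the remaining signature reads split between the −7
and +1 classes with MMEJ probability logistic in (baseline + ln 2 · (γ +
β·features)), so planted γ and β are in log₂ units of the ratio and are
recovered on their own scale.  The baseline MMEJ logit is 0.5 higher in
heterochromatin reporters, reproducing the observation that the MMEJ:NHEJ
ratio is higher there.  Defaults mirror the study design: 519 targeted
proteins, 33 mocks, 19 reporters, 3 replicates.  *Reads*: error-free
amplicons realizing a spectrum exactly; anchors use a G/T alphabet and the
variable window A/C so edits can never create spurious anchor matches.
*Tumors*: an alternating cLAD/ciLAD genome model (10 intervals of 1 Mb per
label); per sample, compartment and class, deletion counts are Poisson with
control means (30/15 MMEJ/NHEJ in Het, 15/30 in Eu — higher MMEJ:NHEJ in
heterochromatin) times a case-effect factor; positions are uniform and fully
contained; lengths are 6 + Poisson(6), MMEJ-class microhomologies
2 + Geometric; 10 cases and 30 controls by default, with metadata passing
the sample filters by construction.

What the generators do *not* emulate: sequencing errors and quality decay,
realistic indel spectra beyond the two signature classes, correlated
chromatin features derived from real epigenome maps, clonal structure of
reporter pools, incomplete knockout penetrance (planted effects are fully
penetrant, so recovered effect sizes are unbiased — in a real screen they
are systematically underestimated), and tumor-genome heterogeneity beyond
Poisson counts.  Passing tests therefore demonstrate the *statistical
machinery* is correct and calibrated, not that real-data effect sizes will
match.

## Problem sizes and numerics

The test suite and acceptance script run screens of 100 conditions (67
targeted + 33 mocks) for calibration and 30-condition screens for recovery,
200 (tests) or 100 (script) null tumor cohorts with 500-draw bootstraps, and
1000-draw bootstraps for power runs — sizes chosen so the full suite
completes in well under a minute while leaving the binomial slack of each
calibration check meaningful.  Numerical edge handling: perfect fits report
p = 0 and constant responses p = 1 in both the PC regression and the
per-feature fits; p-values that underflow to 0 are clipped to 1e-300 before
BH; zero-variance mock nulls, all-zero synergy vectors, all-zero count
tables and degenerate bootstraps raise errors rather than returning NaN.

## Known limitations

- The anchor-spacing indel caller does not resolve complex indels or
  reads with sequencing errors inside an anchor.
- Step-1/step-3 significance rules and the PC count are package choices
  bounded by the mock calibration, not uniquely determined by the screen
  design; the mock pass-rate check is the guard rail.
- Cluster memberships from hierarchical clustering depend on linkage
  choices; only the deterministic ordering is guaranteed.
- The tumor analysis consumes precomputed driver and signature flags; it
  does not call drivers or fit mutational signatures.
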