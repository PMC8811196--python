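# Methods

This note documents the models, defaults and design choices behind
`doclinker`, in the spirit of a statistical-methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Compound-class assignment

Formulas are classified on the van Krevelen plane by an *ordered* table
of rectangular regions with half-open `[low, high)` intervals in both
O:C and H:C; the first matching region wins and points matching none
are `unclassified`. The default table is:

| class | O:C | H:C |
|---|---|---|
| lipid | [0, 0.3) | [1.5, 2.5) |
| protein | [0.3, 0.55) | [1.5, 2.3) |
| amino sugar | [0.55, 0.7) | [1.5, 2.2) |
| carbohydrate | [0.7, 1.5) | [1.5, 2.5) |
| unsaturated hydrocarbon | [0, 0.125) | [0.8, 1.5) |
| lignin | [0.125, 0.65) | [0.8, 1.5) |
| tannin | [0.65, 1.1) | [0.8, 1.5) |
| condensed hydrocarbon | [0, 0.95) | [0.2, 0.8) |

Published boundary schemes differ in detail, so the table is *data*,
not code: it can be replaced from YAML/CSV, and all tests treat the
configured table as the single source of truth. Half-open intervals
plus fixed evaluation order guarantee the plane is partitioned — no
point can be double-assigned, which a grid property-test verifies.
Heteroatoms (N, S, P) do not influence assignment beyond their absence
from the two ratios; peaks without an assigned formula are excluded.

## Merging and lignin normalization

The three sequential extractions of one sample are merged by set union
on the full six-element count vector, so a formula detected in several
solvents contributes one peak. Profiles are *peak counts*, never summed
intensities — electrospray intensities are not quantitative across
compounds.

Lignin-like peaks serve as internal control: lignin enters only with
the litter substrate, so variation in its detected count reflects
ionization (charge-competition) artifacts rather than input. Each
class count is divided by the sample's lignin count; a sample with
zero lignin peaks cannot be normalized and is excluded with a warning.
For ordination the normalized profiles are transformed in the fixed
order log(x + 1) → per-class scaling to unit variance → centering
(centering is implied by standardization). The pseudocount of +1
handles zero counts; a column constant after the log step is centered
but not scaled, with a warning. The order "log, then scale/center" is
a documented choice; the transformation wording in the source
literature is ambiguous on order.

## Community preparation

Taxonomy-confidence retention: an OTU is kept only if its kingdom
assignment has 100% confidence and its phylum at least 80%; below the
phylum, a label needs at least 70%. The *effective rank* is the deepest
rank whose label and all shallower labels pass; sub-cutoff labels are
retained for display but flagged unusable (an OTU with family 90% and
genus 67% resolves to family).

Rarefaction draws each sample to a fixed depth (defaults 1,023 reads
for bacteria, 2,032 for fungi) *without replacement* — a multivariate
hypergeometric draw per sample — so row sums are exact and no count
increases. Samples below depth are dropped (the conservative
convention) with a warning. A single seeded draw is used rather than
averaging repeated rarefactions; the seed is recorded in the run
manifest.

## Consensus taxon selection

*Random forest.* 50 iterations; each fits a 100-tree
`RandomForestRegressor` of DOC on OTU counts using a random 80% of
samples drawn without replacement; impurity importances are averaged
and divided by the maximum, so scores lie in [0, 1] with the top taxon
at 1.

*Neural network.* Features are standardized; a single holdout test
split (25%) scores `n_search = 10` random draws of hidden-layer size
({10, 15, 20, 25}), learning rate and L2 coefficient for a one-hidden-
layer perceptron (logistic hidden activation, identity output, Adam),
each trained with early stopping once validation MSE fails to improve
over 10 epochs. The winning configuration is refit 5 times on the full
data from different initializations and the signed importance is the
restart-averaged connection-weight product `W_in @ w_out`, normalized
by its maximum absolute value. Restart averaging matters: irrelevant
features receive weight products with random signs across refits and
cancel, while genuinely associated features keep a stable sign; the
sign convention is positive = more abundant at high DOC. A
permutation-importance alternative (magnitude from permutation
importance, sign from the feature–response rank correlation) is
available behind `method="permutation"`. With fewer samples than
hidden nodes the layer is shrunk with a warning.

*Indicator species analysis.* Cohorts come from a median split on DOC
(bottom ⌈n/2⌉ low, top ⌊n/2⌋ high; 125 samples give 63/62; other
quantile pairs exclude the middle). For OTU *i* and cohort *g*,
specificity `A = mean_g / (mean_high + mean_low)` uses abundances and
fidelity `B` is the fraction of the cohort's samples with count > 0;
the group-equalized statistic is `sqrt(A·B)` (the classic `A·B`
product is available behind `sqrt_form=False`). Significance is by
label permutation with the +1 correction,
`p = (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm)`; small tables can
enumerate every distinct labeling exactly.

*Consensus.* RF and NN selections default to the cutoff-free rule
"importance above the mean of the nonzero (absolute) importances",
overridable with explicit cutoffs in [0, 1]; IS selection is
`p < 0.05`. The consensus set is the three-way intersection, which is
by construction a subset of each method's selection and shrinks
monotonically as any cutoff rises. The published analyses this
mirrors do not state numeric RF/NN cutoffs, so the mean-of-nonzero
rule is a documented stand-in and the package's accuracy claims rest
on synthetic parameter recovery, not on cutoff values.

## Statistics

Spearman rho is the Pearson correlation of mid-ranks; for n ≤ 9 the
two-sided p-value is exact by enumerating all orderings, otherwise the
t-approximation with n − 2 degrees of freedom is used. Constant
vectors are an error (rho undefined).

PERMANOVA uses the sums-of-squares identity on squared distances:
`SS_total = Σ_{i<j} d²_ij / n`, `SS_within` analogously within groups,
`F = (SS_between/(g−1)) / (SS_within/(n−g))`, `R² = SS_between /
SS_total`; ANOSIM uses `R = (r̄_between − r̄_within)/(M/2)` on
mid-ranked distances, `M = n(n−1)/2`. Both take explicit seeds, use
the +1 permutation correction, and can enumerate all labelings
exhaustively at small n. They are implemented in-package because the
tests require seed-reproducible permutation p-values and exact
enumeration; the test suite cross-checks the statistics against
scikit-bio's implementations.

The default cohort comparison runs on Jaccard distances of merged peak
presence/absence; Bray–Curtis on normalized class counts is available.
The metric choice is exposed, not asserted as the original study's.

PCA is by SVD of the centered matrix with a fixed sign convention (the
largest-|loading| element of each component is positive), making
biplot coordinates reproducible across LAPACK builds.

Network edges keep taxon–class, taxon–DOC and class–DOC Spearman
correlations with raw p < 0.05 by default, mirroring the per-class
reporting convention of the analyses this package reproduces;
Benjamini–Hochberg adjustment is available and recorded in the run
manifest when used. The consistency rule per taxon is
`sign(rho(taxon, class)) · sign(rho(class, DOC)) == +1 for high-DOC
indicators, −1 for low-DOC indicators`; all eight sign/cohort
combinations are covered by a truth-table test.

## Synthetic-study generator

The generator's defaults define the study conditions used throughout
the tests and the acceptance script:

- **Design**: 125 samples; DOC from an equal two-component normal
  mixture, N(8, 6²) and N(45, 6²) mg C/L (clipped at 0.5), giving the
  bimodal high/low design; cohorts are the top/bottom halves by DOC.
- **Chemistry**: per-class peak counts are Poisson with expectation
  `base + slope · z(DOC)` floored at 0 (clamping warns); defaults
  protein 60 + 35z, lipid 40 + 18z, amino sugar 25 + 10z, carbohydrate
  50, tannin 60 − 12z, condensed hydrocarbon 40 − 6z, unsaturated
  hydrocarbon 30 − 4z, unclassified 50 − 3z. The slopes sum positive:
  high-DOC samples are peak-richer overall, which is what drives
  charge competition. Formulas are drawn uniformly inside each class's
  boundary region (with re-checking after integer rounding), so
  downstream classification recovers the planted counts exactly; each
  sample's formulas are split across three solvents with ~20% overlap
  to exercise de-duplication.
- **Lignin artifact**: true lignin input is Poisson(80) independent of
  DOC; the *detected* count is inflated by
  `1 + crowding_strength · T_ref / T_sample`, where `T_sample` is the
  sample's non-lignin total and `T_ref` its expected value at mean
  DOC. With `crowding_strength = 1` detected lignin anti-correlates
  with DOC; at 0 the artifact vanishes and detection is flat.
- **Communities**: 500 bacterial and 150 fungal OTUs; expected
  abundance `exp(a_i + β_i z)` with gamma heterogeneity of variance
  0.3 (an overdispersed, negative-binomial-like null, the standard
  model for amplicon counts) and multinomial sampling to a library
  size uniform in 2,500–6,000 (at or above both rarefaction depths).
  Ten planted taxa (5 positive, 5 negative, β = ±1 per DOC SD) are
  given elevated baseline abundance (log-abundance ≈ 1.5 vs 0 for
  nulls) so they are detectable after rarefaction — deliberately
  strong, clean effects: recovery failures then indicate method
  defects, not underpowered simulation. Planted taxa always receive
  full-confidence taxonomy; the confidence filter is exercised by null
  OTUs (5% sub-threshold at kingdom, 5% at phylum, 15% at a lower
  rank).

What the generator does *not* emulate: compositional correlations
among taxa, phylogenetic structure, m/z measurement noise and
formula-assignment errors, batch effects, or nonlinear taxon–DOC
response shapes. Passing recovery tests therefore demonstrates that
the chain detects monotone planted structure at realistic scale and
noise — not that it would attain the same sensitivity on real
communities.

## Problem sizes and numerics

The acceptance-level checks run at the default scale: parameter
recovery over 10 generator seeds (plus 20 seeds for class–DOC sign
recovery), permutation tests at 999 permutations (199 in calibration
sweeps, which pool ≥1,000 null datasets), and IndVal oracle
equivalence over 200 exhaustively enumerated small tables. Permutation
comparisons use a 1e-12 tolerance when counting `stat_perm ≥ stat_obs`
to keep ties stable in floating point. All stochastic stages take
explicit seeds; the pipeline manifest records every seed and method
decision needed to re-run an identical analysis.

## Known limitations

- The boundary table is a representative stand-in for the cited
  classification scheme, not a reproduction of unpublished values.
- NN importances depend on the search budget; very small budgets give
  noisier signs (mitigated, not removed, by restart averaging).
- PERMANOVA here is one-factor only, with no dispersion diagnostics:
  a significant result can reflect location or spread differences.
- Edges filtered at raw p < 0.05 inflate the family-wise error across
  the network; use the BH option when edge count itself is the claim.
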