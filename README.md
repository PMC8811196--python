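# doclinker

Linking soil microbial community composition and dissolved organic
matter chemistry to dissolved organic carbon (DOC) concentration.

In litter-decomposition microcosms, the DOC that remains in solution is
the carbon pool most likely to be stabilized in soil or lost to
respiration, and both its amount and its molecular makeup are shaped by
the microbial community. `doclinker` implements the inference chain for
studies that measure, per microcosm: DOC concentration (mg C/L),
FTICR-MS peak lists with assigned molecular formulas (C/H/O/N/S/P), and
16S/28S amplicon OTU tables with RDP-classifier taxonomy confidences.
It is aimed at microbial ecologists and biogeochemists who want the
full chain — chemistry profiling, taxon selection, statistics and the
correlation network — as tested, scriptable components rather than a
one-off analysis notebook.

## What it computes

**Compound-class profiling.** Each assigned formula is placed on the
van Krevelen plane (H:C vs O:C molar ratios) and assigned to one of
nine classes (amino sugar, carbohydrate, condensed hydrocarbon, lignin,
lipid, protein, tannin, unsaturated hydrocarbon, unclassified) by an
ordered, half-open boundary table. Peaks from the three sequential
extractions (water, methanol, chloroform) are merged so each distinct
formula counts once. Because lignin enters the system only with the
plant litter and its apparent detection tracks electrospray charge
competition, per-class peak counts are normalized by the lignin count
(lignin as internal control), then log-transformed, scaled and centered
for ordination.

**Consensus taxon selection.** Three routes flag DOC-associated OTUs,
and only taxa identified by all three are reported:

- *Random forest*: importances averaged over 50 forests, each fit on a
  random 80% subsample, max-normalized so the top taxon scores 1.
- *Neural network*: one hidden layer (15 sigmoid nodes, linear output)
  with randomized hyperparameter search and early stopping; signed
  importance from the connection-weight product
  `sum_h w_ih * w_ho ∈ [−1, 1]` (positive = more abundant at high DOC).
- *Indicator species analysis*: samples split into high/low DOC
  cohorts; per OTU and cohort `IndVal_g = sqrt(A_g · B_g)` where A is
  specificity (share of mean abundance in the cohort) and B fidelity
  (occupancy within the cohort), with a label-permutation p-value.

**Statistics and network.** Spearman correlations (exact permutation
p for n ≤ 9), one-factor PERMANOVA and ANOSIM with seeded permutation
nulls, PCA biplot coordinates, and a taxa–compound–DOC Spearman edge
network with a sign-consistency check: a taxon assigned to the low-DOC
cohort should correlate with a compound class in the direction opposite
to that class's correlation with DOC.

**Synthetic studies.** A seeded generator produces complete studies
(DOC mixture, class-consistent FTICR peak lists with the lignin
crowding artifact, overdispersed OTU tables with planted taxa, taxonomy
with sub-threshold confidences) so every stage is testable by parameter
recovery.

## Worked example

Run the full pipeline on a synthetic study (125 samples, 500 bacterial
and 150 fungal OTUs, 10 planted DOC-associated taxa):

```
$ doclinker run --synthetic-seed 7 --out demo_run
PERMANOVA F=10.11 R2=0.076 p=0.001; ANOSIM R=0.794
bacteria: 10 consensus taxa
fungi: 7 consensus taxa
```

The high- and low-DOC cohorts carry distinct compound composition
(PERMANOVA on Jaccard distances of merged peak presence, p = 0.001),
and consensus selection recovers the planted taxa. Per-class DOC
correlations (`demo_run/doc_class_correlations.tsv`):

```
class     rho      p         n
protein   0.926    7.0e-54   125
lipid     0.876    7.3e-41   125
tannin   -0.621    1.1e-14   125
...
```

protein-like compounds rise with DOC and tannin-like compounds fall —
the planted chemistry. The per-OTU score table
(`demo_run/bacteria_feature_scores.tsv`) mirrors the reporting format
of consensus-taxon tables:

```
otu      rf_importance  nn_importance  indval_stat  indval_p  indval_group  consensus
B_OTU_3  1.000          0.956          0.939        0.001     high          True
B_OTU_2  0.276          1.000          0.922        0.001     high          True
...
```

and `demo_run/consistency.tsv` confirms that every selected taxon's
cohort assignment agrees with the sign of its protein correlation
(`consistent = True` throughout). `demo_run/network.sif` and
`network_edges.tsv` hold the correlation network for external
renderers.

Other entry points: `doclinker simulate` (write a synthetic study to
disk), `doclinker indval` (indicator species analysis alone),
`doclinker classify-peaks` (van Krevelen class assignment for a peak
list), or the library API (`doclinker.chem`, `doclinker.community`,
`doclinker.feature_select`, `doclinker.stats`, `doclinker.network`,
`doclinker.synthetic`).

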