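# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic cohort does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Clinical feature extraction

Time is an integer day grid, 0-based from admission; every window is
inclusive on both ends, matching one-day EMR resolution.  Each case carries
exactly one diagnosis code; multi-morbidity is out of scope.

*Disease signatures.*  The pre-treatment values of a test for a case are the
results dated no later than the case's **earliest** prescription start;
same-day results count because a diagnosis typically precedes the first
order on the same calendar day.  Cases with no prescriptions contribute all
results.

*Drug signatures.*  Per prescription episode, the change value `F` is the
signed difference over the time-ordered pair of in-window results with the
largest absolute difference.  The sign is kept deliberately: two drugs that
move the same analyte in opposite directions should look dissimilar.  When
an equal-magnitude rise and fall tie, the rise is reported (an arbitrary but
fixed convention).  Episodes with fewer than two in-window results carry no
information about change and are skipped.  The window is the episode's
`[start_day, end_day]` with no wash-out lag, consistent with the one-day
grid.

*Cohort filters.*  Cases with more than 5 distinct prescribed drugs are
dropped before drug–drug similarity (polypharmacy confounds attribution);
disease-side tests require pre-treatment coverage of ≥ 40% of cases;
drug-side tests require ≥ 30% of drugs to have a qualifying episode and
more than 1,000 qualifying episodes overall.  All four thresholds are
parameters (`FilterParams`), because the episode-count floor in particular
is a property of cohort scale, not of the method.

## Similarity construction

Wilcoxon rank-sum p-values compare two distributions per pair and test; a
*large* p-value (failure to distinguish) is read as similarity.  The
opposite reading is expressible by passing the other direction flag to
`rank_normalize`, which is the single place the convention lives.  Exact
enumeration of the rank-sum null is used for combined samples ≤ 12 without
ties; otherwise the tie-corrected normal approximation.  Groups below
`min_group = 5` observations per side are treated as unavailable rather
than unstable: the pair scores 0 and does not occupy a rank.

Rank normalization divides the tie-averaged rank (most similar highest) by
the number of *scored* pairs, so the most similar pair is exactly 1 and
unavailable pairs do not dilute the scale.  It is invariant under strictly
monotone transforms of the raw scores, which is the property that makes
p-values from heterogeneous tests commensurable.  Aggregation across tests
(and across the two genomic measures) is a cell-wise maximum with the
winning measure recorded per cell; ties go to the lexicographically
smallest label.  Max-aggregation means a single colliding test can award a
high similarity to an otherwise dissimilar pair — visible in practice as
occasional high-ranked false positives — but it is what lets one decisive
shared signature surface from many uninformative tests.

## Genomic similarities

Modules are seed genes plus first PPI neighbors.  The "normalized overlap"
is the overlap coefficient `|A∩B|/min(|A|,|B|)` (Jaccard is available
behind a flag).  Significance comes from an empirical null that redraws
both seed sets, size-matched, uniformly from the gene universe (PPI nodes ∪
seed genes) and rebuilds modules — size is the only preserved invariant; a
degree-preserving null is not attempted.  Add-one smoothing
(`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`) keeps p strictly positive.  The
default 1,000 permutations put the resolution floor at ~1/1001.

Resnik similarity is defined between terms (IC of the most informative
common ancestor after true-path propagation; IC in nats, IC(root) = 0);
the lift to gene sets is the symmetrized best-match average, a standard
choice the measure itself does not dictate.  Genes or sets without usable
annotations are unavailable, not zero-scored, so they fall out of the
ranking rather than distorting it.

## Scoring and fusion

`w(s_p) = ln(1 + D(s_p)) / ln(1 + D_max)` is a saturating degree weight in
`(0, 1]`: drugs with many indications are up-weighted as more "mobile"
across diseases, but logarithmically, so a hub cannot dominate by degree
alone.  The transfer is multiplicative (`w · Sim_S · Sim_T`, maximized over
known indications), the simplest form that stays in `[0, 1]` and reduces to
pure similarity transfer at `w = 1`.  A known indication never supports its
own score.

The fusion `f = P_c + 0.8 · P_g · cos((π/2)(P_c − P_g))` satisfies, by
construction: range exactly `[0, 1.8]` with the maximum at
`P_c = P_g = 1`; strict monotonicity in `P_c` over the whole unit square
(the cosine term's slope is bounded below 1 there); and a genomic bonus
that is granted in full only when the channels agree and is smoothly
discounted as they diverge.  The coefficient 0.8 is fixed by the upper end
of the range.  Note the deliberate asymmetry: `f` is *not* monotone in
`P_g` everywhere — raising a genomic score away from agreement with a low
clinical score can lower `f`.  The clinical channel is the primary signal;
genomics corroborates.  θ defaults to 0.9; `cross_validate` reports
sensitivity/specificity at θ so it can be re-chosen for a target operating
point (F1-maximization over a θ grid is a one-liner on the CV output).

## Evaluation

Cross-validation partitions the known indications into k = 10 seeded folds.
Held-out edges are removed from the network *before* degrees and weights
are computed, so no information leaks through `D(s_p)`.  AUC uses all
never-indicated pairs as negatives — exhaustive, hence deterministic given
the fold split.  The pooled AUC is the fold-size-weighted mean of fold
AUCs, which keeps it inside the fold range by construction.  One subtlety
of this no-leakage design: removing a held-out edge lowers its own drug's
degree and weight, which depresses held-out scores slightly relative to
negatives.  With real signal the effect is negligible; on a null cohort it
shows up as a pooled AUC a few points *below* 0.5 (≈ 0.41 at the default
scale), which is expected, not a bug.

The guilt-by-association baseline is deterministic and unscored: for
every disease pair sharing an indicated drug, each drug indicated for
exactly one of the two is predicted for the other.  Enrichment of a
prediction set against an external catalog is an upper-tail hypergeometric
test.  Matrix clustering is average-linkage agglomeration on
`1 − similarity` with entities pre-sorted lexicographically so that
equal-distance merges are reproducible.

## The synthetic cohort

The generator plants the exact structure the method assumes: matched drug
and disease classes (default 4 × 5/5), class-c drugs indicated for class-c
diseases, 10% of true indications withheld for recovery measurement, and a
seed fully determining every draw (three independent RNG streams for EMR,
genomics and network, so the genomic draws do not shift when only lab
parameters change).

*Clinical side.*  Per (class, test) baselines and per (drug-class, test)
treatment shifts are drawn as `effect_size` (default 1.5) × `noise_sd`
(default 1) × standard normal; case values add unit noise.  Each case stays
14 days, is prescribed 1–3 drugs in non-overlapping windows
([2,4], [6,8], [10,12]) so each episode's change is attributable to one
drug, and carries two pre-treatment results per test (days 0–1) plus one
result at each window edge.  Defaults (1,000 cases, ~2,000 episodes) are
chosen so the verbatim cohort filters — including the >1,000-episode floor —
are exercised rather than bypassed.

*Genomic side.*  Each class owns a 24-gene pool wired densely inside
(p = 0.25) and sparsely to the rest (p = 0.01) over a 136-gene universe; a
two-level ontology gives each class its own branch.  An entity's 8 seed
genes come from its class pool with probability
`class_purity · min(1, effect_size / 1.5)` and uniformly otherwise, and a
gene's annotation lands on a random branch with probability
`annotation_noise`.  The defaults `class_purity = 0.65` and
`annotation_noise = 0.25` deliberately make the genomic channel noisier
than the clinical one: curated gene sets and annotations are incomplete and
error-prone in exactly this way, and the regime of interest for the method
is the one where clinical signatures add information over genomics alone.
At `effect_size = 0` the seed draws become uniform and the lab structure
vanishes, so the whole cohort is exchangeable and recovery collapses to
chance on both channels.

*What it does not emulate.*  Longitudinal disease progression,
pharmacokinetics, correlated test panels, missing-not-at-random lab
ordering, multi-morbidity, dose, or anything at real-registry scale.
Passing tests on this cohort show the pipeline recovers structure *of the
kind the model assumes* when it is present and finds none when it is
absent; they say nothing about effect sizes in hospital data.

## Problem sizes and determinism

Default study conditions: 20 drugs × 20 diseases, 100 true edges (90
emitted), 1,000 cases, 6 tests, 1,000 permutations per pair, 10-fold CV.
A full pipeline run takes ~10 s on one core; the multi-seed robustness
checks in the test suite use 10 seeds at these conditions and a
scaled-down cohort (3 entities per class, 15 cases per disease, 100
permutations, 5 folds, episode floor lowered to match the scale) for the
effect-size sweep.  All randomness flows from explicit integer seeds
(NumPy `default_rng`); pair enumeration, file rows and tie-breaks are
sorted, so repeated runs are byte-identical, which the test suite checks
end to end.

## Known limitations

- Max-aggregation admits single-test collisions (see above); with few
  tests and many pairs, some cross-class pairs reach high rank.
- The permutation null preserves seed-set size only, not degree; hub-heavy
  seed sets are anti-conservative against it.
- The no-leakage holdout slightly biases null AUC below 0.5 (quantified
  above).
- `θ = 0.9` is a ranking convenience at synthetic scale, not a calibrated
  decision threshold; precision at θ depends entirely on class structure
  and cohort size.
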