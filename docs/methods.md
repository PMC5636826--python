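# Methods

## Model and assumptions

The package treats amyloidogenicity as a property of short windows: a
peptide is amyloid iff at least one of its 6-residue windows is
amyloidogenic. Three assumptions follow. (i) Six residues is the
minimal hot-spot length, so every peptide of length ≥ 6 is fully
described by its L − 5 overlapping hexapeptides, each inheriting the
peptide's label. This labelling is noisy for long amyloid peptides —
windows outside the true hot spot are still labelled positive — which is
why curated training sets are capped at 25 residues and stratified into
6, 6-10 and 6-15 ranges. (ii) The signal lives at the level of
physicochemical groups rather than exact residues, so sequences are
rewritten over a reduced alphabet (a partition of the 20 amino acids)
before feature extraction. (iii) Motifs are position-free within a
window and may be gapped, so features are binarized occurrences of
n-gram patterns, not counts or positions.

## Reduced alphabets

Candidate alphabets are produced by agglomerative Ward clustering of
the 20 amino acids in the space of a chosen subset of property scales.
Numerical choices:

- **Normalization**: each property column is min-max scaled to [0, 1]
  over the 20 amino acids before clustering (z-scoring is available via
  `scale="zscore"`). Min-max is the default because the property scales
  have wildly different units and bounded support is the least
  structured assumption.
- **Ward dialect**: scipy's `linkage(method="ward")` on the normalized
  observation matrix, i.e. squared-Euclidean Ward (the Ward.D2 variant);
  the dialect matters because the two classical Ward implementations can
  produce different trees, so it is recorded in the encoding's
  provenance.
- **Cut**: `fcluster(..., criterion="maxclust")` to exactly k clusters;
  scipy's deterministic merge ordering breaks ties in merge heights, so
  a given table and subset always yield the same partition.
- **Degenerate inputs**: a subset in which fewer than k distinct
  property vectors exist raises rather than returning empty groups; a
  constant column is rejected at the correlation-pruning stage (its
  correlation is undefined).

Correlation pruning keeps properties greedily in column order, dropping
any property with |Pearson r| ≥ 0.95 against an already-kept one. The
choice of which member of a correlated pair survives is not
scientifically meaningful (the two encode the same axis); column order
makes it deterministic and auditable.

Encodings are compared with a pair-counting similarity: the fraction of
the 190 unordered residue pairs classified concordantly (together in
both partitions or apart in both). It is 1 exactly for identical
partitions and 0 for the maximally discordant pair (singletons vs one
lump). The measure is pluggable because several alphabet-similarity
measures exist in the literature and none is canonical.

## n-gram feature space

Templates are fixed: 1-grams; 2-grams with a gap of 0-3 wildcards;
3-grams contiguous or with a single 1-position gap after the first or
second symbol. All template spans fit a 6-residue window, giving
m + 4m² + 3m³ features for an m-group alphabet. Gapped 3-grams with
longer gaps are deliberately excluded: including them would break the
closed form that pins the feature space to 120/260/480/798 features for
m = 3..6, which is the framework's defining enumeration. Occurrence is
binarized — a feature present twice in a window still scores 1 — because
the windows are too short for counts to carry reliable extra signal.

## QuiPT

For binary feature f and binary target t, the permutation distribution
of any 2×2-table statistic given the margins (n, n_f1, n_t1) is the
hypergeometric law of the joint count n_11. The exact permutation
p-value is therefore the hypergeometric mass of all achievable joint
counts whose statistic reaches the observed one — an O(min(n_f1, n_t1))
summation instead of an exponential enumeration, with no Monte-Carlo
error. The statistic defaults to information gain (mutual information in
bits) and is pluggable.

Numerical choices: hypergeometric probabilities come from scipy's
`hypergeom.pmf`, which works internally through stable log-Γ
accumulation; statistic ties are compared with an absolute tolerance of
1e-9 so analytically equal gains (e.g. the two tails of symmetric
margins) are never split by float round-off; if every achievable table
qualifies the p-value is returned as exactly 1. The p-values are
discrete and therefore conservative under the null — selection rates at
α = 0.05 run below 5%, never above.

Selection uses raw p < α (strict), matching the framework's original
usage; Benjamini-Hochberg is available (`correction="bh"`) but not the
default, since per-fold refit inside cross-validation already guards
against selection optimism where it matters. In `score_features` the
p-value for each distinct (n_f1, n_11) pair is computed once and cached,
since margins are shared by all features of a matrix.

## Classification and aggregation

The forest uses 500 trees and mtry = ⌊√#features⌋ (the standard
random-forest defaults for this problem class), a mandatory seed, and
out-of-bag scoring. A hexapeptide's probability is the fraction of
trees voting amyloid — hard votes, not averaged leaf frequencies — so
the score has an exact interpretation and is portable across forest
implementations. The peptide score is the maximum over its
hexapeptides: the binary "at least one amyloidogenic window" rule
defines only a call, but ranking metrics need a score, and the max is
the unique aggregation whose thresholding reproduces the binary rule at
every threshold. A score exactly equal to the threshold counts as
amyloid (the boundary must land somewhere; this choice is asserted in
tests). Raising the threshold can therefore never turn a negative call
positive.

## Cross-validation and encoding ranking

Folds partition peptides, never hexapeptides — all windows of a peptide
share its fold, otherwise near-duplicate windows would leak across the
split. QuiPT selection is refit inside every training part for the same
reason. Fold assignment is uniform over peptides (not class-stratified;
stratification is left to the caller because the reference protocol
randomizes plainly), and because longer peptides contribute more
hexapeptides, fold sizes in hexapeptide terms vary — the motivation for
repeating the 5-fold split (15× by default) and averaging.

Per fold, metrics are computed per test length stratum (6, 7-10, 11-15,
16-25, plus "all"); an optional held-out long-peptide set is split into
the same five folds and evaluated alongside, never trained on. Strata
with a single class in a fold are flagged degenerate and excluded from
aggregation, with counts retained. AUC is the rank-based (Mann-Whitney)
estimator with midranks, so it is invariant under monotone score
transforms. MCC and sensitivity/specificity with zero denominators
yield flagged nulls, never silent zeros.

Encodings are ranked per stratum by mean AUC (rank 1 = best, midranks
for ties); the winner minimizes the rank sum across strata, with
rank-sum ties broken by grand-mean AUC. Two classic 5-group alphabets
and the full 20-letter alphabet ship as named baselines.

Edge cases: a fold whose training part is single-class triggers a
resampled assignment within the repeat (logged); if QuiPT selects
nothing at α in a training part — which occurs on effectively null
data — the single smallest-p feature is used so the forest remains
fittable, and the event is logged.

## Benchmark harness

External predictors are compared on their own score files. Raw scores
are min-max normalized to [0, 1], with a sign flip first for tools whose
lower scores mean more amyloidogenic (e.g. energy-based methods), and
each tool's published decision threshold undergoes the identical
transform. AUC is unaffected (monotone invariance); the confusion
metrics then reflect each tool's own operating point. Min-max is used
because the reference protocol normalized energy outputs without
specifying a transform, and min-max is the least committal monotone map
onto the unit interval.

## Synthetic data generator

The generator emulates the *statistical* structure the pipeline
assumes — nothing biophysical. Positives carry a group-level n-gram
motif; the motif's symbols are realized by sampling concrete residues
uniformly from their groups; all other residues come from a background
distribution over groups (uniform over the 20 residues by default; a
hydrophobicity-skewed preset exists). Occurrence is controlled exactly:
carrier status is Bernoulli(p_pos) for positives and Bernoulli(p_neg)
for negatives, carriers get the motif planted at a uniform admissible
offset, and non-carriers are rejection-sampled until no accidental
occurrence remains. Ground truth goes to a sidecar table, never into
FASTA headers.

Defaults (fixed once, before any end-to-end measurement): 200 + 200
peptides; p_pos = 0.9, p_neg = 0.1; the default motif is a contiguous
run of three subgroup-III (I/L/V) symbols of the built-in best
encoding — hydrophobic repeats being the reported amyloid signature;
peptide lengths mirror the empirical mix of 6-15-residue curated
training data (81.5% length 6, 14.1% lengths 7-10, 4.4% lengths 11-15).

What passing tests on this generator do and do not show: they verify the
machinery end to end — that a real group-level motif is found, ranked
first by QuiPT and converted into peptide-level discrimination — but
real amyloid data have correlated residues, composition biases, multiple
interacting motifs and label noise that the generator does not emulate,
so synthetic AUC values say nothing quantitative about benchmark
performance on curated data.

A useful closed form for calibration: when scores depend on the data
only through motif presence, the peptide-level AUC is bounded by
p_pos·(1 − p_neg) + ½·(p_pos·p_neg + (1 − p_pos)(1 − p_neg)); at the
default 0.9/0.1 contrast this ceiling is 0.90, and the pipeline reaches
≈ 0.88 — i.e. ≈ 98% of the information-theoretically achievable
discrimination, with the gap being forest estimation noise.

## Problem sizes

The shipped tests and the acceptance script run entirely on
synthetic/enumerative inputs: configuration counting at P = 17,
feature-space generation at m ≤ 8, exact-test validation against brute
force at n ≤ 10, type-I calibration on 100 null matrices of 200 × 100,
and end-to-end recovery over 20 seeds of 400-peptide sets with
single-repeat 5-fold CV. These sizes were chosen as the smallest at
which the checked properties are statistically meaningful.

## Known limitations

- The exact AAIndex property lists behind published alphabet searches
  are not bundled; the shipped example table holds five classic scales
  for demonstration, so a user reproducing a full search must supply
  their own property CSV.
- QuiPT is strictly binary × binary; continuous features are out of
  scope.
- The hexapeptide labelling assumption mislabels non-hot-spot windows
  of long amyloid peptides; performance on 16-25-residue peptides is
  accordingly the weakest regime.
- Prion-like sequences follow different physicochemical rules and are
  outside the model's intended domain.
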