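# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `coikit`. It describes what the code computes; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes itself.

## Quality control

Three screens run in sequence, each producing per-record reports that merge
into one QC table:

1. **Length.** A record must carry at least `min_length` non-gap characters
   (default 600, i.e. ≥90% of the 664-column barcode region). Ambiguity codes
   count toward length; only gaps do not.
2. **Reading frame and internal stops.** The frame offset ∈ {0, 1, 2} is the
   one minimising the total count of in-frame stop codons across all records
   (ties break to the smallest offset — frame estimation is global because
   all records share one alignment). A record fails if any *complete* codon
   before its final complete codon is a stop under the configured genetic
   code (default NCBI table 2, vertebrate mitochondrial: TAA, TAG, AGA, AGG).
   Codons containing a gap or ambiguity code cannot be called and are
   skipped — conservative, avoiding false flags on ambiguous reads. The
   terminal codon is exempt because a trailing stop is legitimate.
3. **Divergence outliers.** A record whose minimum distance to every other
   record exceeds `outlier_cutoff` (default 0.35 K2p) is flagged; undefined
   (saturated) distances count as exceeding any cutoff. The 0.35 default is a
   configurable stand-in for "suspiciously high": genuine conspecific or
   congeneric relatives sit far below it, while NUMTs and contaminants
   typically have no close neighbour at all.

Identification status is taken from the metadata `status` column when
present, else inferred from the species label: the tokens `sp.` or `aff.`
(case-insensitive, whole-token match) mark a candidate species.

## Distances

Site comparisons use **pairwise deletion**: for each pair, only columns where
both sequences have A/C/G/T are comparable. This preserves information when
record lengths are heterogeneous; the alternative (complete deletion) would
discard columns globally for every gap anywhere. Transitions are mismatches
within a chemical class (A↔G, C↔T), everything else is a transversion.

K2p distances use the closed form d = −½ln(1−2P−Q) − ¼ln(1−2Q). When either
log argument is ≤ 0 the distance is **undefined (NaN)**, propagated
explicitly: undefined pairs are excluded from averages with a warning, and
neighbor joining refuses matrices containing them. Nothing is silently
imputed — saturation is a finding, not a nuisance.

Distances are kept at full precision internally and formatted as percentages
with one decimal only in user-facing tables.

## Neighbor joining and bootstrap

NJ follows the Saitou–Nei scheme with the Studier–Keppler criterion
Q(i,j) = (m−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k). Determinism: the pair
minimising Q with ties broken by smallest (i,j) in the current label order
(row-major argmin); permuting the input labels permutes the tree but leaves
its bipartition set unchanged (tested). Negative branch-length estimates are
clamped to 0 without redistributing the difference — display-safe and
topology-neutral. Trees are unrooted; the terminal three-taxon join uses the
exact three-point formulas.

Bootstrap support is the standard Felsenstein procedure: resample alignment
columns with replacement, rebuild distance matrix and NJ tree, and score each
internal edge of the reference tree by the percentage of replicate trees
containing the same bipartition (bipartitions canonicalised as the leaf set
excluding the lexicographically smallest label; replicate topologies are
compared via leaf bitmasks). Replicate r draws from a fresh generator seeded
`seed + r`, so runs are reproducible and trivially parallelisable. A
replicate whose resampled matrix contains an undefined distance is dropped
and counted; if more than 10% drop, the analysis errors rather than report
support computed from a biased replicate subset. Short fragments of deeply
divergent datasets genuinely trigger this (saturation over 100 columns), and
the experiment driver records such conditions as failures instead of scoring
them.

## Monophyly

A group is monophyletic on the unrooted tree iff its leaf set is one side of
a bipartition (convexity). This equals rooted monophyly for any root outside
the group and is invariant to rerooting (tested by rerooting at every edge
against a brute-force edge-removal oracle). The whole-leaf-set group is
monophyletic by convention with support N/A; a group missing a single leaf
corresponds to a pendant edge and likewise reports N/A rather than a
bootstrap value. Groups with fewer than two members are excluded from
scoring, and non-monophyletic groups report support N/A rather than 0.
"Well supported" defaults to bootstrap > 90.

## Species delimitation

* **Sister pairs**: two *nominal* species of the same family whose records
  form a two-leaf cherry with bootstrap support strictly above 70. Both
  orientations of each bipartition are checked, since a cherry containing the
  anchor leaf is stored as its complement.
* **Thresholds**: per family, the unweighted arithmetic mean of sister-pair
  distances, computed separately for K2p and p. Families with no qualifying
  pair get no threshold; their query records are reported as unresolved
  rather than borrowing a global threshold.
* **Lineages**: candidate/unidentified records of a family are merged by
  single-linkage at distances below the family threshold. Single linkage is
  the conservative choice: it prevents double-counting conspecific
  candidates, at the cost of potentially chaining distinct ones.
* **Flagging**: a lineage is a candidate species iff the minimum distance
  from any member to any nominal-species record of the whole dataset exceeds
  the threshold. "Closest relative" is operationalised as the distance-matrix
  nearest neighbour, the simplest reading consistent with distance-threshold
  barcoding practice (not a tree-path distance).
* **Min–max count**: the rule runs under the K2p and p thresholds
  separately; lineages from the two runs are matched by shared members
  (connected components over member overlap). A component flagged under both
  models counts toward the minimum, under at least one toward the maximum.

## Experiments

Subsampling draws species (not records) uniformly without replacement —
`round(fraction × n_species)` of them, half-away-from-zero, floored at 3 —
keeping all conspecific records together. Truncation keeps alignment columns
1..L, preserving the frame offset (the barcode region is a fixed coordinate
system). Each condition × replicate re-runs the full
distance → NJ → bootstrap → scoring chain; failed replicates are logged and
reported while the series continues. Groups reduced to a single member in a
subset are excluded post hoc from that replicate's scores.

The species-uniqueness check reports, for a given prefix length, all record
pairs from different species with zero differences over comparable sites;
pairs with no comparable sites are listed separately as incomparable rather
than counted as collisions.

## Synthetic data generator

The generator emulates what a curated multi-family barcode library looks
like; all depths are in expected substitutions per site.

* **Trees.** Ultrametric. Families attach to a star backbone at height
  `family_depth` (default 0.25, giving ~50% expected between-family
  divergence — deep, as in old vertebrate families). Within a family, genera
  join at 1.10–1.30 × `species_depth` and species within genera at
  0.60–1.00 × `species_depth` (default 0.10, putting within-family means near
  ~22% and the shallowest species pairs above ~12%). Conspecific samples
  coalesce at `intraspecific_depth`/2 (default 0.01 total), an order of
  magnitude below species-level divergence, as in typical COI surveys.
  Join heights are stratified into bands with draws hugging the band
  extremes, which bounds every recoverable internal edge away from zero;
  unconstrained draws frequently place two joins nearly on top of each
  other, making cherry edges unrecoverable by bootstrap and leaving whole
  families without sister pairs. Realized within-family mean paths land
  ~10–20% above 2 × `species_depth`, within the generator's calibration
  band (tested over repeated simulations).
* **Sequences.** Root sequence drawn uniformly over non-stop codons; sites
  evolve independently under the K2p process with ts/tv rate ratio `kappa`
  (default 4, typical for mitochondrial protein-coding genes). After each
  branch, any codon that became an in-frame stop reverts to its pre-mutation
  state, so generated data pass the stop-codon screen by construction. The
  reversion removes a small fraction of substitutions on deep branches —
  a mild downward bias that affects thresholds and query distances alike.
* **Planted candidates.** Each `(family, multiplier)` entry evolves one extra
  record from a random nominal species of that family along a branch of
  `multiplier × expected sister-pair distance` (the mean over that family's
  realized cherries), labels it `unidentified`, and records the multiplier in
  the ground truth. Its nearest nominal neighbour is the source species at
  that expected distance. Validation plants at 2.0× (well above threshold)
  and 0.4× (well below): at the alignment length of 664 the K2p estimator's
  standard error (~0.02 at these depths) makes boundary plantings at exactly
  1.5×/0.5× a coin flip per dataset, whereas the chosen margins separate the
  populations by many standard errors while testing the same rule.
* **Default shape**: 8 families × 4 genera × 3 species (~96–200 records at
  1–2 samples per species). Three-species genera guarantee one cherry per
  genus, so every family has several sister-pair candidates; with 4-species
  genera, a family can lose all its supported cherries to short ladder edges
  and end up without a threshold.

What the generator does **not** emulate: rate variation among sites is off
by default (a gamma-rates option is not included; the analysis model matches
the generating model exactly, which is what makes estimator-consistency tests
sharp), indels and alignment error, NUMTs, codon-position effects, selection,
geographic structure within species, and non-ultrametric rate variation
among lineages. Passing tests therefore demonstrate the correctness of the
pipeline's logic and calibration under its own model assumptions, not
robustness to every artefact of real barcode libraries.

## Problem sizes used in validation

Validation runs are desk-scaled: bootstraps use 50–100 replicates (the CLI
default remains 1000), planted-recovery uses 20 datasets of ~100 records,
subsampling uses 10 subsets per fraction on the default dataset, and the
fragment-length trend pools 10 datasets of 3 families × 2 genera × 3 species
× 2 samples. The smaller fragment-trend datasets keep 100-bp bootstrap
matrices clear of K2p saturation, which large deeply-divergent datasets
genuinely hit at that length.

## Known limitations

* Distance-threshold delimitation inherits the usual caveats: it ignores
  coalescent variance, cannot separate recent species, and thresholds from
  few sister pairs are noisy. The min–max range only reflects model
  disagreement (K2p vs p), not that uncertainty.
* NJ is a point estimate; only bootstrap proportions quantify uncertainty.
* The divergence-outlier cutoff is a fixed number, not an adaptive rule.
* Undefined distances make NJ refuse the matrix rather than attempt repair;
  heavily saturated datasets must be subsetted or analysed at p-distance.
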