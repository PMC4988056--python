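# Methods

## Gene-content dissimilarity

A genome's gene content is represented as an orthologous-gene profile:
for each orthologous group (OG) of a reference catalogue, the number of
genes whose best search hit falls in that group. Hits are read from
12-column tabular search output (BLAST/USEARCH `outfmt 6` dialect) and
retained when `e-value ≤ 1e-5` and `global identity ≥ 30 %`; both
boundaries are inclusive, the conventional reading of "cutoff". Each gene
is then assigned to the OG of its single best surviving hit, with a total
tie-break key (bitscore desc, e-value asc, identity desc, OG id asc) so
assignment is independent of input order and never fractional. Filtering
before best-hit selection and selecting the best hit among filtered hits
coincide whenever the best surviving hit is sought; we filter first and
log the counts. Genomes mapping fewer than 1000 genes (configurable)
carry too little signal and are excluded from the profile table.

Two profiles are compared with weighted Bray-Curtis,
`BC = 1 − 2·C/(S_i + S_j)` with `C` the summed per-OG minima. Counts are
multiplicities, not presence/absence: gene duplication and loss move the
index, which is the point of choosing a weighted index. `BC` is 0 iff
the profiles are identical and 1 iff they share no OG. A pair of empty
profiles is an error, not a sentinel; upstream QC makes it unreachable.
Matrices are stored fully (square TSV with labels, or square PHYLIP);
symmetry is enforced on construction and re-verified on read, with a
1e-12 tolerance.

## Delineation cutoffs

Species and family membership are called at BC < 0.2 and BC < 0.4.
Comparisons are strict (`<`), so a boundary tie is "different" — the
calibration language is "values smaller than the cutoff". Both cutoffs
are configurable; a same-species call always implies a same-family call.
Rank summaries bin the pair values of each rank relation (lowest shared
rank of the pair) over (0, 0.2, 0.4, 0.5, 0.8, 1.0) by default, bins
left-closed with the last bin closed. TPR/FPR at a cutoff are computed
**per pair** (fraction of same-rank pairs below the cutoff, fraction of
different-rank pairs below it); a per-strain reading exists in the
literature but is ambiguous for multi-strain species, so the pair-level
rate is used and stated. Pairs whose taxonomy is blank at the deciding
rank are excluded from that statistic rather than guessed. Self-pairs are
always excluded and pairs are unordered.

## Ordination and MRPP

PCoA follows Gower: eigendecomposition of `−½·J·D²·J`. Coordinates are
eigenvectors scaled by `√λ` for positive eigenvalues only; negative
eigenvalues (non-Euclidean input) are reported as a relative mass
`Σ|λ₋|/Σ|λ|` and excluded, with no Cailliez/Lingoes correction —
Bray-Curtis matrices are mildly non-Euclidean and the uncorrected
embedding is what the standard tools plot. Proportion explained is taken
over the positive eigenvalue sum. Eigenvalues below `n·1e-12·max|λ|` are
treated as zero.

MRPP uses the group-size weighting `w_g = n_g/N` (the default of the R
package this test is conventionally run with; the weighting is not
otherwise dictated). The observed statistic is the weighted mean
within-group distance δ; the null distribution shuffles labels with a
seeded generator; `E[δ]` is the mean permuted δ and `A = 1 − δ/E[δ]`.
The p-value uses the add-one estimator `(1 + #{δ_perm ≤ δ_obs})/(1 + n_perm)`
with inclusive ties (a 1e-12-relative slack absorbs summation-order
noise), so `p ≥ 1/(n_perm+1)` and p = 0 is impossible. Permutation deltas
are computed in one vectorised pass (membership-mask quadratic forms).
Unseeded calls draw a seed and record it in the result; the CLI requires
or records a seed. Species-vs-rest grouping (one-vs-rest) is the default
comparison; any label map can be supplied for one-vs-each designs.

## Sequence-identity indices

Both indices use a built-in affine-gap aligner (match +1, mismatch −1,
gap open −2 for the first gap column, −1 per further column;
deterministic diagonal-first traceback), jit-compiled and intended for
desk-scale sequences — 16S genes, kilobase fragments, toy proteomes — not
multi-megabase production genomes. Identity is always
`matches / alignment columns`, gap columns included (the "global
identity" convention of usearch-style tools).

16S identity is the mean end-to-end identity over **all** cross pairs of
16S copies of the two strains (|A|×|B| alignments), not the best pair.

ANI follows the ANIb/JSpecies recipe: the query is cut into consecutive
non-overlapping 1020-nt fragments (a trailing remainder is discarded and
logged); each fragment is locally aligned to its best location on the
subject; fragments with ≥ 30 % identity over ≥ 70 % of their length are
retained; ANI is the mean retained identity. Zero retained fragments is
a defined failure (reported counts, no value), which is what unrelated
random sequences produce. ANI is directional by default — the underlying
convention is directional — with an explicit symmetric mean exposed. The
local search runs a score-only rolling scan over the full subject to
locate the optimum's end cell, then a traceback DP on a subject window of
`2·|fragment|+8` columns, which provably contains the whole alignment
(every gap column of a positive-scoring alignment is paid for by a
match); a defensive full rescan covers the (unreached) miss case.

## Synthetic cohorts

The cohort generator emulates the statistical structure a rank-stratified
genome collection shows — low intra-species BC, high inter-family BC —
without simulating evolution. Strains are built from nested OG cores
(universal, order, family, genus, species; disjoint OG id blocks) plus
per-strain private accessory genes. For a pair, the shared gene mass is
exactly the mass of the cores below its lowest common rank, so each
relation's BC is controlled directly: core masses are solved from the
midpoints of the designed per-relation BC ranges, private-gene counts are
jittered over the middle half of the feasible interval, and the generator
recomputes the realized matrix and raises if any pair escapes its range
(infeasible designs error out rather than silently drift). Defaults: 2
orders × 2 families × 2 genera × 2 species × 3 strains (48 strains),
~1200 genes per strain (above the 1000-gene QC bar), intra-species BC in
(0.05, 0.18), inter-species (0.22, 0.38), inter-genus (0.28, 0.42),
inter-family (0.45, 0.70), inter-order (0.75, 0.90); one core OG in five
carries two gene copies so the weighting is exercised.

`make_proteomes` lowers a count table to sequence level: one random
reference protein per OG (uniform 20-letter alphabet, length 80–160),
each designed gene an independently substituted copy (rate ≤ 0.5 so
identities stay above the 30 % filter), optional decoy database entries.
The toy search aligns genes against the database behind a shared-4-mer
prescreen (the word heuristic of real search tools) and emits 12-column
hit lines with a Karlin-Altschul-style plausibility e-value — adequate
for threshold plumbing, not a real statistic. Genome pairs for ANI are a
random sequence and a per-site substituted copy.

What passing on these cohorts does **not** show: robustness to annotation
error, incomplete genomes, database bias, indels in proteins, horizontal
transfer of whole islands, or the overlapping rank distributions real
collections have. The separable cohort demonstrates the machinery
(perfect TPR/FPR by construction), not the empirical calibration; the
calibration percentages reported for real multi-thousand-genome
collections require those genomes.

## Problem sizes and numerical choices

Test and demonstration sizes are chosen for the desk: 48-strain cohorts,
~60-gene strains for sequence-level round trips, 51-kb genomes (50 ANI
fragments), MRPP calibration with 500 replicates of 999 permutations at
n = 40. Determinism: every stochastic component takes an explicit seed
(numpy `default_rng`); identical seeds give byte-identical numeric
output. Matrix symmetry and range checks use absolute 1e-12; PCoA
round-trip accuracy is ~1e-8 on well-conditioned inputs. Degenerate
inputs are errors with named offenders (duplicate strain ids, missing
taxonomy entries, empty sequences, non-DNA characters, single-member MRPP
groups, sub-2-strain tables).

## Known limitations

- The built-in aligner is exact but quadratic; production ANI on real
  genomes should come from dedicated tools, whose tabular output the
  profile builder can consume.
- Only COG/NOG-style single-membership assignment is modelled; a gene
  never contributes to several OGs.
- The presence/absence variant of the index is deliberately not provided;
  the weighted form is the method.
- MRPP assumes exchangeable strains under the null; phylogenetic
  autocorrelation within groups is not modelled.
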