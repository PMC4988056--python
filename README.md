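# gcdiss — gene-content dissimilarity for microbial delineation

Sequence-identity indices (16S rRNA identity, ANI) compare conserved
sequence, which saturates among closely related prokaryotes. Gene-content
dissimilarity instead compares *which genes a genome carries, and how many
copies*: each genome is summarised as an orthologous-gene profile — the
number of genes assigned (by best database hit) to each orthologous group
(OG) of a reference catalogue such as eggNOG — and two genomes are compared
with the weighted Bray-Curtis index

```
BC_ij = 1 − 2·C_ij / (S_i + S_j)
```

where `S_i`, `S_j` are the total gene counts mapped to OGs in each genome
and `C_ij = Σ_og min(count_i(og), count_j(og))`. Because counts are gene
multiplicities, duplications and losses — the genomic fluidity that drives
prokaryotic divergence — move the index even when conserved genes are
nearly identical. Calibration on complete-genome collections supports
cutoffs of **0.2** for species and **0.4** for family membership, and the
index resolves notoriously entangled groups (*E. coli*/*Shigella*,
*Yersinia*, *S. mitis*/*oralis*/*pneumoniae*) at sub-species level.

The package is aimed at microbial taxonomists and clinical/environmental
genomics workflows: it turns tabular protein-vs-ortholog-database search
output into profiles, computes pairwise dissimilarity matrices, applies
the delineation cutoffs, and provides the surrounding machinery — rank-level
distribution summaries, principal coordinates analysis (PCoA), the
multi-response permutation procedure (MRPP), mean 16S identity and
fragment-based ANI (ANIb convention) — plus seeded synthetic cohorts so the
whole pipeline can be exercised without downloads.

## Worked example

The two-strain miniature shipped with the package maps 9 and 11 genes onto
five OGs with counts (1, 2, 4, 0, 2) and (1, 4, 2, 2, 2). The shared gene
sum is `min` per OG: 1 + 2 + 2 + 0 + 2 = 7, so
`BC = 1 − 2·7/(9 + 11) = 0.3`:

```python
from gcdiss.datasets import table1_profiles
from gcdiss.dissimilarity import pairwise_matrix

dm = pairwise_matrix(table1_profiles())
print(dm.to_frame().round(3))
```

```
     I    J
I  0.0  0.3
J  0.3  0.0
```

A BC of 0.3 sits above the 0.2 species cutoff and below the 0.4 family
cutoff: these two strains would be called different species of the same
family.

The CLI runs the same pipeline end to end on a simulated cohort
(48 strains, 2 orders × 2 families × 2 genera × 2 species × 3 strains,
~1200 genes each, intra-species BC designed in 0.05–0.18 and
inter-family BC in 0.45–0.70):

```bash
gcdiss simulate --outdir run --seed 7
gcdiss dist     --table run/profiles.tsv --out run/bc.tsv
gcdiss classify --matrix run/bc.tsv --taxonomy run/taxonomy.tsv --outdir run/cls
gcdiss mrpp     --matrix run/bc.tsv --taxonomy run/taxonomy.tsv \
                --rank species --n-perm 999 --seed 7 --out run/mrpp.tsv
```

```
simulate: wrote cohort of 48 strains to run
dist: 48x48 matrix -> run/bc.tsv
classify: 1128 pairs -> run/cls
mrpp[species]: delta=0.1225 E(delta)=0.6403 A=0.8087 p=0.001 (seed 7)
```

`run/cls/confusion.tsv` then reports a species-cutoff true-positive rate
of 1.0 with false-positive rate 0.0 on this separable-by-design cohort
(48 intra-species and 1080 inter-species pairs), and the MRPP line says
the within-species mean distance (δ = 0.12) is far below its permutation
expectation (0.64), effect size A = 0.81, p = 0.001 with 999 permutations.
`gcdiss profile` builds profiles from 12-column tabular search hits,
`gcdiss pcoa` writes ordination coordinates (optionally a scatter plot),
and `gcdiss ani` / `gcdiss rrna-id` compute the two comparison indices
from FASTA input.

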