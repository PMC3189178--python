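# circlin

Comparative genomics of circular prokaryotic chromosomes: gene-order
colinearity between two genomes, rearrangement simulation, cumulative
GC-skew replication-origin analysis, low-G+C segmentation, and
gene-content gain/loss reconstruction under a birth–death model on a
guide tree. The motivating use case is the comparison of crenarchaeal
genomes such as *Thermoproteus tenax* (a 1.84 Mb circular chromosome,
~55% G+C) against *Pyrobaculum aerophilum*, but every operation is
generic over circular genomes and gene-family matrices.

## The statistics it computes

**Colinearity factor C.** Orthologs between a query and a target genome
are placed by their ordinal CDS ranks (x_i in the query, y_i in the
target, out of O target CDSs). For each pair of query-neighbouring
orthologs the circular rank distance in the target is

    D_i = min(|y_{i+1} − y_i|, O − |y_{i+1} − y_i|),   C = Σ D_i / O.

Conserved gene order gives C ≈ 1; a fully shuffled genome gives
C ≈ n·E[D]/O ≈ n/4 for n ortholog pairs. Ortholog pairing is reciprocal
best hit (RBH) with an e-value cutoff (default 1e-15) applied to both
search directions. A randomization null (`random_null`) and its exact
expectation (`expected_null_C`) calibrate observed values.

**Cumulative GC skew.** Windowed skew (G−C)/(G+C) is accumulated along
the circle; the global cumulative minimum is the conventional
replication-origin marker, and `rotate_to_skew_minimum` re-linearizes
the genome so that minimum becomes bp 1.

**Low-GC regions.** Sliding windows below a GC threshold (default 47%)
are chained, merged and length-filtered into candidate laterally
acquired segments, reported as BED.

**Gene content.** Gene-family presence/absence evolves on a rooted
guide tree as a two-state continuous-time Markov chain with gain rate g
and loss rate l per unit branch length. The package computes pattern
likelihoods by Felsenstein pruning, fits (g, l) by bounded maximum
likelihood (optionally conditioned on families being observable),
infers per-node posterior presence probabilities by the up-down
recursion with presence called at posterior > 0.5, counts per-branch
gains and losses, and extracts group cores and lineage-specific
families from phyletic matrices.

## Worked example

```python
from circlin import (SimulationRecipe, simulate_genome_pair,
                     colinearity_factor, random_null)

recipe = SimulationRecipe(n_genes=1000, n_inversions=50,
                          ortholog_retention=0.9, seed=7)
genome_a, genome_b, pairs = simulate_genome_pair(recipe)
result = colinearity_factor(pairs, wrap=True)
null = random_null(len(pairs), 1000, reps=1000, seed=7, wrap=True)
print(f"C = {result.C:.2f} over {result.n_pairs_used} pairs "
      f"(null mean {null.mean:.1f} +/- {null.sd:.1f})")
```

prints

```
C = 23.15 over 904 pairs (null mean 226.0 +/- 4.4)
```

meaning: after 50 random inversions the surviving 904 ortholog pairs
still sit far closer to the diagonal (C ≈ 23) than a shuffled genome
would (null C ≈ 226 for this many pairs), i.e. gene order is strongly
conserved. The same computation is available from the shell:

```
circlin simulate pair --n-genes 1000 --inversions 50 --seed 7 --out sim
circlin colin --query-cds sim.A.cds.tsv --target-cds sim.B.cds.tsv \
    --hits-ab ab.tsv --hits-ba ba.tsv --evalue 1e-15 --out run
circlin skew --genome genome.fasta --window 1000 --step 1000 --rotate --out skew
circlin lowgc --genome genome.fasta --threshold 0.47 --out lowgc
circlin genecontent fit --matrix arcogs.tsv --tree guide.nwk --out rates
```

Every run writes a `.meta.json` sidecar (version, parameters, seed,
input checksums) from which it can be reproduced.

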