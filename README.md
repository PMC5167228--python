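# barcodelim

Single-locus species delimitation for COI DNA barcodes.

Large barcoding surveys of taxonomically difficult groups (the motivating
case is a species-rich Neotropical fish genus) face the same question: how
many species-level units do a few hundred to a few thousand ~650-bp COI
sequences contain, and how much do different delimitation criteria agree?
`barcodelim` implements the full cross-validation workflow such studies
use:

1. **Initial clustering** — Kimura 2-parameter (K2P) pairwise distances, a
   neighbor-joining tree, and single-linkage clusters at a 2% divergence
   cutoff define the initial putative species.
2. **Three independent delimiters** re-partition the same data:
   - **ABGD-style barcode-gap discovery**: recursive partitioning at the
     gap between intra- and interspecific divergence, scanned over a
     log-spaced grid of prior intraspecific limits P ∈ [0.005, 0.1] with
     relative gap width X = 0.1;
   - **single-threshold GMYC**: on an ultrametric tree of unique
     haplotypes, a maximum-likelihood time threshold T separating a Yule
     (speciation) process from within-species coalescent processes, with
     total branching rate
     `b = λ₁·nᵖ¹ + λ₂·Σⱼ (nⱼ(nⱼ−1))ᵖ²` between events, a likelihood-ratio
     test against a single-coalescent null (χ², 2 df), and a confidence
     set of entity counts within 2 log-likelihood units;
   - **BIN-style clustering**: a 2.2% threshold pre-stage refined by
     Markov clustering (MCL) of the similarity graph.
3. **Congruence** — every initial cluster is labeled by how many methods
   reproduce it exactly: pattern **A** (all three), **B** (two), **C**
   (one), **D** (none; the 2%-cutoff cluster then stands as the OTU), and
   a final OTU table is assembled, adopting a split of an initial cluster
   when at least two methods support the identical sub-partition.

Because the original field data live in curated databases, the package
ships a first-class synthetic generator with the survey's statistical
shape — many species in a few deep clades, mean within-species K2P
divergence ≈ 0.44%, mean between-clade divergence ≈ 18.8%, 633-bp
alignments, a fixed singleton fraction, duplicated haplotypes — and known
ground truth, so every stage is validated by recovery.

## Worked example

Simulate a 10-species, two-clade dataset and run the whole flow:

```bash
cat > demo.yaml <<EOF
sim:
  n_species: 10
  n_clades: 2
  min_species_split: 0.12
  seed: 7
EOF
barcodelim run --config demo.yaml --out demo_run
```

prints

```
final OTUs: 10
pattern A/B/C/D %: 100.0/0.0/0.0/0.0
```

meaning the 2%-cutoff analysis found 10 initial clusters and all three
delimiters reproduced every one of them (pattern A), so the final OTU
table equals the simulated truth. The run directory contains each stage's
artifact (`k2p.tsv`, `nj_tree.nwk`, `partition_*.tsv`, `congruence.tsv`,
`final_otus.tsv`, Table-style summaries `method_counts.tsv` and
`distance_clade_matrix.tsv`):

```
$ head -4 demo_run/method_counts.tsv
        NJ2  ABGD  GMYC  BIN
all      10    10    10   10
clade1    2     2     2    2
clade2    8     8     8    8
```

Individual stages are also exposed (`barcodelim simulate | distances |
cluster-threshold | abgd | gmyc | bin | congruence`), e.g. a GMYC fit on
the same data:

```
$ barcodelim gmyc --fasta demo_run/alignment.fasta --metadata demo_run/metadata.tsv --out gmyc.tsv
10 entities (CI 10-11), threshold time -0.0277964, LR=21.883 p=0.0000
```

The negative threshold time is the fitted species/population boundary in
substitutions-per-site units before the present; the significant
likelihood ratio rejects the single-population null. Everything is equally
usable as a library (`barcodelim.pairwise_k2p`, `threshold_clusters`,
`abgd_partition`, `gmyc_fit`, `bin_partition`, `classify_patterns`,
`simulate_dataset`, `run_pipeline`).

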