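# Methods

This note documents the models, numerical choices and design decisions
behind `barcodelim`, and what the synthetic validation does and does not
demonstrate about real barcode data.

## Distances

Pairwise distances use the Kimura 2-parameter model,
`d = -1/2 ln((1-2P-Q)·sqrt(1-2Q))`, with P and Q the proportions of
transition and transversion differences over the sites both sequences
resolve (pairwise deletion of N and gap positions; purines {A,G},
pyrimidines {C,T}). When a log argument is non-positive the pair is
saturated: the cell is carried as NaN, reported, and treated by every
clustering stage as "always split" — capping it would bias gap detection
downward. Non-N IUPAC ambiguity codes are mapped to N on input (count
logged); K2P then treats them as missing. Haplotype collapsing uses exact
string identity, so sequences differing only at an N remain distinct
haplotypes, mirroring exact-duplicate removal tools. Distance summaries
report singleton clusters' within-mean as not-applicable, never zero; the
clade matrix places within-clade means on the diagonal, between-clade
means below it and the analytic standard error of each between mean
(sd/√n over pairwise values) above it.

## Trees

Neighbor joining is the standard Saitou–Nei agglomeration with two
determinism policies: Q-criterion ties break on the lowest current index
pair, and a negative branch length is clamped to zero with the deficit
absorbed by its sister so the joined pair's distance is preserved; the
final leftover edge is likewise floored at zero (reduced distances can go
slightly negative on noisy matrices). On additive matrices the
implementation reproduces the generating path-length matrix to 1e-9 and
agrees with dendropy's independent NJ. UPGMA (scipy average linkage, node
height = half the merge distance) supplies the ultrametric tree for GMYC
when no externally dated tree is given; full Bayesian dating is out of
scope, and on well-separated data the tree estimator is not the limiting
factor — the simulator's true trees are used to validate the GMYC model
itself separately from the tree estimate. Ultrametricity is always
computed from branch lengths (relative tolerance 1e-9), never trusted
from input.

## Threshold clustering

Initial clusters are connected components of the graph with an edge where
`d < cutoff` (strict inequality: pairs at exactly the cutoff split). The
default matches the 2% convention for these data; the BIN pre-stage uses
2.2%. An alternative mode cuts at patristic distances on the NJ tree; on
clean data the two agree and the matrix mode is the default because it is
deterministic and matches the cutoff-value semantics.

## Barcode-gap discovery (ABGD-style)

The published gap-discovery procedure is a cited tool whose exact
comparator leaves implementation freedom; this implementation is
validated by species-count recovery on known truth, not by output-file
equality with any external program. Three choices matter, all driven by
properties of real ~650-bp barcodes:

- **Scan domain.** The gap is sought among the single-linkage merge
  heights of the distance matrix (n−1 values) rather than the n(n−1)/2
  raw pairwise distances. These are exactly the thresholds at which the
  resulting clustering changes; with hundreds of specimens, sampling
  noise in the huge between-species pair set otherwise floods every
  distance bin and no empty interval survives at any scale.
- **Comparator.** A jump `d(i+1) − d(i)` qualifies as a gap when it lands
  above the prior P and exceeds both `X·w(i)` (w(i) = running spread of
  the distances below, X = 0.1 by default) and P itself. The second
  condition encodes the method's premise — a gap separating intra- from
  interspecific variation must be at least as wide as the assumed
  intraspecific range — and is what prevents the ~1/L quantization steps
  of sparse within-species distance sets from registering as gaps. Among
  qualifying jumps the one with the largest *relative* width (gap over
  the distance at its lower edge) wins: the barcode gap sits just above
  the intraspecific bulk, whereas wide-but-proportionally-small jumps
  occur in the sparse deep tail.
- **Recursion.** Clusters from the initial split are re-scanned and split
  while a gap is found (clusters of fewer than three members have no
  interior distribution to test). Recursive candidates are restricted to
  heights above the dataset-level gap's lower edge: a split below that
  edge would contradict the global intra/inter classification the gap
  established. Without this, the exponential tail of the within-species
  coalescent (its final waiting interval has mean equal to the mean
  pairwise divergence) makes low-prior oversplitting near-certain —
  which is also the documented behaviour of the original tool at small
  priors.

One partition is produced per prior on a 20-step log grid (defaults
P ∈ [0.005, 0.1], X = 0.1).

## Single-threshold GMYC

On an ultrametric tree of unique haplotypes, nodes older than a threshold
age T belong to a speciation process and nodes younger than T to
independent within-species coalescents. The likelihood is the classic
waiting-time form: between consecutive branching events the total rate is

    b = λ_yule · n^p_yule + λ_coal · Σ_j (n_j(n_j−1))^p_coal

with n the number of species-level lineages (constant at the entity count
below T) and n_j the lineage count inside species j; each of the n−1
events contributes `log b − b·x` for its interval. Note the event term
uses the total rate — the data are the waiting times, with the node
classification entering through the n_j bookkeeping. A per-component
event-term variant was evaluated and rejected: it lets the
single-coalescent null dominate every structured tree (the (N(N−1))^p
factor over all lineages outgrows any within-species factor), destroying
recovery while the total-rate form recovers cleanly.

Candidate thresholds are the midpoints between consecutive node ages,
plus a just-younger-than-the-youngest-node boundary (all singletons; with
λ_coal = 0 the likelihood then reduces to the pure Yule form, which is
oracle-tested) and a just-older-than-the-root boundary (one entity — the
null single-coalescent model). Per candidate the four parameters are
maximized with L-BFGS-B from three fixed starts (central start:
per-component Poisson rate estimates at unit exponents); exponents are
bounded to [0, 2], log-rates to ±30. The LR statistic
`2(logL_mixed − logL_null)` is referred to χ² with 2 df, following the
originating literature, with the known caveat that mixture corrections
exist; the validated surface is recovery and null calibration, not
p-value exactness. The confidence set collects entity counts of
candidates within 2 log-likelihood units of the maximum. Threshold times
are reported negative (before present). Rescaling all branch lengths by c
leaves the entity count invariant and rescales the rates by 1/c.

## BIN-style clustering

The production BIN algorithm is not published in reproducible detail;
this is a fully specified stand-in with the two stated stages, labeled
BIN-style throughout. Stage 1: threshold components at 2.2%. Stage 2:
within each component of ≥4 members, Markov clustering of the similarity
graph with weights `max(0, 1 − d/threshold)`, unit self-loops, expansion
by squaring and element-wise inflation (default 2.0) with column
renormalization, to convergence 1e-9 or 200 iterations; clusters are the
connected components of the limit matrix's support. Refinement can only
split stage-1 components, never merge across them; at inflation → 1⁺ it
degenerates to a no-op.

## Congruence and final OTUs

A method *agrees* with an initial cluster only on exact set equality with
one of its clusters — any tolerance would be an uncited parameter.
Patterns: 3 agreements → A, 2 → B, 1 → C, 0 → D. Discordant (D) clusters
stand as OTUs themselves, per the cutoff-criterion rule. For A–C, when at
least two methods cleanly split the cluster into the same sub-partition
(every part a whole cluster of each method), that split is adopted — this
is the mechanism by which the final OTU count can exceed the initial
count; the adopting methods are logged per cluster. A partition may cover
only part of the data (the BIN situation when some records are absent
from the reference system): uncovered specimens are ignored in that
method's comparison, and when under half a cluster is covered the method
abstains — the pattern is then the best attainable from the remaining two
(2 → B, 1 → C, 0 → D), flagged in the report. Pattern percentages are
`100·count/n_final_otus` to one decimal, with per-OTU pattern labels
inherited from their initial cluster.

## Synthetic data generator

The generator emulates the statistical structure of a large COI survey:

- **Species tree**: a Yule topology whose internal-node ages are
  affine-mapped onto `[min_species_split/2, U]`, with U solved in closed
  form so the sample-weighted mean cross-clade tip-pair path length
  equals `target_inter`. Branch lengths are in expected substitutions per
  site, and the K2P estimator is unbiased for the generating path length,
  so distance calibration is analytic. The floor exists because an
  unconstrained Yule draw routinely places splits shallower than the
  within-species coalescent, making the truth unrecoverable by *any*
  threshold — the floor is what makes "well separated" a property of the
  generated data rather than a hope. Clades are the subtrees below the
  deepest n_clades−1 splits.
- **Within species**: a Kingman coalescent scaled so a lineage pair's
  coalescence time has mean `target_intra/2` (mean pairwise divergence =
  `target_intra`, default 0.44%). `max_within_tmrca` optionally bounds
  the genealogy depth (genealogies exceeding it are shrunk): species
  defined operationally by a distance cutoff cannot contain within-group
  divergences beyond it, so profiles emulating cutoff-defined groups set
  this bound; the unbounded default keeps the pure coalescent.
- **Sequences**: evolved site-independently under the exact two-parameter
  transition kernel (the closed-form probabilities of identity,
  transition, and each transversion; base codes chosen so the mutation is
  an XOR), κ = 2 by default, 633 bp, no indels or stop-codon logic (the
  emulated data had none). `mutation_scale = 0` yields identical
  sequences.
- **Sampling**: the singleton quota is honored exactly
  (`round(singleton_fraction · n_species)` species get one specimen);
  remaining species draw `2 + Poisson` counts matching the requested
  mean. Duplicated haplotypes are injected by overwriting a specimen with
  a copy of an earlier conspecific at the given rate; optional uniform
  N-masking exercises pairwise deletion. Everything is deterministic
  given the seed.

`paper_scale_profile()` is the desk-scale analogue of the study: 124
species, five clades, 31 singletons, 633 bp, 0.44% within / 18.8%
between, duplicate rate 0.2, a mean of 5 specimens per species (the field
survey averaged ~13.5; 5 keeps the full pipeline, including GMYC over all
haplotypes, in the tens of seconds), `min_species_split = 0.12` and
`max_within_tmrca = 0.005`. The last two place the profile firmly in the
well-separated regime: species divergences 12–30%, within-group depths
compatible with 2%-cutoff-defined groups. What passing at this profile
shows is that the *pipeline machinery* — distances, four delimiters,
congruence — recovers a clean 124-species structure end to end; it does
not show how the methods adjudicate the hard cases of real data (species
2–4% apart, within-species divergences overlapping the cutoff), where the
methods genuinely disagree and no synthetic truth could call a winner.

## Validation fixtures and their problem sizes

- K2P: 1000 random (P, Q) against direct formula evaluation (1e-12) and
  the p-distance lower bound.
- NJ: 50 random additive matrices, 5–12 taxa, path-matrix equality 1e-9.
- Threshold clustering: union-find oracle on 100 random matrices;
  monotonicity in the cutoff.
- ABGD: 20 datasets of 3–30 species (within ≈ 0.4%, between 18–26%,
  i.e. ≥ 40× within); exact species count at every prior in ≥ 19/20 runs.
  Between-divergences must clear the top prior (0.1) with noise margin
  for the property to be attainable at all, which fixes the fixture's
  separation.
- GMYC: 50 single-population coalescent trees (20 tips) for null
  calibration (≥ 90% non-significant at α = 0.05) and 50 ten-species
  trees at a 100:1 species/coalescent depth ratio for recovery (≥ 90%
  exact, with the truth in the confidence set).
- BIN: split-never-merge and per-bin stability on 50 random datasets; the
  12-specimen constructed merge case against the direct MCL matrix
  iteration.
- Congruence: exactness of the pattern rules and the percentage
  arithmetic (63, 41, 17, 4)/125 → 50.4/32.8/13.6/3.2.
- End to end: one study-scale profile run (≈ 600 specimens); all four
  methods within ±10% of 124 clusters and ≥ 95% pattern A, in well under
  the stated budget.

## Known limitations

- The ABGD stand-in is validated by recovery, not bit-compatibility with
  the original program; its initial/recursive dual-output distinction is
  not reproduced.
- GMYC here is single-threshold only, with a 2-df χ² LR test; no
  multiple thresholds, no integration over tree posteriors.
- The BIN stand-in does not reproduce actual BIN identifiers and its
  refinement details are this package's specification, not BOLD's.
- The simulator has no indels, no codon structure, no migration or
  hybridization, and its well-separated profiles deliberately exclude
  the overlap regimes where real delimitation is contentious.
- Saturated distance pairs abort tree building by design; datasets deep
  enough to saturate COI K2P need a different marker or model.
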