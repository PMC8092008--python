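# Methods

## The loss chain

A hexaploid locus holds up to three homoeologs, one per parental subgenome
(1 = LF, 2 = MF1, 3 = MF2).  Copy loss is irreversible, so the copy-number
process is a continuous-time Markov chain over the seven nonempty subsets of
`{1,2,3}` ordered by inclusion: T; D12, D13, D23; S1, S2, S3 (absorbing).
The base triplicate-loss rate α is not a free parameter: it is absorbed into
per-edge branch lengths ν = αt, so "time" is measured in expected T→D losses
of the baseline subgenome.  Loss of copy *g* proceeds at rate `fT[g]` out of
T and `σ·fD[g]` out of a D state.  MF2 is the fixed baseline (`f[3] ≡ 1`).
Descriptions of this model family usually name only the relative
fractionation factors; placing a factor at *both* the T and D levels per
non-baseline subgenome is the unique parameterization consistent with the
nested-model degree-of-freedom ladder 1 → 3 → 5 → {10, 8}.

Fractionation factors are constrained to [0, 1]: the baseline (MF2) is by
convention the fastest-losing subgenome.  Because relabeling subgenomes 1
and 2 (together with mirroring the hidden permutations) leaves the
likelihood invariant, fitted G3-family models are reported in a canonical
form with subgenome 1 the least fractionated.

### The two-step root model

The two-step hexaploidy variant starts every locus in the two-subgenome
state left by the first hybridization (D23 when LF arrives last) and lets
the last subgenome arrive on the root branch at rate τ (straight to T) or
β12/β13 (arrival combined with a prior MF2/MF1 loss).  Arrival can happen
at most once, so the root branch runs internally on an augmented ten-state
chain that distinguishes the *pre-arrival* D23 (and the single-copy states
reached from it by the σ-losses that continue to compete with arrival) from
the identical-looking post-arrival states; the augmented states project back
onto the seven-state space at the first speciation.  Without this
distinction a locus that lost its newly arrived copy could "re-arrive",
which breaks the model's semantics and its τ→∞ collapse onto the one-step
model.  The public seven-state generator view writes the arrival rates onto
the shared D row for inspection; the likelihood always uses the augmented
chain.

Pre-arrival loss fractions count, per early subgenome *m*, the expected
number of root-branch jumps that drop *m* from a pre-arrival state (β jumps
and pre-arrival σ-losses alike) against those dropping *m* after arrival.
Expected jump counts per type are computed with the Van Loan block-matrix
integral conditioned on the posterior of the root-branch endpoint; expected
per-branch loss totals elsewhere use the identity survivors(parent) −
losses = survivors(child), exact because each copy is lost at most once.

## The pillar hidden Markov chain

A pillar contributes, per genome, an observed subset of its three track
slots; the hidden state assigns each genome's slots to subgenomes (6
permutations per genome, `6^G` combined states).  Emissions are computed by
Felsenstein pruning over the species tree on the full `7^G` grid of
tip-state combinations once per parameter setting, then gathered per
distinct observation pattern; the forward pass uses the factorized
persistence/redraw kernel (per genome: keep with probability 1−θ, redraw
uniformly over all six permutations otherwise, forced redraw at annotated
synteny breaks) so one step costs `O(G·6^G)`.  The initial hidden
distribution is uniform: nothing is known before the first pillar.  The
forward/backward kernels are numba-compiled with a pure NumPy fallback.

When a pillar's scaled emission mass underflows (possible only at absurd
parameter corners visited by the optimizer), its log contribution is floored
at log(1e-290) and the chain restarts from uniform; this keeps the
likelihood surface finite and monotone in the number of underflowed pillars,
which bounded quasi-Newton optimization requires.

## Fitting

Maximum likelihood by L-BFGS-B: positive rates (σ, τ, β, branch lengths) on
a log scale with bounds [1e-4, 100] (branch lengths [1e-6, 20]),
fractionation factors and θ on their natural scale with box bounds.
Convergence tolerance 1e-6 on the projected gradient; multi-start with five
seeded random restarts by default (heavier experiments in the test-suite and
acceptance script use one or two restarts, with warm starts from the nested
model where a nested/general pair is compared — warm-starting guarantees a
nonnegative likelihood-ratio statistic).  θ can be per-genome, shared, or
fixed.  Non-convergence after all restarts is reported with a warning, never
silently.

Likelihood-ratio tests use a plain χ² reference with df equal to the
difference in free loss-parameter counts (branch lengths and θ are common to
both models and cancel).  Caveat: under a true boundary null (e.g. data
generated without bias, so the general model's f parameters sit at their
upper bound 1) the statistic is a mixture with a large point mass at zero
and the χ² test is conservative — measured type-I error at nominal 5% is
≈ 0–1% rather than 5%.  The test never over-rejects.  G3 is nested in the
two-step model only in the τ→∞ limit; following standard practice the
comparison is still referred to χ²₃.

## Synthetic data

`simulate_pillars` is the generative counterpart of the likelihood: hidden
permutations follow the persistence chain, and each pillar's copy-number
history is simulated exactly (competing exponentials) down the tree — on the
augmented root chain for the two-step variant — with every loss/arrival
event recorded and tagged pre/post-arrival.  Defaults are the study-like
conditions used throughout: the four-taxon tree
(((B_rapa, B_oleracea), C_hispanica), S_alba) with a root edge of ν = 0.45
(chosen so roughly a third of all copies are lost before the first
speciation, the regime of heavy early fractionation) and tip/internal edges
0.08–0.28; the generating loss model G3 with σ = 0.8, fT = (0.6, 0.8, 1),
fD = (0.5, 0.7, 1); synteny persistence θ = 0.05.  `simulate_labeled_network`
produces G(n,p)-style graphs whose same-class pairs are enrichment-fold more
likely to be connected (enrichment 1 = exchangeable null);
`simulate_expression` plants block-correlated latent factors in half the
genes and exponentiates to an RPKM-like scale (rank correlations are
preserved).  What the generator does *not* emulate: real tandem-array
structure inside pillars, assembly/annotation error, genome-specific gene
content differences, or expression count noise — so green tests demonstrate
correctness of the inference machinery under the model, not robustness to
real-data artifacts.

## Synteny pillars and ancestral order

Pillar construction filters homolog pairs at ≥ 70% amino-acid identity with
the shorter sequence ≥ 80% of the longer (both inclusive), collapses tandem
outgroup duplicates within a configurable gap (default 1) by transitive
closure, and then anneals pillar gene assignments and pillar order to
maximize the triple-conserved-synteny score: the number of (genome, track)
gene pairs in adjacent pillars within a window of w positions on the same
chromosome (w = 1 by default; synteny is order-based, not base-pair-based).
Annealing moves: relocate (and possibly reverse) a short pillar block, swap
two track slots, move a gene between pillars sharing a homologous anchor;
geometric cooling (T₀ = 1, factor 0.995 per sweep, stop after 200 sweeps
without improvement), followed by a greedy block-relocation polish, with
best-seen semantics so the result never scores below the input.  Merged
pillars keep only anchors with at least one surviving gene in every genome.
The intended scale is the small-to-moderate instances of the test-suite and
demonstrations (tens of pillars); the objective is re-evaluated per proposal
rather than incrementally.

Ancestral-order reconstruction gives each homology set a head and a tail
endpoint, weights observed set adjacencies by how many gene-copy adjacencies
realize them, and selects a maximum-weight endpoint matching
(networkx); selected cycles are broken at their lowest-weight edge.
Orientation of a candidate follows the majority observed direction, ties
toward the lexicographically smaller set id — gene strand is not part of the
input, so this is a convention, not an inference.  Contigs with ≤ 4 genes
from the required genome are dropped, as are contigs whose members' ancient
chromosome labels fail a 0.8 majority (the mixed-origin rule is
operationalized as a configurable majority threshold; no exact published
rule exists).  A second matching round over contig endpoints orders the
contigs into chromosome-scale sequences.  Homology sets are accepted as
input; the built-in fallback builds them as connected components of the
homology graph split greedily to per-genome caps.

## Network statistics

Permutation tests shuffle node labels over a fixed topology (optionally
holding e.g. retained-triplet nodes frozen) and report add-one empirical
p-values, both tails.  The coexpression network uses Spearman ρ on
pairwise-complete observations (average ranks for ties), edges at |ρ| ≥ 0.9,
after excluding genes missing more than one of the 32 conditions; constant
genes are skipped with a warning.  The rewiring null applies repeated double
edge swaps (5 per edge on average, labels fixed to their nodes), preserving
every degree exactly; graphs with no valid swap are left unchanged.  The
sweep association is a Pearson χ² without continuity correction (the tables
exceed 2×2) with standardized residuals per cell.  Because the test
statistics are integer edge counts, permutation and rewiring p-values are
discrete and mildly conservative under the null; the calibration tests
allow for that.

## Problem sizes

The validation experiments use: parameter recovery at 5,000 pillars over
four genomes (fractionation factors recovered within ±0.05, σ within ±0.1);
two-step behavior at 2,000 pillars with τ = 1, β = 0.3 and the τ = 10⁴
collapse checked at 100 pillars (the residual likelihood gap between the
two-step and one-step models scales as n/τ, so the limit statement is
checked at a pillar count where the bound 1e-3 is meaningful); null
calibration on 200 datasets of 500 pillars over two genomes; resampling-test
calibration over 100 seeded networks.  Exhaustive oracles (hidden-path
enumeration, internal-state enumeration, brute-force matching, exhaustive
pillar orders) cover instances up to 2 genomes × 4 pillars, 3 tips, 12 sets
and 6 pillars respectively.

## Known limitations

* Pillars missing a genome entirely are rejected, matching the
  all-genomes-present pillar definition.
* No gene conversion, no copy regain, no time calibration of ν into years.
* The χ² reference for boundary nulls is conservative (see above).
* Annealing is stochastic; optimality is only guaranteed in the best-seen
  sense, and the schedule is tuned for small instances.
* The coexpression builder computes a dense gene × gene correlation matrix;
  it is meant for thousands of genes, not the full transcriptome.
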