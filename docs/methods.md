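# Methods

This note records the model, the parameter choices, the numerical
decisions, and what the synthetic test bed does and does not demonstrate.

## The containment score and its matrix

`pckm_k(g_i, g_j)` is the fraction of genome j's k-mers — counted with
multiplicity and with overlap — that also occur in genome i. It is a
containment, not a Jaccard index: it is asymmetric, and it weights by
occurrence counts in the *second* argument. Two normalization details
differ from the naive `|g_j| − k + 1` denominator:

- The denominator is the count of **valid** windows (all bases ACGT, never
  spanning record boundaries in multi-record genomes). With ambiguity
  codes present, the naive denominator would make self-containment < 1;
  with the valid-window count, `pckm(g, g) = 1` exactly whenever g has at
  least one valid window, which the rest of the model (unit diagonal of
  `A(k)`) relies on.
- K-mers are collapsed with their reverse complements (canonical form) by
  default, in both training and sample counting, because shotgun reads
  come from both strands; a flag restores strand-specific counting. All
  small worked examples in the tests are written to be canonical-invariant
  or to pass `canonical=False` explicitly.

Counting is exact and hash-based. Probabilistic counting structures
(bloom filters, compacted de Bruijn graphs) are scale optimizations for
databases of thousands of genomes and are deliberately out of scope; the
implementation targets in-memory reference panels (up to roughly 10^8
k-mers comfortably).

## Hypothetical organisms and the two-k link

A relative of reference g_i at similarity level h is modelled by capping
g_i's 30-mer palette column at h: entries above h are rounded **down** to
h, entries below are kept, because a strain that recently diverged from
g_i still shares g_i's (older) pattern of k-mer sharing with outgroup
references. The matching 50-mer column is `p(min(h, col30))` for the
degree-3, zero-intercept polynomial p. Since p is increasing on [0, 1],
applying the cap before or after the map is equivalent
(`p(min(h, x)) = min(p(h), p(x))`); the cap-then-map form is used.

Capping with `max` instead of `min` was considered and rejected: it would
*raise* the entries of dissimilar outgroups to h, making every
hypothetical column nearly constant and destroying the outgroup-sharing
structure that identifies which reference the novel organism is near.

The packaged default coefficients (−0.5141, 1.0932, 0.3824) summarize the
30↔50-mer relationship across a large panel of real bacterial genomes and
are only meaningful for the (30, 50) size pair. Because that relationship
depends on the divergence process (for pure i.i.d. substitution it is
exactly `s50 = s30^(5/3)`), training refits p by no-intercept least
squares on the `(A30[i,j], A50[i,j])` pairs of the freshly built matrices
whenever the design has rank 3, and falls back to the default otherwise
(e.g., panels of mutually unrelated genomes, where all off-diagonal
entries are ~0). The fit reports RMSE and R².

Default bins are h = 0.9, 0.8, …, 0.1, giving the stacked system
`[A30 | capped blocks; A50 | mapped blocks]` of size 2M × 10M. Rows are
the k = 30 block then the k = 50 block; columns are genome-ordered blocks,
reference first.

## Sample signature

`y_i(k)` is the fraction of **all** valid sample k-mers (not only those
matching some reference) that occur in genome i, computed over the pooled
sample rather than per read. Including unmatched k-mers in the denominator
means foreign sample content depresses every entry proportionally — which
is exactly the signature of a distant hypothetical organism, and is how
that mass gets absorbed rather than distorting reference abundances.
Paired-end mates are treated as independent sequences.

With FASTQ input, an optional Phred threshold `qmin` counts a window only
when **every** one of its k bases reaches the threshold — the strictest
reading of quality-gated counting, chosen because a single erroneous base
already falsifies the whole k-mer. FASTA input with `qmin` set warns and
ignores the threshold.

## Deconvolution

The solved program is `min ‖z‖₁² + λ²‖Az − y‖₂²` subject to `z ≥ 0`. Under
nonnegativity `‖z‖₁ = Σz`, so the problem is ordinary least squares on the
augmented matrix `[1…1; λA]` against `[0; λy]`, solved by scipy's
Lawson–Hanson active-set NNLS. λ = 200 throughout: large enough that the
fit term dominates for well-explained samples, small enough that the ℓ1²
term suppresses spurious columns. The solver is deterministic for fixed
input; degenerate ties resolve by the active-set insertion order, which is
implementation-defined but reproducible. A λ-continuation toward the exact
ℓ1-minimal solution is intentionally not implemented.

Post-processing prunes entries below `eps · max(x)` (eps = 1e−4; outputs
are observed sparse, no printed threshold exists to inherit) and
renormalizes to sum to 1. Degenerate inputs: an all-zero y short-circuits
to the zero solution; a fully pruned solution warns and returns an empty
table.

## Taxonomy mapping

Lineages are fixed-rank (superkingdom … strain, complete paths,
placeholder taxids allowed). Reference-column mass maps to its genome's
strain. Hypothetical mass (genome i, bin h) searches for a partner j with
`|A30[i, j] − h| < δ` (δ = 0.05 by default; the threshold is named but
unvalued in the literature) choosing the j minimizing the gap, with a
global-nearest fallback when no candidate qualifies, and assigns the mass
to the LCA rank of lineages i and j. The bins are defined on 30-mer
similarity, so matching uses `A30`. Single-genome databases fall back to a
fixed bin→rank ladder (1.0→strain, 0.9→species, …, ≤0.3→superkingdom).
Cross-superkingdom LCAs (the unranked root) are reported at genome i's
superkingdom, the shallowest representable rank.

Three modes: `default` = pure LCA; `sensitive` = the deeper of LCA and the
fixed ladder; `specific` = the shallower. The hybrid definitions are this
package's concrete, monotone realization of "hybrid" options whose
originals are undocumented; by construction sensitive ≥ default ≥ specific
in assignment depth.

Profiles credit each entry's mass to its assigned taxon and every
ancestor, so percentages are upward-consistent, sum to 100 at the top
rank, and may sum to < 100 at deep ranks (mass assigned above stays
unassigned below). Output is the Bioboxes profiling format v0.9 with exact
header tokens.

## Strain trees and placement

Distance is `1 − symmetrized mean of A30 and A50` (self-similarity 1 →
distance 0; no explicit transform is prescribed elsewhere, and this is the
simplest one with the right fixed points). Neighbor joining is delegated
to scikit-bio (Saitou–Nei, lowest-index tie-break, negative branch-length
estimates clamped to 0), with n ≤ 2 handled as degenerate cases; it
recovers additive metrics exactly, which the tests assert to 1e−9.

For placement the tree is midpoint-rooted — purely to orient "above"
versus "below"; no rooting rule is prescribed by the method itself. Mass
for (i, h) with partner j attaches on the path between leaf i and the i–j
ancestor: at the ancestor when `h = A30[i,j]` (to 1e−9), toward the leaf
when h is larger (the novel organism is closer to i than j is), toward the
root when smaller. The strict above/below offset is 25% of the adjacent
edge length — a display convention, declared arbitrary. Placement
conserves total mass, and lowering h never moves mass leafward.

## Comparison metrics

`divergence = Σ log2(x*_i / x_i)` over taxa with both truth and prediction
positive; the printed formula in the benchmarking literature is ambiguous
about absolute values, so the signed sum is the default and
`absolute=True` sums magnitudes. Disjoint support returns 0 with a
warning. `FP = |{i : x*_i > 0, x_i = 0}|` counts spurious taxa and is
scale-invariant. Profile alignment is by taxid at a caller-chosen rank,
zero-filling taxa missing from one side.

## Synthetic test bed

Generators are deterministic per seed. `random_genome` draws i.i.d. bases
at a target GC; `mutate_genome` applies i.i.d. substitutions (no indels),
for which the k-mer survival law `E[pckm_k] = (1−μ)^k` is exact and serves
as an oracle — the tests check it within 3 standard errors on 100-kb
genomes for μ ∈ {0.001, 0.01, 0.05}, k ∈ {20, 30, 50}. `simulate_reads`
draws multinomial read counts at the specified mixture, uniform start
positions on the linear genome, random strand, i.i.d. substitution errors,
and constant Phred strings encoding the error rate.

`strain_panel` generates panels with alternating conserved/variable 500-bp
blocks, each strain substituting only variable positions at its own rate.
This emulates the core/accessory structure of real strain panels and is
what makes the hypothetical-column outgroup assumption hold: a further
relative of one strain keeps the panel's conserved-core sharing. Under
uniform i.i.d. divergence that assumption is deliberately violated (novel
mutations also erode outgroup sharing), so the two generators are kept
separate and the novelty experiments use the panel generator.

What the fixtures do **not** model: indels and rearrangements,
recombination, position-dependent and instrument-specific error profiles,
coverage bias, contamination. Passing tests therefore demonstrate
correctness of the algorithmic chain and calibration under the stated
generative assumptions, not field performance on real metagenomes.

## Problem sizes and defaults

Test and acceptance runs use 3–5 reference genomes of 20 kb, 20k–50k reads
of 100 bp, and 100-kb genomes for the survival law (15–20 replicates) —
sizes chosen so every property is measurable with comfortable statistical
margins while the full suite runs in well under a minute of compute per
experiment. Key defaults: k = (30, 50); bins 0.9…0.1; λ = 200; δ = 0.05;
prune eps = 1e−4; canonical counting on; polynomial refit on.

## Known limitations

- Exact in-memory counting bounds the practical database size; there is
  no disk-backed or probabilistic counting path.
- The default polynomial is tied to the (30, 50) pair; other k-size pairs
  require refitting (done automatically at training, but the fallback
  coefficients would be wrong for them).
- Hypothetical columns inherit their genome's outgroup pattern; lineages
  with strongly heterogeneous evolutionary rates would warrant
  taxonomy-dependent link polynomials, which are not implemented.
- Sample-restricted training matrices and coverage-weighted columns are
  documented extension hooks, not implemented.
- No read-level assignment: the method profiles the pooled sample only.
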