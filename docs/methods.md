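# Methods

`clonegrower` infers a clonal tree, clonal SNV genotypes and a cell
clustering from ultra-low coverage single-cell DNA sequencing of a tumor.
This note records the model, the search, the synthetic data generator, and
the numerical and design choices a maintainer would want to know about.

## Problem setting

Ultra-low coverage scDNA-seq (0.01–0.25× per cell) trades depth for
uniformity: binned read counts are proportional to local copy number, which
is excellent for copy-number work, but a given SNV locus is covered in only
a few percent of cells. The input is a sparse pair of `n × m` matrices of
variant reads `A` and total reads `D` over `n` cells and `m` SNV loci,
plus binned read counts `R` over `b` genomic windows (or a precomputed
low-dimensional embedding of them). The output is a rooted clonal tree `T`
whose nodes carry binary genotypes `Y` under the infinite sites model (each
SNV is gained on exactly one edge and never lost) and a cell clustering
`φ` assigning every cell to a node. Nodes with cells are *clones*; a node
may be cell-free (an unobserved ancestor), so the node count can exceed the
clone count.

## Probabilistic model

**SNV reads.** Conditional on depth `d_iq`, the variant count `a_iq` is
binomial. Under genotype 0 the success probability is the per-base
sequencing error `α`. Under genotype 1 the variant allele fraction depends
on the latent allele-specific copy number state `(x, y)` — `x ≥ 1` mutated
copies of `y ≤ c` total — which is marginalized under a uniform prior over
the `c(c+1)/2` states, each with error-adjusted VAF
`x/y·(1−α) + (1−x/y)·α`. Entries with `d = 0` contribute exactly 0 in log
space, so posteriors are comparable across trees on the same data. The
likelihood of a tree factorizes over entries given `(Y, φ)`; we precompute,
for the nonzero entries of `D`, the genotype-0 log-likelihood total and the
sparse matrix of genotype-1 minus genotype-0 differences, which makes any
tree's SNV term one sparse column-sum per node.

**Embedding.** Cells of a clone are modeled as a spherical Gaussian around
the clone centroid in the embedding, with a single pooled variance shared by
all clones and profiled out at its maximum-likelihood value (floored at
1e-6). The embedding itself is `log2(x+1)`-transformed, library-size
normalized binned counts projected on the top `ℓ = 10` principal axes
(deterministic; a seeded UMAP reduction is optional). A user-supplied
embedding is accepted verbatim.

**Priors.** Uniform over trees and, per SNV, uniform over attachment nodes
(`−m log k` for a `k`-node tree); no cell-assignment prior. Posterior
ordering is therefore a likelihood ordering with a mild penalty on node
count.

## Search

Growth starts from a single root clone holding every cell with all SNVs
clonal, and repeatedly extends frontier leaves with three elementary
operations: **Linear** (leaf → parent–child chain; stepwise acquisition),
**Branching** (leaf → parent with two children; divergence — the parent
keeps no cells during the operation), and **Identity** (close the leaf).

Linear and Branching are solved by coordinate descent. With genotypes
fixed, the leaf's cells are bipartitioned by a normalized cut: the feature
is each cell's standardized embedding row concatenated with a standardized
SNV-evidence column (the cell mutational burden over the SNV set being
reassigned; cells covering no locus are imputed at the cohort mean and
flagged), the similarity graph is a Gaussian kernel with bandwidth equal to
the median pairwise distance, the Fiedler vector is computed with
warm-started LOBPCG (dense-eigensolver fallback), and the threshold is the
sweep position minimizing the exact Ncut. With the bipartition fixed, each
SNV is re-attached to the node of the extended subtree maximizing its
marginal posterior contribution — one sparse column-sum per node, `O(nm)`
total, and infinite sites holds by construction of the attachment
representation. Iteration stops when the bipartition is unchanged up to
0.5–1% of cells, repeats a previous state, or the best local score has
stagnated for three rounds; of `restarts = 15` seeded runs (bandwidth
perturbed ±20%, sweep threshold jittered among near-optimal positions, and
a balance floor on the sweep rising to 40/60 across restarts), the best
*admissible* iterates are kept. In the Linear operation the side with
higher mean SNV evidence becomes the descendant, and the swapped
orientation is also evaluated as a candidate, because the full-tree
posterior is a better judge of orientation than the local heuristic.

**Acceptance gates.** A proposed split enters the candidate set only if

1. every affected clone has at least `max(10, 0.01 n)` cells
   (regularization);
2. every affected clone is *detectable*: averaged over its newly introduced
   SNVs, at least `t` of its cells have nonzero depth at the SNV;
3. every demotion is *absence-supported*: averaged over the SNVs pushed
   below a node, the complement side (Linear: the parent side; Branching:
   the sibling side) shows at least `t` covered, variant-free entries per
   SNV. Coordinate descent demotes an SNV exactly when the complement
   happens to carry no variant reads; without this mirror-image of
   detectability, splits of a homogeneous clone can look favorable purely
   through that selection effect, in a regime where the absence carries no
   information;
4. the tree passes the quality check: for each new node with gain set `S`,
   the median mutational burden over `S` of covered cells outside the
   node's clade is at most `qc`.

**Enumeration and ranking.** Each operation contributes up to 3 distinct
admissible splits, so the candidate set contains alternative topologies and
the posterior — not the local cut — decides among them. Because an
operation touches only the operated leaf's cells and SNVs, its solution is
cached by leaf state and shared across candidate trees. The search expands
candidates in waves, carrying the 5 highest-posterior trees of a wave
forward (every accepted tree still enters the final ranking); every
accepted operation raises the clone count by one and clones have a minimum
size, so the search terminates. The 10 best candidates are post-processed —
cells re-assigned to their maximum-posterior node with genotypes fixed (an
EM-style ascent whose posterior never decreases), cell-free gain-free nodes
contracted — and the 3 best are refined further before the final
maximum-posterior pick. Beam width, splits per operation and the
post-processing pool are package defaults chosen to keep a 1000-cell ×
5000-SNV instance around a minute on one core; widening them buys a more
exhaustive search at linear cost.

**Arrangement refinement.** Greedy top-down growth cannot revisit a split,
so it sometimes delivers the right clones in the wrong arrangement — a
truly ancestral clone parked as a sibling, or a parent-child pair nested
upside down — even though the posterior, which scores genotype nesting,
prefers the correct arrangement. Two ascent-only repairs run on the top
candidates before the final ranking. With the cell partition fixed, the
embedding term and node-count prior are constant over arrangements and the
SNV term decomposes into per-clone column sums, so for up to 6 clones
*every* rooted arrangement of the clones under an optional cell-free root
(`(k+1)^(k-1)` labeled trees, enumerated via Prüfer sequences) is scored
exactly and the argmax kept if it improves the posterior. For larger trees
a local search applies four structure moves — promote a clone's cells into
an empty parent, invert a parent-child pair, re-attach a node under a
sibling, hoist a node to its grandparent — re-attaching the two affected
nodes' SNVs after each move and keeping only strict posterior improvements;
since no move changes the cell partition, each trial costs two sparse
column-sums.

## Hyperparameters

| name | default | meaning |
| --- | --- | --- |
| `alpha` | 0.001 | per-base sequencing error probability |
| `max_copies` (`c`) | 5 | maximum total copies at a locus; genotype-1 states `(x, y)`, `1 ≤ x ≤ y ≤ c` |
| `threshold` (`t`) | 5 | detection threshold: mean covering cells per introduced SNV, and mean absence observations per demoted SNV |
| `qc` | 0.025 | quality-check bound on the median outside-clade mutational burden |
| `restarts` | 15 | seeded restarts per elementary operation |
| `max_iter` | 50 | coordinate-descent iteration cap per operation |
| `min_clone_size` | `max(10, 0.01 n)` | smallest admissible clone |
| `embedding_dim` (`ℓ`) | 10 | principal axes kept in the embedding |

`t` couples clone size, coverage and gain-set size: a clone of `s` cells at
coverage `g` covers each of its SNVs in about `s·g·(copies/2)` cells, so at
0.05× only clones of roughly 100+ cells are detectable and raising `t` to
11 prunes aggressively — the detection limit is a property of the data, not
a removable nuisance.

## Synthetic data generator

The generator emulates current ultra-low coverage tumor scDNA-seq. A
uniform random labeled rooted tree on `k` nodes (defaults `k ∈ {5, 9}`)
carries `m` SNVs (default 5000): 30% truncal at the root, the rest spread
over non-root nodes with symmetric Dirichlet proportions. `n` cells
(default 1000) are assigned with Dirichlet proportions resampled until
every clone holds at least 2%. Each non-root edge acquires 1–3 segmental
copy-number events (gain or loss of one allele over a contiguous 2–10% of
the `b = 1000` bins, clamped to total copies in `[0, c]`); with CNAs off
every locus stays heterozygous diploid. Each SNV sits in one bin on one
allele; a carried SNV's mutated-copy count follows its allele through the
CNA history, floored at one copy so infinite sites holds in the data
(Dollo mode instead deletes each SNV on at most one descendant edge with
probability 0.05). Reads: `d_iq ~ Poisson(g·y/2)`,
`a_iq ~ Binom(d_iq, vaf')`; binned counts are Poisson with 5000 reads per
bin per 1× coverage for a diploid bin (500-kb bins at 100-bp reads). At
`g = 0.01` about 99 of every 100 diploid entries have zero depth.

What the generator does **not** emulate: GC and mappability bias or bin-level
overdispersion (bins are clean Poisson, so the copy-number signal is
stronger than in real data and embedding-based clustering — including the
Baseline — is flattered); doublets; read-level artifacts; variant-calling
errors upstream of the count matrices. Passing tests therefore demonstrate
correctness of the method under its own generative assumptions, not
performance on any particular real dataset.

## Evaluation

Pair metrics classify every unordered item pair (cells or SNVs placed on
tree nodes) as clustered / ancestral / incomparable; APR, IPR, CPR are the
per-class recalls against the ground truth, orientation-sensitive for
ancestral pairs, and accuracy is their truth-pair-count weighted average
(empty classes excluded; counting is grouped by label pairs, so it scales
with the number of distinct node pairs rather than item pairs). Genotype
similarity is 1 minus the normalized Hamming distance between true and
inferred cell-level genotype matrices. The cell mutational burden
CMB(i, M) = (# loci of M with a variant read in cell i) / (# covered loci)
is undefined for cells covering no locus of M; undefined values are
excluded from summaries, not imputed. The Baseline genotyper clusters cells
on the embedding alone (HDBSCAN, minimum cluster size `max(10, 0.01 n)`,
outliers joined to the nearest centroid; k-means when the cluster count is
fixed) and sets `y = 1` when the pooled alternate/total ratio strictly
exceeds 0.05.

## Numerical choices

Log-space arithmetic with log-sum-exp for the copy-state marginalization;
binomial log-pmfs via `betaln`, vectorized over the few distinct `(a, d)`
pairs of sparse data. Posterior-ascent assertions use a 1e-9 tolerance.
Ties in SNV attachment (e.g. zero-coverage SNVs) go to the shallowest
candidate node, matching the uniform attachment prior. The pairwise-distance
median is subsampled deterministically above 20k pairs. All randomness
flows from a single integer seed (restart `r` uses `seed + r`); identical
inputs and seed reproduce the output bit for bit.

## Known limitations

- Top-down recursion cannot revisit a committed split; the multi-split
  candidate set mitigates but does not eliminate early-commitment errors,
  which surface as reduced ancestral-pair recall on cells.
- No explicit placement of CNA events on the tree; the embedding only
  guides the clustering.
- The inference model assumes infinite sites; Dollo-generated data is
  handled only in the sense of robustness, losses are never inferred.
- Clones below the detection limit (`≈ t/g` cells) are absorbed into their
  ancestors by design.
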