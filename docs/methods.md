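# Methods

## The model

Given an expression matrix *E* over genes *G* = {g₁,…,gₙ} and samples
*S* = {s₁,…,sₘ}, a bicluster *b* = (*G′*, *S′*) is a gene subset together
with a sample subset on which every member gene is coherently — here:
uniformly highly or uniformly lowly — expressed, and significantly more so
inside *S′* than outside.  The pipeline has four stages.

### 1. Binarization

Entries of *E* are taken to be log2 ratios against a reference.  A
fold-change cut-off *c* > 1 (default 2) produces two boolean matrices: the
up-regulation matrix marks entries with value ≥ log2 *c*, the
down-regulation matrix entries with value ≤ −log2 *c*.  Missing entries
binarize to 0 (absence of evidence of regulation) and are never imputed.
Matrices that arrive already binarized (e.g. gene-set membership tables,
where a 1 means "gene affected under this perturbation/pathway") bypass
thresholding entirely (`as_given`).

*E* is assumed log-scaled because the datasets this method targets
(two-channel ratio compendia, drug-perturbation profiles) are
conventionally distributed that way; `--linear` applies log2 first.

### 2. Seed discovery by maximal frequent gene-set mining

The *support* of a gene is the fraction of samples on which its binary row
is 1; the support of a gene set is the support of its *phenotype vector*,
the elementwise AND of the member rows.  A gene set is (c1, c2)-frequent
when its support reaches c1 and its cardinality reaches c2, and *maximal*
when no strict superset is frequent.  Support is anti-monotone — every
subset of a frequent set is frequent — which is what makes lattice pruning
sound.

The miner does a depth-first traversal of the gene-set lattice over a
static support-descending gene order, with two prunings: candidate genes
whose conjunction with the current head drops below the support count are
removed from the tail, and a subtree whose head∪tail is contained in an
already-recorded maximal set is abandoned.  Sample sets are machine-word
bitmasks (Python ints), so a support count is one popcount.  An exhaustive
enumerator over all 2ⁿ gene subsets (n ≤ 20) with the identical contract
serves as the oracle in the tests.

Seeds are found by running the miner repeatedly: the first threshold is the
highest single-gene support; after each round all genes of the found
maximal sets are deleted from the working matrix, and the next threshold is
the highest single-gene support still present (strictly below the previous
threshold when that value is exhausted).  This "distinct-support descent"
is the laziest schedule consistent with starting at the maximum support and
guarantees progress; a geometric schedule (threshold × 0.9 per round) is
available as `schedule="decay"`.  The loop stops when the threshold would
fall below the user-set minimum support (default 0.05) or no genes remain.
Seed gene sets are therefore pairwise disjoint.  Each seed's phenotype
vector is computed on the **original** matrix and is frozen from then on.

### 3. Extension and filtering

For each seed with phenotype vector *C* (n_in member samples), every gene
is scored by a one-sided Fisher exact test on the 2×2 table of (gene bit) ×
(phenotype bit): with σ₁,IN the gene's 1-count inside the bicluster samples
and K its total 1-count, p = P(X ≥ σ₁,IN) for X hypergeometric(M=m, K,
N=n_in).  Seed genes with p > α are deleted; other genes with p < α are
added; p = α exactly changes nothing.  One-sidedness is a deliberate
choice: a two-sided independence test would admit genes significantly
*depleted* in the bicluster, contradicting the requirement that member
genes be regulated on all bicluster samples.  The sample set is never
recomputed during extension — only the gene dimension mutates.

Most genes never need the test.  The tail is monotone in both margins
(non-increasing in σ₁,IN at fixed σ₁,OUT, non-decreasing in σ₁,OUT at fixed
σ₁,IN), so two cut-offs are precomputed per phenotype: min σ₁,IN, the
largest count whose best case (all ones inside) still has p > α, and max
σ₁,OUT, the smallest outside count at which even full inside coverage has
p > α.  Only genes with σ₁,IN > min σ₁,IN and σ₁,OUT < max σ₁,OUT are
tested; every skipped gene provably has p > α (this soundness is asserted
directly in the tests).  At α = 1 the cut-offs degenerate (min σ₁,IN = −1)
so that nothing is skipped.

Bicluster *size* is |genes| × |samples|; the overlap area of two biclusters
is |common genes| × |common samples|.  Filtering is greedy largest-first:
walk the collection in size order (ties by discovery order) and delete any
bicluster whose overlap with an already-kept one strictly exceeds L × its
own size (default L = 0.5).  Up- and down-regulation runs are concatenated
before filtering, so the two directions compete in one pool.

### 4. Scoring and the choice of α

A bicluster's raw score is I = −Σ_g ln p_g over its member genes.  I grows
with size, so it is normalized by its randomization expectation: 500 (by
default) random phenotype vectors with the same number of member samples
are drawn without replacement, the member genes are re-tested against each,
and E[I] is the mean random score.  NI = I / E[I]; a bicluster sampled at
random from a background matrix has NI ≈ 1, a planted block has NI ≫ 1.
If E[I] = 0 (every random p-value is 1 — the member rows are uninformative)
NI is defined as 0 with a warning.  The total score CS of a bicluster set
is Σ NI.

α is selected by running the whole pipeline per grid value and keeping the
CS-maximizing α (ties go to the smaller α; if no α yields any bicluster the
largest is returned with a warning).  Seed discovery does not depend on α
and is done once per direction.  The default grid is {10⁻², 10⁻⁴, 10⁻⁸,
10⁻¹⁶, 10⁻³², 10⁻⁶⁴, 10⁻¹⁰⁰}: CS is slowly varying in log α, and the dense
grid 10⁻²…10⁻¹⁰⁰ (available as `FULL_ALPHA_GRID` / `--alpha-grid full`)
costs ~14× more for the same argmax in every case we examined.  Each α is
scored by a generator freshly seeded from the run seed, so results do not
depend on grid order; draws are not shared across α values.

## Synthetic benchmark

The generator emulates the classic implanted-bicluster design: a zero
background (100 genes × 50 samples by default) with ten 10×5 elevated
blocks tiled along the diagonal.  Two block models: *constant* (every block
cell at level 2.0 on the log2 scale, i.e. 4-fold up) and *additive* (level
plus per-row and per-column offsets drawn uniformly from [0, level/2], so
expression varies over conditions while every cell stays above the
fold-change-2 threshold — a threshold method could not recover the truth
otherwise).  Stress axes: i.i.d. Gaussian noise with σ = noise × level
added to the whole matrix (or, in binary output mode, independent bit flips
with probability = noise), and an overlap degree d that shifts consecutive
blocks so adjacent truth biclusters share exactly d genes and d samples.
Everything is deterministic per seed.

What the generator does **not** emulate: correlated noise between samples,
down-regulated or sign-mixed blocks, probe-level artifacts, non-block
expression structure, and realistic background expression variation.
Passing the recovery tests therefore demonstrates correct mechanics and
noise robustness of the thresholding/mining/extension chain, not
performance on real compendia.

Recovered sets are scored two ways:

* **recovery** — mean over implanted biclusters of the best Jaccard
  similarity on the gene dimension to any found bicluster (and its
  transpose, **relevance**, averaging over found).  Insensitive to the
  number of found biclusters.
* **consensus** — Jaccard similarity on (gene, sample) cell sets, maximized
  by an exact one-to-one assignment (Hungarian algorithm via
  `scipy.optimize.linear_sum_assignment`) and divided by the size of the
  larger collection, penalizing over- and under-segmentation.  Both sets
  empty scores 1; exactly one empty scores 0.

The benchmark driver runs generate → full pipeline (α selected per run,
overlap filtering at L = 0.25) → both scores, one row per scenario ×
replicate.

## Numerical choices

* Supports are rationals k/m compared as integer counts; the fraction
  thresholds c1 and min_support are applied with a 10⁻¹² slack so a support
  exactly equal to the threshold counts as frequent despite float
  representation.
* Cardinality "reaches c2" is inclusive (≥ c2) by default — the exclusive
  reading would make c2 = 1 forbid singletons — with a
  `strict_cardinality` flag for the other convention.
* Miner output is canonically ordered (descending support, then
  lexicographic gene indices) for determinism.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, memoized on
  (σ₁,IN, K, n_in, M) and vectorized over unique pairs; the tests check
  them against independent exact enumeration with integer binomial
  coefficients to 10⁻¹².
* The overlap-filter comparison `overlap > L × smaller` uses a 10⁻⁹
  absolute slack so exact rational boundaries (e.g. L = 0.5 of an even
  size) are not decided by float rounding.
* Degenerate inputs: an all-zero matrix yields an empty seed list; a
  degenerate phenotype (all or no samples) gives p = 1 everywhere and the
  bicluster is dropped; the empty gene set has no phenotype (AND over
  nothing) and is rejected.

## Problem sizes used in the tests

Unit and property tests run on matrices up to 20×16; miner/oracle
equivalence uses 100 random matrices up to 12×12 across c1 ∈ {0.2, 0.4,
0.6} and c2 ∈ {1, 2}.  The recovery benchmark in the acceptance tests and
`scripts/acceptance.py` uses the full default scenario (ten 10×5 blocks in
100×50) with noise levels {0, 0.05, 0.10}, ten replicates per level per
block model, α selected over the default grid, and 500 randomization
replicates per bicluster score — 60 full pipeline runs in total, which
complete in a few seconds.

## Known limitations

* The overlap scenario shows the method's documented weakness: shared
  block parts surface as separate biclusters and both scores drop well
  below their no-overlap values; the tests assert the direction of this
  effect, not a magnitude.
* The threshold schedule visits only single-gene support values; gene
  *sets* whose joint support lies strictly between visited thresholds and
  the minimum support can only be found once the schedule descends past
  their support.
* No multiple-testing correction is applied across genes during extension;
  α itself is the globally tuned quantity.
* Mining cost grows with matrix density; the bitmask DFS is built for the
  sparse post-binarization regime and has no guarantees on dense matrices.
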