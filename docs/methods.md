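# Methods

This note documents the models and procedures implemented in `ccvtyper`,
the parameter choices that matter, the numerical conventions, and what the
synthetic validation does and does not demonstrate.

## Sequence representation

### Alphabet contract

Input residues are uppercased on read; alignment gap characters (`-`, `.`)
are stripped because the composition-vector representation consumes
ungapped sequence; RNA is folded into the DNA alphabet (`U → T`) so a
single 4-letter k-mer space serves both nucleic-acid types. IUPAC ambiguity
codes (`N`, `R`, `Y`, …) are kept in the record, but any k-mer window
containing one is excluded from counting: there is no defensible frequency
model for an ambiguous symbol, and dropping the window biases p(α) less
than spreading fractional counts would. The window total `L − k + 1` (the
denominator of p) is *not* reduced by skipped windows, so probabilities sum
to slightly less than one for sequences with ambiguity codes — a
deliberate, documented property rather than a renormalization.

### Composition values

For k-mer α of order k ≥ 3:

- observed: `p(α) = f(α) / (L − k + 1)`;
- expected under a second-order Markov background:
  `q(α) = p(prefix) · p(suffix) / p(middle)`, where prefix/suffix are the
  two (k−1)-mers of α and middle is its central (k−2)-mer;
- composition value: `π(α) = p/q − 1` when q > 0, else 0.

The q = 0 → π = 0 branch can only fire for substrings absent from the
sequence (any observed α has all its substrings observed), so stored values
are always finite. Vectors are stored sparsely — only observed substrings —
because the realized fraction of the 4^k (or 20^k) space is tiny for k up
to 9.

The complete composition vector concatenates orders k = 3..M. **M = 9** is
the default order ceiling: beyond it, k-mers in gene-sized sequences are
nearly all unique (p ≈ 1/(L−k+1) for every observed k-mer) and contribute
noise rather than signal, while the memory cost grows linearly in L per
order.

### Background and feature selection

The background vector Π is the CCV of the pooled dataset. Pooling is
per-sequence — counts and window totals are summed, windows never span two
sequences — which equals "concatenate everything" minus the chimeric
boundary windows, and makes two identities exact: a single-sequence
dataset's background is its own CCV, and duplicating a sequence leaves the
background unchanged.

Revised relative entropy scores each substring's information content
across the dataset:

    RE(α) = Σᵢ π(α, i) · ln( π(α, i) / Π(α) )

Composition values can be negative or zero, so the log is guarded: a term
contributes 0 when π(α,i) = 0, Π(α) = 0, or the ratio is non-positive. The
guard keeps RE finite, preserves the identity RE ≡ 0 when every sequence
equals the background (each term is ln 1), and in practice fires on a small
minority of (sequence, substring) pairs whose observed and expected
deviations disagree in sign. Substrings with |RE| < 1.0 are dropped;
**1.0** is the default cutoff and a single global threshold is applied
across all orders k, matching the single-cutoff design of the scoring
scheme.

A substring retained by the filter but absent from a particular sequence
enters that sequence's row as π = 0 by default. The alternative reading —
absence means p = 0 against a positive expectation, i.e. π = −1 — is
available as `absent_pi="minus-one"`; on held-out data the two conventions
rescale mostly-absent columns differently, but on the planted-structure
validation they do not change cluster recovery.

### Normalization

Retained columns are z-scored with the **population** standard deviation
(this is a normalization, not an estimate of a population parameter; the
sample/population choice rescales every column by the same factor
√(n/(n−1)) and so cannot change cosine or relative Euclidean structure).
Columns with zero variance carry no between-sample information and are
dropped and logged. After normalization every surviving column has mean 0
and unit variance to 1e−9.

## Distances

- **Cosine** (default): `D = (1 − C)/2` with C the cosine similarity of
  the two rows, so D ∈ [0, 1]. This scaling is what makes the clustering
  similarity `s = 1 − D = (1 + C)/2` increase monotonically with C.
- **Euclidean**: the ordinary ℓ₂ distance over retained columns.

The matrix is computed in fixed-size row chunks (128 rows); a worker count
> 1 parallelizes across those same chunks with threads. Because chunk
boundaries do not depend on the worker count and every cell is written
once, the output is byte-identical for any worker setting. Exact symmetry
and the zero diagonal are enforced by mirroring the upper triangle.

Text interchange uses 6-decimal fixed point (PHYLIP convention): PHYLIP
square (count line, then name + n values per row) and a packed
strictly-lower-triangle dialect (`n label0` header, then row i holding
label_i and D(i, 0..i−1)) suited to streaming neighbour joining. Write →
read round trips are exact to 5e−7 and a second write is byte-stable.

## Genotyping by affinity propagation

Similarities: `s = 1 − D` for cosine (and would-be Manhattan input is
accepted as `s = −D` alongside Euclidean). Affinity propagation exchanges
responsibility and availability messages:

    r(i,k) = s(i,k) − max_{k'≠k} [ a(i,k') + s(i,k') ]
    a(i,k) = min(0, r(k,k) + Σ_{i'∉{i,k}} max(0, r(i',k)))   (i ≠ k)
    a(k,k) = Σ_{i'≠k} max(0, r(i',k))

damped by λ = 0.9 (new = λ·old + (1−λ)·update), for up to 1000 sweeps,
declaring convergence when the exemplar set {k : r(k,k) + a(k,k) > 0} is
unchanged for 100 consecutive sweeps. These defaults mirror the reference
implementation of the algorithm. After message passing terminates, each
cluster's exemplar is re-elected as the member maximizing the intra-cluster
similarity sum and points are reassigned to their most similar exemplar —
the refinement step of the reference implementation. Without it, message
passing regularly parks an exemplar on a non-medoid cluster member; with
it, the returned exemplar set matches an exhaustive search over all
exemplar subsets (maximizing net similarity
Σᵢ s(i, exemplar(i)) + K·preference) on every tested instance of two tight,
widely separated groups.

Determinism: no noise is added, and argmax ties break toward the lowest
index, so identical inputs give identical results across runs and
platforms. The price is that *exactly* tied similarities (literally
duplicated points) make the symmetric all-exemplar configuration a stable
fixed point that messages cannot escape; the documented `--jitter ε --seed
N` option adds tiny seeded noise for such degenerate inputs, at the cost of
bit-reproducibility. If no point ends with positive self-evidence, the
single best point by r + a becomes the exemplar and the run is flagged
non-converged (K ≥ 1 always holds).

### Preference selection

The shared scalar preference is swept over **four equally spaced values
from the minimum to the median off-diagonal similarity** (inclusive
endpoints — the span recommended for low-to-moderate cluster counts), and
the run with the highest mean silhouette wins; ties prefer fewer clusters,
then the lower preference. Silhouettes use the distance matrix:
`s(i) = (bᵢ − aᵢ)/max(aᵢ, bᵢ)` with aᵢ the mean within-cluster distance
and bᵢ the smallest mean distance to another cluster. Conventions where
the formula is silent: a singleton cluster scores s(i) = 0, and a
single-cluster partition receives the sentinel mean −1 so it can never win
model selection. If every off-diagonal similarity is equal, the sweep
degenerates to a single preference and warns.

Per-point preferences (for the "some exemplars are known" scenario) are
accepted by the low-level API but the sweep operates on scalars.

### Composite genotypes

For segmented genomes, each sample's per-segment cluster labels form a
tuple in fixed segment order; distinct tuples are numbered 1..G by first
appearance. Samples sharing a tuple share a whole-genome genotype.

## Neighbour joining

Canonical Saitou–Nei agglomeration with the Studier–Keppler criterion
`Q(i,j) = (n−2)·D(i,j) − Σₖ D(i,k) − Σₖ D(j,k)`, branch lengths
`lᵢ = D(i,j)/2 + (rᵢ − rⱼ)/(2(n−2))`, `lⱼ = D(i,j) − lᵢ`, and reduction
`D(u,m) = (D(i,m) + D(j,m) − D(i,j))/2`. Ties in min Q break toward the
lexicographically smallest index pair of the working matrix. The final
three nodes join at a trifurcating root (the tree is unrooted); for n = 2
the single observed distance is split evenly between the two leaves — any
split is consistent with one observation, so the 50/50 convention is
documented rather than derived. Negative branch lengths (possible on
non-additive input) are preserved by default; `--clamp-negative` sets them
to 0.

The implementation is O(n³) with cached row sums; the removed row/column is
overwritten in place by the last active one, so one n×n workspace serves
the whole run. Packed lower-triangle matrices are accepted directly. On
additive matrices NJ provably recovers the generating tree, and the
patristic distances of the output reproduce the input to 1e−9 — this
additivity theorem is the module's main oracle. Trees are dendropy objects:
Newick serialization (full float precision, labels quoted when they contain
reserved characters) and leaf-to-leaf path sums reuse dendropy; the
agglomeration itself is implemented here, with dendropy's own NJ serving
as an independent topology cross-check in the tests.

## Validation measures

- **Adjusted Rand Index** (Hubert–Arabie): chance-corrected pair-count
  agreement from the contingency table; expected 0 under independence,
  1 for identical partitions, invariant to label permutation. When both
  partitions are trivial (max index equals expected index) the value is
  defined as 1.
- **Patristic comparison**: for two trees on the same leaves, every
  unordered leaf pair contributes a point (d_a, d_b); Pearson correlation
  (default — a linear relationship is the criterion of interest) or
  Spearman via a flag.

## Synthetic data

The generator evolves a uniform-random root sequence down a star-of-stars
tree: g group ancestors diverge from the root at the between-group rate,
then each leaf diverges from its ancestor at the within-group rate.
Substitutions are i.i.d. per site with a uniform choice among the
alternative residues (Jukes–Cantor-like); branch lengths of the returned
true tree are the rates themselves (expected substitutions per site). The
standard validation conditions are **4 groups × 10 sequences × 1000 bp,
within-rate 0.01, between-rate 0.15** — comfortably below DNA saturation
(0.75) and separated enough that genotype recovery should be exact, which
is precisely what the acceptance checks assert.

What this does *not* emulate: insertions/deletions and rearrangements
(which the alignment-free representation is designed to tolerate but the
generator never produces), reassortment, rate heterogeneity across sites or
lineages, and base-composition skew. Passing the planted-structure checks
therefore demonstrates correctness of the pipeline's machinery under a
clean substitution model, not robustness to every artifact of real
surveillance data. The star-of-stars topology is chosen for planted-truth
clarity; random binary trees (with uniform [0.1, 2) branch lengths) are
used separately to exercise neighbour-joining additivity.

The affinity-propagation optimality check uses a separate instance family:
two tight 2-D point groups (radius 0.5, 3–5 points each, centers ≥ 10
apart, n ≤ 8) under Euclidean similarity with the preference at the median
off-diagonal similarity. Group sizes ≥ 3 matter: with a preference on the
between-group similarity scale, deleting a 2-point group's exemplar is
nearly net-neutral, so the global optimum sits on a knife edge that no
message-passing scheme resolves reliably — and an agreement check against
exhaustive search is only meaningful where the optimum is robust.

## Problem sizes and runtime

The shipped validation runs at desk scale by design: 15–40 sequences of
0.6–1 kb for end-to-end genotyping (a full pipeline run takes about a
second), n ≤ 16 for tree recovery, n ≤ 8 for the exhaustive
affinity-propagation oracle (subset enumeration is exponential). The
implementation itself handles larger inputs — the distance stage chunks
rows, and NJ's in-place O(n³) loop with packed input is intended for
matrices in the thousands of leaves.

## Known limitations

- The RE guard (zeroing non-positive-ratio terms) is one defensible
  resolution of a formula whose literal reading is undefined for negative
  composition values; alternative conventions would select slightly
  different feature sets near the threshold.
- Exactly tied similarities require jitter to cluster sensibly (see
  above); real sequence data essentially never produces exact ties.
- Affinity propagation is a heuristic: outside well-separated regimes the
  preference sweep can return different K across metrics, and lowering the
  preference is not guaranteed to lower K monotonically.
- Protein support treats the 20-letter alphabet sparsely but applies the
  same DNA-derived defaults (M = 9, |RE| ≥ 1.0); no protein-specific
  calibration is shipped.
- The CLI accepts one FASTA per segment and assumes segment files share
  sample identifiers for composite genotyping.
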